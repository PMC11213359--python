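"""Simulate a trajectory, hide some observations, and encode it three ways.

Shows what the summary network actually receives: E1 fills missing entries
with a dummy constant, E2 additionally appends the 0/1 availability column,
and E3 keeps only available rows labelled with their time points.
"""

import numpy as np

import flowmiss as fm

model = fm.default_model("conversion_reaction")  # B(t) observed at t = 0, 5, 10
rng = np.random.default_rng(0)

theta = np.array([-0.98, -0.66])  # (ln k1, ln k2)
x = fm.add_noise(fm.simulate(theta, model), model.noise_sd, rng)
print("complete noisy trajectory:", np.round(x.values[:, 0], 3))

mask = np.array([1, 0, 1])  # the middle observation is missing
x_obs = fm.apply_mask(x, mask)
print("with missing entry:       ", np.round(x_obs.values[:, 0], 3))

print("\nE1 (insert c=-1):\n", fm.encode_E1(x_obs, c=-1.0).matrix)
print("\nE2 (insert + 0/1 indicator):\n", fm.encode_E2(x_obs, c=-1.0).matrix)
print("\nE3 (available rows + time labels):\n", fm.encode_E3(x_obs).matrix)
print("\nE2 keeps a fixed shape for any mask; E3 drops rows, so its row count")
print("equals the number of available observations:", x_obs.n_available)
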