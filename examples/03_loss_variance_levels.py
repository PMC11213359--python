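"""Why the number of missing points should be sampled per sample, not per batch.

Uses the sinusoid model with variable-length series (trailing missingness,
lengths 2..41).  After a short warm-up training, the loss is evaluated on 500
fresh batches under both sampling levels.  Sharing one missingness level per
batch leaves the loss mean unchanged (unbiased) but inflates its variance
across batches — the fluctuation that destabilizes gradient descent.
Runs in about half a minute.
"""

import numpy as np

import flowmiss as fm
from flowmiss.networks import ArchConfig
from flowmiss.training import TrainConfig, loss_variance_experiment, train_online

model = fm.default_model("sinusoid")
prior = fm.default_prior("sinusoid")
config = TrainConfig(
    epochs=2, iterations_per_epoch=100, encoding="E2", c=-5.0,
    missingness={"kind": "trailing", "n_min": 2}, level="per_sample",
    arch=ArchConfig(lstm_hidden=32), seed=42,
)
amortizer, _ = train_online(model, prior, config)  # warm-up, then freeze

res = loss_variance_experiment(
    amortizer, model, prior, config, n_batches=500, rng=np.random.default_rng(7)
)
print(f"loss mean  per-sample: {res['mean_per_sample']:.4f}   per-batch: {res['mean_per_batch']:.4f}")
print(f"loss var   per-sample: {res['variance_per_sample']:.4f}   per-batch: {res['variance_per_batch']:.4f}")
print(f"variance inflation from batch-level sampling: "
      f"{res['variance_per_batch'] / res['variance_per_sample']:.1f}x")
print("the means agree (the estimator stays unbiased); only the variance differs")
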