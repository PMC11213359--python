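"""Amortized posterior sampling and posterior predictive checks.

Once trained, drawing posterior samples for a new incomplete dataset costs
no model simulations at all: the observed data are encoded and summarized
once, and standard-normal latent draws are pushed through the flow in the
inverse direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amortizer import Amortizer
from .errors import ConfigurationError, SimulationError
from .missingness import IncompleteData, encode_E1, encode_E2, encode_E3
from .models import ModelSpec, add_noise, simulate

__all__ = ["PosteriorSamples", "sample_posterior", "posterior_predictive", "encode_observed"]


@dataclass
class PosteriorSamples:
    """L x n_theta posterior draws with provenance."""

    theta: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if t.shape[0] < 1 or not np.all(np.isfinite(t)):
            raise ConfigurationError("posterior samples must be a non-empty finite matrix")
        self.theta = t

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]


def encode_observed(x_obs: IncompleteData, amortizer: Amortizer) -> np.ndarray:
    """Encode observed data exactly as during training; refuse on mismatch."""
    if x_obs.mask.size != amortizer.time_grid.size or not np.allclose(
        x_obs.time_grid, amortizer.time_grid
    ):
        raise ConfigurationError(
            "observed data grid does not match the grid the networks were trained on"
        )
    if amortizer.encoding == "E1":
        return encode_E1(x_obs, amortizer.c).matrix
    if amortizer.encoding == "E2":
        return encode_E2(x_obs, amortizer.c).matrix
    return encode_E3(x_obs, amortizer.time_grid).matrix


def sample_posterior(
    x_obs: IncompleteData,
    amortizer: Amortizer,
    n_samples: int = 2000,
    rng: np.random.Generator | None = None,
) -> PosteriorSamples:
    """Draw ``n_samples`` from the amortized posterior pi(theta | x_avai).

    The summary vector is computed once; each latent z ~ N(0, I) is mapped
    through the inverse flow and de-standardized to the prior scale.
    """
    if rng is None:
        rng = np.random.default_rng()
    x_aug = encode_observed(x_obs, amortizer)
    if x_aug.shape[0] == 0:  # all entries missing under E3
        h = np.zeros((1, amortizer.summary.hidden))
    else:
        h = amortizer.summary.forward_np(x_aug[None, :, :])
    z = rng.standard_normal((n_samples, amortizer.n_theta))
    theta_std = amortizer.flow.inverse_np(z, np.repeat(h, n_samples, axis=0))
    theta = amortizer.destandardize(theta_std)
    if not np.all(np.isfinite(theta)):
        raise ConfigurationError("flow produced non-finite posterior draws")
    return PosteriorSamples(
        theta,
        provenance={
            "encoding": amortizer.encoding,
            "n_available": int(x_obs.n_available),
            "model": amortizer.meta.get("model"),
        },
    )


def posterior_predictive(
    samples: PosteriorSamples,
    model: ModelSpec,
    n_draws: int,
    rng: np.random.Generator,
) -> dict:
    """Re-simulate noisy trajectories for the first ``n_draws`` posterior rows.

    Returns the trajectory ensemble, its pointwise mean, and the central 90%
    credible band (5% / 95% quantiles).
    """
    if n_draws > samples.n_samples:
        raise ConfigurationError("n_draws exceeds the number of posterior samples")
    trajs = []
    failures = []
    for i in range(n_draws):
        try:
            x = simulate(samples.theta[i], model, rng)
            trajs.append(add_noise(x, model.noise_sd, rng).values)
        except SimulationError as err:
            failures.append((i, str(err)))
    if not trajs:
        raise SimulationError(f"all {n_draws} predictive simulations failed: {failures}")
    ensemble = np.stack(trajs)
    return {
        "ensemble": ensemble,
        "mean": ensemble.mean(axis=0),
        "lower": np.quantile(ensemble, 0.05, axis=0),
        "upper": np.quantile(ensemble, 0.95, axis=0),
        "failures": failures,
    }
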