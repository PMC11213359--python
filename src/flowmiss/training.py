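"""Monte-Carlo loss and the online training loop.

Each iteration simulates a fresh batch: draw parameters from the prior,
simulate complete noisy data, sample an availability mask, mask, encode,
summarize, and push the (standardized) parameters through the flow.  The
objective is the Monte-Carlo estimate of the negative conditional
log-likelihood of the flow,

    L = (1/M) sum_m [ 1/2 ||f(theta_m; h(x_m))||^2 - log |det J_m| ],

minimized jointly over flow and summary parameters with Adam, cosine
learning-rate decay and global-norm gradient clipping.  Online simulation
means every batch is new, so there is no training set to overfit.

The number of missing entries can be drawn per sample or once per batch.
Per-batch sampling (required by the variable-row-count E3 encoding) couples
all samples in a batch to one missingness level, which leaves the loss
estimate unbiased but inflates its across-batch variance;
:func:`loss_variance_experiment` measures exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amortizer import Amortizer
from .autodiff import Tensor
from .errors import ConfigurationError, TrainingError
from .missingness import encode_batch, mask_trailing, sample_mask_uniform, _place_zeros
from .models import ModelSpec, PriorSpec, simulate_batch
from .networks import ArchConfig, init_networks

__all__ = ["TrainConfig", "LossHistory", "loss_batch", "train_online", "loss_variance_experiment", "sample_masks"]


@dataclass(frozen=True)
class TrainConfig:
    """Training-run configuration (defaults are the desk-scale budget)."""

    epochs: int = 30
    iterations_per_epoch: int = 200
    batch_size: int = 64
    encoding: str = "E2"
    c: float | None = -1.0
    missingness: dict = field(default_factory=lambda: {"kind": "uniform", "n_missing_max": 2})
    level: str = "per_sample"  # per_sample | per_batch
    lr_initial: float = 5e-4
    lr_final: float = 1e-5
    grad_clip: float = 5.0
    arch: ArchConfig = ArchConfig()
    seed: int | None = None

    def __post_init__(self):
        if self.batch_size < 2 or self.epochs < 1 or self.iterations_per_epoch < 1:
            raise ConfigurationError("need batch_size >= 2 and positive epochs/iterations")
        if self.encoding not in ("E1", "E2", "E3"):
            raise ConfigurationError(f"unknown encoding {self.encoding!r}")
        if self.level not in ("per_sample", "per_batch"):
            raise ConfigurationError(f"unknown sampling level {self.level!r}")
        if self.encoding == "E3" and self.level != "per_batch":
            raise ConfigurationError(
                "E3 produces variable row counts; the number of missing entries "
                "must be sampled once per batch (level='per_batch')"
            )
        kind = self.missingness.get("kind")
        if kind not in ("uniform", "trailing", "param"):
            raise ConfigurationError(f"unknown missingness mechanism {kind!r}")
        if kind == "param" and self.encoding == "E3":
            raise ConfigurationError("parameter-dependent missingness needs a fixed-shape encoding")


@dataclass
class LossHistory:
    per_iteration: np.ndarray
    iterations_per_epoch: int

    @property
    def epoch_averages(self) -> np.ndarray:
        return self.per_iteration.reshape(-1, self.iterations_per_epoch).mean(axis=1)


def loss_batch(theta, x_aug, flow, summary, standardizer=None) -> Tensor:
    """Differentiable scalar Monte-Carlo loss for one batch.

    ``theta`` is (M, n_theta) on the prior scale; ``standardizer`` is an
    optional (mean, std) pair applied before the flow.  ``x_aug`` is the
    (M, T, W) encoded data batch.
    """
    theta = np.asarray(theta, dtype=float)
    if standardizer is not None:
        mean, std = standardizer
        theta = (theta - mean) / std
    h = summary.forward(np.asarray(x_aug, dtype=float))
    z, logdet = flow.forward(Tensor(theta), h)
    return ((z * z).sum(axis=1) * 0.5 - logdet).mean()


def sample_masks(config: TrainConfig, theta: np.ndarray, n_x: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the batch's availability masks under the configured mechanism."""
    m = theta.shape[0]
    miss = config.missingness
    kind = miss["kind"]
    if kind == "uniform":
        return sample_mask_uniform(n_x, miss["n_missing_max"], rng, config.level, m)
    if kind == "trailing":
        n_min = miss.get("n_min", 1)
        if config.level == "per_sample":
            lengths = rng.integers(n_min, n_x + 1, size=m)
        else:
            lengths = np.full(m, rng.integers(n_min, n_x + 1))
        return np.stack([mask_trailing(n_x, int(n)) for n in lengths])
    # parameter-dependent: the portion of missing values is a model parameter
    p = theta[:, miss["p_index"]]
    counts = np.floor(p * n_x).astype(int)
    return _place_zeros(n_x, counts, rng)


def _input_width(encoding: str, d_obs: int) -> int:
    return d_obs if encoding == "E1" else d_obs + 1


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8, clip=5.0):
        self.params = params
        self.beta1, self.beta2, self.eps, self.clip = beta1, beta2, eps, clip
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.v) for p in self.params]
        if self.clip is not None:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if norm > self.clip:
                grads = [g * (self.clip / norm) for g in grads]
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, s in zip(self.params, grads, self.m, self.s):
            m *= self.beta1
            m += (1 - self.beta1) * g
            s *= self.beta2
            s += (1 - self.beta2) * g * g
            p.v = p.v - lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)


def train_online(
    model: ModelSpec,
    prior: PriorSpec,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
    callback=None,
) -> tuple[Amortizer, LossHistory]:
    """Joint online training of flow and summary network.

    Fully reproducible given ``config.seed`` (or the passed generator).
    Aborts with :class:`TrainingError` after 10 consecutive non-finite
    losses; isolated non-finite batches are skipped without an update.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arch = config.arch
    flow, summary = init_networks(prior.n_theta, _input_width(config.encoding, model.d_obs), arch, rng)
    amor = Amortizer(
        flow=flow,
        summary=summary,
        encoding=config.encoding,
        c=config.c,
        time_grid=model.time_grid,
        theta_mean=prior.mean,
        theta_std=prior.std,
        meta={"model": model.name, "missingness": config.missingness, "level": config.level},
    )
    params = list(amor.params().values())
    opt = Adam(params, clip=config.grad_clip)
    total = config.epochs * config.iterations_per_epoch
    history = np.empty(total)
    standardizer = (amor.theta_mean, amor.theta_std)
    bad_streak = 0
    for it in range(total):
        lr = config.lr_final + 0.5 * (config.lr_initial - config.lr_final) * (
            1 + np.cos(np.pi * it / max(total - 1, 1))
        )
        theta, values = simulate_batch(model, prior, config.batch_size, rng)
        masks = sample_masks(config, theta, model.n_x, rng)
        x_aug = encode_batch(values, masks, config.encoding, config.c, model.time_grid)
        for p in params:
            p.grad = None
        loss = loss_batch(theta, x_aug, flow, summary, standardizer)
        val = float(loss.v)
        if not np.isfinite(val):
            bad_streak += 1
            if bad_streak >= 10:
                raise TrainingError(f"non-finite loss for {bad_streak} consecutive batches at iteration {it}")
            history[it] = history[it - 1] if it else np.nan
            continue
        bad_streak = 0
        loss.backward()
        opt.step(lr)
        history[it] = val
        if callback is not None:
            callback(it, val)
    return amor, LossHistory(history, config.iterations_per_epoch)


def loss_variance_experiment(
    amortizer: Amortizer,
    model: ModelSpec,
    prior: PriorSpec,
    config: TrainConfig,
    n_batches: int,
    rng: np.random.Generator,
) -> dict:
    """Across-batch loss mean/variance under the two mask-sampling levels.

    The networks are frozen (forward evaluation only).  Per-sample sampling
    averages over missingness levels inside every batch; per-batch sampling
    shares one level per batch, adding between-batch variance while leaving
    the mean unchanged.
    """
    out = {}
    standardizer = (amortizer.theta_mean, amortizer.theta_std)
    for level in ("per_sample", "per_batch"):
        cfg_level = TrainConfig(
            epochs=config.epochs,
            iterations_per_epoch=config.iterations_per_epoch,
            batch_size=config.batch_size,
            encoding=config.encoding,
            c=config.c,
            missingness=config.missingness,
            level=level,
            arch=config.arch,
        )
        losses = np.empty(n_batches)
        for i in range(n_batches):
            theta, values = simulate_batch(model, prior, config.batch_size, rng)
            masks = sample_masks(cfg_level, theta, model.n_x, rng)
            x_aug = encode_batch(values, masks, config.encoding, config.c, model.time_grid)
            losses[i] = float(loss_batch(theta, x_aug, amortizer.flow, amortizer.summary, standardizer).v)
        out[f"mean_{level}"] = float(losses.mean())
        out[f"variance_{level}"] = float(losses.var(ddof=1))
        out[f"se_{level}"] = float(losses.std(ddof=1) / np.sqrt(n_batches))
    return out
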