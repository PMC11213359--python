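"""Availability masks, masking, and the three missing-data encodings.

An availability mask ``tau`` in {0,1}^n_x marks which time points of a
trajectory were observed (1) or are missing (0).  Incomplete data carry an
explicit NaN sentinel at masked rows; the sentinel never reaches a network
input.  Three encodings turn incomplete data into purely numeric arrays:

* E1 ("insert c") — replace each missing entry by a constant dummy value c.
* E2 ("augment by 0/1") — as E1, plus the mask appended as a trailing binary
  indicator column; the output shape is independent of how much is missing.
* E3 ("time labels") — keep only available rows and append each row's actual
  time point as a positional label; the row count varies with the mask.

Time series of variable length embed into this scheme as trailing
missingness: a series of length ``n`` inside a maximal grid of length
``n_max`` is a mask with ones in the first ``n`` positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "IncompleteData",
    "AugmentedData",
    "sample_mask_uniform",
    "sample_mask_param_dependent",
    "mask_trailing",
    "apply_mask",
    "encode_E1",
    "encode_E2",
    "encode_E3",
    "decode_E2",
    "encode_batch",
]

ENCODINGS = ("E1", "E2", "E3")


@dataclass(frozen=True)
class IncompleteData:
    """Trajectory with missing rows marked by NaN; mask has 1 where observed."""

    values: np.ndarray  # (n_x, d_obs), NaN at masked rows
    mask: np.ndarray  # (n_x,) in {0,1}
    time_grid: np.ndarray

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[0] == 1 and np.asarray(self.mask).size > 1:
            v = v.T
        tau = np.asarray(self.mask, dtype=np.int8)
        if tau.ndim != 1 or v.shape[0] != tau.size:
            raise ConfigurationError("mask length must match the number of time points")
        if not np.all((tau == 0) | (tau == 1)):
            raise ConfigurationError("mask entries must be 0 or 1")
        nan_rows = np.any(np.isnan(v), axis=1)
        if not np.array_equal(nan_rows, tau == 0):
            raise ConfigurationError("NaN rows must coincide exactly with mask zeros")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", tau)

    @property
    def n_available(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class AugmentedData:
    """Numeric encoder output fed to the summary network."""

    encoding: str  # E1 | E2 | E3
    matrix: np.ndarray  # E1: (n_x, d); E2: (n_x, d+1); E3: (sum tau, d+1)

    def __post_init__(self):
        if self.encoding not in ENCODINGS:
            raise ConfigurationError(f"unknown encoding {self.encoding!r}")
        m = np.asarray(self.matrix, dtype=float)
        if np.any(np.isnan(m)):
            raise ConfigurationError("encoded data must not contain missing markers")
        object.__setattr__(self, "matrix", m)


# --------------------------------------------------------------------------
# mask mechanisms
# --------------------------------------------------------------------------


def _place_zeros(n_x: int, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Masks (len(counts), n_x) with counts[i] zeros placed uniformly w/o replacement."""
    # argsort of uniforms gives a uniform random permutation per row
    order = np.argsort(rng.random((counts.size, n_x)), axis=1)
    masks = np.ones((counts.size, n_x), dtype=np.int8)
    cols = np.arange(n_x)[None, :] < counts[:, None]
    rows = np.repeat(np.arange(counts.size), counts)
    masks[rows, order[cols]] = 0
    return masks


def sample_mask_uniform(
    n_x: int,
    n_missing_max: int,
    rng: np.random.Generator,
    level: str = "per_sample",
    batch_size: int = 1,
) -> np.ndarray:
    """MCAR masks: zero-count uniform on {0..n_missing_max}, positions uniform.

    ``level='per_sample'`` draws an independent zero-count for every mask;
    ``level='per_batch'`` draws one shared zero-count for the whole batch
    (zero positions remain sample-specific).  Returns (batch_size, n_x).
    """
    if not 0 <= n_missing_max <= n_x:
        raise ConfigurationError(f"n_missing_max must be in [0, {n_x}], got {n_missing_max}")
    if level == "per_sample":
        counts = rng.integers(0, n_missing_max + 1, size=batch_size)
    elif level == "per_batch":
        counts = np.full(batch_size, rng.integers(0, n_missing_max + 1))
    else:
        raise ConfigurationError(f"unknown sampling level {level!r}")
    return _place_zeros(n_x, counts, rng)


def sample_mask_param_dependent(p: float, n_x: int, rng: np.random.Generator) -> np.ndarray:
    """Mask with exactly floor(p * n_x) zeros at uniform positions; (n_x,)."""
    if not 0.0 <= p < 1.0:
        raise ConfigurationError(f"missingness parameter p must be in [0, 1), got {p}")
    n_missing = int(np.floor(p * n_x))
    return _place_zeros(n_x, np.array([n_missing]), rng)[0]


def mask_trailing(n_x_max: int, n_x_actual: int) -> np.ndarray:
    """Embed a length-``n_x_actual`` series: ones then trailing zeros."""
    if not 1 <= n_x_actual <= n_x_max:
        raise ConfigurationError(f"need 1 <= n_x_actual <= {n_x_max}, got {n_x_actual}")
    mask = np.zeros(n_x_max, dtype=np.int8)
    mask[:n_x_actual] = 1
    return mask


# --------------------------------------------------------------------------
# masking and encoding
# --------------------------------------------------------------------------


def apply_mask(x, tau: np.ndarray) -> IncompleteData:
    """x_avai = x (.) tau + NA (.) (1 - tau): NaN where tau is 0."""
    tau = np.asarray(tau)
    values = np.array(x.values, dtype=float, copy=True)
    if tau.shape != (values.shape[0],):
        raise ConfigurationError("mask length must equal the number of time points")
    values[tau == 0, :] = np.nan
    return IncompleteData(values, tau, x.time_grid)


def encode_E1(x_avai: IncompleteData, c: float) -> AugmentedData:
    """Insert the dummy value c in place of every missing entry."""
    if not np.isfinite(c):
        raise ConfigurationError("dummy value c must be finite")
    filled = np.where(np.isnan(x_avai.values), float(c), x_avai.values)
    return AugmentedData("E1", filled)


def encode_E2(x_avai: IncompleteData, c: float) -> AugmentedData:
    """As E1, plus the availability mask as a trailing 0/1 column."""
    filled = encode_E1(x_avai, c).matrix
    return AugmentedData("E2", np.column_stack([filled, x_avai.mask.astype(float)]))


def encode_E3(x_avai: IncompleteData, time_grid: np.ndarray | None = None) -> AugmentedData:
    """Available rows only, each labelled with its actual time point."""
    t = np.asarray(time_grid if time_grid is not None else x_avai.time_grid, dtype=float)
    keep = x_avai.mask == 1
    return AugmentedData("E3", np.column_stack([x_avai.values[keep], t[keep]]))


def decode_E2(aug: AugmentedData, time_grid: np.ndarray) -> IncompleteData:
    """Invert E2 via its indicator column (the encoding is lossless)."""
    if aug.encoding != "E2":
        raise ConfigurationError("decode_E2 expects an E2 encoding")
    tau = aug.matrix[:, -1].astype(np.int8)
    values = np.array(aug.matrix[:, :-1], copy=True)
    values[tau == 0, :] = np.nan
    return IncompleteData(values, tau, time_grid)


def encode_batch(
    values: np.ndarray,
    masks: np.ndarray,
    encoding: str,
    c: float | None = None,
    time_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized encoder for a simulated batch.

    ``values`` is (M, n_x, d_obs) *complete* data and ``masks`` is (M, n_x);
    masking and encoding happen in one step (no NaN ever materializes).
    E3 requires all masks in the batch to share one zero-count and returns
    (M, sum tau, d_obs + 1).
    """
    m, n_x, d = values.shape
    tau = masks.astype(float)[:, :, None]
    if encoding in ("E1", "E2"):
        if c is None or not np.isfinite(c):
            raise ConfigurationError("E1/E2 require a finite dummy value c")
        filled = values * tau + float(c) * (1.0 - tau)
        if encoding == "E1":
            return filled
        return np.concatenate([filled, tau], axis=2)
    if encoding == "E3":
        counts = masks.sum(axis=1)
        if not np.all(counts == counts[0]):
            raise ConfigurationError("E3 batches require a shared number of missing entries")
        if time_grid is None:
            raise ConfigurationError("E3 requires the time grid for positional labels")
        keep = masks == 1
        n_keep = int(counts[0])
        kept_vals = values[keep].reshape(m, n_keep, d)
        labels = np.broadcast_to(np.asarray(time_grid, float), (m, n_x))[keep].reshape(m, n_keep, 1)
        return np.concatenate([kept_vals, labels], axis=2)
    raise ConfigurationError(f"unknown encoding {encoding!r}")
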