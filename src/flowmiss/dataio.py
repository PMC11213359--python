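"""CSV / HDF5 interchange for observed data, masks, samples and batches."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .missingness import IncompleteData

__all__ = [
    "read_observed_csv",
    "write_observed_csv",
    "write_mask_csv",
    "write_samples_csv",
    "export_batch_hdf5",
]


def read_observed_csv(path) -> IncompleteData:
    """Read an observed incomplete dataset.

    Expected columns: ``time`` then one or more value columns; empty cells
    mark missing observations.  A row is missing iff any of its value cells
    is empty (masking is per time point).
    """
    df = pd.read_csv(path)
    if "time" not in df.columns or df.shape[1] < 2:
        raise ConfigurationError("observed CSV needs a 'time' column and at least one value column")
    time_grid = df["time"].to_numpy(dtype=float)
    values = df.drop(columns="time").to_numpy(dtype=float)
    mask = (~np.any(np.isnan(values), axis=1)).astype(np.int8)
    values[mask == 0, :] = np.nan
    return IncompleteData(values, mask, time_grid)


def write_observed_csv(path, x_obs: IncompleteData) -> None:
    cols = {"time": x_obs.time_grid}
    for j in range(x_obs.values.shape[1]):
        cols[f"value{j + 1}" if x_obs.values.shape[1] > 1 else "value"] = x_obs.values[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_mask_csv(path, masks: np.ndarray) -> None:
    """Masks as 0/1 columns, one column per mask."""
    masks = np.atleast_2d(masks)
    pd.DataFrame(masks.T.astype(int), columns=[f"mask{i + 1}" for i in range(masks.shape[0])]).to_csv(
        path, index=False
    )


def write_samples_csv(path, theta: np.ndarray, names=None) -> None:
    theta = np.atleast_2d(theta)
    names = names or [f"theta{i + 1}" for i in range(theta.shape[1])]
    pd.DataFrame(theta, columns=list(names)).to_csv(path, index=False)


def export_batch_hdf5(path, theta: np.ndarray, values: np.ndarray, time_grid: np.ndarray) -> None:
    """Simulated batch (parameters + trajectories) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("theta", data=theta)
        f.create_dataset("values", data=values)
        f.create_dataset("time_grid", data=time_grid)
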