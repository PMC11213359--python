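"""Trained-network bundle and checkpoint persistence.

An :class:`Amortizer` carries everything needed to reproduce posterior
samples: the flow, the summary network, the data-encoding configuration
(encoding tag, dummy value, time grid) and the parameter standardization
constants.  Inference refuses to run if the observed data do not match the
encoding the networks were trained with — a silent mismatch would produce
posteriors for a different conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .autodiff import Tensor
from .errors import ConfigurationError
from .networks import ArchConfig, ConditionalFlow, LSTMSummary

__all__ = ["Amortizer", "save_checkpoint", "load_checkpoint"]


@dataclass
class Amortizer:
    flow: ConditionalFlow
    summary: LSTMSummary
    encoding: str  # E1 | E2 | E3
    c: float | None  # dummy value (E1/E2)
    time_grid: np.ndarray
    theta_mean: np.ndarray  # standardization under the prior
    theta_std: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_theta(self) -> int:
        return self.flow.n_theta

    def params(self) -> dict[str, Tensor]:
        return {**self.flow.params(), **self.summary.params()}

    def standardize(self, theta: np.ndarray) -> np.ndarray:
        return (theta - self.theta_mean) / self.theta_std

    def destandardize(self, theta_std: np.ndarray) -> np.ndarray:
        return theta_std * self.theta_std + self.theta_mean


def save_checkpoint(path, amortizer: Amortizer) -> None:
    """Write all network parameters + configuration to an HDF5 file."""
    arch = amortizer.flow.arch
    with h5py.File(path, "w") as f:
        f.attrs["encoding"] = amortizer.encoding
        f.attrs["c"] = np.nan if amortizer.c is None else float(amortizer.c)
        f.attrs["n_theta"] = amortizer.flow.n_theta
        f.attrs["input_width"] = amortizer.summary.d_in
        f.attrs["arch"] = json.dumps(
            {
                "n_coupling_layers": arch.n_coupling_layers,
                "st_hidden": list(arch.st_hidden),
                "lstm_hidden": arch.lstm_hidden,
                "clamp_alpha": arch.clamp_alpha,
            }
        )
        f.attrs["meta"] = json.dumps(amortizer.meta)
        f.create_dataset("time_grid", data=amortizer.time_grid)
        f.create_dataset("theta_mean", data=amortizer.theta_mean)
        f.create_dataset("theta_std", data=amortizer.theta_std)
        f.create_dataset("perms", data=np.array(amortizer.flow.perms, dtype=np.int64))
        grp = f.create_group("params")
        for name, tensor in amortizer.params().items():
            grp.create_dataset(name, data=tensor.v)


def load_checkpoint(path) -> Amortizer:
    """Bit-exact reconstruction of a saved bundle."""
    with h5py.File(path, "r") as f:
        arch_d = json.loads(f.attrs["arch"])
        arch = ArchConfig(
            n_coupling_layers=int(arch_d["n_coupling_layers"]),
            st_hidden=tuple(arch_d["st_hidden"]),
            lstm_hidden=int(arch_d["lstm_hidden"]),
            clamp_alpha=float(arch_d["clamp_alpha"]),
        )
        rng = np.random.default_rng(0)  # placeholder init, overwritten below
        flow = ConditionalFlow(int(f.attrs["n_theta"]), arch.lstm_hidden, rng, arch)
        summary = LSTMSummary(int(f.attrs["input_width"]), arch.lstm_hidden, rng)
        flow.perms = [np.array(p) for p in f["perms"][...]]
        amor = Amortizer(
            flow=flow,
            summary=summary,
            encoding=str(f.attrs["encoding"]),
            c=None if np.isnan(f.attrs["c"]) else float(f.attrs["c"]),
            time_grid=f["time_grid"][...],
            theta_mean=f["theta_mean"][...],
            theta_std=f["theta_std"][...],
            meta=json.loads(f.attrs["meta"]),
        )
        stored = f["params"]
        for name, tensor in amor.params().items():
            if name not in stored:
                raise ConfigurationError(f"checkpoint is missing parameter {name!r}")
            tensor.v = stored[name][...]
    return amor
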