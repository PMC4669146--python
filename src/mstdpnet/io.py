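"""HDF5 checkpoints and CSV spike export."""

from __future__ import annotations

from pathlib import Path

import h5py

from .homeostasis import HomeostasisState
from .network import SpikeRecord, WeightState

__all__ = ["save_checkpoint", "load_checkpoint", "spikes_to_csv"]


def save_checkpoint(
    path: str | Path,
    weights: WeightState,
    homeo: HomeostasisState,
    n_done: int = 0,
    meta: dict | None = None,
):
    """Persist weights and homeostatic state (datasets W, Q, scale, A)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=weights.W)
        f.create_dataset("Q", data=weights.Q)
        f.create_dataset("scale", data=homeo.scale)
        f.create_dataset("A", data=homeo.activity)
        f.attrs["weight_mode"] = weights.mode
        f.attrs["homeo_mode"] = homeo.mode
        f.attrs["rho"] = homeo.rho
        f.attrs["kappa"] = homeo.kappa
        f.attrs["ema_decay"] = homeo.ema_decay
        f.attrs["n_done"] = int(n_done)
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def load_checkpoint(path: str | Path) -> tuple[WeightState, HomeostasisState, int, dict]:
    with h5py.File(path, "r") as f:
        weights = WeightState(f["W"][...], f["Q"][...], str(f.attrs["weight_mode"]))
        homeo = HomeostasisState(
            str(f.attrs["homeo_mode"]),
            f["scale"][...],
            f["A"][...],
            rho=float(f.attrs["rho"]),
            kappa=float(f.attrs["kappa"]),
            ema_decay=float(f.attrs["ema_decay"]),
        )
        n_done = int(f.attrs["n_done"])
        meta = {
            k: f.attrs[k]
            for k in f.attrs
            if k not in ("weight_mode", "homeo_mode", "rho", "kappa", "ema_decay", "n_done")
        }
    return weights, homeo, n_done, meta


def spikes_to_csv(record: SpikeRecord, path: str | Path):
    """Write spike events as CSV rows: population, neuron_id, time_ms."""
    lines = ["population,neuron_id,time_ms"]
    for pop in ("visible", "hidden", "visible_inh", "hidden_inh"):
        for i, train in enumerate(getattr(record, pop)):
            for t in train:
                lines.append(f"{pop},{i},{t:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
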