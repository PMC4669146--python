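"""Deterministic test assets: bar stimulus sets, frozen Poisson spike
records, and tiny pre-initialized networks.

Bars are the canonical toy set: every stimulus is one horizontal or
vertical bar on an otherwise empty grid, so a grid of size g has exactly
2g distinct stimuli and each is reconstructable from a sparse hidden
code -- the same learning problem as the full-scale image experiments at
desk scale.  All assets regenerate bit-identically from their parameters
and seed; nothing needs to be stored.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .homeostasis import HomeostasisState
from .network import SpikeRecord, WeightState
from .stimuli import RawStimulus, Stimulus, preprocess, split_on_off

__all__ = [
    "BarsDataset",
    "make_bars_dataset",
    "make_frozen_spike_records",
    "spike_record_checksum",
    "make_toy_network",
]


@dataclass
class BarsDataset:
    """Bar stimuli ready for presentation, with their latent labels.

    stimuli : ON/OFF rate vectors (mean-subtracted, split)
    labels : tuples of bar identities; bar k < grid is row k, otherwise
        column k - grid
    raw : the unprocessed images
    mean : per-pixel mean of the single-bar set used for preprocessing
    grid : grid side length
    """

    stimuli: list[Stimulus]
    labels: list[tuple[int, ...]]
    raw: list[RawStimulus]
    mean: np.ndarray
    grid: int

    @property
    def n_vis(self) -> int:
        return 2 * self.grid * self.grid


def _bar_image(grid: int, bar: int) -> np.ndarray:
    img = np.zeros((grid, grid))
    if bar < grid:
        img[bar, :] = 1.0
    else:
        img[:, bar - grid] = 1.0
    return img


def make_bars_dataset(
    grid: int = 8, seed: int = 0, include_two_bar: bool = False
) -> BarsDataset:
    """All 2*grid single-bar stimuli (plus optional two-bar superpositions),
    mean-subtracted against the single-bar set mean and ON/OFF split."""
    if grid < 4:
        raise ValueError("grid must be >= 4")
    singles = [_bar_image(grid, b) for b in range(2 * grid)]
    mean = np.mean([img.ravel() for img in singles], axis=0)

    raw: list[RawStimulus] = [RawStimulus(img) for img in singles]
    labels: list[tuple[int, ...]] = [(b,) for b in range(2 * grid)]
    if include_two_bar:
        for r in range(grid):
            for c in range(grid):
                img = np.clip(_bar_image(grid, r) + _bar_image(grid, grid + c), 0, 1)
                raw.append(RawStimulus(img))
                labels.append((r, grid + c))

    stimuli = [split_on_off(preprocess(r, mean)) for r in raw]
    return BarsDataset(stimuli=stimuli, labels=labels, raw=raw, mean=mean, grid=grid)


def make_frozen_spike_records(
    n_vis: int,
    n_hid: int,
    rate: float,
    duration: float,
    count: int,
    seed: int,
) -> list[SpikeRecord]:
    """Seeded Poisson spike records (visible + hidden populations only),
    for plasticity oracle and regression tests.

    ``rate`` is in spikes/ms per neuron over ``duration`` ms.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(count):
        def trains(n: int) -> list[np.ndarray]:
            out = []
            for _ in range(n):
                if rate == 0:
                    out.append(np.empty(0))
                    continue
                n_spk = rng.poisson(rate * duration)
                out.append(np.sort(rng.uniform(0, duration, size=n_spk)))
            return out

        records.append(SpikeRecord(visible=trains(n_vis), hidden=trains(n_hid)))
    return records


def spike_record_checksum(record: SpikeRecord) -> str:
    """Stable hash of a spike record (times rounded to 1e-9 ms)."""
    h = hashlib.sha256()
    for pop in ("visible", "hidden", "visible_inh", "hidden_inh"):
        for train in getattr(record, pop):
            h.update(np.round(np.asarray(train, dtype=float), 9).tobytes())
            h.update(b"|")
        h.update(b"#")
    return h.hexdigest()


def make_toy_network(
    n_vis: int,
    n_hid: int,
    mode: str = "nonneg",
    seed: int = 0,
    init_scale: float = 0.04,
    rho: float = 0.05,
    kappa: float = 0.05,
) -> tuple[WeightState, HomeostasisState]:
    """Small reproducible network state for unit tests.

    mode "nonneg": uniform weights on [0, init_scale], multiplicative
    homeostasis.  mode "signed": uniform on [-init_scale, init_scale],
    additive homeostasis.  mode "symmetric": non-negative with Q = W^T
    (tied weights from the start).
    """
    if n_vis > 1024:
        raise ValueError("toy networks are capped at 1024 visible units")
    rng = np.random.default_rng(seed)
    if mode == "signed":
        W = rng.uniform(-init_scale, init_scale, size=(n_vis, n_hid))
        Q = rng.uniform(-init_scale, init_scale, size=(n_hid, n_vis))
        weights = WeightState(W, Q, "signed")
        homeo = HomeostasisState.initial(n_hid, "additive", rho=rho, kappa=kappa)
    elif mode in ("nonneg", "symmetric"):
        W = rng.uniform(0, init_scale, size=(n_vis, n_hid))
        Q = W.T.copy() if mode == "symmetric" else rng.uniform(0, init_scale, size=(n_hid, n_vis))
        weights = WeightState(W, Q, "nonneg")
        homeo = HomeostasisState.initial(n_hid, "multiplicative", rho=rho, kappa=kappa)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return weights, homeo
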