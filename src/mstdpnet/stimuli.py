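"""Stimulus preprocessing and spike encoding.

Raw images are mean-subtracted, which leaves signed pixel values, and then
split into paired ON/OFF channels carrying the positive and negative parts
as non-negative rates (the retinal ON/OFF-cell strategy: twice as many
visible neurons as pixels, all with non-negative drive).  Rates are turned
into external input spike trains by homogeneous Poisson sampling over a
brief stimulation window at the start of each trial.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RawStimulus",
    "Stimulus",
    "EncodingParams",
    "preprocess",
    "split_on_off",
    "contrast_filter",
    "poisson_encode",
    "generate_synthetic_stimuli",
    "read_idx_images",
    "read_idx_labels",
    "downsample_2x2",
    "save_stimuli",
    "load_stimuli",
]


@dataclass(frozen=True)
class RawStimulus:
    """A 2-D image of real-valued intensities, before any preprocessing."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Stimulus:
    """Non-negative ON/OFF rate vector of length 2P driving the visible layer.

    The first P entries are the ON channel (positive part of the signed
    stimulus), the last P the OFF channel (negative part).
    """

    rates: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 1 or r.size % 2 != 0:
            raise ValueError("rates must be a 1-D vector of even length")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite and non-negative")
        object.__setattr__(self, "rates", r)

    @property
    def n_pixels(self) -> int:
        return self.rates.size // 2

    @property
    def on_half(self) -> slice:
        return slice(0, self.n_pixels)

    @property
    def off_half(self) -> slice:
        return slice(self.n_pixels, 2 * self.n_pixels)

    def signed(self) -> np.ndarray:
        """Recover the signed stimulus, ON minus OFF (the split is lossless)."""
        return self.rates[self.on_half] - self.rates[self.off_half]


@dataclass(frozen=True)
class EncodingParams:
    """Poisson encoding of rates into external input spikes.

    rate_scale : spikes/second generated by a unit-intensity pixel.  The
        default gives roughly 5-10 spikes per stimulation window for a
        unit pixel, matching the magnitude of the initial activity bout.
    stimulus_duration : length of the external stimulation window in ms.
        External drive ends here; the trial itself runs longer so that
        feedforward and feedback activity can play out.
    """

    rate_scale: float = 800.0
    stimulus_duration: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")


def preprocess(raw: RawStimulus, dataset_mean: np.ndarray) -> np.ndarray:
    """Mean-subtract and flatten an image to a signed vector (row-major)."""
    mean = np.asarray(dataset_mean, dtype=float).ravel()
    flat = raw.pixels.ravel()
    if mean.size != flat.size:
        raise ValueError(
            f"dataset_mean has length {mean.size}, expected {flat.size}"
        )
    return flat - mean


def split_on_off(signed: np.ndarray) -> Stimulus:
    """Split a signed vector into non-negative ON/OFF rate channels."""
    v = np.asarray(signed, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("signed input must be finite")
    return Stimulus(np.concatenate([np.maximum(0.0, v), np.maximum(0.0, -v)]))


def contrast_filter(signed_patch: np.ndarray, threshold: float = 0.06) -> bool:
    """True iff the patch has enough contrast to be worth presenting.

    The criterion is that the mean of the ON/OFF rate vector -- equivalently
    the mean absolute signed value -- is at least ``threshold``.  Low-contrast
    patches drive the visible layer only weakly, evoke no hidden spikes, and
    therefore produce no learning.
    """
    v = np.asarray(signed_patch, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty patch")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return bool(np.mean(np.abs(v)) >= threshold)


def poisson_encode(
    stim: Stimulus,
    params: EncodingParams,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Sample homogeneous Poisson spike trains for each visible neuron.

    Neuron i fires at rate ``stim.rates[i] * params.rate_scale`` (spikes/s)
    over ``[0, params.stimulus_duration]`` ms.  Returns one strictly
    increasing array of spike times (ms) per visible neuron.  Identical
    seed and input give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    duration = params.stimulus_duration
    trains: list[np.ndarray] = []
    for rate in stim.rates:
        if rate < 0:
            raise ValueError("negative rate")
        r_ms = rate * params.rate_scale * 1e-3  # spikes per ms
        if r_ms == 0:
            trains.append(np.empty(0))
            continue
        # cumulative exponential gaps guarantee strictly increasing times
        expected = r_ms * duration
        n_draw = max(8, int(expected + 6 * np.sqrt(expected) + 10))
        times = np.cumsum(rng.exponential(1.0 / r_ms, size=n_draw))
        while times[-1] <= duration:  # pragma: no cover - rare tail top-up
            extra = np.cumsum(rng.exponential(1.0 / r_ms, size=n_draw))
            times = np.concatenate([times, times[-1] + extra])
        trains.append(times[times < duration])
    return trains


def generate_synthetic_stimuli(
    kind: str, grid_size: int, count: int, seed: int
) -> list[RawStimulus]:
    """Generate toy images with known latent structure.

    kinds:
      ``bars``    -- one horizontal or vertical bar at unit intensity
      ``blobs``   -- one Gaussian blob at a random centre
      ``strokes`` -- a short unit-intensity line segment
    """
    if grid_size < 4:
        raise ValueError("grid_size must be >= 4")
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[RawStimulus] = []
    if kind == "bars":
        for _ in range(count):
            img = np.zeros((grid_size, grid_size))
            idx = rng.integers(2 * grid_size)
            if idx < grid_size:
                img[idx, :] = 1.0
            else:
                img[:, idx - grid_size] = 1.0
            out.append(RawStimulus(img))
    elif kind == "blobs":
        yy, xx = np.mgrid[0:grid_size, 0:grid_size]
        sigma = grid_size / 8.0
        for _ in range(count):
            cy, cx = rng.uniform(0, grid_size - 1, size=2)
            img = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            out.append(RawStimulus(img))
    elif kind == "strokes":
        length = max(2, grid_size // 2)
        for _ in range(count):
            img = np.zeros((grid_size, grid_size))
            y, x = rng.integers(grid_size, size=2)
            dy, dx = [(0, 1), (1, 0), (1, 1), (1, -1)][rng.integers(4)]
            for step in range(length):
                py, px = y + step * dy, x + step * dx
                if 0 <= py < grid_size and 0 <= px < grid_size:
                    img[py, px] = 1.0
            out.append(RawStimulus(img))
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    return out


# --- optional readers for the two experiments' native formats -------------


def read_idx_images(path: str | Path) -> np.ndarray:
    """Read an IDX image file (big-endian, magic 2051) -> (n, h, w) floats in [0,1]."""
    data = Path(path).read_bytes()
    magic, n, h, w = struct.unpack(">iiii", data[:16])
    if magic != 2051:
        raise ValueError(f"bad IDX image magic {magic}")
    arr = np.frombuffer(data, dtype=np.uint8, offset=16).reshape(n, h, w)
    return arr.astype(float) / 255.0


def read_idx_labels(path: str | Path) -> np.ndarray:
    """Read an IDX label file (big-endian, magic 2049)."""
    data = Path(path).read_bytes()
    magic, n = struct.unpack(">ii", data[:8])
    if magic != 2049:
        raise ValueError(f"bad IDX label magic {magic}")
    return np.frombuffer(data, dtype=np.uint8, offset=8).copy()


def downsample_2x2(pixels: np.ndarray) -> np.ndarray:
    """Down-sample an image by 2x2 block averaging (e.g. 28x28 -> 14x14)."""
    px = np.asarray(pixels, dtype=float)
    h, w = px.shape
    if h % 2 or w % 2:
        raise ValueError("image dimensions must be even")
    return px.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def save_stimuli(path: str | Path, stimuli: Sequence[Stimulus], meta: dict | None = None):
    """Persist stimuli as an HDF5 matrix plus a JSON provenance sidecar."""
    import h5py

    path = Path(path)
    mat = np.stack([s.rates for s in stimuli])
    with h5py.File(path, "w") as f:
        f.create_dataset("stimuli", data=mat)
    sidecar = dict(meta or {})
    sidecar.update({"count": len(stimuli), "length": int(mat.shape[1])})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_stimuli(path: str | Path) -> list[Stimulus]:
    import h5py

    with h5py.File(path, "r") as f:
        mat = f["stimuli"][...]
    return [Stimulus(row) for row in mat]
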