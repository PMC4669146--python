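"""Evaluation quantities: reconstruction loss, sparsity loss, weight
symmetry, hidden-unit correlations, and receptive-field rendering.

The reconstruction loss is 1 minus the mean Pearson correlation between
each test input rate vector nu and the feedback excitation Q^T z it
evokes (z = hidden spike counts); it lives in [0, 2] and is invariant to
positive rescaling of the feedback weights.  The sparsity loss is the
squared deviation of the activation fractions A_j from the target rho,
normalized by rho^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MetricsHistory",
    "pearson",
    "reconstruction_loss",
    "sparsity_loss",
    "symmetry_correlation",
    "hidden_correlations",
    "render_receptive_fields",
    "save_receptive_field_grid",
]


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


def reconstruction_loss(
    test_inputs: Sequence[np.ndarray],
    feedback: Sequence[np.ndarray],
    return_detail: bool = False,
):
    """1 - mean Pearson correlation between inputs and their feedback
    excitation.

    Pairs where either vector is constant (e.g. a stimulus that evoked no
    hidden spikes, so Q^T z is all zero) have undefined correlation; they
    contribute 0 -- worst-case-neutral -- and are counted.  With
    ``return_detail`` the count of such degenerate pairs is returned too.
    """
    if len(test_inputs) != len(feedback):
        raise ValueError("input and feedback lists must have equal length")
    if len(test_inputs) == 0:
        raise ValueError("empty test set")
    corrs = []
    n_degenerate = 0
    for nu, fb in zip(test_inputs, feedback):
        nu = np.asarray(nu, dtype=float)
        fb = np.asarray(fb, dtype=float)
        if nu.shape != fb.shape:
            raise ValueError("dimension mismatch between input and feedback")
        c = pearson(nu, fb)
        if np.isnan(c):
            c = 0.0
            n_degenerate += 1
        corrs.append(c)
    loss = 1.0 - float(np.mean(corrs))
    if return_detail:
        return loss, n_degenerate
    return loss


def sparsity_loss(A: np.ndarray, rho: float) -> float:
    """||A - rho||^2 / rho^2 summed over hidden units."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or np.any(A > 1):
        raise ValueError("activation fractions must lie in [0, 1]")
    return float(np.sum((A - rho) ** 2) / rho**2)


def symmetry_correlation(W: np.ndarray, Q: np.ndarray) -> float:
    """Pearson correlation between vec(W) and vec(Q^T).

    1 when feedback weights are a positive multiple of the transposed
    feedforward weights (tied weights); NaN for constant matrices.
    """
    W = np.asarray(W, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if Q.shape != W.shape[::-1]:
        raise ValueError("Q must have the transposed shape of W")
    return pearson(W.ravel(), Q.T.ravel())


def hidden_correlations(
    data: np.ndarray, source: str = "weights"
) -> tuple[np.ndarray, int]:
    """All pairwise Pearson correlations between hidden units.

    source "weights": data is W (n_vis x n_hid); each unit's vector is its
    column of incoming weights.  source "spike_counts": data is
    (n_stimuli x n_hid); each unit's vector is its response profile across
    stimuli.  Pairs involving a constant vector are skipped; the skip
    count is returned alongside the values.
    """
    if source not in ("weights", "spike_counts"):
        raise ValueError("source must be 'weights' or 'spike_counts'")
    data = np.asarray(data, dtype=float)
    n_hid = data.shape[1]
    if n_hid < 2:
        raise ValueError("need at least 2 hidden units")
    vals, skipped = [], 0
    for i, j in combinations(range(n_hid), 2):
        c = pearson(data[:, i], data[:, j])
        if np.isnan(c):
            skipped += 1
        else:
            vals.append(c)
    return np.array(vals), skipped


def render_receptive_fields(
    W: np.ndarray,
    grid_shape: tuple[int, int],
    per_unit_normalize: bool = True,
) -> np.ndarray:
    """Render each hidden unit's receptive field as an ON-minus-OFF image.

    The first half of the visible rows of W is the ON channel, the second
    half the OFF channel; the field is their difference reshaped to
    ``grid_shape``.  With ``per_unit_normalize`` each field is divided by
    its largest absolute value (all-zero fields are left as zeros).
    Returns an array of shape (n_hid, height, width).
    """
    W = np.asarray(W, dtype=float)
    n_vis = W.shape[0]
    if n_vis % 2:
        raise ValueError("visible count must be even (ON/OFF doubling)")
    p = n_vis // 2
    h, w = grid_shape
    if h * w != p:
        raise ValueError("grid_shape does not match pixel count")
    fields = (W[:p] - W[p:]).T.reshape(-1, h, w)
    if per_unit_normalize:
        peaks = np.abs(fields).max(axis=(1, 2), keepdims=True)
        fields = np.where(peaks > 0, fields / np.where(peaks == 0, 1.0, peaks), 0.0)
    return fields


def save_receptive_field_grid(path: str | Path, fields: np.ndarray, n_cols: int = 8):
    """Save receptive fields as a PNG grid (diverging colormap, symmetric scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = fields.shape[0]
    n_rows = int(np.ceil(n / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(n_cols, n_rows), squeeze=False)
    for k in range(n_rows * n_cols):
        ax = axes[k // n_cols][k % n_cols]
        ax.axis("off")
        if k < n:
            vmax = max(np.abs(fields[k]).max(), 1e-12)
            ax.imshow(fields[k], cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.tight_layout(pad=0.1)
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class MetricsHistory:
    """Per-evaluation records accumulated during training."""

    records: list[dict] = field(default_factory=list)

    def append(
        self,
        presentation_index: int,
        reconstruction_loss: float,
        sparsity_loss: float,
        symmetry_correlation: float,
        mean_activation: float,
        **extra,
    ):
        rec = {
            "presentation_index": presentation_index,
            "reconstruction_loss": reconstruction_loss,
            "sparsity_loss": sparsity_loss,
            "symmetry_correlation": symmetry_correlation,
            "mean_activation": mean_activation,
        }
        rec.update(extra)
        self.records.append(rec)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path: str | Path):
        self.to_frame().to_csv(path, index=False)

    def column(self, name: str) -> np.ndarray:
        return np.array([r[name] for r in self.records])

    def __len__(self) -> int:
        return len(self.records)
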