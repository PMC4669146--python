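"""Training loop: sequential stimulus presentations with per-trial
mirrored-STDP updates and homeostatic scaling, periodic frozen-plasticity
evaluation, and HDF5 checkpointing.

Two experiment modes mirror the two image experiments:

``signed_additive``
    Weights may be positive or negative (a negative weight acts as an
    inhibitory conductance) and homeostasis uses additive synaptic
    offsets -- the idealized, bias-term-like variant.
``nonneg_multiplicative``
    Weights are clipped at zero and homeostasis uses multiplicative
    scaling factors -- the variant obeying Dale's law.

All randomness derives from one master seed, split into independent
streams for weight initialization, presentation order, per-trial Poisson
encoding, and test-image encoding.  Per-trial streams are keyed by the
presentation index, so an interrupted run resumed from a checkpoint
reproduces the uninterrupted run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import homeostasis as hstat
from .homeostasis import HomeostasisState
from .io import save_checkpoint
from .metrics import (
    MetricsHistory,
    reconstruction_loss,
    sparsity_loss,
    symmetry_correlation,
)
from .network import NetworkConfig, NeuronParams, WeightState, simulate_trial
from .plasticity import PlasticityParams, apply_trial_update, mstdp_trial_update
from .stimuli import EncodingParams, Stimulus, poisson_encode

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalResult",
    "RunawayExcitationError",
    "initialize_weights",
    "train",
    "evaluate",
    "load_config",
]

# seed-stream tags (combined with the master seed in a SeedSequence)
_STREAM_INIT = 0
_STREAM_ORDER = 1
_STREAM_ENCODE = 2
_STREAM_TEST = 3
_STREAM_TESTPICK = 4


class RunawayExcitationError(RuntimeError):
    """Raised when a trial's total spike count exceeds the configured
    ceiling, the runaway-excitation failure mode of strong recurrent
    excitation."""


@dataclass
class TrainConfig:
    mode: str  # "signed_additive" | "nonneg_multiplicative"
    n_presentations: int
    network: NetworkConfig
    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    encoding: EncodingParams = field(default_factory=EncodingParams)
    init: str = "independent"  # "symmetric" | "independent"
    init_scale: float = 0.04
    eval_every: int = 500
    test_set_size: int = 100
    master_seed: int = 0
    rho: float = 0.05
    kappa: float = 0.05
    ema_decay: float = 0.005
    runaway_factor: float = 20.0
    presentation_order: str = "random"  # "random" | "epochs"

    def __post_init__(self):
        if self.mode not in ("signed_additive", "nonneg_multiplicative"):
            raise ValueError("unknown training mode")
        if self.init not in ("symmetric", "independent"):
            raise ValueError("init must be 'symmetric' or 'independent'")
        if self.n_presentations < 0:
            raise ValueError("n_presentations must be >= 0")

    @property
    def weight_mode(self) -> str:
        return "signed" if self.mode == "signed_additive" else "nonneg"

    @property
    def homeo_mode(self) -> str:
        return "additive" if self.mode == "signed_additive" else "multiplicative"


@dataclass
class TrainResult:
    weights: WeightState
    homeostasis: HomeostasisState
    history: MetricsHistory


@dataclass
class EvalResult:
    """Frozen-plasticity evaluation over a test set.

    nu : input rate vectors, one row per test stimulus
    z : hidden spike counts per test stimulus
    feedback : feedback excitation Q^T z per test stimulus
    metrics : summary dict (reconstruction/sparsity losses, symmetry
        correlation, mean activation fraction, mean input-feedback
        correlation)
    """

    nu: np.ndarray
    z: np.ndarray
    feedback: np.ndarray
    metrics: dict


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, *key]))


def initialize_weights(config: TrainConfig) -> WeightState:
    """Draw initial weights from a uniform distribution on a small interval.

    symmetric init ties Q = (zeta/eta) * W^T exactly; independent init
    draws W and Q separately (their vectorized correlation is then near
    zero).  Non-negative mode truncates the interval at zero.
    """
    rng = _rng(config.master_seed, _STREAM_INIT)
    shape = (config.network.n_vis, config.network.n_hid)
    s = config.init_scale
    if config.weight_mode == "signed":
        draw = lambda sh: rng.uniform(-s, s, size=sh)
    else:
        draw = lambda sh: rng.uniform(0, s, size=sh)
    W = draw(shape)
    if config.init == "symmetric":
        ratio = config.plasticity.zeta / config.plasticity.eta
        Q = ratio * W.T.copy()
    else:
        Q = draw(shape[::-1])
    return WeightState(W, Q, config.weight_mode)


def _presentation_order(config: TrainConfig, n_stimuli: int) -> np.ndarray:
    rng = _rng(config.master_seed, _STREAM_ORDER)
    n = config.n_presentations
    if config.presentation_order == "random":
        return rng.integers(n_stimuli, size=n)
    reps = int(np.ceil(n / n_stimuli))
    order = np.concatenate([rng.permutation(n_stimuli) for _ in range(reps)])
    return order[:n]


def _pick_test_set(
    config: TrainConfig, dataset: Sequence[Stimulus]
) -> list[tuple[int, Stimulus]]:
    if len(dataset) <= config.test_set_size:
        return list(enumerate(dataset))
    rng = _rng(config.master_seed, _STREAM_TESTPICK)
    idx = rng.choice(len(dataset), size=config.test_set_size, replace=False)
    return [(int(i), dataset[int(i)]) for i in idx]


def evaluate(
    weights: WeightState,
    homeo: HomeostasisState,
    test_stimuli: Sequence[tuple[int, Stimulus]] | Sequence[Stimulus],
    config: TrainConfig,
    scale_boost: float = 1.0,
) -> EvalResult:
    """Present the test set with plasticity and homeostasis frozen.

    Test inputs are encoded from per-image frozen seed streams, so the
    same test stimuli produce identical spike trains at every evaluation.
    ``scale_boost`` multiplies the homeostatic factors during this
    evaluation only (e.g. 1.5 boosts every hidden unit's excitability by
    50%), recruiting hidden units that would otherwise stay subthreshold.
    """
    if len(test_stimuli) == 0:
        raise ValueError("empty test set")
    pairs = [
        item if isinstance(item, tuple) else (k, item)
        for k, item in enumerate(test_stimuli)
    ]
    h_eval = homeo.copy()
    if scale_boost != 1.0:
        h_eval.scale = h_eval.scale * scale_boost
    W_eff = hstat.effective_weights(weights.W, h_eval)
    eff = WeightState(W_eff, weights.Q.copy(), "signed")

    nus, zs, fbs = [], [], []
    for img_idx, stim in pairs:
        rng = _rng(config.master_seed, _STREAM_TEST, img_idx)
        spikes_in = poisson_encode(stim, config.encoding, rng)
        rec = simulate_trial(config.network, config.neuron, eff, spikes_in)
        z = rec.counts("hidden").astype(float)
        nus.append(stim.rates)
        zs.append(z)
        fbs.append(z @ weights.Q)  # feedback excitation Q^T z
    nu = np.stack(nus)
    z = np.stack(zs)
    fb = np.stack(fbs)

    A_test = (z > 0).mean(axis=0)
    loss, n_deg = reconstruction_loss(list(nu), list(fb), return_detail=True)
    metrics = {
        "reconstruction_loss": loss,
        "mean_input_feedback_corr": 1.0 - loss,
        "n_degenerate_pairs": n_deg,
        "sparsity_loss": sparsity_loss(A_test, homeo.rho),
        "symmetry_correlation": symmetry_correlation(weights.W, weights.Q),
        "mean_activation": float(A_test.mean()),
    }
    return EvalResult(nu=nu, z=z, feedback=fb, metrics=metrics)


def train(
    dataset: Sequence[Stimulus],
    config: TrainConfig,
    out_dir: str | Path | None = None,
    start_weights: WeightState | None = None,
    start_homeo: HomeostasisState | None = None,
    start_presentation: int = 0,
    history: MetricsHistory | None = None,
    freeze_plasticity: bool = False,
    freeze_homeostasis: bool = False,
) -> TrainResult:
    """Run sequential stimulus presentations with learning.

    Each presentation: Poisson-encode the stimulus, simulate one trial
    with homeostatically scaled effective weights, apply the
    mirrored-STDP trial update (clipped to the weight bounds), then
    update the homeostatic state from whether each hidden unit fired.
    Every ``eval_every`` presentations the test set is run with plasticity
    disabled and the metrics are appended to the history (plus a
    checkpoint if ``out_dir`` is given).

    A trial whose total spike count exceeds ``runaway_factor`` times the
    median of the first 100 trials aborts with
    :class:`RunawayExcitationError`.

    The ``start_*`` arguments resume from a checkpoint; because per-trial
    seed streams are keyed by presentation index, a resumed run is
    bit-identical to an uninterrupted one.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    weights = start_weights.copy() if start_weights is not None else initialize_weights(config)
    homeo = (
        start_homeo.copy()
        if start_homeo is not None
        else HomeostasisState.initial(
            config.network.n_hid,
            config.homeo_mode,
            rho=config.rho,
            kappa=config.kappa,
            ema_decay=config.ema_decay,
        )
    )
    history = history if history is not None else MetricsHistory()
    order = _presentation_order(config, len(dataset))
    test_set = _pick_test_set(config, dataset)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    early_totals: list[int] = []
    ceiling = np.inf

    for t in range(start_presentation, config.n_presentations):
        stim = dataset[int(order[t])]
        rng = _rng(config.master_seed, _STREAM_ENCODE, t)
        spikes_in = poisson_encode(stim, config.encoding, rng)
        W_eff = hstat.effective_weights(weights.W, homeo)
        eff = WeightState(W_eff, weights.Q, "signed")
        rec = simulate_trial(config.network, config.neuron, eff, spikes_in)

        total = rec.total_spikes()
        if t - start_presentation < 100:
            early_totals.append(total)
            if len(early_totals) == 100:
                med = float(np.median(early_totals))
                ceiling = config.runaway_factor * max(med, 1.0)
        elif total > ceiling:
            raise RunawayExcitationError(
                f"presentation {t}: {total} spikes exceeds ceiling {ceiling:.0f} "
                f"({config.runaway_factor}x median of first 100 trials)"
            )

        if not freeze_plasticity:
            dW, dQ = mstdp_trial_update(rec, weights, config.plasticity)
            apply_trial_update(weights, dW, dQ, config.plasticity)
        if not freeze_homeostasis:
            fired = rec.counts("hidden") > 0
            hstat.update_activity(homeo, fired)
            hstat.update_scaling(homeo)

        done = t + 1
        if config.eval_every > 0 and done % config.eval_every == 0:
            ev = evaluate(weights, homeo, test_set, config)
            history.append(
                presentation_index=done,
                reconstruction_loss=ev.metrics["reconstruction_loss"],
                sparsity_loss=ev.metrics["sparsity_loss"],
                symmetry_correlation=ev.metrics["symmetry_correlation"],
                mean_activation=ev.metrics["mean_activation"],
            )
            if out_dir is not None:
                save_checkpoint(
                    out_dir / "checkpoint.h5",
                    weights,
                    homeo,
                    n_done=done,
                    meta={"master_seed": config.master_seed},
                )
                history.to_csv(out_dir / "metrics.csv")

    return TrainResult(weights=weights, homeostasis=homeo, history=history)


# --- config file loading ---------------------------------------------------


def load_config(path: str | Path) -> TrainConfig:
    """Build a TrainConfig from a YAML file mirroring the dataclass layout."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    sub = {
        "network": NetworkConfig,
        "neuron": NeuronParams,
        "plasticity": PlasticityParams,
        "encoding": EncodingParams,
    }
    kwargs = {}
    for key, val in raw.items():
        if key in sub:
            kwargs[key] = sub[key](**val)
        else:
            kwargs[key] = val
    return TrainConfig(**kwargs)
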