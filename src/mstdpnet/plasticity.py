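"""Mirrored STDP: paired additive STDP / anti-Hebbian STDP updates.

Feedforward synapses (visible -> hidden) follow standard additive STDP:
a pre-synaptic (visible) spike followed by a post-synaptic (hidden) spike
potentiates, the reverse order depresses, with exponential dependence on
the timing difference and all possible spike pairs contributing.  Feedback
synapses (hidden -> visible) follow the temporally reversed rule (aSTDP).
Because the pre/post roles of the same two neurons are swapped across the
two connection directions, both rules reduce to a single kernel in terms
of visible and hidden spike times: potentiation when the hidden spike is
later.  The feedforward and feedback updates are therefore exactly
proportional (dW[i,j]/eta == dQ[j,i]/zeta), which is what keeps the
weights tied and lets the network approximate autoencoder gradient
descent.

When spikes cluster into three bouts at separations dt1 (visible->hidden)
and dt2 (hidden->late visible), the trial update collapses to the
effective rate rule  dW[i,j] = eta * (beta*x_i - gamma*xhat_i) * y_j  with
beta = exp(-dt1/tau+), gamma = exp(-dt2/tau-); and when gamma/beta equals
1/alpha this is proportional to the scaled autoencoder rule
dW[i,j] = (x_i - xhat_i/alpha) * y_j.  Both limits are provided here as
oracles (they are never used for training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SpikeRecord, TrialCounts, WeightState

__all__ = [
    "PlasticityParams",
    "EffectiveRuleParams",
    "stdp_pair_sum",
    "astdp_pair_sum",
    "mstdp_kernel",
    "mstdp_trial_update",
    "apply_trial_update",
    "effective_rule_prediction",
    "scaled_autoencoder_rule",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Learning rates and STDP time constants.

    eta : feedforward (STDP) learning rate
    zeta : feedback (aSTDP) learning rate; the tied-weight scale is
        alpha ~ zeta/eta
    tau_plus / tau_minus : potentiation / depression timescales (ms)
    w_max : magnitude bound; signed mode clips to [-w_max, w_max],
        non-negative mode to [0, w_max]
    """

    eta: float = 1e-4
    zeta: float = 1e-4
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    w_max: float = 0.2

    def __post_init__(self):
        if self.eta <= 0 or self.zeta <= 0:
            raise ValueError("learning rates must be positive")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")


@dataclass(frozen=True)
class EffectiveRuleParams:
    """Parameters of the analytic bout-timing limit of the trial update."""

    alpha: float
    dt1: float
    dt2: float
    tau_plus: float = 20.0
    tau_minus: float = 20.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def beta(self) -> float:
        return float(np.exp(-self.dt1 / self.tau_plus))

    @property
    def gamma(self) -> float:
        return float(np.exp(-self.dt2 / self.tau_minus))


def stdp_pair_sum(
    pre_spikes: np.ndarray, post_spikes: np.ndarray, params: PlasticityParams
) -> float:
    """All-pairs additive STDP sum (weight change per unit learning rate).

    Each (pre, post) spike pair contributes +exp(-|dt|/tau+) when the post
    spike is strictly later, else -exp(-|dt|/tau-); simultaneous spikes
    count as depression.
    """
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    d = post[None, :] - pre[:, None]  # post minus pre
    vals = np.where(d > 0, np.exp(-d / params.tau_plus), -np.exp(d / params.tau_minus))
    return float(vals.sum())


def astdp_pair_sum(
    pre_spikes: np.ndarray, post_spikes: np.ndarray, params: PlasticityParams
) -> float:
    """Anti-Hebbian STDP: the temporally reversed all-pairs sum.

    Pre-before-post depresses, post-before-pre (or simultaneous)
    potentiates.
    """
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    d = post[None, :] - pre[:, None]
    vals = np.where(d <= 0, np.exp(d / params.tau_plus), -np.exp(-d / params.tau_minus))
    return float(vals.sum())


def _gather(trains: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    ids = np.concatenate(
        [np.full(t.size, i, dtype=int) for i, t in enumerate(trains)]
    ) if trains else np.empty(0, dtype=int)
    times = np.concatenate(trains) if trains else np.empty(0)
    return ids, times


def mstdp_kernel(
    visible_trains: list[np.ndarray],
    hidden_trains: list[np.ndarray],
    params: PlasticityParams,
) -> np.ndarray:
    """Per-(visible, hidden)-pair mirrored-STDP kernel sums K[i, j].

    K sums +exp(-|dt|/tau+) over pairs where the hidden spike is strictly
    later than the visible spike and -exp(-|dt|/tau-) otherwise.  The
    feedforward update is eta*K and the feedback update is zeta*K.T.
    """
    n_vis, n_hid = len(visible_trains), len(hidden_trains)
    K = np.zeros((n_vis, n_hid))
    vis_ids, vis_t = _gather(visible_trains)
    hid_ids, hid_t = _gather(hidden_trains)
    if vis_t.size == 0 or hid_t.size == 0:
        return K
    d = hid_t[None, :] - vis_t[:, None]  # hidden minus visible
    vals = np.where(d > 0, np.exp(-d / params.tau_plus), -np.exp(d / params.tau_minus))
    np.add.at(K, (vis_ids[:, None], hid_ids[None, :]), vals)
    return K


def mstdp_trial_update(
    trial_spikes: SpikeRecord, weights: WeightState, params: PlasticityParams
) -> tuple[np.ndarray, np.ndarray]:
    """Mirrored-STDP weight changes (dW, dQ) for one completed trial.

    By construction dW[i, j]/eta == dQ[j, i]/zeta exactly.  The changes
    are returned unapplied; use :func:`apply_trial_update` to add and clip.
    """
    if len(trial_spikes.visible) != weights.n_vis or len(trial_spikes.hidden) != weights.n_hid:
        raise ValueError("spike record does not match weight shapes")
    K = mstdp_kernel(trial_spikes.visible, trial_spikes.hidden, params)
    return params.eta * K, params.zeta * K.T


def apply_trial_update(
    weights: WeightState,
    dW: np.ndarray,
    dQ: np.ndarray,
    params: PlasticityParams,
) -> WeightState:
    """Apply accumulated trial changes in place and clip to the mode's bounds."""
    lo = -params.w_max if weights.mode == "signed" else 0.0
    np.clip(weights.W + dW, lo, params.w_max, out=weights.W)
    np.clip(weights.Q + dQ, lo, params.w_max, out=weights.Q)
    return weights


def effective_rule_prediction(
    counts: TrialCounts, params: PlasticityParams
) -> np.ndarray:
    """Analytic bout-limit prediction of the trial update.

    dW[i, j] = eta * (beta*x_i - gamma*xhat_i) * y_j with
    beta = exp(-dt1/tau+) and gamma = exp(-dt2/tau-), valid when spikes
    cluster tightly around the three bout times.
    """
    x = np.asarray(counts.x, dtype=float)
    y = np.asarray(counts.y, dtype=float)
    xhat = np.asarray(counts.xhat, dtype=float)
    beta_term = np.zeros_like(x)
    gamma_term = np.zeros_like(x)
    if x.sum() > 0 and y.sum() > 0:
        if np.isnan(counts.dt1):
            raise ValueError("dt1 undefined but early-bout pairs exist")
        beta_term = np.exp(-counts.dt1 / params.tau_plus) * x
    if xhat.sum() > 0 and y.sum() > 0:
        if np.isnan(counts.dt2):
            raise ValueError("dt2 undefined but late-bout pairs exist")
        gamma_term = np.exp(-counts.dt2 / params.tau_minus) * xhat
    return params.eta * np.outer(beta_term - gamma_term, y)


def scaled_autoencoder_rule(
    x: np.ndarray, y: np.ndarray, xhat: np.ndarray, alpha: float
) -> np.ndarray:
    """The target rate rule dW[i, j] = (x_i - xhat_i/alpha) * y_j.

    This is the approximate-gradient-descent rule the spiking update
    should follow; it is an oracle for tests and analysis, never used in
    training.  Its fixed point is the scaled reconstruction xhat = alpha*x.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.outer(x - xhat / alpha, y)
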