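"""Conductance-based LIF simulation of one stimulus presentation.

The network has four populations: visible excitatory, hidden excitatory,
and one pool of inhibitory neurons per layer.  Every visible neuron is
connected reciprocally with every hidden neuron (feedforward matrix W,
feedback matrix Q); inhibitory pools are connected all-to-all with the
excitatory neurons of their layer with fixed uniform weights.  Excitatory
neurons carry a spike-frequency adaptation conductance; inhibitory neurons
do not.  Integration is exponential-Euler with a fixed timestep, and every
delivered spike arrives one synaptic transmission delay after emission.

Activity during a trial falls into three rough bouts: an initial bout of
visible spikes driven by the external input (spike counts x), an
intermediate bout of hidden spikes driven by feedforward excitation
(counts y), and a late bout of visible spikes driven by feedback (counts
x-hat, the network's attempted reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "NetworkConfig",
    "WeightState",
    "SpikeRecord",
    "TrialCounts",
    "simulate_trial",
    "count_bouts",
    "lif_fi_rate",
    "simulate_constant_drive",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron parameters.  Conductances are in units of the leak
    conductance; voltages in mV, times in ms.

    These defaults follow the Vogels-Abbott-style conductance LIF family
    (20 ms membrane, -70/-54/-60 rest/threshold/reset, 2 ms refractory,
    5/10 ms excitatory/inhibitory synapses, 0/-80 mV reversals) and are
    reconstructions: the published model's exact tables are not available,
    so every value is overridable.
    """

    tau_m: float = 20.0
    v_rest: float = -70.0
    v_thresh: float = -54.0
    v_reset: float = -60.0
    t_ref: float = 2.0
    tau_exc: float = 5.0
    tau_inh: float = 10.0
    e_exc: float = 0.0
    e_inh: float = -80.0
    adapt_increment: float = 0.02
    tau_adapt: float = 100.0

    def __post_init__(self):
        if self.v_thresh <= self.v_rest:
            raise ValueError("threshold must exceed resting potential")
        for name in ("tau_m", "tau_exc", "tau_inh", "tau_adapt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_ref < 0:
            raise ValueError("refractory period must be non-negative")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and fixed (non-plastic) connectivity.

    Inhibitory weights and the external-input weight never change during a
    simulation; only W and Q are plastic.  ``feedback_gain`` scales the
    efficacy of feedback synapses during simulation only (a network
    excitability knob for small networks where few hidden units are active
    per stimulus); it does not touch the learned Q used by the metrics.
    """

    n_vis: int
    n_hid: int
    n_inh: int = 8
    delay: float = 2.0
    trial_duration: float = 65.0
    dt: float = 0.1
    w_ext: float = 0.25
    feedback_gain: float = 1.0
    w_vis_to_inh: float = 0.05
    w_hid_to_inh: float = 0.05
    w_inh_to_vis: float = 0.05
    w_inh_to_hid: float = 0.05
    input_as_current: bool = False  # if True, external spikes inject current-like drive

    def __post_init__(self):
        if self.n_vis <= 0 or self.n_hid <= 0 or self.n_inh < 0:
            raise ValueError("population sizes must be positive (n_inh >= 0)")
        if self.delay < 0:
            raise ValueError("synaptic delay must be non-negative")
        if self.trial_duration <= 0 or self.dt <= 0:
            raise ValueError("trial_duration and dt must be positive")


@dataclass
class WeightState:
    """Plastic weights: feedforward W (n_vis x n_hid), feedback Q
    (n_hid x n_vis).  ``mode`` is "signed" (entries may be negative; a
    negative weight acts as an inhibitory conductance of equal magnitude)
    or "nonneg" (all entries >= 0)."""

    W: np.ndarray
    Q: np.ndarray
    mode: str = "nonneg"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.W.ndim != 2 or self.Q.shape != self.W.shape[::-1]:
            raise ValueError("Q must have the transposed shape of W")
        if self.mode not in ("signed", "nonneg"):
            raise ValueError("mode must be 'signed' or 'nonneg'")
        if self.mode == "nonneg" and (self.W.min(initial=0) < 0 or self.Q.min(initial=0) < 0):
            raise ValueError("non-negative mode forbids negative weights")

    @property
    def n_vis(self) -> int:
        return self.W.shape[0]

    @property
    def n_hid(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "WeightState":
        return WeightState(self.W.copy(), self.Q.copy(), self.mode)


@dataclass
class SpikeRecord:
    """Per-neuron ordered spike-time lists (ms) for the four populations."""

    visible: list[np.ndarray]
    hidden: list[np.ndarray]
    visible_inh: list[np.ndarray] = field(default_factory=list)
    hidden_inh: list[np.ndarray] = field(default_factory=list)

    def counts(self, population: str) -> np.ndarray:
        trains = getattr(self, population)
        return np.array([t.size for t in trains], dtype=int)

    def total_spikes(self) -> int:
        return int(
            sum(t.size for pop in (self.visible, self.hidden, self.visible_inh, self.hidden_inh) for t in pop)
        )


@dataclass
class TrialCounts:
    """Spike counts of the three bouts plus mean bout separations.

    x : visible counts before the bout boundary (initial bout)
    y : hidden counts over the whole trial (intermediate bout)
    xhat : visible counts at/after the boundary (attempted reconstruction)
    dt1 : mean hidden spike time minus mean early visible spike time (ms);
          NaN when either set is empty
    dt2 : mean late visible spike time minus mean hidden spike time (ms)
    """

    x: np.ndarray
    y: np.ndarray
    xhat: np.ndarray
    dt1: float
    dt2: float


def _to_trains(n: int, step_times: list[float], step_ids: list[np.ndarray]) -> list[np.ndarray]:
    if not step_times:
        return [np.empty(0) for _ in range(n)]
    all_ids = np.concatenate(step_ids)
    all_t = np.concatenate(
        [np.full(ids.size, t) for t, ids in zip(step_times, step_ids)]
    )
    order = np.argsort(all_ids, kind="stable")  # stable keeps times sorted per neuron
    all_ids, all_t = all_ids[order], all_t[order]
    bounds = np.searchsorted(all_ids, np.arange(n + 1))
    return [all_t[bounds[i]: bounds[i + 1]] for i in range(n)]


def simulate_trial(
    config: NetworkConfig,
    neuron_params: NeuronParams,
    weights: WeightState,
    input_spikes: Sequence[np.ndarray],
    seed: int = 0,
) -> SpikeRecord:
    """Simulate one stimulus presentation and return all spikes.

    ``weights`` should already carry any homeostatic scaling (effective
    weights).  ``input_spikes`` is one array of external spike times per
    visible neuron; each external spike adds ``w_ext`` of excitatory
    conductance to its visible neuron.  The simulation is deterministic
    given its inputs (``seed`` is accepted for interface stability; the
    integrator itself is noise-free).
    """
    p, cfg = neuron_params, config
    if not (np.all(np.isfinite(weights.W)) and np.all(np.isfinite(weights.Q))):
        raise ValueError("non-finite weights")
    if p.t_ref > 0 and cfg.dt > p.t_ref:
        raise ValueError("timestep exceeds refractory period")
    if len(input_spikes) != cfg.n_vis:
        raise ValueError("input_spikes must have one train per visible neuron")

    dt = cfg.dt
    n_steps = int(round(cfg.trial_duration / dt))
    delay_steps = max(1, int(round(cfg.delay / dt)))
    ref_steps = int(round(p.t_ref / dt))

    n_vis, n_hid, n_inh = cfg.n_vis, cfg.n_hid, cfg.n_inh
    N = n_vis + n_hid + 2 * n_inh
    vis = slice(0, n_vis)
    hid = slice(n_vis, n_vis + n_hid)
    vinh = slice(n_vis + n_hid, n_vis + n_hid + n_inh)
    hinh = slice(n_vis + n_hid + n_inh, N)

    # fixed per-trial connectivity, split into excitatory / inhibitory parts
    M_exc = np.zeros((N, N))
    M_inh = np.zeros((N, N))
    W = weights.W
    Q = weights.Q * cfg.feedback_gain
    M_exc[vis, hid] = np.maximum(W, 0.0)
    M_inh[vis, hid] = np.maximum(-W, 0.0)
    M_exc[hid, vis] = np.maximum(Q, 0.0)
    M_inh[hid, vis] = np.maximum(-Q, 0.0)
    if n_inh > 0:
        M_exc[vis, vinh] = cfg.w_vis_to_inh
        M_exc[hid, hinh] = cfg.w_hid_to_inh
        M_inh[vinh, vis] = cfg.w_inh_to_vis
        M_inh[hinh, hid] = cfg.w_inh_to_hid

    # external drive binned onto steps
    ext = np.zeros((n_steps, n_vis))
    for i, times in enumerate(input_spikes):
        if len(times) == 0:
            continue
        steps = np.floor(np.asarray(times) / dt).astype(int)
        steps = steps[(steps >= 0) & (steps < n_steps)]
        np.add.at(ext, (steps, np.full(steps.size, i)), cfg.w_ext)

    V = np.full(N, p.v_rest)
    g_e = np.zeros(N)
    g_i = np.zeros(N)
    g_a = np.zeros(N)
    ref = np.zeros(N, dtype=int)
    s_ext = np.zeros(n_vis)  # current-mode external drive trace
    b_vec = np.zeros(N)
    b_vec[: n_vis + n_hid] = p.adapt_increment  # only E cells adapt

    L = delay_steps + 1
    buf_e = np.zeros((L, N))
    buf_i = np.zeros((L, N))

    decay_e = np.exp(-dt / p.tau_exc)
    decay_i = np.exp(-dt / p.tau_inh)
    decay_a = np.exp(-dt / p.tau_adapt)

    step_times: list[float] = []
    step_ids: list[np.ndarray] = []

    for t in range(n_steps):
        cur = t % L
        g_e *= decay_e
        g_i *= decay_i
        g_a *= decay_a
        g_e += buf_e[cur]
        g_i += buf_i[cur]
        buf_e[cur] = 0.0
        buf_i[cur] = 0.0
        if cfg.input_as_current:
            s_ext *= decay_e
            s_ext += ext[t]
        else:
            g_e[vis] += ext[t]

        g_tot = 1.0 + g_e + g_i + g_a
        drive = p.v_rest + g_e * p.e_exc + g_i * p.e_inh + g_a * p.e_inh
        if cfg.input_as_current:
            # current-like pulse: fixed driving force, no shunting term
            drive[vis] += s_ext * (p.e_exc - p.v_rest)
        v_inf = drive / g_tot
        V = v_inf + (V - v_inf) * np.exp(-dt * g_tot / p.tau_m)

        refractory = ref > 0
        if refractory.any():
            V[refractory] = p.v_reset
            ref[refractory] -= 1

        spk = V >= p.v_thresh
        if spk.any():
            idx = np.nonzero(spk)[0]
            V[idx] = p.v_reset
            ref[idx] = ref_steps
            g_a[idx] += b_vec[idx]
            dest = (t + delay_steps) % L
            if idx.size == 1:
                buf_e[dest] += M_exc[idx[0]]
                buf_i[dest] += M_inh[idx[0]]
            else:
                buf_e[dest] += M_exc[idx].sum(axis=0)
                buf_i[dest] += M_inh[idx].sum(axis=0)
            step_times.append(t * dt)
            step_ids.append(idx)

    # split concatenated indices back into the four populations
    def pop_trains(lo: int, n: int) -> list[np.ndarray]:
        times, ids = [], []
        for tt, ii in zip(step_times, step_ids):
            sel = ii[(ii >= lo) & (ii < lo + n)]
            if sel.size:
                times.append(tt)
                ids.append(sel - lo)
        return _to_trains(n, times, ids)

    return SpikeRecord(
        visible=pop_trains(0, n_vis),
        hidden=pop_trains(n_vis, n_hid),
        visible_inh=pop_trains(n_vis + n_hid, n_inh),
        hidden_inh=pop_trains(n_vis + n_hid + n_inh, n_inh),
    )


def count_bouts(spikes: SpikeRecord, boundary: float) -> TrialCounts:
    """Split visible spikes at ``boundary`` (ms) into initial (x) and late
    (x-hat) bouts, count hidden spikes (y), and compute mean bout
    separations Δt1 and Δt2 (NaN when a bout is empty)."""
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    x = np.array([np.sum(t < boundary) for t in spikes.visible], dtype=int)
    xhat = np.array([np.sum(t >= boundary) for t in spikes.visible], dtype=int)
    y = spikes.counts("hidden")

    early = np.concatenate([t[t < boundary] for t in spikes.visible]) if x.sum() else np.empty(0)
    late = np.concatenate([t[t >= boundary] for t in spikes.visible]) if xhat.sum() else np.empty(0)
    hid_times = (
        np.concatenate([t for t in spikes.hidden if t.size]) if y.sum() else np.empty(0)
    )

    dt1 = float(hid_times.mean() - early.mean()) if hid_times.size and early.size else float("nan")
    dt2 = float(late.mean() - hid_times.mean()) if late.size and hid_times.size else float("nan")
    return TrialCounts(x=x, y=y, xhat=xhat, dt1=dt1, dt2=dt2)


def lif_fi_rate(params: NeuronParams, g_exc: float) -> float:
    """Closed-form steady firing rate (Hz) of a LIF neuron under constant
    excitatory conductance ``g_exc`` (leak units), without adaptation.

    The membrane relaxes toward V_inf = (V_rest + g E_exc)/(1 + g) with
    effective time constant tau_m/(1 + g); the interspike interval is the
    refractory period plus the time to charge from reset to threshold.
    """
    p = params
    g_tot = 1.0 + g_exc
    v_inf = (p.v_rest + g_exc * p.e_exc) / g_tot
    if v_inf <= p.v_thresh:
        return 0.0
    tau_eff = p.tau_m / g_tot
    isi = p.t_ref + tau_eff * np.log((v_inf - p.v_reset) / (v_inf - p.v_thresh))
    return 1000.0 / isi


def simulate_constant_drive(
    params: NeuronParams,
    g_exc: float,
    duration: float,
    dt: float = 0.1,
    adaptation: bool = False,
) -> np.ndarray:
    """Simulate a single LIF neuron under constant excitatory conductance.

    Returns spike times (ms).  Uses the same exponential-Euler integrator
    as the network, so it serves to check the discretized dynamics against
    the closed-form f-I curve (``lif_fi_rate``).
    """
    p = params
    n_steps = int(round(duration / dt))
    ref_steps = int(round(p.t_ref / dt))
    decay_a = np.exp(-dt / p.tau_adapt)
    V = p.v_rest
    g_a = 0.0
    ref = 0
    spikes = []
    for t in range(n_steps):
        g_a *= decay_a
        g_tot = 1.0 + g_exc + g_a
        v_inf = (p.v_rest + g_exc * p.e_exc + g_a * p.e_inh) / g_tot
        V = v_inf + (V - v_inf) * np.exp(-dt * g_tot / p.tau_m)
        if ref > 0:
            V = p.v_reset
            ref -= 1
        if V >= p.v_thresh:
            V = p.v_reset
            ref = ref_steps
            if adaptation:
                g_a += p.adapt_increment
            spikes.append(t * dt)
    return np.array(spikes)
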