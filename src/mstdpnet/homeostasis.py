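"""Homeostatic synaptic scaling toward a target lifetime activation rate.

Each hidden unit tracks a running average A_j of the fraction of trials in
which it fired at least one spike.  After every trial its synaptic offset
phi_j (additive mode) or scaling factor Phi_j (multiplicative mode) moves
by kappa*(rho - A_j), raising excitability when the unit is quieter than
the target rate rho and lowering it when more active.  Scaling acts only
on the feedforward excitation of hidden units: visible-unit responses to
the external input and to feedback are untouched.

Additive offsets behave like a bias term and work with signed weights;
multiplicative factors require non-negative weights so that scaling moves
net excitation monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HomeostasisState", "update_activity", "update_scaling", "effective_weights"]


@dataclass
class HomeostasisState:
    """Per-hidden-unit homeostatic state.

    mode : "additive" (offsets phi_j) or "multiplicative" (factors Phi_j)
    scale : the offsets/factors themselves
    activity : running activation fractions A_j in [0, 1]
    rho : target activation rate (fraction of trials with >= 1 spike)
    kappa : homeostatic learning rate
    ema_decay : per-trial weight of the newest observation in A_j
        (default 0.005, an effective window of ~200 trials, small enough
        that the equilibrium jitter of A_j stays well inside +-0.5*rho)
    """

    mode: str
    scale: np.ndarray
    activity: np.ndarray
    rho: float = 0.05
    kappa: float = 0.05
    ema_decay: float = 0.005

    def __post_init__(self):
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError("mode must be 'additive' or 'multiplicative'")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if not 0 < self.ema_decay < 1:
            raise ValueError("ema_decay must lie in (0, 1)")
        self.scale = np.asarray(self.scale, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.scale.shape != self.activity.shape:
            raise ValueError("scale and activity must have the same shape")
        if self.mode == "multiplicative" and np.any(self.scale < 0):
            raise ValueError("multiplicative factors must be non-negative")

    @classmethod
    def initial(
        cls,
        n_hid: int,
        mode: str,
        rho: float = 0.05,
        kappa: float = 0.05,
        ema_decay: float = 0.005,
    ) -> "HomeostasisState":
        scale0 = np.ones(n_hid) if mode == "multiplicative" else np.zeros(n_hid)
        return cls(mode, scale0, np.zeros(n_hid), rho=rho, kappa=kappa, ema_decay=ema_decay)

    @property
    def n_hid(self) -> int:
        return self.scale.size

    def copy(self) -> "HomeostasisState":
        return HomeostasisState(
            self.mode, self.scale.copy(), self.activity.copy(),
            rho=self.rho, kappa=self.kappa, ema_decay=self.ema_decay,
        )


def update_activity(state: HomeostasisState, fired: np.ndarray) -> HomeostasisState:
    """Fold one trial's did-it-fire outcome into the running averages A_j."""
    fired = np.asarray(fired, dtype=float)
    if fired.shape != state.activity.shape:
        raise ValueError("fired must have one entry per hidden unit")
    d = state.ema_decay
    state.activity *= 1.0 - d
    state.activity += d * fired
    return state


def update_scaling(state: HomeostasisState) -> HomeostasisState:
    """Move offsets/factors by kappa*(rho - A_j); called once per trial
    after :func:`update_activity`.  Multiplicative factors are floored at 0."""
    state.scale += state.kappa * (state.rho - state.activity)
    if state.mode == "multiplicative":
        np.maximum(state.scale, 0.0, out=state.scale)
    return state


def effective_weights(W: np.ndarray, state: HomeostasisState) -> np.ndarray:
    """Effective feedforward weights used in simulation.

    Additive: w~_ij = w_ij + phi_j.  Multiplicative: w~_ij = w_ij * Phi_j
    (requires non-negative raw weights).  Column j of W holds the incoming
    weights of hidden unit j.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[1] != state.n_hid:
        raise ValueError("W must have one column per hidden unit")
    if state.mode == "additive":
        return W + state.scale[None, :]
    if np.any(W < 0):
        raise ValueError("multiplicative scaling requires non-negative weights")
    return W * state.scale[None, :]
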