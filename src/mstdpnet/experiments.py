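"""Canonical desk-scale experiment configurations.

The bars experiment is the package's reference end-to-end run: an 8x8
grid of single-bar stimuli (16 distinct bars, ON/OFF doubled to 128
visible neurons), 16 hidden units, non-negative weights with
multiplicative synaptic scaling, independent weight initialization, and
5,000 presentations.  It exercises the same learning dynamics as the
full-scale image experiments -- sparse hidden codes whose feedback
weights reconstruct the input -- at a size where a complete training run
takes about two minutes on one CPU.

The network/neuron parameters here were chosen so that a presentation
produces the three-bout activity pattern (initial visible bout driven by
the 10 ms external input, hidden bout at 5-15 ms, weak feedback-driven
late visible bout) without runaway excitation; see the methods notes for
the reasoning behind each value.
"""

from __future__ import annotations

from .network import NetworkConfig, NeuronParams
from .plasticity import PlasticityParams
from .stimuli import EncodingParams
from .trainer import TrainConfig

__all__ = ["bars_network_config", "bars_neuron_params", "bars_train_config"]


def bars_network_config(grid: int = 8, n_hid: int = 16) -> NetworkConfig:
    """Network architecture for the bars experiment.

    The feedback gain compensates for the small number of hidden units
    active per stimulus (one or two here, versus hundreds in a
    full-scale network): without it the summed feedback conductance is
    too weak to evoke any reconstruction bout.
    """
    return NetworkConfig(
        n_vis=2 * grid * grid,
        n_hid=n_hid,
        n_inh=8,
        w_ext=1.0,
        feedback_gain=8.0,
        w_vis_to_inh=0.15,
        w_hid_to_inh=0.5,
        w_inh_to_vis=0.3,
        w_inh_to_hid=0.8,
    )


def bars_neuron_params() -> NeuronParams:
    """LIF parameters for the bars experiment: defaults with a weak
    adaptation increment, so hidden units answer with a few spikes
    rather than a single one (better-conditioned spike-count codes)."""
    return NeuronParams(adapt_increment=0.05)


def bars_train_config(
    n_presentations: int = 5000,
    master_seed: int = 1,
    grid: int = 8,
    n_hid: int = 16,
    eval_every: int = 100,
) -> TrainConfig:
    """The reference bars training configuration.

    Target activation rho = 1/16 matches one bar per hidden unit (each
    bar appears on 1/16 of presentations); the homeostatic rate and
    activity window (kappa = 0.1, ema_decay = 0.01) are fast enough that
    units knocked below threshold by depression recover within a few
    hundred trials.
    """
    return TrainConfig(
        mode="nonneg_multiplicative",
        init="independent",
        n_presentations=n_presentations,
        eval_every=eval_every,
        test_set_size=2 * grid,
        master_seed=master_seed,
        init_scale=0.08,
        rho=1.0 / 16.0,
        kappa=0.1,
        ema_decay=0.01,
        network=bars_network_config(grid=grid, n_hid=n_hid),
        neuron=bars_neuron_params(),
        plasticity=PlasticityParams(eta=1e-3, zeta=1e-3, tau_plus=20.0, tau_minus=30.0, w_max=0.4),
        encoding=EncodingParams(rate_scale=800.0, stimulus_duration=10.0),
    )
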