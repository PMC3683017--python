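"""Trace-rule synaptic modification and the layer-by-layer training schedule.

The trace rule is a Hebbian rule whose postsynaptic term is an exponentially
decaying average (the *trace*) of the neuron's recent firing:

    trace(t) = (1 - eta) * y(t) + eta * trace(t - 1)

The default weight update uses the trace from the immediately preceding
timestep only,

    dw_j = lr * trace(t - 1) * x_j(t),

so a neuron that fired for the previous frame of a sequence strengthens its
synapses from inputs active in the current (shifted) frame — binding the
frames of one eye-movement sequence onto the same cells.  Two variants are
available: ``trace_current`` (the historical form, postsynaptic term
trace(t)) and ``hebb`` (postsynaptic term y(t); identical to
``trace_current`` with eta = 0).

Weight vectors are renormalized to unit length after every update, as usual
in competitive learning.  Layers train strictly bottom-up, one at a time,
with the lower layers frozen; the learning rate anneals linearly from 1
toward 0 across the epochs of the layer being trained.  The trace is reset
to zero at sequence boundaries so that different hand-object configurations
are never temporally associated — the behaviour-critical assumption of the
whole scheme, exposed in the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from visnet_hand.network import Network, SynapticTopology

__all__ = [
    "TrainingSchedule",
    "update_trace",
    "trace_weight_update",
    "normalize_weights",
    "train_layer",
    "train_network",
]

RULES = ("trace_lagged", "trace_current", "hebb")


@dataclass
class TrainingSchedule:
    """Epoch counts and rule options for the bottom-up training protocol."""

    epochs_per_layer: tuple[int, ...] = (50, 50, 50, 50)
    eta: float = 0.8
    rule: str = "trace_lagged"
    lr_scale: float = 1.0
    reset_trace_per_sequence: bool = True
    temporal_scramble: bool = False

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; choose from {RULES}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")


def update_trace(y_now: np.ndarray, trace_prev: np.ndarray, eta: float) -> np.ndarray:
    """trace = (1 - eta) y + eta trace_prev; eta = 0 recovers the raw rate."""
    return (1.0 - eta) * np.asarray(y_now) + eta * np.asarray(trace_prev)


def trace_weight_update(weights: np.ndarray, pre_index: np.ndarray,
                        x_pre: np.ndarray, post_term: np.ndarray,
                        lr: float) -> None:
    """In-place dw_ij = lr * post_term_i * x_j; caller picks the postsynaptic
    term (lagged trace, current trace, or current rate)."""
    weights += lr * post_term[:, None] * x_pre.ravel()[pre_index]


def normalize_weights(topology: SynapticTopology) -> SynapticTopology:
    """Rescale every neuron's afferent weight vector to unit length."""
    norms = np.linalg.norm(topology.weights, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("cannot normalize a zero weight vector")
    topology.weights /= norms
    return topology


def _presentation_stream(pre_rates: list[list[np.ndarray]], epoch_rng: np.random.Generator | None):
    """Yield (sequence_boundary, frame_rates) in presentation order.

    The normal stream visits sequences round-robin, frames in temporal
    order.  With an epoch RNG supplied, all frames are pooled and presented
    in a random order as one unbroken stream — the shuffled-time negative
    control that destroys the temporal structure trace learning needs.
    """
    if epoch_rng is None:
        for seq in pre_rates:
            for t, frame in enumerate(seq):
                yield (t == 0), frame
    else:
        pool = [frame for seq in pre_rates for frame in seq]
        order = epoch_rng.permutation(len(pool))
        for n, idx in enumerate(order):
            yield (n == 0), pool[idx]


def train_layer(network: Network, pre_rates: list[list[np.ndarray]], layer_index: int,
                epochs: int, schedule: TrainingSchedule,
                rng: np.random.Generator | None = None) -> Network:
    """Train one layer on precomputed presynaptic rates.

    ``pre_rates`` holds, per sequence, the frozen presynaptic rate vector of
    every frame (the retina response for layer 0).  Within each epoch every
    sequence is presented frame-by-frame in temporal order; the learning
    rate is annealed linearly, lr(e) = 1 - e / epochs.
    """
    topo = network.topologies[layer_index]
    n_post = network.configs[layer_index].n_neurons
    trace = np.zeros(n_post)
    scramble_rng = rng if schedule.temporal_scramble else None
    if schedule.temporal_scramble and rng is None:
        raise ValueError("temporal_scramble requires an rng")
    for epoch in range(epochs):
        lr = schedule.lr_scale * (1.0 - epoch / epochs)
        for at_boundary, x in _presentation_stream(pre_rates, scramble_rng):
            if at_boundary and schedule.reset_trace_per_sequence:
                trace = np.zeros(n_post)
            y = network.layer_step(layer_index, x).rates.ravel()
            if schedule.rule == "trace_lagged":
                post = trace
            elif schedule.rule == "trace_current":
                post = update_trace(y, trace, schedule.eta)
            else:  # hebb
                post = y
            if lr != 0.0:
                trace_weight_update(topo.weights, topo.pre_index, x, post, lr)
                normalize_weights(topo)
            trace = update_trace(y, trace, schedule.eta)
    return network


def train_network(network: Network, retina_sequences: list[list[np.ndarray]],
                  schedule: TrainingSchedule,
                  rng: np.random.Generator | None = None) -> Network:
    """Full bottom-up protocol: train layer 1 first, then 2, 3, 4.

    While layer k trains, the layers below are frozen, so their responses to
    every training frame are computed once and reused for all of layer k's
    epochs.  ``retina_sequences`` holds the Gabor-filtered frames, grouped
    by sequence.
    """
    if len(schedule.epochs_per_layer) != len(network.configs):
        raise ValueError("schedule must give an epoch count for every layer")
    for k, epochs in enumerate(schedule.epochs_per_layer):
        pre = []
        for seq in retina_sequences:
            frames = []
            for frame in seq:
                x = np.asarray(frame).ravel()
                if k > 0:
                    x = network.forward(x, upto=k - 1)[-1].rates.ravel()
                frames.append(x)
            pre.append(frames)
        if epochs > 0:
            train_layer(network, pre, k, epochs, schedule, rng=rng)
    return network
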