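"""End-to-end experiment protocols with replicate averaging.

Four protocols are provided, differing only in their configuration:

* ``baseline`` — 3 hand-object configurations (Up / Left / Right), 128-px
  retina, 5-px eye-movement shifts, 50 training epochs per layer.
* ``epoch_sweep`` — the baseline repeated at several per-layer epoch counts
  (untrained, 1, 2, 5, 10, 50) to chart how fast selectivity emerges.
* ``density_sweep`` — 3..10 target locations evenly spaced on the 36-px
  semicircle, 5 replicate simulations each.
* ``large_retina`` — doubled 256-px retina, 64 Gabor channels, 35-px
  shifts, with the scaled connection counts and radii.

Every replicate draws its own synaptic topology and initial weights from a
stream spawned off the master seed; stimuli and their Gabor responses are
deterministic and shared across replicates.  Results aggregate the
per-location counts of perfectly selective cells (cells at the single-cell
information maximum) over replicates as mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from visnet_hand import info_metrics, stimuli, v1_frontend
from visnet_hand.info_metrics import InfoReport, ResponseTable
from visnet_hand.learning import TrainingSchedule, train_network
from visnet_hand.network import (
    Network,
    baseline_layer_configs,
    large_retina_layer_configs,
)

__all__ = [
    "ExperimentConfig",
    "ReplicateResult",
    "ExperimentResult",
    "filtered_training_set",
    "run_replicate",
    "run_experiment",
    "count_selective_cells",
    "profile_cell",
]

EXPERIMENTS = ("baseline", "epoch_sweep", "density_sweep", "large_retina")


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one experiment, resolvable to a full protocol."""

    experiment: str = "baseline"
    retina_size: int = 128
    n_channels: int = 32
    n_target_locations: int = 3
    shift_step: int = 5
    n_shifts: int = 5
    epochs_per_layer: int = 50
    n_replicates: int = 1
    seed: int = 0
    eta: float = 0.8
    rule: str = "trace_lagged"
    n_bins: int = 3
    temporal_scramble: bool = False
    epoch_grid: tuple[int, ...] = (0, 1, 2, 5, 10, 50)
    location_grid: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9, 10)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.retina_size not in (128, 256):
            raise ValueError("retina_size must be 128 or 256")
        if (self.retina_size == 128) != (self.n_channels == 32):
            raise ValueError("128-px retina pairs with 32 channels, 256-px with 64")
        if not 1 <= self.n_target_locations <= 10:
            raise ValueError("n_target_locations must be in 1..10")

    def layer_configs(self):
        if self.retina_size == 128:
            return baseline_layer_configs()
        return large_retina_layer_configs()

    @classmethod
    def baseline(cls, seed: int = 0, **kw) -> "ExperimentConfig":
        return cls(experiment="baseline", seed=seed, **kw)

    @classmethod
    def large_retina(cls, seed: int = 0, **kw) -> "ExperimentConfig":
        return cls(experiment="large_retina", retina_size=256, n_channels=64,
                   shift_step=35, seed=seed, **kw)


@dataclass
class ReplicateResult:
    """Untrained and trained analyses of one seeded simulation."""

    seed_key: tuple[int, int]
    untrained: InfoReport
    trained: InfoReport
    untrained_table: ResponseTable
    trained_table: ResponseTable
    network: Network | None = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    replicates: list[ReplicateResult] = field(default_factory=list)

    @property
    def counts(self) -> np.ndarray:
        """(n_replicates, n_locations) perfectly-selective-cell counts."""
        return np.stack([count_selective_cells(r.trained) for r in self.replicates])

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def sd_counts(self) -> np.ndarray:
        return self.counts.std(axis=0, ddof=1) if len(self.replicates) > 1 \
            else np.zeros(self.counts.shape[1])

    @property
    def mean_total(self) -> float:
        return float(self.counts.sum(axis=1).mean())


def filtered_training_set(config: ExperimentConfig,
                          bank: v1_frontend.GaborBank | None = None
                          ) -> tuple[list[list[np.ndarray]], list[str]]:
    """Render the stimulus sequences and push every frame through V1.

    Returns (sequences of retina responses, stimulus labels); deterministic,
    so callers may cache the result across replicates.
    """
    seqs = stimuli.build_training_set(config.n_target_locations, config.retina_size,
                                      config.shift_step, config.n_shifts)
    if bank is None:
        bank = v1_frontend.build_gabor_bank(
            v1_frontend.default_bank_spec(config.retina_size, config.n_channels),
            expected_channels=config.n_channels)
    filtered = [[v1_frontend.filter_image(f, bank) for f in seq.frames] for seq in seqs]
    labels = [seq.config_label for seq in seqs]
    return filtered, labels


def run_replicate(config: ExperimentConfig, replicate: int,
                  filtered: list[list[np.ndarray]], labels: list[str],
                  epochs_per_layer: int | None = None,
                  keep_network: bool = False) -> ReplicateResult:
    """Build, evaluate untrained, train, evaluate trained — one seed."""
    epochs = config.epochs_per_layer if epochs_per_layer is None else epochs_per_layer
    rng = np.random.default_rng([config.seed, replicate])
    retina_shape = (config.retina_size, config.retina_size, config.n_channels)
    net = Network.build(config.layer_configs(), retina_shape, rng)
    table0 = info_metrics.compute_response_table(net, filtered, labels)
    report0 = info_metrics.analyse_responses(table0, n_bins=config.n_bins)
    schedule = TrainingSchedule(
        epochs_per_layer=(epochs,) * len(net.configs),
        eta=config.eta, rule=config.rule,
        temporal_scramble=config.temporal_scramble)
    train_network(net, filtered, schedule, rng=rng)
    table1 = info_metrics.compute_response_table(net, filtered, labels)
    report1 = info_metrics.analyse_responses(table1, n_bins=config.n_bins)
    return ReplicateResult(seed_key=(config.seed, replicate),
                           untrained=report0, trained=report1,
                           untrained_table=table0, trained_table=table1,
                           network=net if keep_network else None)


def run_experiment(config: ExperimentConfig, keep_networks: bool = False) -> ExperimentResult:
    """Run all replicates of one experiment configuration."""
    filtered, labels = filtered_training_set(config)
    result = ExperimentResult(config=config)
    for r in range(config.n_replicates):
        result.replicates.append(
            run_replicate(config, r, filtered, labels, keep_network=keep_networks))
    return result


def count_selective_cells(report: InfoReport, per_location: bool = True) -> np.ndarray:
    """Count perfectly selective cells, per preferred target location.

    A cell counts for location L when it sits at the information maximum and
    its preferred stimulus is L; the per-location counts therefore partition
    the total number of at-max cells.
    """
    mask = report.at_max_mask()
    n_stim = report.info_per_stimulus.shape[1]
    counts = np.bincount(report.preferred_stimulus[mask], minlength=n_stim)
    if per_location:
        return counts
    return np.array([counts.sum()])


def profile_cell(network: Network, cell_index: int,
                 filtered: list[list[np.ndarray]]) -> np.ndarray:
    """Firing-rate matrix (n_stimuli x n_locations) of one output cell."""
    n_cells = network.configs[-1].n_neurons
    if not 0 <= cell_index < n_cells:
        raise IndexError(f"cell index {cell_index} out of range 0..{n_cells - 1}")
    out = np.empty((len(filtered), len(filtered[0])))
    for s, seq in enumerate(filtered):
        for l, frame in enumerate(seq):
            out[s, l] = network.output_rates(frame).ravel()[cell_index]
    return out
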