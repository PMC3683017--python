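"""Shared fixtures: rendered stimuli, filter banks, and small networks.

Everything is generated programmatically at test time; the heavier trained
networks are session-scoped so several test modules can share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from visnet_hand import experiments, network, stimuli, v1_frontend


@pytest.fixture(scope="session")
def gabor_bank():
    return v1_frontend.build_gabor_bank(v1_frontend.default_bank_spec(128, 32),
                                        expected_channels=32)


@pytest.fixture(scope="session")
def baseline_config():
    return experiments.ExperimentConfig.baseline(seed=1)


@pytest.fixture(scope="session")
def baseline_filtered(baseline_config):
    """Gabor responses of the 3-configuration x 5-shift training set."""
    return experiments.filtered_training_set(baseline_config)


@pytest.fixture(scope="session")
def baseline_runs(baseline_config, baseline_filtered):
    """Five independent baseline simulations (topology + weight seeds)."""
    filtered, labels = baseline_filtered
    return [experiments.run_replicate(baseline_config, r, filtered, labels,
                                      keep_network=True)
            for r in range(5)]


@pytest.fixture(scope="session")
def untrained_network():
    rng = np.random.default_rng(3)
    return network.Network.build(network.baseline_layer_configs(),
                                 (128, 128, 32), rng)


# -- a miniature pipeline for cheap structural tests ------------------------

MINI_RETINA = (32, 32, 8)


@pytest.fixture(scope="session")
def mini_bank():
    spec = v1_frontend.GaborBankSpec(n_orientations=2, phases=(0.0, np.pi),
                                     wavelengths=(3.0, 6.0))
    return v1_frontend.build_gabor_bank(spec, expected_channels=8)


def mini_layer_configs():
    return [
        network.LayerConfig(grid=8, n_afferents=20, radius=3.0, sigma=1.38,
                            delta=1.5, percentile=95.0, slope=190.0),
        network.LayerConfig(grid=8, n_afferents=20, radius=3.0, sigma=2.7,
                            delta=1.5, percentile=95.0, slope=40.0),
    ]


@pytest.fixture()
def mini_network():
    rng = np.random.default_rng(11)
    return network.Network.build(mini_layer_configs(), MINI_RETINA, rng)


@pytest.fixture(scope="session")
def mini_sequences(mini_bank):
    """Two 3-frame sequences on a 32-px retina (scaled-down scene)."""
    seqs = []
    for idx in (0, 2):
        spec = stimuli.SceneSpec(retina_size=32, hand_centre=(14.0, 16.0),
                                 n_target_locations=3, target_location_index=idx,
                                 semicircle_diameter=9.0, object_radius=2.0,
                                 hand_scale=6.0, hand_stroke=1.0)
        seq = stimuli.make_sequence(spec, n_shifts=3, shift_step=2)
        seqs.append([v1_frontend.filter_image(f, mini_bank) for f in seq.frames])
    return seqs
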