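import numpy as np
import pytest

import nmrmultiplet as nm
from nmrmultiplet.classifier import NetworkConfig, TrainingConfig, build_network, train


@pytest.fixture(scope="session")
def default_config():
    return nm.SimulationConfig()


@pytest.fixture(scope="session")
def segment_batch_10k(default_config):
    """10,000 segments under the default study conditions (shared, read-only)."""
    seeds = np.random.SeedSequence(20230111).generate_state(10_000, dtype=np.uint32)
    return [
        nm.generate_segment(default_config, np.random.default_rng(int(s))) for s in seeds
    ]


@pytest.fixture(scope="session")
def easy_training_run():
    """The scaled-down learning-sanity protocol, shared across tests.

    2,000 easy-mode segments (SNR >= 10^1.5, J/FWHM >= 4, no phase or
    baseline distortion), 75/25 split, 10 epochs on the compact network,
    plus an independently generated easy-mode test set.
    """
    cfg = nm.SimulationConfig.easy_mode()
    dataset = nm.generate_dataset(cfg, 2000, (0.75, 0.25), seed=1234)
    network = NetworkConfig.compact()
    model = build_network(network, seed=7)
    tconfig = TrainingConfig(
        n_epochs=10, batch_size=4, learning_rate=2.5e-3, seed=3,
        lr_schedule="cosine", normalization="max-abs-sqrt",
    )
    clf = train(model, dataset, tconfig, network_config=network)
    test_set = nm.generate_dataset(cfg, 300, (1.0,), seed=999)
    return clf, dataset, test_set


@pytest.fixture(scope="session")
def easy_test_predictions(easy_training_run):
    """Predictions of the learning-sanity model on the independent test set."""
    clf, _, test_set = easy_training_run
    model = clf.to_model()
    preds = [nm.predict(model, seg.intensity) for seg in test_set.segments]
    truths = [seg.labels for seg in test_set.segments]
    return preds, truths
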