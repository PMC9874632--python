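"""Train a small classifier on easy synthetic data, then classify a fresh segment.

A deliberately tiny run (300 segments, 3 epochs, compact network) so it
finishes in about a minute on one CPU core; accuracy is accordingly
modest.  The learning-sanity protocol in the test suite uses 2,000
segments and 10 epochs.

Run:  python examples/02_train_and_predict.py
"""

import numpy as np

from nmrmultiplet import (
    NetworkConfig,
    SimulationConfig,
    TrainingConfig,
    build_network,
    generate_dataset,
    generate_segment,
    predict,
    train,
)
from nmrmultiplet.evaluation import label_runs

config = SimulationConfig.easy_mode()
dataset = generate_dataset(config, 300, (0.75, 0.25), seed=1)

network = NetworkConfig(
    conv_filters_each=8, post_conv_dense_units=32, lstm_units_per_direction=48,
    dense_stack_units=(64, 32, 8), temporal_pool=8,
)
model = build_network(network, seed=0)
clf = train(
    model,
    dataset,
    TrainingConfig(n_epochs=3, batch_size=8, learning_rate=2.5e-3,
                   lr_schedule="cosine", normalization="max-abs-sqrt", seed=0),
    network_config=network,
    log=print,
)
print(f"\nheld-out point accuracy after 3 epochs: {clf.history['val_accuracy'][-1]:.3f}")

fresh = generate_segment(config, np.random.default_rng(99))
result = predict(clf, fresh.intensity)
agree = float(np.mean(result.labels == fresh.labels))
print(f"agreement with ground truth on a fresh segment: {agree:.3f}")
print("predicted runs:", [(lab, a, b) for lab, a, b in label_runs(result.labels) if lab])
print("true runs:     ", [(lab, a, b) for lab, a, b in label_runs(fresh.labels) if lab])
# The predicted nonzero runs should roughly coincide with the true signal
# regions; class identity improves with longer training.
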