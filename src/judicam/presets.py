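"""Published training-parameter presets for the full-scale pipelines.

These mirror the hyperparameters reported for the original transfer-learned
ResNeXt-50 classifiers and the four map autoencoders. They describe
fine-tuning of a large pretrained backbone ("last layer" / "last block"
learning rates with the remainder frozen), so they are kept as reference
configuration data; the miniature from-scratch models in this package train
all layers with their own defaults.

Note on the autoencoder rows: the published table labels two rows
"positive AM4"; by the surrounding protocol (two autoencoders per level)
the third and fourth rows are taken to be the AM3 pair, and are named so
here.
"""

HIGH_SENSITIVITY_CLASSIFIER = {
    "epochs": 20,
    "batch_size": 72,
    "learning_rate_last_layer": 0.081,
    "learning_rate_last_block": 0.0091,
    "frozen": "all other layers",
    "optimizer": "adam",
}

HIGH_SPECIFICITY_CLASSIFIER = {
    "epochs": 20,
    "batch_size": 120,
    "learning_rate_last_layer": 0.011,
    "learning_rate_last_block": 0.0001,
    "frozen": "all other layers",
    "optimizer": "sgd",
}

AUTOENCODERS = {
    ("positive", "AM4"): {"epochs": 200, "batch_size": 50, "learning_rate": 0.80, "optimizer": "sgd"},
    ("negative", "AM4"): {"epochs": 150, "batch_size": 60, "learning_rate": 0.70, "optimizer": "sgd"},
    # published as a second "positive (AM4)" row; interpreted as the AM3 pair
    ("positive", "AM3"): {"epochs": 250, "batch_size": 80, "learning_rate": 0.85, "optimizer": "sgd"},
    ("negative", "AM3"): {"epochs": 300, "batch_size": 85, "learning_rate": 0.75, "optimizer": "sgd"},
}
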