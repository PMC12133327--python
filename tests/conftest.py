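"""Shared fixtures.

The expensive artifacts (the end-to-end demo run, which trains three
classifiers and four autoencoders) are session-scoped so the whole suite
pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from judicam.cli_io import RunConfig, run_end_to_end
from judicam.synthetic_data import generate_dataset, split_dataset


@pytest.fixture(scope="session")
def dataset():
    """The default study dataset: 100+100 easy 64x64 images, seed 7."""
    return generate_dataset(100, 100, side=64, difficulty="easy", seed=7)


@pytest.fixture(scope="session")
def splits(dataset):
    return split_dataset(dataset, seed=7)


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    """One full end-to-end run with the default configuration."""
    out = tmp_path_factory.mktemp("demo_run")
    return run_end_to_end(RunConfig(out_dir=str(out)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
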