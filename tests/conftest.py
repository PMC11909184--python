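"""Shared fixtures: small seeded synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from modhash.synthetic import SyntheticConfig, default_label_space, generate_dataset


@pytest.fixture(scope="session")
def micro_dataset(tmp_path_factory):
    """A very small dataset (15 combos x 9 images, 16 px) for plumbing tests."""
    cfg = SyntheticConfig(
        label_space=default_label_space(),
        image_size=16,
        n_per_combination=9,
        split_fractions=(0.6, 0.25, 0.15),
        seed=7,
        noise_level=0.05,
    )
    out = tmp_path_factory.mktemp("micro_data")
    manifest = generate_dataset(cfg, out)
    return cfg, manifest, out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
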