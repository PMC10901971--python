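"""Shared fixtures: small seeded synthetic datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from cardiolead.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 mixed-pathology records at 500 Hz, default priors, seed 0."""
    records, manifest = generate_dataset(SynthConfig(n_records=60, seed=0))
    return records, manifest


@pytest.fixture(scope="session")
def separable_dataset():
    """500 records over three well-separated classes (NORM/CLBBB/LVH)."""
    cfg = SynthConfig(
        n_records=500,
        seed=11,
        class_priors={"NORM": 0.34, "CLBBB": 0.33, "LVH": 0.33},
    )
    records, _ = generate_dataset(cfg)
    return records


@pytest.fixture(scope="session")
def imi_dataset():
    """240 records, half NORM, half inferior infarction (IMI)."""
    cfg = SynthConfig(
        n_records=240, seed=5, class_priors={"NORM": 0.5, "IMI": 0.5}
    )
    records, _ = generate_dataset(cfg)
    return records


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
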