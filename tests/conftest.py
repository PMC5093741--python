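"""Shared fixtures: random-sequence helpers and one cached noise-free
synthetic genome pair reused by the recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from orgdecay.synthetic_data import GeneratorConfig, make_organelle_pair

BASES = list("ACGT")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, n))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noise_free_pair():
    """One noise-free (identity 1.0, no read errors) synthetic pair with
    its truth manifest; session-scoped because generation and detection
    are the expensive steps."""
    config = GeneratorConfig(seed=7, mipt_identity=1.0)
    mito, plastid, features, manifest = make_organelle_pair(config)
    return config, mito, plastid, features, manifest
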