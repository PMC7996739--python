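from __future__ import annotations

import numpy as np
import pytest

from mirscout.synthetic import build_family, implant, make_hairpin


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def hairpin_and_family():
    rng = np.random.default_rng(7)
    hairpin = make_hairpin(30, 6, rng, name="famT")
    family = build_family(hairpin, rng)
    return hairpin, family


@pytest.fixture(scope="session")
def small_world():
    """A 200 kb world with 6 implanted precursors and 6 decoys."""
    return implant(genome_length=200_000, n_hairpins=6, n_decoys=6, seed=5)
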