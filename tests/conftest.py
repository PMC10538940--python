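"""Shared fixtures: small synthetic libraries generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from vscreen.data import assign_training_labels, stratified_library_split
from vscreen.fingerprints import Fingerprint
from vscreen.synthetic import (
    SyntheticLibraryConfig,
    generate_chemotypes,
    generate_screening_library,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_fp(bits, n_bits=64) -> Fingerprint:
    return Fingerprint(on_bits=tuple(bits), n_bits=n_bits)


def random_fingerprints(rng: np.random.Generator, n: int, n_bits: int = 128,
                        popcount: int = 12) -> list[Fingerprint]:
    out = []
    for _ in range(n):
        k = int(rng.integers(1, popcount + 1))
        out.append(Fingerprint(tuple(int(b) for b in rng.choice(n_bits, k, replace=False)),
                               n_bits=n_bits))
    return out


@pytest.fixture(scope="session")
def small_config() -> SyntheticLibraryConfig:
    # deliberately enriched prevalence so tiny folds still hold actives
    return SyntheticLibraryConfig(
        n_compounds=5000, active_fraction_target=0.01, n_chemotypes=12, seed=11
    )


@pytest.fixture(scope="session")
def small_templates(small_config):
    return generate_chemotypes(small_config)


@pytest.fixture(scope="session")
def small_library(small_config, small_templates):
    records = generate_screening_library(small_templates, small_config)
    return assign_training_labels(records)


@pytest.fixture(scope="session")
def small_folds(small_library):
    return stratified_library_split(small_library, k=10, seed=5)
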