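"""Shared fixtures: a small, fast synthetic study for unit tests.

The small study uses shorter domains and genome than the full defaults so
the whole unit suite stays quick; the end-to-end acceptance test builds
the full-size study itself.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from isdetect.phmm import calibrate_noise_cutoff
from isdetect.synth import (
    FixtureSpec,
    build_models,
    build_reference_db,
    make_decoys,
    make_families,
    plant_genome,
)


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(
        rng_seed=7,
        n_families=2,
        seqs_per_family=12,
        domain_len_aa=60,
        genome_len=30_000,
        n_planted=3,
        decoy_count=120,
        decoy_len_aa=200,
    )


@pytest.fixture(scope="session")
def small_families(small_spec):
    return make_families(small_spec)


@pytest.fixture(scope="session")
def small_models(small_spec, small_families):
    models = build_models(small_families)
    decoys = make_decoys(small_spec, small_families)
    for m in models:
        calibrate_noise_cutoff(m, decoys)
    return models


@pytest.fixture(scope="session")
def small_ref_db(small_families):
    return build_reference_db(small_families)


@pytest.fixture(scope="session")
def small_genome(small_spec, small_families):
    genome, truth, features = plant_genome(small_spec, small_families)
    return genome, truth, features
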