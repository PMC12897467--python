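"""Shared fixtures: worked cases and a default synthetic cohort."""

from __future__ import annotations

import pytest
from hypothesis import settings

from acidbase import bench

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from acidbase.cases import load_cases
from acidbase.chem import panel_table
from acidbase.cohort import CohortSpec, generate_cohort, make_temporal_split


@pytest.fixture(scope="session")
def cases_df():
    return load_cases()


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions: n=2000, seed 42, default marginals."""
    return generate_cohort(CohortSpec(n=2000, seed=42))


@pytest.fixture(scope="session")
def default_panels(default_cohort):
    return panel_table(default_cohort.records)


@pytest.fixture(scope="session")
def dev_features(default_cohort):
    """Development-half feature table after the emulated temporal split."""
    dev, _ = make_temporal_split(default_cohort, 0.654)
    return bench.feature_table(dev.records, panel_table(dev.records))
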