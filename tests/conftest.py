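"""Shared fixtures: simulated cohorts and small hand-built objects."""

from __future__ import annotations

import pytest

from pedvar.annotations import annotation_map
from pedvar.filtering import FilterConfig
from pedvar.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def make_cohort():
    """Factory for simulated cohorts with caching across tests."""
    cache: dict = {}

    def _make(seed: int, **kwargs):
        key = (seed, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = simulate_cohort(SimulationConfig(seed=seed, **kwargs))
        return cache[key]

    return _make


@pytest.fixture(scope="session")
def default_cohort(make_cohort):
    return make_cohort(1234)


def wgs_filter_config(cohort) -> FilterConfig:
    """Cascade configuration matching the cohort's sequenced affected set."""
    return FilterConfig(
        affected_sample_ids=tuple(cohort.truth.wgs_ids),
        panel_genes=frozenset(cohort.config.panel_genes),
    )


@pytest.fixture()
def annotations_by_key(default_cohort):
    return annotation_map(default_cohort.annotations)
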