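"""Shared fixtures: small synthetic landscapes and training tables."""

import numpy as np
import pytest

import seasdm as s


@pytest.fixture(scope="session")
def small_grid():
    return s.GridSpec(n_rows=30, n_cols=30)


@pytest.fixture(scope="session")
def strong_table():
    """Strong-signal single-driver training table (300 presences,
    2,000 background on a 200x200 grid)."""
    stack, truth = s.single_driver_scenario(seed=11)
    return s.make_presence_table(stack, truth, 300, 2000, seed=12)


@pytest.fixture(scope="session")
def small_driver_table():
    """A cheaper single-driver table for unit-level model checks."""
    stack, truth = s.single_driver_scenario(seed=21, n_rows=80, n_cols=80)
    return s.make_presence_table(stack, truth, 120, 600, seed=22)


@pytest.fixture(scope="session")
def tiny_landscape():
    """Default-scenario landscape on a small grid, with seasonal stacks."""
    from seasdm.pipeline import build_candidate_stack

    scenario = s.default_scenario(seed=5, n_rows=40, n_cols=40)
    landscape = s.generate_landscape(scenario)
    stacks = {
        season: build_candidate_stack(landscape, season, include_elevation=False)
        for season in ("winter", "spring", "summer", "autumn")
    }
    return scenario, landscape, stacks
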