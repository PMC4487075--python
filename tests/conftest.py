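"""Shared fixtures: small designs, coarse solver profiles, and a cached
reward-rate optimum so expensive objects are built once per session."""
import numpy as np
import pytest

from multiddm import (ExperimentDesign, RewardSpec, default_template,
                      make_stimulus_profile, optimize_bounds)


@pytest.fixture(scope="session")
def profile_fine():
    """1 ms grid over the 2 s stimulus (solver reference resolution)."""
    return make_stimulus_profile(2.0, 0.001)


@pytest.fixture(scope="session")
def profile_coarse():
    """10 ms grid: the resolution used for fitting/optimization."""
    return make_stimulus_profile(2.0, 0.01)


@pytest.fixture(scope="session")
def profile_long():
    """Long flat horizon for constant-drift closed-form oracles."""
    return make_stimulus_profile(10.0, 0.001)


@pytest.fixture(scope="session")
def small_template():
    """One-coherence template subject (3 condition cells)."""
    return default_template(coherences=(0.7,))


@pytest.fixture(scope="session")
def small_design(small_template):
    return ExperimentDesign(coherences=small_template.coherences,
                            headings_deg=(-16., -8., -2., 2., 8., 16.))


@pytest.fixture(scope="session")
def small_opt(small_template, small_design, profile_coarse):
    """Reward-rate optimum of the small template (shared, seeded)."""
    return optimize_bounds(small_template, small_design, RewardSpec(),
                           n_restarts=3, seed=7, profile=profile_coarse,
                           n_x=81)
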