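import datetime as dt

import numpy as np
import pytest

from ihcrisk import (
    CohortMember,
    MatchCriteria,
    PhantomSpec,
    SimParams,
    build_default_stain_basis,
    eligible_cases,
    incidence_density_match,
    render_phantom,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def basis():
    return build_default_stain_basis()


@pytest.fixture(scope="session")
def phantom(basis):
    """One noise-free phantom with 25%/20% positive fractions."""
    spec = PhantomSpec(
        brown_positive_fraction=0.25, blue_positive_fraction=0.20, noise_sd=0.0, seed=11
    )
    rgb, truth = render_phantom(spec, basis)
    return spec, rgb, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A 3000-member simulated cohort (session-cached for speed)."""
    return simulate_cohort(SimParams(n=3000, seed=5))


@pytest.fixture(scope="session")
def matched_sample(small_cohort):
    criteria = MatchCriteria()
    cases = eligible_cases(small_cohort, criteria)
    pairs, unmatched = incidence_density_match(cases, small_cohort, criteria, seed=9)
    return pairs, unmatched


def make_member(**kwargs) -> CohortMember:
    """Handcrafted cohort member with sensible defaults."""
    defaults = dict(
        id=0,
        race="White",
        age_at_entry=64.0,
        entry_date=dt.date(2000, 1, 1),
        psa=5.0,
        inflammation="none",
        nfkb_expr=-5.0,
        gdf15_expr=-7.0,
        event_time=10.0,
        is_case=False,
    )
    defaults.update(kwargs)
    return CohortMember(**defaults)


@pytest.fixture
def member_factory():
    return make_member


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
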