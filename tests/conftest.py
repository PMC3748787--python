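import numpy as np
import pytest
from hypothesis import settings

from natalstrat import load_uk_regions
from natalstrat.io import MonthOfBirthTable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uk_regions():
    return load_uk_regions()


@pytest.fixture
def flat_table():
    """1,000 births in every month of a non-leap year."""
    return MonthOfBirthTable("UK", 1950, np.full(12, 1000.0))


@pytest.fixture(scope="session")
def uk_like():
    """Structured synthetic population with its case/control distributions."""
    from natalstrat.confounding import (
        case_mixture_from_regions,
        case_month_distribution,
        control_month_distribution,
    )
    from natalstrat.simulate import uk_like_population

    tables, regions, year_weights = uk_like_population(seed=0)
    mixture = case_mixture_from_regions(tables, regions, year_weights)
    case_dist = case_month_distribution(tables, mixture)
    ctrl_dist = control_month_distribution(tables)
    return {
        "tables": tables,
        "regions": regions,
        "year_weights": year_weights,
        "mixture": mixture,
        "case_dist": case_dist,
        "ctrl_dist": ctrl_dist,
    }
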