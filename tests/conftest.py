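import numpy as np
import pytest

from nichepart.core.types import FishRecord, PREY_CATEGORIES


def make_fish(
    fish_id="f1",
    species="charr",
    habitat="littoral",
    month="June",
    year=2005,
    total_length=20.0,
    weight=100.0,
    fullness=None,
    gear_class="survey",
):
    """Build a valid FishRecord from a category->fullness mapping."""
    fullness = dict(fullness or {})
    total = sum(fullness.values())
    return FishRecord(
        fish_id=fish_id,
        species=species,
        habitat=habitat,
        month=month,
        year=year,
        total_length=total_length,
        weight=weight,
        stomach_total_fullness=total,
        fullness_by_prey=fullness,
        gear_class=gear_class,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def simplex_pair(rng):
    x = rng.dirichlet(np.ones(len(PREY_CATEGORIES)))
    y = rng.dirichlet(np.ones(len(PREY_CATEGORIES)))
    return x, y
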