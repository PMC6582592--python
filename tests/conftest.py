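import numpy as np
import pytest

from vegdyn.climate import make_climate
from vegdyn.states import CompositionClass, SpeciesPool, StateTable
from vegdyn.synthetic import (
    HazardParams,
    KernelConfig,
    make_site_grid,
    make_truth_kernel,
    simple_pool,
    three_state_kernel,
)


@pytest.fixture(scope="session")
def pool():
    return simple_pool()


@pytest.fixture(scope="session")
def pool20():
    codes = ("piab", "fasy", "lade", "pisy", "abal") + tuple(f"sp{i:02d}" for i in range(15))
    return SpeciesPool(codes)


@pytest.fixture()
def small_table(pool):
    table = StateTable(pool)
    for code in pool.species:
        table.add_state(CompositionClass("dominated", (code,)), 5, 1)
    return table


@pytest.fixture(scope="session")
def three_state():
    """(table, kernel) for the cyclic 3-state kernel."""
    return three_state_kernel(seed=0)


@pytest.fixture()
def flat_climate():
    """Single-region constant climate, long enough for most unit tests."""
    return make_climate({0: 9.0}, year0=2000, n_years=300, temp_noise_sd=0.0, seed=0)


@pytest.fixture()
def small_site():
    return make_site_grid(12, 12, seed=1)


def constant_hazard(h: float) -> HazardParams:
    """R- and T-independent hazard exactly equal to ``h``.

    For h <= 1/2 a zero-steepness logistic gives base/2; above that the
    midpoint is pushed to -inf so the logistic saturates at 1."""
    if h <= 0.5:
        return HazardParams(base=2 * h, midpoint=0.0, steepness=0.0)
    return HazardParams(base=h, midpoint=-1e9, steepness=1.0)


def two_state_constant_kernel(hazard_a: float = 0.2, hazard_b: float = 0.2):
    """Two dominated states flipping into each other at constant hazards."""
    pool = simple_pool()
    table = StateTable(pool)
    table.add_state(CompositionClass("dominated", ("piab",)), 5, 1)
    table.add_state(CompositionClass("dominated", ("fasy",)), 5, 1)
    config = KernelConfig(
        hazards={0: constant_hazard(hazard_a), 1: constant_hazard(hazard_b)},
        successors={0: (1,), 1: (0,)},
    )
    return table, make_truth_kernel(table, config, seed=0)
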