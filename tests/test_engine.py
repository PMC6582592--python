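import numpy as np
import pandas as pd
import pytest

from vegdyn import engine
from vegdyn.attributes import build_attribute_db
from vegdyn.climate import make_climate
from vegdyn.spatial import (
    TIER1_OFFSETS,
    TIER2_OFFSETS,
    distance_to_edge_grid,
    tier_share_grids,
    tier_shares_at,
)
from vegdyn.states import CompositionClass, SpeciesPool, StateTable
from vegdyn.synthetic import (
    SiteGrid,
    analytic_stationary,
    make_site_grid,
    simple_pool,
)
from vegdyn.transition import kernel_tabulated

from conftest import two_state_constant_kernel


# ---------------------------------------------------------------------------
# spatial predictors


class TestTierShares:
    def test_offset_counts(self):
        assert len(TIER1_OFFSETS) == 8
        assert len(TIER2_OFFSETS) == 20
        # tier 2: centre distance <= 300 m, excluding focal and tier 1
        for dr, dc in TIER2_OFFSETS:
            assert dr * dr + dc * dc <= 9 and max(abs(dr), abs(dc)) > 1

    def _uniform_setup(self, state_id=0, shape=(7, 7)):
        pool = simple_pool()
        table = StateTable(pool)
        for code in pool.species:
            table.add_state(CompositionClass("dominated", (code,)), 5, 1)
        states = np.full(shape, state_id, np.int32)
        active = np.ones(shape, bool)
        return table, states, active

    def test_all_neighbours_same_species(self):
        table, states, active = self._uniform_setup(0)
        w = table.species_weight_matrix()
        t1, t2 = tier_shares_at(states, active, w, np.array([3]), np.array([3]))
        assert t1[0, 0] == pytest.approx(1.0)
        assert t2[0, 0] == pytest.approx(1.0)
        assert t1[0, 1:].sum() == 0.0

    def test_corner_cell_fixed_denominator(self):
        table, states, active = self._uniform_setup(0)
        w = table.species_weight_matrix()
        t1, _ = tier_shares_at(states, active, w, np.array([0]), np.array([0]))
        # only 3 of 8 neighbours are in bounds
        assert t1[0, 0] == pytest.approx(3.0 / 8.0)

    def test_mixed_neighbourhood_hand_computed(self):
        pool = simple_pool()
        table = StateTable(pool)
        for code in pool.species:
            table.add_state(CompositionClass("dominated", (code,)), 5, 1)
        mix = table.add_state(CompositionClass("mixture", ("piab", "fasy")), 4, 1)
        states = np.zeros((5, 5), np.int32)
        states[1, 2] = 1  # fasy N
        states[2, 1] = 2  # quro W
        states[1, 1] = mix.state_id  # piab+fasy NW
        active = np.ones((5, 5), bool)
        w = table.species_weight_matrix()
        t1, t2 = tier_shares_at(states, active, w, np.array([2]), np.array([2]))
        # hand computation over the 8 neighbours of (2,2):
        # 5 piab-dominated (1 each), 1 fasy, 1 quro, 1 mixture (0.5/0.5)
        assert t1[0, pool.index("piab")] == pytest.approx((5 + 0.5) / 8)
        assert t1[0, pool.index("fasy")] == pytest.approx((1 + 0.5) / 8)
        assert t1[0, pool.index("quro")] == pytest.approx(1.0 / 8)
        # tier 2: of the 20 cells, 4 (the +-3 offsets) fall outside the 5x5
        # grid and count as zero weight in the fixed denominator
        assert t2[0, pool.index("piab")] == pytest.approx(16.0 / 20.0)

    def test_inactive_cells_dilute_shares(self):
        table, states, active = self._uniform_setup(0)
        active[2, 3] = False  # neighbour of the focal cell
        w = table.species_weight_matrix()
        t1, _ = tier_shares_at(states, active, w, np.array([2]), np.array([2]))
        assert t1[0, 0] == pytest.approx(7.0 / 8.0)

    def test_grid_variant_matches_pointwise(self):
        rng = np.random.default_rng(0)
        table, states, active = self._uniform_setup(0, shape=(9, 9))
        states = rng.integers(0, 3, (9, 9)).astype(np.int32)
        active[rng.random((9, 9)) < 0.2] = False
        w = table.species_weight_matrix()
        g1, g2 = tier_share_grids(states, active, w)
        rows, cols = np.nonzero(active)
        p1, p2 = tier_shares_at(states, active, w, rows, cols)
        np.testing.assert_allclose(g1[rows, cols], p1, atol=1e-12)
        np.testing.assert_allclose(g2[rows, cols], p2, atol=1e-12)


class TestDistanceToEdge:
    def test_boundary_cell(self):
        active = np.ones((5, 5), bool)
        d = distance_to_edge_grid(active)
        assert d[0, 2] == 100.0
        assert d[2, 2] == 300.0

    def test_cap_in_large_block(self):
        active = np.ones((21, 21), bool)
        d = distance_to_edge_grid(active)
        # oracle: Chebyshev scan from the centre to the nearest outside cell
        cheb = min(10 + 1, 10 + 1)
        assert d[10, 10] == min(cheb * 100.0, 1000.0) == 1000.0

    def test_inactive_hole(self):
        active = np.ones((9, 9), bool)
        active[4, 4] = False
        d = distance_to_edge_grid(active)
        assert d[4, 5] == 100.0
        assert d[4, 4] == 0.0


# ---------------------------------------------------------------------------
# scheduling and stepping


class _FixedModel:
    """Point-mass or fixed-matrix heads for engine unit tests."""

    requires_features = False
    requires_context = True

    def __init__(self, p_dr_row, state_map, state_class_ids, horizon=10):
        self.p_dr_row = np.asarray(p_dr_row, float)
        self.state_map = state_map  # current state -> target state
        self.state_class_ids = np.asarray(state_class_ids)
        self.n_dr = horizon + 1

    def predict(self, X=None, context=None):
        n = len(context)
        p_dr = np.tile(self.p_dr_row, (n, 1))
        p_st = np.zeros((n, len(self.state_class_ids)))
        ids = list(self.state_class_ids)
        for i, s in enumerate(context["state_id"]):
            p_st[i, ids.index(self.state_map[int(s)])] = 1.0
        return p_dr, p_st


def _flat_landscape(table, shape=(6, 6), state=0):
    site = make_site_grid(*shape, seed=0)
    return engine.Landscape(
        site, table,
        np.full(shape, state, np.int32), np.zeros(shape, np.int32),
    )


@pytest.fixture()
def climate60():
    return make_climate({0: 9.0}, 2000, 60, temp_noise_sd=0.0, seed=0)


class TestScheduleTransition:
    def test_point_mass_offset(self, climate60):
        table, _ = two_state_constant_kernel()
        land = _flat_landscape(table)
        p = np.zeros(11)
        p[3] = 1.0
        model = _FixedModel(p, {0: 1, 1: 0}, [0, 1])
        rng = np.random.default_rng(0)
        engine.initialize_schedules(land, model, climate60, 2000, rng)
        assert (land.sched[land.site.active] == 2003).all()
        assert (land.requery[land.site.active] == engine.NO_SCHEDULE).all()

    def test_censored_requery_after_horizon(self, climate60):
        table, _ = two_state_constant_kernel()
        land = _flat_landscape(table)
        p = np.zeros(11)
        p[0] = 1.0
        model = _FixedModel(p, {0: 1, 1: 0}, [0, 1])
        engine.initialize_schedules(land, model, climate60, 2000, np.random.default_rng(0))
        assert (land.sched[land.site.active] == engine.NO_SCHEDULE).all()
        assert (land.requery[land.site.active] == 2010).all()

    def test_uniform_head_frequencies(self, climate60):
        table, _ = two_state_constant_kernel()
        land = _flat_landscape(table, shape=(100, 100))
        model = _FixedModel(np.full(11, 1 / 11), {0: 1, 1: 0}, [0, 1])
        engine.initialize_schedules(land, model, climate60, 2000, np.random.default_rng(1))
        offsets = np.where(
            land.sched[land.site.active] == engine.NO_SCHEDULE,
            0,
            land.sched[land.site.active] - 2000,
        )
        counts = np.bincount(offsets, minlength=11)
        n = land.n_active
        se = np.sqrt((1 / 11) * (10 / 11) / n)
        assert (np.abs(counts / n - 1 / 11) < 4 * se).all()


class TestStep:
    def test_no_schedule_ages_everyone(self, climate60):
        table, _ = two_state_constant_kernel()
        land = _flat_landscape(table)
        p = np.zeros(11)
        p[0] = 1.0
        model = _FixedModel(p, {0: 1, 1: 0}, [0, 1])
        rngs = engine.make_rng_streams(0)
        engine.initialize_schedules(land, model, climate60, 2000, rngs["schedule"])
        before = land.state.copy()
        engine.step(land, model, climate60, 2000, None, rngs)
        np.testing.assert_array_equal(land.state, before)
        assert (land.res_time[land.site.active] == 1).all()

    def test_deterministic_transition_next_year(self, climate60):
        table, _ = two_state_constant_kernel()
        land = _flat_landscape(table, state=0)
        p = np.zeros(11)
        p[1] = 1.0
        model = _FixedModel(p, {0: 1, 1: 0}, [0, 1])
        rngs = engine.make_rng_streams(0)
        engine.initialize_schedules(land, model, climate60, 2000, rngs["schedule"])
        engine.step(land, model, climate60, 2000, None, rngs)
        act = land.site.active
        assert (land.state[act] == 1).all()
        assert (land.res_time[act] == 0).all()
        # and the next schedule was drawn immediately
        assert (land.sched[act] == 2002).all()

    def test_residence_time_law_along_run(self, climate60, three_state):
        table, kernel = three_state
        tab = kernel_tabulated(kernel, r_max=40, fixed_temperature=9.0)
        land = _flat_landscape(table, shape=(10, 10))
        rngs = engine.make_rng_streams(3)
        engine.initialize_schedules(land, tab, climate60, 2000, rngs["schedule"])
        for t in range(30):
            prev_s = land.state.copy()
            prev_r = land.res_time.copy()
            engine.step(land, tab, climate60, 2000 + t, None, rngs)
            act = land.site.active
            changed = land.state != prev_s
            assert (land.res_time[act & changed] == 0).all()
            assert (land.res_time[act & ~changed] == prev_r[act & ~changed] + 1).all()

    def test_occupancy_matches_stationary(self, three_state):
        table, kernel = three_state
        climate = make_climate({0: 9.0}, 2000, 240, temp_noise_sd=0.0, seed=0)
        tab = kernel_tabulated(kernel, r_max=80, fixed_temperature=9.0)
        land = _flat_landscape(table, shape=(40, 40))
        out = engine.run(land, tab, climate, years=220, seed=5)
        occ = np.bincount(out.final.state[land.site.active], minlength=3) / land.n_active
        ana = analytic_stationary(kernel, 9.0, r_max=80)
        assert np.abs(occ - ana.occupancy).max() < 0.04  # 1600 cells, single year

    def test_attribute_refresh(self, climate60):
        table, _ = two_state_constant_kernel()
        land = _flat_landscape(table)
        recs = pd.DataFrame(
            {"state_id": [0, 1], "R": [0, 0], "live_carbon": [10.0, 99.0]}
        )
        db = build_attribute_db(recs)
        p = np.zeros(11)
        p[1] = 1.0
        model = _FixedModel(p, {0: 1, 1: 0}, [0, 1])
        rngs = engine.make_rng_streams(0)
        engine.initialize_schedules(land, model, climate60, 2000, rngs["schedule"])
        engine.step(land, model, climate60, 2000, db, rngs)
        act = land.site.active
        assert (land.attributes["live_carbon"][act] == 99.0).all()


class TestRun:
    def test_zero_years_outputs_initial(self, climate60, three_state):
        table, kernel = three_state
        tab = kernel_tabulated(kernel, r_max=40, fixed_temperature=9.0)
        land = _flat_landscape(table)
        out = engine.run(land, tab, climate60, years=0, seed=0)
        assert list(out.state_rasters) == [2000]
        assert len(out.summary) == 1

    def test_same_seed_bit_identical(self, climate60, three_state):
        table, kernel = three_state
        tab = kernel_tabulated(kernel, r_max=40, fixed_temperature=9.0)
        outs = []
        for _ in range(2):
            land = _flat_landscape(table, shape=(12, 12))
            outs.append(engine.run(land, tab, climate60, years=40, seed=11))
        np.testing.assert_array_equal(outs[0].final.state, outs[1].final.state)
        np.testing.assert_array_equal(outs[0].final.res_time, outs[1].final.res_time)
        pd.testing.assert_frame_equal(outs[0].summary, outs[1].summary)

    def test_different_seed_differs(self, climate60, three_state):
        table, kernel = three_state
        tab = kernel_tabulated(kernel, r_max=40, fixed_temperature=9.0)
        a = engine.run(_flat_landscape(table, shape=(12, 12)), tab, climate60, years=40, seed=1)
        b = engine.run(_flat_landscape(table, shape=(12, 12)), tab, climate60, years=40, seed=2)
        assert (a.final.state != b.final.state).any()

    def test_inactive_cells_untouched(self, climate60, three_state):
        table, kernel = three_state
        tab = kernel_tabulated(kernel, r_max=40, fixed_temperature=9.0)
        active = np.ones((10, 10), bool)
        active[:3, :3] = False
        site = SiteGrid(
            np.full((10, 10), 50.0), np.full((10, 10), 0.5),
            np.zeros((10, 10), int), active,
        )
        land = engine.Landscape(site, table, np.zeros((10, 10), np.int32), np.zeros((10, 10), np.int32))
        out = engine.run(land, tab, climate60, years=30, seed=0)
        assert (out.final.res_time[~active] == 0).all()
        assert (out.final.state[~active] == 0).all()


class TestLandscapeSummary:
    def test_uniform_single_class(self, three_state):
        table, _ = three_state
        land = _flat_landscape(table, state=1)
        row = engine.landscape_summary(land, 2000)
        assert row["comp:FASY"] == pytest.approx(1.0)
        assert row["comp:other"] == 0.0

    def test_frequencies_sum_to_one(self, three_state):
        table, _ = three_state
        land = _flat_landscape(table)
        rng = np.random.default_rng(0)
        land.state[:] = rng.integers(0, 3, land.state.shape)
        row = engine.landscape_summary(land, 2000)
        comp_total = sum(v for k, v in row.items() if k.startswith("comp:"))
        lai_total = sum(v for k, v in row.items() if k.startswith("lai:"))
        assert comp_total == pytest.approx(1.0)
        assert lai_total == pytest.approx(1.0)

    def test_top18_plus_other_against_hand_ranking(self):
        # 30 composition classes with known counts
        codes = tuple(f"s{i:02d}" for i in range(30))
        pool = SpeciesPool(codes)
        table = StateTable(pool)
        for code in codes:
            table.add_state(CompositionClass("dominated", (code,)), 5, 1)
        shape = (30, 31)
        site = make_site_grid(*shape, seed=0)
        rng = np.random.default_rng(1)
        # cell counts 1..30 for classes 0..29, rest filled with class 0
        cells = []
        for sid in range(30):
            cells += [sid] * (sid + 1)
        cells += [0] * (shape[0] * shape[1] - len(cells))
        states = np.array(cells, np.int32)
        rng.shuffle(states)
        land = engine.Landscape(site, table, states.reshape(shape), np.zeros(shape, np.int32))
        row = engine.landscape_summary(land, 2000)
        # independent hand ranking via a plain counter
        from collections import Counter

        tally = Counter(states.tolist())
        ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        n = states.size
        for sid, count in ranked[:18]:
            label = table[sid].composition.label()
            assert row[f"comp:{label}"] == pytest.approx(count / n)
        expected_other = sum(c for _, c in ranked[18:]) / n
        assert row["comp:other"] == pytest.approx(expected_other)
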