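import numpy as np
import pandas as pd
import pytest

from vegdyn.climate import make_climate
from vegdyn.synthetic import (
    extract_training_examples,
    make_site_grid,
    simulate_trajectories,
)
from vegdyn.transition import (
    ExampleSet,
    FeatureSchema,
    KernelDirectModel,
    MLPTransitionModel,
    ModelConfig,
    build_feature_matrix,
    evaluate,
    fit_dnn,
    fit_tabulated,
    kernel_tabulated,
)
from vegdyn.transition.metrics import mean_tv_distance


@pytest.fixture()
def schema3(pool):
    return FeatureSchema(state_ids=(0, 1, 2), species=pool.species)


def _context(n, pool, **overrides):
    base = {
        "cell_row": 0,
        "cell_col": 0,
        "year": 2000,
        "region": 0,
        "state_id": 0,
        "R": 0,
        "soil_depth": 0.0,
        "soil_fertility": 0.0,
        "tmean": 9.0,
        "edge_dist": 0.0,
    }
    for sp in pool.species:
        base[f"t1_{sp}"] = 0.0
        base[f"t2_{sp}"] = 0.0
    base.update(overrides)
    return pd.DataFrame([base] * n)


class TestFeatures:
    def test_vector_length_arithmetic(self, schema3, pool):
        # |states| + R + 2 soils + 240 climate + 2*pool shares + edge
        expected = 3 + 1 + 2 + 240 + 2 * len(pool.species) + 1
        assert schema3.length == expected
        assert len(schema3.column_names) == expected

    def test_decadal_encoding_length(self, pool):
        schema = FeatureSchema((0, 1, 2), pool.species, climate_encoding="decadal_means")
        assert schema.n_climate == 24
        assert schema.length == 3 + 1 + 2 + 24 + 2 * len(pool.species) + 1

    def test_zero_context(self, schema3, pool, flat_climate):
        X = build_feature_matrix(_context(2, pool), flat_climate, schema3)
        assert X.shape == (2, schema3.length)
        assert np.isfinite(X).all()
        names = schema3.column_names
        share_cols = [i for i, n in enumerate(names) if n.startswith(("t1_", "t2_"))]
        assert (X[:, share_cols] == 0).all()
        assert X[0, 0] == 1.0  # state one-hot

    def test_determinism(self, schema3, pool, flat_climate):
        a = build_feature_matrix(_context(3, pool), flat_climate, schema3)
        b = build_feature_matrix(_context(3, pool), flat_climate, schema3)
        np.testing.assert_array_equal(a, b)

    def test_unknown_state_rejected(self, schema3, pool, flat_climate):
        ctx = _context(1, pool, state_id=9)
        with pytest.raises(ValueError, match="absent from schema"):
            build_feature_matrix(ctx, flat_climate, schema3)

    def test_missing_climate_rejected(self, schema3, pool):
        short = make_climate({0: 9.0}, 2000, 5, seed=0)
        with pytest.raises(ValueError, match="not covered"):
            build_feature_matrix(_context(1, pool), short, schema3)

    def test_schema_hash_sensitivity(self, pool):
        a = FeatureSchema((0, 1), pool.species)
        b = FeatureSchema((0, 1, 2), pool.species)
        c = FeatureSchema((0, 1), pool.species, climate_encoding="decadal_means")
        assert len({a.schema_hash(), b.schema_hash(), c.schema_hash()}) == 3
        assert a.schema_hash() == FeatureSchema((0, 1), pool.species).schema_hash()


def _toy_examples(schema, n, rng, n_states=3, deterministic=False):
    """Synthetic example set with state-dependent or random labels."""
    states = rng.integers(0, n_states, n)
    X = np.zeros((n, schema.length), dtype=np.float32)
    X[np.arange(n), states] = 1.0
    X[:, n_states] = rng.random(n)
    if deterministic:
        # state s always transitions at dR = s + 1 into state (s + 1) % k
        y_dr = states + 1
        y_state = (states + 1) % n_states
    else:
        y_dr = rng.integers(0, schema.horizon + 1, n)
        y_state = np.where(y_dr != 0, rng.integers(0, n_states, n), -1)
    ctx = pd.DataFrame(
        {
            "cell_row": rng.integers(0, 10, n),
            "cell_col": rng.integers(0, 10, n),
            "year": 2000,
            "region": 0,
            "state_id": states,
            "R": rng.integers(0, 20, n),
            "soil_depth": 50.0,
            "soil_fertility": 0.5,
            "tmean": 9.0,
            "edge_dist": 500.0,
        }
    )
    for sp in schema.species:
        ctx[f"t1_{sp}"] = 0.0
        ctx[f"t2_{sp}"] = 0.0
    return ExampleSet(X, y_dr.astype(np.int64), y_state.astype(np.int64), ctx, schema)


class TestExampleSet:
    def test_label_validation(self, schema3, pool):
        rng = np.random.default_rng(0)
        ex = _toy_examples(schema3, 10, rng)
        bad_state = ex.y_state.copy()
        bad_state[ex.y_dr == 0] = 2  # censored rows must not carry S*
        with pytest.raises(ValueError):
            ExampleSet(ex.X, ex.y_dr, bad_state, ex.context, schema3)

    def test_cell_block_split_disjoint(self, schema3):
        rng = np.random.default_rng(1)
        ex = _toy_examples(schema3, 500, rng)
        train, val = ex.split_by_cell_block(0.3, block=2, seed=0)
        tcells = set(zip(train.context["cell_row"], train.context["cell_col"]))
        vcells = set(zip(val.context["cell_row"], val.context["cell_col"]))
        assert tcells.isdisjoint(vcells)
        assert len(train) + len(val) == len(ex)

    def test_scenario_split(self, schema3):
        rng = np.random.default_rng(2)
        a = _toy_examples(schema3, 50, rng)
        a.context["scenario"] = "A"
        b = _toy_examples(schema3, 70, rng)
        b.context["scenario"] = "B"
        both = ExampleSet.concat([a, b])
        train, val = both.split_by_scenario("B")
        assert len(val) == 70 and len(train) == 50
        with pytest.raises(ValueError):
            both.split_by_scenario("C")

    def test_save_load_round_trip(self, three_state, flat_climate, tmp_path):
        table, kernel = three_state
        site = make_site_grid(5, 5, seed=0)
        traj = simulate_trajectories(kernel, site, flat_climate, 25, np.zeros((5, 5), np.int32), seed=1)
        ex = extract_training_examples(traj, site, flat_climate, table)
        path = tmp_path / "examples.csv"
        ex.save(path)
        loaded = ExampleSet.load(path, flat_climate)
        np.testing.assert_allclose(loaded.X, ex.X, rtol=1e-6)
        np.testing.assert_array_equal(loaded.y_dr, ex.y_dr)
        np.testing.assert_array_equal(loaded.y_state, ex.y_state)

    def test_zero_tier_features(self, three_state, flat_climate):
        table, kernel = three_state
        site = make_site_grid(6, 6, seed=0)
        traj = simulate_trajectories(kernel, site, flat_climate, 20, np.zeros((6, 6), np.int32), seed=1)
        ex = extract_training_examples(traj, site, flat_climate, table)
        ablated = ex.zero_tier_features()
        names = ex.schema.column_names
        cols = [i for i, n in enumerate(names) if n.startswith(("t1_", "t2_"))]
        assert (ablated.X[:, cols] == 0).all()
        other = [i for i in range(len(names)) if i not in cols]
        np.testing.assert_array_equal(ablated.X[:, other], ex.X[:, other])


class TestTabulated:
    def test_single_example_point_mass(self, schema3):
        rng = np.random.default_rng(3)
        ex = _toy_examples(schema3, 200, rng).select(np.array([0]))
        model = fit_tabulated(ex, keys=("state_id", "R"))
        p_dr, p_st = model.predict(context=ex.context)
        assert p_dr[0, ex.y_dr[0]] == 1.0
        if ex.y_dr[0] != 0:
            pos = list(model.state_class_ids).index(ex.y_state[0])
            assert p_st[0, pos] == 1.0

    def test_hand_counted_contingency(self, schema3):
        # 20 rows over two (S, R) groups with known label counts
        rows = []
        X = np.zeros((20, schema3.length), dtype=np.float32)
        y_dr = np.array([1] * 6 + [2] * 4 + [0] * 5 + [3] * 5, dtype=np.int64)
        y_state = np.array([1] * 6 + [2] * 4 + [-1] * 5 + [1] * 5, dtype=np.int64)
        state_id = np.array([0] * 10 + [1] * 10)
        ctx = pd.DataFrame(
            {
                "cell_row": 0, "cell_col": 0, "year": 2000, "region": 0,
                "state_id": state_id, "R": np.array([4] * 10 + [7] * 10),
                "soil_depth": 0.0, "soil_fertility": 0.0, "tmean": 9.0, "edge_dist": 0.0,
            }
        )
        for sp in schema3.species:
            ctx[f"t1_{sp}"] = 0.0
            ctx[f"t2_{sp}"] = 0.0
        ex = ExampleSet(X, y_dr, y_state, ctx, schema3)
        model = fit_tabulated(ex, keys=("state_id", "R"))
        p_dr, p_st = model.predict(context=ex.context)
        # group (0, 4): dR 1 x6, dR 2 x4 -> 0.6 / 0.4; S* 1 x6, 2 x4
        assert p_dr[0, 1] == pytest.approx(0.6)
        assert p_dr[0, 2] == pytest.approx(0.4)
        ids = list(model.state_class_ids)
        assert p_st[0, ids.index(1)] == pytest.approx(0.6)
        assert p_st[0, ids.index(2)] == pytest.approx(0.4)
        # group (1, 7): censored x5, dR 3 x5
        assert p_dr[10, 0] == pytest.approx(0.5)
        assert p_dr[10, 3] == pytest.approx(0.5)

    def test_backoff_to_marginal(self, schema3):
        rng = np.random.default_rng(4)
        ex = _toy_examples(schema3, 100, rng)
        model = fit_tabulated(ex, keys=("state_id", "R"))
        ctx = ex.context.iloc[:1].copy()
        ctx["R"] = 9999
        p_dr, _ = model.predict(context=ctx)
        np.testing.assert_allclose(p_dr[0], model.marginal[0])
        assert model.backoff_count == 1

    def test_converges_to_bayes(self, three_state, flat_climate):
        # empirical conditionals keyed on the kernel's true inputs approach
        # the kernel probabilities (TV <= 0.02 at ~10^5 examples)
        table, kernel = three_state
        site = make_site_grid(32, 32, seed=5)
        traj = simulate_trajectories(kernel, site, flat_climate, 130, np.zeros((32, 32), np.int32), seed=6)
        ex = extract_training_examples(traj, site, flat_climate, table)
        assert len(ex) >= 1e5
        emp = fit_tabulated(ex, keys=("state_id", "R"), r_cap=40)
        oracle = kernel_tabulated(kernel, r_max=40, fixed_temperature=9.0)
        probe = ex.subsample(4000, np.random.default_rng(0))
        p_emp, s_emp = emp.predict(context=probe.context)
        p_ora, s_ora = oracle.predict(context=probe.context)
        tv_dr = 0.5 * np.abs(p_emp - p_ora).sum(axis=1).mean()
        tv_st = mean_tv_distance(s_emp, emp.state_class_ids, s_ora, oracle.state_class_ids)
        assert tv_dr <= 0.02
        assert tv_st <= 0.02


class TestMLP:
    def test_deterministic_mapping_learned(self, schema3):
        rng = np.random.default_rng(5)
        ex = _toy_examples(schema3, 4000, rng, deterministic=True)
        train, val = ex.select(np.arange(3000)), ex.select(np.arange(3000, 4000))
        model = fit_dnn(train, val, ModelConfig(hidden=(32,), dropout=0.0, epochs=15, seed=0))
        m = evaluate(model, val)
        assert m["top1_dr"] == 1.0
        assert m["top1_state"] == 1.0

    def test_label_shuffle_gives_majority_rate(self, schema3):
        rng = np.random.default_rng(6)
        ex = _toy_examples(schema3, 6000, rng, deterministic=True)
        # shuffle timing labels to break the feature-label link
        perm = rng.permutation(len(ex))
        shuffled = ExampleSet(
            ex.X, ex.y_dr[perm], ex.y_state[perm], ex.context, ex.schema
        )
        train = shuffled.select(np.arange(5000))
        val = shuffled.select(np.arange(5000, 6000))
        model = fit_dnn(train, val, ModelConfig(hidden=(16,), dropout=0.0, epochs=8, seed=0))
        m = evaluate(model, val)
        counts = np.bincount(train.y_dr, minlength=11)
        majority_rate = counts.max() / counts.sum()
        # binomial slack around the majority-class rate
        assert abs(m["top1_dr"] - majority_rate) < 0.06

    def test_normalized_outputs(self, schema3):
        rng = np.random.default_rng(7)
        ex = _toy_examples(schema3, 500, rng)
        model = fit_dnn(ex, None, ModelConfig(hidden=(16,), epochs=2, seed=0))
        p_dr, p_st = model.predict(ex.X)
        np.testing.assert_allclose(p_dr.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(p_st.sum(axis=1), 1.0, atol=1e-6)
        assert (p_dr >= 0).all() and (p_st >= 0).all()

    def test_divergence_raises(self, schema3):
        # a non-finite input propagates to a NaN loss, which must abort with
        # diagnostics rather than training on silently
        rng = np.random.default_rng(8)
        ex = _toy_examples(schema3, 500, rng)
        ex.X[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            fit_dnn(ex, None, ModelConfig(hidden=(32,), epochs=2, seed=0))

    def test_seeded_reproducibility(self, schema3):
        rng = np.random.default_rng(9)
        ex = _toy_examples(schema3, 1000, rng)
        cfg = ModelConfig(hidden=(16,), dropout=0.1, epochs=3, seed=42)
        m1 = fit_dnn(ex, None, cfg)
        m2 = fit_dnn(ex, None, cfg)
        p1, s1 = m1.predict(ex.X)
        p2, s2 = m2.predict(ex.X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)

    def test_save_load_round_trip(self, schema3, tmp_path):
        rng = np.random.default_rng(10)
        ex = _toy_examples(schema3, 800, rng)
        model = fit_dnn(ex, None, ModelConfig(hidden=(16, 16), epochs=2, seed=1))
        model.save(tmp_path / "model")
        loaded = MLPTransitionModel.load(tmp_path / "model")
        p1, s1 = model.predict(ex.X)
        p2, s2 = loaded.predict(ex.X)
        np.testing.assert_allclose(p1, p2, atol=1e-7)
        np.testing.assert_allclose(s1, s2, atol=1e-7)
        assert (tmp_path / "model" / "training_log.csv").exists()

    def test_split_head_config(self, schema3):
        rng = np.random.default_rng(11)
        ex = _toy_examples(schema3, 1500, rng, deterministic=True)
        model = fit_dnn(ex, None, ModelConfig(hidden=(24,), epochs=10, seed=0, shared_trunk=False))
        m = evaluate(model, ex)
        assert m["top1_dr"] > 0.95 and m["top1_state"] > 0.95
        p_dr, p_st = model.predict(ex.X)
        np.testing.assert_allclose(p_dr.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(p_st.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_training_rejected(self, schema3):
        rng = np.random.default_rng(12)
        ex = _toy_examples(schema3, 10, rng).select(np.array([], dtype=int))
        with pytest.raises(ValueError):
            fit_dnn(ex, None, ModelConfig(hidden=(8,), epochs=1))


class _UniformModel:
    """Predicts uniform distributions; for analytic-expectation checks."""

    requires_features = False
    requires_context = True

    def __init__(self, n_states, horizon=10):
        self.state_class_ids = np.arange(n_states)
        self.n_dr = horizon + 1
        self._k = n_states

    def predict(self, X=None, context=None):
        n = len(context)
        return (
            np.full((n, self.n_dr), 1.0 / self.n_dr),
            np.full((n, self._k), 1.0 / self._k),
        )


class TestEvaluate:
    def test_perfect_predictions(self, schema3):
        rng = np.random.default_rng(13)
        ex = _toy_examples(schema3, 2000, rng, deterministic=True)
        model = fit_dnn(ex, None, ModelConfig(hidden=(32,), epochs=15, seed=0))
        m = evaluate(model, ex)
        assert m["top1_dr"] == 1.0 and m["top1_state"] == 1.0 and m["top3_state"] == 1.0

    def test_uniform_expected_top1(self, schema3):
        rng = np.random.default_rng(14)
        ex = _toy_examples(schema3, 4000, rng)
        model = _UniformModel(3)
        m = evaluate(model, ex)
        # argmax of a uniform row is the first class; expected accuracy is
        # the empirical rate of that class
        rate_dr = (ex.y_dr == 0).mean()
        rate_st = (ex.y_state[ex.y_dr != 0] == 0).mean()
        assert m["top1_dr"] == pytest.approx(rate_dr, abs=1e-12)
        assert m["top1_state"] == pytest.approx(rate_st, abs=1e-12)

    def test_top3_at_least_top1(self, schema3):
        rng = np.random.default_rng(15)
        ex = _toy_examples(schema3, 1000, rng)
        model = fit_dnn(ex, None, ModelConfig(hidden=(16,), epochs=2, seed=0))
        m = evaluate(model, ex)
        assert m["top3_state"] >= m["top1_state"]

    def test_reference_tv_zero_against_self(self, three_state, flat_climate):
        table, kernel = three_state
        site = make_site_grid(6, 6, seed=0)
        traj = simulate_trajectories(kernel, site, flat_climate, 30, np.zeros((6, 6), np.int32), seed=1)
        ex = extract_training_examples(traj, site, flat_climate, table)
        model = KernelDirectModel(kernel)
        m = evaluate(model, ex, reference=model)
        assert m["mean_tv_state"] == 0.0
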