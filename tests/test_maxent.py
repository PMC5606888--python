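import numpy as np
import pytest
from scipy.special import expit, logsumexp

from habsuit import (
    Grid,
    Raster,
    SuitabilityMap,
    average_sets,
    build_features,
    class_frequency,
    fit_maxent,
    percent_contribution,
    presence_background_auc,
    response_curve,
    run_replicates,
    sample_background,
)
from habsuit.maxent import Feature, HingeBasis, MaxentModel
from conftest import make_occurrences, make_stack


def objective(lam, fp, fb, beta):
    """Independent recomputation of the regularised maxent log-loss."""
    return (
        -float(np.mean(fp @ lam))
        + float(logsumexp(fb @ lam))
        + float(np.sum(beta * np.abs(lam)))
    )


def signal_stack(size=50, seed=0):
    """Two-layer stack where only 'signal' drives presence density."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    z = gaussian_filter(rng.standard_normal((size, size)), 5, mode="wrap")
    z = (z - z.mean()) / z.std()
    noise = gaussian_filter(rng.standard_normal((size, size)), 5, mode="wrap")
    noise = (noise - noise.mean()) / noise.std()
    stack = make_stack({"signal": z, "noise": noise})
    p = expit(2.5 * z)
    return stack, p, rng


def sample_presences(stack, p, rng, n=300):
    rows, cols = np.nonzero(stack.mask)
    w = p[rows, cols] / p[rows, cols].sum()
    idx = rng.choice(len(rows), size=n, p=w)
    g = stack.grid
    x = g.xll + (cols[idx] + 0.5) * g.cellsize
    y = g.yll + (g.nrows - rows[idx] - 0.5) * g.cellsize
    return make_occurrences(np.column_stack([x, y]))


class TestBuildFeatures:
    def test_single_knot_at_median_and_hinge_value(self):
        x = np.linspace(0, 1, 1001)
        basis = build_features({"v": "continuous"}, {"v": x}, knots_per_variable=1)
        fwd = [f for f in basis.features if f.kind == "fwd"]
        assert len(fwd) == 1 and fwd[0].knot == pytest.approx(0.5)
        assert fwd[0].evaluate(np.array([0.75]))[0] == pytest.approx(0.5)

    def test_categorical_three_levels_three_indicators(self):
        basis = build_features(
            {"c": "categorical"}, {"c": np.array([0.0, 1.0, 2.0, 1.0])}, 5
        )
        assert len(basis) == 3
        assert all(f.kind == "cat" for f in basis.features)

    def test_design_matrix_matches_hand_recompute(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(2.0, 10.0, 500)
        k = 5
        basis = build_features({"v": "continuous"}, {"v": x}, knots_per_variable=k)
        probes = np.array([2.5, 4.0, 7.3, 9.9])
        got = basis.design_matrix({"v": probes})
        # independent recompute from the stated formulas
        knots = np.quantile(x, (np.arange(k) + 1) / (k + 1))
        x_min, x_max = x.min(), x.max()
        cols = []
        for knot in knots:
            cols.append(np.maximum(0, (probes - knot) / (x_max - knot)))
            cols.append(np.maximum(0, (knot - probes) / (knot - x_min)))
        assert np.allclose(got, np.column_stack(cols))

    def test_constant_variable_emits_no_features(self):
        basis = build_features({"v": "continuous"}, {"v": np.ones(10)}, 3)
        assert len(basis) == 0

    def test_features_bounded_on_background(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 3, 1000)
        basis = build_features({"v": "continuous"}, {"v": x}, 10)
        f = basis.design_matrix({"v": x})
        assert f.min() >= 0 and f.max() <= 1 + 1e-12


class TestFitMaxent:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        fp = rng.random((20, 4))
        fb = rng.random((100, 4))
        model = fit_maxent(fp, fb, reg_multiplier=1e6)
        assert np.all(model.lam == 0)
        assert model.entropy == pytest.approx(np.log(100))
        assert np.allclose(model.logistic(fb), 0.5)

    def test_single_binary_feature_matches_grid_search(self):
        fp = np.ones((25, 1))
        fb = np.zeros((100, 1))
        fb[:50] = 1.0
        model = fit_maxent(fp, fb, reg_multiplier=2.0, tol=1e-10)
        beta = model.beta
        grid = np.arange(-5, 5, 1e-4)
        vals = [objective(np.array([g]), fp, fb, beta) for g in grid]
        best = grid[int(np.argmin(vals))]
        assert model.lam[0] == pytest.approx(best, abs=1e-3)

    def test_objective_decreases_and_gain_trace_nonnegative(self):
        rng = np.random.default_rng(1)
        fp = rng.random((50, 6))
        fb = rng.random((300, 6))
        model = fit_maxent(fp, fb)
        start = objective(np.zeros(6), fp, fb, model.beta)
        final = objective(model.lam, fp, fb, model.beta)
        assert final <= start + 1e-12
        assert all(g >= 0 for g in model.gain_trace.values())
        # the recorded gains account exactly for the objective drop
        assert sum(model.gain_trace.values()) == pytest.approx(start - final, abs=1e-8)

    def test_raw_distribution_sums_to_one(self):
        rng = np.random.default_rng(2)
        fp = rng.random((30, 5))
        fb = rng.random((200, 5))
        model = fit_maxent(fp, fb)
        assert model.raw(fb).sum() == pytest.approx(1.0, abs=1e-8)
        assert model.entropy >= 0

    def test_nonfinite_features_rejected(self):
        fp = np.array([[np.nan]])
        fb = np.zeros((5, 1))
        with pytest.raises(ValueError, match="non-finite"):
            fit_maxent(fp, fb)

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        x = rng.random(200)
        basis = build_features({"v": "continuous"}, {"v": x}, 5)
        fb = basis.design_matrix({"v": x})
        fp = basis.design_matrix({"v": rng.random(20) * 0.3 + 0.7})
        model = fit_maxent(fp, fb, basis)
        model.to_json(tmp_path / "m.json")
        back = MaxentModel.from_json(tmp_path / "m.json")
        probe = basis.design_matrix({"v": np.array([0.1, 0.5, 0.9])})
        assert np.array_equal(model.logistic(probe), back.logistic(probe))


class TestLogisticOutput:
    def hand_model(self):
        basis = HingeBasis([Feature("v", "fwd", 0.0, 0.0, 1.0)])
        fb = np.array([[0.0], [0.5], [1.0]])
        lam = np.array([2.0])
        log_z = logsumexp(fb @ lam)
        q = np.exp(fb @ lam - log_z)
        entropy = float(log_z - q @ (fb @ lam))
        return MaxentModel(basis, lam, np.zeros(1), float(log_z), entropy), fb

    def test_hand_computed_three_point_model(self):
        model, fb = self.hand_model()
        # hand arithmetic: eta = (0, 1, 2); Z = 1 + e + e^2
        z = 1 + np.e + np.e**2
        q_hand = np.array([1, np.e, np.e**2]) / z
        h_hand = -np.sum(q_hand * np.log(q_hand))
        expected = (np.exp(h_hand) * q_hand) / (1 + np.exp(h_hand) * q_hand)
        assert np.allclose(model.logistic(fb), expected)

    def test_midpoint_and_zero(self):
        model, _ = self.hand_model()
        # a cell with raw density exp(-H) scores exactly 0.5
        eta_mid = model.log_z - model.entropy
        f_mid = np.array([[eta_mid / model.lam[0]]])
        assert model.logistic(f_mid)[0] == pytest.approx(0.5)
        assert model.raw(np.array([[-1e9]]))[0] == pytest.approx(0.0)
        assert model.logistic(np.array([[-1e9]]))[0] == pytest.approx(0.0)

    def test_monotone_in_raw_density(self):
        model, _ = self.hand_model()
        f = np.linspace(0, 1, 50)[:, None]
        out = model.logistic(f)
        assert np.all(np.diff(out) > 0)


class TestSampleBackground:
    def test_uniform_bias_uniform_frequencies(self):
        r = Raster(np.zeros((2, 2)), Grid(0, 0, 1.0, 2, 2))
        rows, cols = sample_background(r, None, n=20000, seed=0)
        counts = np.bincount(rows * 2 + cols, minlength=4)
        assert np.all(np.abs(counts / 20000 - 0.25) < 0.02)

    def test_biased_two_cell_grid(self):
        from habsuit import BiasSurface

        r = Raster(np.zeros((1, 2)), Grid(0, 0, 1.0, 1, 2))
        bias = BiasSurface(Raster(np.array([[30.0, 1.0]]), r.grid), 1.0)
        rows, cols = sample_background(r, bias, n=10000, seed=1)
        frac = np.mean(cols == 0)
        assert abs(frac - 30 / 31) < 0.01

    def test_determinism(self):
        r = Raster(np.zeros((5, 5)), Grid(0, 0, 1.0, 5, 5))
        a = sample_background(r, None, 100, seed=3)
        b = sample_background(r, None, 100, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_all_nodata_errors(self):
        r = Raster(np.full((2, 2), -9999.0), Grid(0, 0, 1.0, 2, 2))
        with pytest.raises(ValueError, match="no valid cells"):
            sample_background(r, None, 10, 0)


class TestAuc:
    def test_perfect_separation(self):
        assert presence_background_auc([2, 3], [0, 1]) == 1.0

    def test_all_tied_is_half(self):
        assert presence_background_auc([1, 1, 1], [1, 1]) == 0.5

    def test_midrank_hand_value(self):
        # presences (3, 1), background (2, 1): pairs -> win, tie, win, tie
        assert presence_background_auc([3, 1], [2, 1]) == pytest.approx(0.625)


class TestRunReplicates:
    def test_single_replicate_surface_in_unit_interval(self):
        stack, p, rng = signal_stack(40, seed=7)
        occ = sample_presences(stack, p, rng, 80)
        smap, aucs, _ = run_replicates(
            occ, stack, None, n_rep=1, seed=1, n_background=500, knots_per_variable=5
        )
        v = smap.grid.valid_values()
        assert v.min() >= 0 and v.max() <= 1
        assert len(aucs) == 1

    def test_huge_regularization_gives_half_auc(self):
        stack, p, rng = signal_stack(30, seed=8)
        occ = sample_presences(stack, p, rng, 60)
        _, aucs, models = run_replicates(
            occ, stack, None, n_rep=2, seed=2, n_background=400,
            knots_per_variable=5, reg_multiplier=1e6,
        )
        assert all(abs(a - 0.5) < 0.01 for a in aucs)
        assert all(np.abs(m.lam).sum() == 0 for m in models)

    def test_strong_signal_discriminates(self):
        stack, p, rng = signal_stack(50, seed=9)
        occ = sample_presences(stack, p, rng, 250)
        _, aucs, _ = run_replicates(
            occ, stack, None, n_rep=3, seed=3, n_background=1000, knots_per_variable=8
        )
        assert np.mean(aucs) > 0.65

    def test_too_few_records_error(self):
        stack, p, rng = signal_stack(30, seed=10)
        occ = sample_presences(stack, p, rng, 3)
        with pytest.raises(ValueError, match="at least 4"):
            run_replicates(occ, stack, None, n_rep=1, seed=0)


class TestAverageSets:
    def test_identical_maps_unchanged(self):
        r = Raster(np.random.default_rng(0).random((4, 4)), Grid(0, 0, 1.0, 4, 4))
        m = SuitabilityMap(r, ["a"])
        out = average_sets([m, m, m])
        assert np.allclose(out.grid.values, r.values)

    def test_constant_maps_average(self):
        g = Grid(0, 0, 1.0, 3, 3)
        a = SuitabilityMap(Raster(np.full((3, 3), 0.2), g))
        b = SuitabilityMap(Raster(np.full((3, 3), 0.6), g))
        assert np.allclose(average_sets([a, b]).grid.values, 0.4)

    def test_five_random_maps_match_recompute(self):
        rng = np.random.default_rng(1)
        g = Grid(0, 0, 1.0, 5, 5)
        mats = [rng.random((5, 5)) for _ in range(5)]
        maps = [SuitabilityMap(Raster(m, g)) for m in mats]
        assert np.allclose(average_sets(maps).grid.values, np.mean(mats, axis=0))

    def test_nodata_propagates(self):
        g = Grid(0, 0, 1.0, 2, 2)
        a = np.array([[0.1, 0.2], [0.3, 0.4]])
        b = a.copy()
        b[0, 0] = -9999.0
        out = average_sets([SuitabilityMap(Raster(a, g)), SuitabilityMap(Raster(b, g))])
        assert not out.grid.mask[0, 0]


class TestPercentContribution:
    def test_single_variable_gets_all(self):
        rng = np.random.default_rng(2)
        x = rng.random(300)
        basis = build_features({"v": "continuous"}, {"v": x}, 5)
        fb = basis.design_matrix({"v": x})
        fp = basis.design_matrix({"v": 0.6 + 0.4 * rng.random(40)})
        model = fit_maxent(fp, fb, basis)
        contrib = percent_contribution(model)
        assert contrib["v"] == pytest.approx(100.0)

    def test_sums_to_hundred(self):
        stack, p, rng = signal_stack(40, seed=12)
        occ = sample_presences(stack, p, rng, 150)
        _, _, models = run_replicates(
            occ, stack, None, n_rep=1, seed=4, n_background=600, knots_per_variable=6
        )
        contrib = percent_contribution(models[0])
        assert contrib.sum() == pytest.approx(100.0, abs=1e-9)

    def test_informative_variable_dominates(self):
        stack, p, rng = signal_stack(50, seed=13)
        occ = sample_presences(stack, p, rng, 300)
        _, _, models = run_replicates(
            occ, stack, None, n_rep=1, seed=5, n_background=1000, knots_per_variable=8
        )
        contrib = percent_contribution(models[0])
        assert contrib["signal"] > 90.0


class TestResponseCurve:
    def test_monotone_fixture_monotone_curve(self):
        stack, p, rng = signal_stack(40, seed=14)
        occ = sample_presences(stack, p, rng, 200)
        values = np.linspace(-1.5, 1.5, 25)
        curve = response_curve("signal", occ, stack, values, n_background=800,
                               knots_per_variable=8, seed=1)
        s = curve["suitability"].to_numpy()
        # increasing over the central 90% of the probed range
        inner = s[1:-1]
        assert np.sum(np.diff(inner) >= -1e-9) >= 0.9 * (len(inner) - 1)
        assert s[-2] > s[1]

    def test_uninformative_variable_flat_near_half(self):
        stack, p, rng = signal_stack(40, seed=15)
        # presences drawn uniformly: no signal in either variable
        occ = sample_presences(stack, np.ones_like(p), rng, 200)
        curve = response_curve("noise", occ, stack, np.linspace(-1, 1, 15),
                               n_background=600, knots_per_variable=5, seed=2)
        assert np.all(np.abs(curve["suitability"] - 0.5) < 0.1)

    def test_categorical_one_value_per_level(self):
        rng = np.random.default_rng(16)
        cats = rng.integers(0, 2, (30, 30)).astype(float)
        stack = make_stack({"veg": cats}, kinds={"veg": "categorical"})
        rows, cols = np.nonzero(cats == 1)
        g = stack.grid
        pick = rng.choice(len(rows), 60)
        occ = make_occurrences(
            np.column_stack(
                [g.xll + (cols[pick] + 0.5) * g.cellsize,
                 g.yll + (g.nrows - rows[pick] - 0.5) * g.cellsize]
            )
        )
        curve = response_curve("veg", occ, stack, np.array([0.0, 1.0]),
                               n_background=500, seed=3)
        assert len(curve) == 2
        assert curve["suitability"].iloc[1] > curve["suitability"].iloc[0]


class TestClassFrequency:
    def test_uniform_map_single_class(self):
        g = Grid(0, 0, 100.0, 4, 4)
        smap = SuitabilityMap(Raster(np.full((4, 4), 0.65), g))
        recs = make_occurrences([[50, 50], [150, 150]])
        table = class_frequency(smap, recs)
        assert len(table) == 9
        row = table.iloc[6]  # [0.6, 0.7)
        assert row["pct_area"] == pytest.approx(100.0)
        assert row["pct_records"] == pytest.approx(100.0)

    def test_toy_map_hand_tally(self):
        g = Grid(0, 0, 100.0, 1, 10)
        vals = np.array([[0.05, 0.15, 0.15, 0.25, 0.45, 0.65, 0.65, 0.65, 0.85, 0.95]])
        smap = SuitabilityMap(Raster(vals, g))
        recs = make_occurrences([[50, 50], [150, 50], [550, 50], [850, 50], [950, 50]])
        table = class_frequency(smap, recs)
        # hand tally: area 1,2,1,0,1,0,3,0,2 of 10; records 1,1,0,0,0,0,1,0,2 of 5
        assert np.allclose(table["pct_area"], [10, 20, 10, 0, 10, 0, 30, 0, 20])
        assert np.allclose(table["pct_records"], [20, 20, 0, 0, 0, 0, 20, 0, 40])

    def test_columns_sum_to_hundred(self):
        rng = np.random.default_rng(17)
        g = Grid(0, 0, 100.0, 8, 8)
        smap = SuitabilityMap(Raster(rng.random((8, 8)), g))
        recs = make_occurrences(rng.uniform(0, 800, (20, 2)))
        table = class_frequency(smap, recs)
        assert table["pct_area"].sum() == pytest.approx(100.0, abs=1e-9)
        assert table["pct_records"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_top_bin_closed_above(self):
        g = Grid(0, 0, 100.0, 1, 2)
        smap = SuitabilityMap(Raster(np.array([[0.88, 0.95]]), g))
        table = class_frequency(smap, make_occurrences(np.empty((0, 2))))
        assert table["pct_area"].iloc[-1] == pytest.approx(100.0)
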