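import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esdm.env_stack import GridSpec
from esdm.projection import (
    BinaryMap,
    ScenarioDelta,
    SuitabilityMap,
    apply_scenario,
    binarize,
    project,
    range_change,
    range_change_table,
)


class ConstModel:
    def __init__(self, value, predictors):
        self.value = value
        self.predictors = predictors

    def predict(self, X):
        return np.full(len(X), self.value)


class MeanModel:
    def __init__(self, predictors):
        self.predictors = predictors

    def predict(self, X):
        v = X[self.predictors].mean(axis=1).to_numpy()
        return 1 / (1 + np.exp(-(v - v.mean()) if len(v) else v))


def random_binary_pair(seed, shape=(20, 20)):
    rng = np.random.default_rng(seed)
    grid = GridSpec(0, shape[1], 0, shape[0], 1.0)
    mask = rng.uniform(size=shape) < 0.8
    cur = (rng.uniform(size=shape) < 0.5) & mask
    fut = (rng.uniform(size=shape) < 0.5) & mask
    if not cur.any():
        cur[np.nonzero(mask)[0][0], np.nonzero(mask)[1][0]] = True
    return (
        BinaryMap(grid, cur, mask, scenario_label="current"),
        BinaryMap(grid, fut, mask, scenario_label="future"),
    )


class TestProject:
    def test_constant_model_gives_uniform_map(self, small_stack):
        m = ConstModel(0.3, small_stack.names)
        smap = project(m, small_stack)
        vals = smap.values[smap.mask]
        assert np.all(vals == 0.3)
        assert np.array_equal(smap.mask, small_stack.joint_mask)

    def test_values_at_points_match_direct_calls(self, small_stack):
        m = MeanModel(["T", "Sal"])
        smap = project(m, small_stack)
        X, rows, cols = small_stack.table()
        direct = m.predict(X)
        np.testing.assert_allclose(smap.values[rows, cols], direct)

    def test_map_mean_matches_sampled_direct_calls(self, small_stack):
        m = MeanModel(small_stack.names)
        smap = project(m, small_stack)
        X, rows, cols = small_stack.table()
        rng = np.random.default_rng(0)
        idx = rng.choice(len(X), size=min(1000, len(X)), replace=False)
        oracle = m.predict(X.iloc[idx]).mean()
        assert np.nanmean(smap.values[rows[idx], cols[idx]]) == pytest.approx(oracle)

    def test_missing_predictor_layer_named(self, small_stack):
        m = ConstModel(0.5, ["T", "NotALayer"])
        with pytest.raises(ValueError, match="NotALayer"):
            project(m, small_stack)


class TestBinarize:
    def _smap(self, seed=0):
        rng = np.random.default_rng(seed)
        grid = GridSpec(0, 10, 0, 10, 1.0)
        mask = rng.uniform(size=(10, 10)) < 0.9
        values = np.where(mask, rng.uniform(size=(10, 10)), np.nan)
        return SuitabilityMap(grid, values, mask)

    def test_threshold_zero_all_valid_suitable(self):
        smap = self._smap()
        b = binarize(smap, 0.0)
        assert b.n_suitable == int(smap.mask.sum())

    def test_threshold_one_keeps_only_exact_ones(self):
        smap = self._smap()
        smap.values[smap.mask] = 0.5
        r, c = np.nonzero(smap.mask)
        smap.values[r[0], c[0]] = 1.0
        assert binarize(smap, 1.0).n_suitable == 1

    def test_count_matches_bruteforce_scan(self):
        smap = self._smap(3)
        t = 0.4
        b = binarize(smap, t)
        brute = sum(
            1
            for i in range(10)
            for j in range(10)
            if smap.mask[i, j] and smap.values[i, j] >= t
        )
        assert b.n_suitable == brute

    def test_threshold_range_validated(self):
        with pytest.raises(ValueError):
            binarize(self._smap(), 1.5)


class TestRangeChange:
    def test_identical_maps_zero_change(self):
        cur, _ = random_binary_pair(0)
        s = range_change(cur, cur)
        assert (s.perc_loss, s.perc_gain, s.perc_stable) == (0.0, 0.0, 100.0)
        assert s.species_range_change == 0.0

    def test_total_loss_is_minus_hundred(self):
        cur, fut = random_binary_pair(1)
        fut.suitable[:] = False
        s = range_change(cur, fut)
        assert s.species_range_change == -100.0
        assert s.perc_stable == 0.0

    def test_table_two_cell_loss_gain_arithmetic(self):
        # 100,000 current suitable; 75,626 lost; 3,995 gained
        grid = GridSpec(0, 400, 0, 300, 1.0)
        mask = np.ones((300, 400), dtype=bool)
        cur = np.zeros((300, 400), dtype=bool)
        cur.ravel()[:100_000] = True
        fut = cur.copy()
        fut.ravel()[:75_626] = False
        fut.ravel()[100_000 : 100_000 + 3_995] = True
        s = range_change(BinaryMap(grid, cur, mask), BinaryMap(grid, fut, mask))
        assert s.perc_loss == pytest.approx(75.626)
        assert s.perc_gain == pytest.approx(3.995)
        assert s.perc_stable == pytest.approx(24.374)
        assert s.species_range_change == pytest.approx(-71.631)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_cellwise_tally_and_identities(self, seed):
        cur, fut = random_binary_pair(seed)
        s = range_change(cur, fut)
        lost = gained = stable = n_cur = 0
        for i in range(20):
            for j in range(20):
                if not cur.mask[i, j]:
                    continue
                c, f = cur.suitable[i, j], fut.suitable[i, j]
                n_cur += c
                lost += c and not f
                gained += f and not c
                stable += c and f
        assert (s.n_lost, s.n_gained, s.n_stable, s.n_current) == (lost, gained, stable, n_cur)
        assert s.perc_loss + s.perc_stable == pytest.approx(100.0)
        assert s.species_range_change == pytest.approx(s.perc_gain - s.perc_loss)

    def test_zero_current_suitable_errors(self):
        cur, fut = random_binary_pair(2)
        cur.suitable[:] = False
        with pytest.raises(ValueError):
            range_change(cur, fut)

    def test_mask_mismatch_errors(self):
        cur, fut = random_binary_pair(3)
        fut.mask = ~fut.mask
        with pytest.raises(ValueError):
            range_change(cur, fut)

    def test_area_weighted_variant_uses_cos_latitude(self):
        grid = GridSpec(0, 60, 0, 60, 30.0)  # 2×2; row centers at 45° and 15°
        mask = np.ones((2, 2), dtype=bool)
        cur = np.array([[True, False], [True, False]])
        fut = np.array([[False, False], [True, False]])  # lose the 45° cell
        s = range_change(BinaryMap(grid, cur, mask), BinaryMap(grid, fut, mask), area_weighted=True)
        w45, w15 = np.cos(np.deg2rad(45)), np.cos(np.deg2rad(15))
        assert s.perc_loss == pytest.approx(100 * w45 / (w45 + w15))

    def test_range_change_table_layout(self):
        rows = []
        for seed, label in [(0, "s1"), (1, "s2")]:
            cur, fut = random_binary_pair(seed)
            fut.scenario_label = label
            rows.append(range_change(cur, fut))
        table = range_change_table(rows)
        assert list(table.columns) == ["s1", "s2"]
        assert list(table.index) == ["PercLoss", "PercGain", "PercStable", "SpeciesRangeChange"]


class TestApplyScenario:
    def test_zero_delta_changes_only_label(self, small_stack):
        out = apply_scenario(small_stack, ScenarioDelta("null", {}))
        assert out.scenario_label == "null"
        for name in small_stack.names:
            np.testing.assert_array_equal(
                out[name].values[out.joint_mask], small_stack[name].values[small_stack.joint_mask]
            )

    def test_uniform_temperature_shift_mean(self, small_stack):
        out = apply_scenario(small_stack, ScenarioDelta("warm", {"T": 2.87}))
        diff = out["T"].values - small_stack["T"].values
        assert np.nanmean(diff) == pytest.approx(2.87)
        # other layers untouched
        np.testing.assert_array_equal(
            np.nan_to_num(out["Depth"].values), np.nan_to_num(small_stack["Depth"].values)
        )

    def test_spatially_varying_delta_elementwise(self, small_stack):
        rng = np.random.default_rng(0)
        field = rng.normal(size=small_stack.grid.shape)
        out = apply_scenario(small_stack, ScenarioDelta("spatial", {"Sal": field}))
        m = small_stack.joint_mask
        np.testing.assert_allclose(
            out["Sal"].values[m] - small_stack["Sal"].values[m], field[m]
        )

    def test_missing_layer_rejected(self, small_stack):
        with pytest.raises(ValueError):
            apply_scenario(small_stack, ScenarioDelta("x", {"Oxygen": 1.0}))

    def test_constant_layers_cannot_shift(self):
        with pytest.raises(ValueError):
            ScenarioDelta("bad", {"Depth": 5.0})
        with pytest.raises(ValueError):
            ScenarioDelta("bad", {"Dshore": -1.0})
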