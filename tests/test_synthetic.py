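"""Synthetic land-cover generator: validation, operators, truth log."""

import numpy as np
import pandas as pd
import pytest

from landmetrics import (
    ChangeOperator,
    SyntheticScenario,
    apply_change_operator,
    generate_initial_map,
    generate_series,
)
from landmetrics.synthetic import replay_log

from oracles import bfs_patch_count


def scenario(**kw):
    base = dict(
        grid_rows=60, grid_cols=60,
        classes=[(1, 0.6), (2, 0.4)],
        years=(1992, 1994),
        cluster_density=0.4,
        seed=5,
    )
    base.update(kw)
    return SyntheticScenario(**base)


class TestScenarioValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            scenario(classes=[(1, 0.6), (2, 0.3)])

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            scenario(classes=[(1, 1.5), (2, -0.5)])

    def test_cluster_density_range(self):
        with pytest.raises(ValueError):
            scenario(cluster_density=0.0)

    def test_grid_too_small_for_classes(self):
        with pytest.raises(ValueError, match="fewer land cells"):
            scenario(grid_rows=1, grid_cols=2,
                     classes=[(1, 0.4), (2, 0.3), (3, 0.3)])

    def test_unknown_operator_kind(self):
        with pytest.raises(ValueError, match="unknown operator kind"):
            ChangeOperator(1993, 1994, "teleport", source=1, rate=1, target=2)

    def test_operator_target_cannot_be_ocean(self):
        with pytest.raises(ValueError, match="ocean or NoData"):
            scenario(operators=[ChangeOperator(1993, 1994, "contract",
                                               source=1, target=0, rate=1)])

    def test_yaml_round_trip(self, tmp_path):
        scen = scenario(operators=[
            ChangeOperator(1993, 1994, "expand", source=1, rate=3,
                           region=(0, 0, 10, 10))])
        p = tmp_path / "scen.yaml"
        scen.to_yaml(p)
        back = SyntheticScenario.from_yaml(p)
        assert back == scen


class TestInitialMap:
    def test_single_class_fills_everything(self):
        scen = scenario(classes=[(1, 1.0)], ocean_fraction=0.0)
        g = generate_initial_map(scen)
        assert (g == 1).all()

    def test_composition_close_to_targets(self):
        scen = SyntheticScenario(
            grid_rows=200, grid_cols=200, classes=[(1, 0.7), (2, 0.3)],
            years=(1992, 1992), cluster_density=0.4, seed=7)
        g = generate_initial_map(scen)
        f1 = (g == 1).mean()
        assert abs(f1 - 0.7) < 0.05

    def test_composition_recovery_over_seeds(self):
        devs = []
        for seed in range(20):
            scen = SyntheticScenario(
                grid_rows=200, grid_cols=200,
                classes=[(1, 0.5), (2, 0.3), (3, 0.2)],
                years=(1992, 1992), ocean_fraction=0.1,
                cluster_density=0.4, seed=seed)
            g = generate_initial_map(scen)
            n_land = (g != 0).sum()
            devs.append(np.mean([abs((g == c).sum() / n_land - p)
                                 for c, p in scen.classes]))
        assert np.mean(devs) < 0.05

    def test_determinism(self):
        scen = scenario(ocean_fraction=0.2)
        assert np.array_equal(generate_initial_map(scen), generate_initial_map(scen))

    def test_ocean_fraction_and_contiguity(self):
        scen = scenario(ocean_fraction=0.25)
        g = generate_initial_map(scen)
        ocean = g == 0
        assert ocean.sum() == round(0.25 * g.size)
        assert bfs_patch_count(ocean.astype(int), 1, 4) == 1
        # edge-anchored
        assert ocean[0].any() or ocean[-1].any() or ocean[:, 0].any() or ocean[:, -1].any()

    def test_autocorrelation_increases_with_density(self):
        def joinfrac(g):
            return ((g[:, 1:] == g[:, :-1]).mean() + (g[1:, :] == g[:-1, :]).mean()) / 2

        vals = []
        for cd in (0.2, 0.5, 0.8):
            acc = [joinfrac(generate_initial_map(
                SyntheticScenario(grid_rows=150, grid_cols=150,
                                  classes=[(1, 0.5), (2, 0.5)],
                                  years=(1992, 1992), cluster_density=cd,
                                  seed=s))) for s in range(3)]
            vals.append(np.mean(acc))
        assert vals[0] < vals[1] < vals[2]


class TestOperators:
    def test_expand_adds_exact_cell_count(self):
        scen = scenario()
        g = np.full((20, 20), 2, np.uint8)
        g[10, 10] = 1
        op = ChangeOperator(1993, 1993, "expand", source=1, rate=10)
        out, entries = apply_change_operator(g, op, 0, scen)
        assert (out == 1).sum() == 11
        assert len(entries) == 10
        assert (g == 1).sum() == 1  # input untouched

    def test_expansion_is_contiguous(self):
        scen = scenario()
        g = np.full((30, 30), 2, np.uint8)
        g[15, 15] = 1
        op = ChangeOperator(1993, 1993, "expand", source=1, rate=40)
        out, _ = apply_change_operator(g, op, 1, scen)
        assert bfs_patch_count(out, 1, 8) == 1

    def test_expand_respects_region(self):
        scen = scenario()
        g = np.full((20, 20), 2, np.uint8)
        g[5, 5] = 1
        op = ChangeOperator(1993, 1993, "expand", source=1, rate=200,
                            region=(0, 0, 10, 10))
        out, _ = apply_change_operator(g, op, 2, scen)
        assert (out[10:, :] == 1).sum() == 0 and (out[:, 10:] == 1).sum() == 0

    def test_contract_zero_rate_is_identity(self):
        scen = scenario()
        g = np.full((10, 10), 2, np.uint8)
        g[4:6, 4:6] = 1
        op = ChangeOperator(1993, 1993, "contract", source=1, target=2, rate=0)
        out, entries = apply_change_operator(g, op, 3, scen)
        assert np.array_equal(out, g) and entries == []

    def test_contract_removes_boundary_cells(self):
        scen = scenario()
        g = np.full((10, 10), 2, np.uint8)
        g[3:7, 3:7] = 1
        op = ChangeOperator(1993, 1993, "contract", source=1, target=2, rate=5)
        out, entries = apply_change_operator(g, op, 4, scen)
        assert (out == 1).sum() == 11
        assert all(f == 1 and t == 2 for _, _, f, t, _ in entries)

    def test_fragment_splits_corridor(self):
        scen = scenario()
        g = np.full((7, 11), 2, np.uint8)
        g[2:5, 1:4] = 1
        g[2:5, 7:10] = 1
        g[3, 4:7] = 1
        op = ChangeOperator(1993, 1993, "fragment", source=1, target=2, rate=1)
        out, _ = apply_change_operator(g, op, 5, scen)
        assert bfs_patch_count(g, 1, 8) == 1
        assert bfs_patch_count(out, 1, 8) == 2

    def test_convert_relabels_smallest_patch(self):
        scen = scenario()
        g = np.full((12, 12), 2, np.uint8)
        g[1:5, 1:5] = 1  # 16 cells
        g[8:10, 8:10] = 1  # 4 cells
        op = ChangeOperator(1993, 1993, "convert", source=1, target=2, rate=1)
        out, entries = apply_change_operator(g, op, 6, scen)
        assert (out[8:10, 8:10] == 2).all()
        assert (out[1:5, 1:5] == 1).all()
        assert len(entries) == 4

    def test_missing_source_rejected(self):
        scen = scenario()
        g = np.full((5, 5), 2, np.uint8)
        op = ChangeOperator(1993, 1993, "contract", source=1, target=2, rate=1)
        with pytest.raises(ValueError, match="absent"):
            apply_change_operator(g, op, 0, scen)

    def test_ocean_never_modified(self):
        scen = scenario(ocean_fraction=0.3)
        g = generate_initial_map(scen)
        ocean = g == 0
        op = ChangeOperator(1993, 1993, "expand", source=1, rate=500)
        out, _ = apply_change_operator(g, op, 7, scen)
        assert (out[ocean] == 0).all()


class TestSeries:
    def test_no_operators_means_identical_years(self):
        scen = scenario()
        series, log = generate_series(scen)
        assert len(series.years) == 3
        assert log.empty
        assert np.array_equal(series.data[0], series.data[2])

    def test_unconstrained_expand_grows_linearly(self):
        scen = SyntheticScenario(
            grid_rows=50, grid_cols=50, classes=[(1, 0.1), (2, 0.9)],
            years=(1992, 1996), cluster_density=0.4, seed=2,
            operators=[ChangeOperator(1993, 1996, "expand", source=1, rate=7)])
        series, log = generate_series(scen)
        areas = [(series.data[i] == 1).sum() for i in range(5)]
        assert np.diff(areas).tolist() == [7, 7, 7, 7]

    def test_truth_log_replay_reproduces_final_year(self):
        scen = scenario(operators=[
            ChangeOperator(1993, 1994, "expand", source=1, rate=9),
            ChangeOperator(1993, 1994, "contract", source=2, target=1, rate=4),
        ])
        series, log = generate_series(scen)
        final = replay_log(series.data[0], log, scen.years[1])
        assert np.array_equal(final, series.data[-1])

    def test_log_completeness_per_year(self):
        scen = scenario(operators=[
            ChangeOperator(1993, 1994, "contract", source=1, target=2, rate=6)])
        series, log = generate_series(scen)
        for i, year in enumerate(series.years[1:], start=1):
            changed = set(zip(*np.nonzero(series.data[i] != series.data[i - 1])))
            logged = set(zip(log[log["year"] == year]["row"],
                             log[log["year"] == year]["col"]))
            assert changed == logged

    def test_cell_and_ocean_conservation(self):
        scen = scenario(ocean_fraction=0.2, operators=[
            ChangeOperator(1993, 1994, "expand", source=2, rate=15)])
        series, _ = generate_series(scen)
        for i in range(len(series.years)):
            assert series.data[i].shape == (60, 60)
            assert np.array_equal(series.data[i] == 0, series.data[0] == 0)

    def test_series_determinism(self):
        scen = scenario(operators=[
            ChangeOperator(1993, 1994, "expand", source=1, rate=5)])
        s1, l1 = generate_series(scen)
        s2, l2 = generate_series(scen)
        assert np.array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(l1, l2)
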