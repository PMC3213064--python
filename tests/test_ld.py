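import numpy as np
import pandas as pd
import pytest

from germpop.ld import (
    LDDecayModel,
    binned_mean_r2,
    expected_r2_hill_weir,
    fit_effective_population_size,
    ld_decay_distance,
    ld_summary,
    ne_per_linkage_group,
    pairwise_r2_table,
    unlinked_r2_quantile,
    window_mean_r2,
)
from germpop.panel import GenotypePanel, GeneticMap
from .conftest import grid_map, random_panel


def r2_oracle(panel, min_lines=3):
    """Brute-force pairwise-complete squared correlations."""
    m = panel.n_markers
    out = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            x, y = panel.dosage[:, i], panel.dosage[:, j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < min_lines:
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                continue
            out[i, j] = np.corrcoef(xs, ys)[0, 1] ** 2
    return out


def table_from(dosages, gmap=None, **kw):
    dosages = np.asarray(dosages, dtype=float)
    panel = GenotypePanel(
        [f"l{i}" for i in range(dosages.shape[0])],
        [f"m{j}" for j in range(dosages.shape[1])],
        dosages,
    )
    if gmap is None:
        gmap = grid_map(panel.marker_ids, n_groups=1)
    return pairwise_r2_table(panel, gmap, **kw)


class TestPairwiseR2:
    def test_duplicated_marker_r2_one(self):
        col = np.array([0, 1, 0, 1, 1.0])
        tab = table_from(np.column_stack([col, col]))
        assert tab.pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_markers_r2_zero(self):
        tab = table_from(np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]]))
        assert tab.pairs["r2"].iloc[0] == pytest.approx(0.0)

    def test_haplotype_count_example(self):
        # 2x2 haplotype counts AB=40, Ab=10, aB=10, ab=40 over 100 lines:
        # D = 0.4 - 0.25 = 0.15, r2 = D^2 / (0.5^4) = 0.36
        X = np.array([[1, 1]] * 40 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 40, float)
        tab = table_from(X)
        assert tab.pairs["r2"].iloc[0] == pytest.approx(0.36)

    def test_matches_brute_force_oracle_with_missingness(self, small_panel, small_map):
        tab = pairwise_r2_table(small_panel, small_map)
        oracle = r2_oracle(small_panel)
        midx = {m: k for k, m in enumerate(small_panel.marker_ids)}
        assert len(tab.pairs) == np.isfinite(oracle).sum()
        for row in tab.pairs.itertuples():
            assert row.r2 == pytest.approx(
                oracle[midx[row.marker_a], midx[row.marker_b]], abs=1e-12
            )

    def test_monomorphic_marker_pairs_dropped(self):
        X = np.array([[0, 0], [0, 1], [0, 0], [0, 1.0]])
        tab = table_from(X)
        assert len(tab.pairs) == 0 and tab.n_dropped == 1

    def test_linkage_status_and_distance(self):
        panel = random_panel(n_lines=10, n_markers=4, missing=0.0, seed=1)
        gmap = GeneticMap.from_arrays(panel.marker_ids, ["A", "A", "B", "B"], [0, 7, 0, 3])
        tab = pairwise_r2_table(panel, gmap)
        rec = tab.pairs.set_index(["marker_a", "marker_b"])
        assert rec.loc[("m0", "m1"), "linked"]
        assert rec.loc[("m0", "m1"), "distance_cm"] == pytest.approx(7.0)
        assert not rec.loc[("m0", "m2"), "linked"]


class TestUnlinkedQuantile:
    def test_constant_values(self):
        from germpop.ld import LDTable

        pairs = pd.DataFrame({
            "marker_a": [f"a{i}" for i in range(30)],
            "marker_b": [f"b{i}" for i in range(30)],
            "r2": 0.42, "linked": False, "distance_cm": np.nan, "n_used": 50,
        })
        assert unlinked_r2_quantile(LDTable(pairs)) == pytest.approx(0.42)

    def test_interpolation_convention(self):
        from germpop.ld import LDTable

        vals = np.arange(1, 101) / 1000.0
        pairs = pd.DataFrame({
            "marker_a": [f"a{i}" for i in range(100)],
            "marker_b": [f"b{i}" for i in range(100)],
            "r2": vals, "linked": False, "distance_cm": np.nan, "n_used": 50,
        })
        assert unlinked_r2_quantile(LDTable(pairs), 0.95) == pytest.approx(0.09505)
        assert unlinked_r2_quantile(LDTable(pairs), 1.0) == pytest.approx(0.1)

    def test_no_unlinked_pairs_rejected(self):
        tab = table_from(np.array([[0, 0], [1, 1], [0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            unlinked_r2_quantile(tab)


class TestHillWeirExpectation:
    def test_value_at_c_zero(self):
        assert expected_r2_hill_weir(0.0, 100) == pytest.approx(
            (10 / 22) * (1 + 36 / 2200), rel=1e-12
        )

    def test_limit_is_sampling_floor(self):
        assert expected_r2_hill_weir(1e9, 100) == pytest.approx(1 / 100, rel=1e-4)

    def test_strictly_decreasing_in_c(self):
        grid = np.linspace(0, 1e4, 4000)
        vals = expected_r2_hill_weir(grid, 50)
        assert np.all(np.diff(vals) < 0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            expected_r2_hill_weir(1.0, 1)


class TestDecayFit:
    @pytest.mark.parametrize("ne_true", [10, 50, 500])
    def test_noiseless_self_consistency(self, ne_true):
        d = np.linspace(1, 50, 60)
        r = np.minimum(d / 100, 0.5)
        r2 = expected_r2_hill_weir(4 * ne_true * r, 100)
        fit = LDDecayModel(d, r2, n=100).fit()
        assert fit.ne == pytest.approx(ne_true, rel=1e-4)

    def test_floor_only_data_hits_upper_bound(self):
        d = np.linspace(40, 90, 30)
        r2 = np.full_like(d, 1 / 100)
        with pytest.warns(UserWarning, match="bound"):
            fit = LDDecayModel(d, r2, n=100).fit()
        assert fit.at_bound

    def test_doubling_distances_halves_ne(self):
        rng = np.random.default_rng(3)
        d = np.linspace(1, 20, 40)
        r2 = expected_r2_hill_weir(4 * 80 * d / 100, 120) + rng.normal(0, 0.01, d.size)
        r2 = np.clip(r2, 0, 1)
        ne1 = LDDecayModel(d, r2, n=120).fit().ne
        ne2 = LDDecayModel(2 * d, r2, n=120).fit().ne
        assert ne2 == pytest.approx(ne1 / 2, rel=1e-3)

    def test_decay_distance_inverts_curve(self):
        d = np.linspace(1, 50, 60)
        r2 = expected_r2_hill_weir(4 * 50 * np.minimum(d / 100, 0.5), 100)
        fit = LDDecayModel(d, r2, n=100).fit()
        fit.threshold = fit.expected(10.0)
        assert ld_decay_distance(fit) == pytest.approx(10.0, abs=1e-6)

    def test_threshold_above_intercept_gives_zero(self):
        fit = LDDecayModel([5.0], [0.3], n=100).fit()
        fit.threshold = 0.99
        assert ld_decay_distance(fit) == 0.0
        assert fit.decay_flag == "above_intercept"

    def test_threshold_below_floor_never_decays(self):
        fit = LDDecayModel([5.0], [0.3], n=100).fit()
        fit.threshold = 1 / 200
        assert ld_decay_distance(fit) is None
        assert fit.decay_flag == "never_decays"

    def test_summary_mentions_ne(self):
        fit = LDDecayModel(np.linspace(1, 30, 20),
                           expected_r2_hill_weir(4 * 30 * np.linspace(1, 30, 20) / 100, 80),
                           n=80).fit()
        assert "Ne" in fit.summary() and "80" in fit.summary()


class TestProfilesAndSummary:
    def test_binned_means(self):
        from germpop.ld import LDTable

        pairs = pd.DataFrame({
            "marker_a": ["a", "b", "c"], "marker_b": ["x", "y", "z"],
            "r2": [0.4, 0.2, 0.6], "linked": True,
            "distance_cm": [1.0, 2.0, 5.0], "n_used": 50,
        })
        binned = binned_mean_r2(LDTable(pairs), bin_width=5)
        assert binned.loc[0, "mean_r2"] == pytest.approx(0.3)
        assert binned.loc[0, "n_pairs"] == 2
        # half-open rule: pair at exactly 5.0 falls in [5, 10)
        assert binned.loc[1, "mean_r2"] == pytest.approx(0.6)

    def test_window_assignment_rules(self):
        ids = ["m1", "m2", "m3", "m4", "m5", "m6"]
        gmap = GeneticMap.from_arrays(ids, ["A"] * 6, [1, 2, 7, 8, 4, 6])
        from germpop.ld import LDTable

        pairs = pd.DataFrame({
            "marker_a": ["m1", "m3", "m5"], "marker_b": ["m2", "m4", "m6"],
            "r2": [0.5, 0.1, 0.9], "linked": True,
            "distance_cm": [1.0, 1.0, 2.0], "n_used": 50,
        })
        win = window_mean_r2(LDTable(pairs), gmap, window=5)
        w = win.set_index("window_start")
        assert w.loc[0, "mean_r2"] == pytest.approx(0.5)  # m1-m2 inside [0,5)
        assert w.loc[5, "mean_r2"] == pytest.approx(0.1)  # m3-m4 inside [5,10)
        # m5-m6 spans the 5 cM boundary: contributes to no window

    def test_summary_percentages(self):
        from germpop.ld import DecayFit, LDTable

        pairs = pd.DataFrame({
            "marker_a": ["a", "b", "c"], "marker_b": ["x", "y", "z"],
            "r2": [0.9, 0.5, 0.1], "linked": True,
            "distance_cm": [1.0, 2.0, 3.0], "n_used": 50,
        })
        fit = DecayFit(ne=50, n=100, sse=0, n_pairs=3, threshold=0.4)
        out = ld_summary(LDTable(pairs), fit)
        assert out["pct_linked_above_threshold"] == pytest.approx(200 / 3)
        assert out["pct_linked_above_0.8"] == pytest.approx(100 / 3)


class TestPerLinkageGroup:
    def test_noiseless_recovery_per_group(self):
        rng = np.random.default_rng(8)
        from germpop.ld import LDTable

        # build a table whose markers map onto three groups
        ids, groups, pos = [], [], []
        pairs_rows = []
        k = 0
        for g in ("A", "B", "C"):
            d = rng.uniform(1, 40, 40)
            for dist in d:
                a, b = f"m{k}", f"m{k + 1}"
                ids += [a, b]
                groups += [g, g]
                pos += [0.0, dist]
                pairs_rows.append({
                    "marker_a": a, "marker_b": b,
                    "r2": expected_r2_hill_weir(4 * 60 * dist / 100, 150),
                    "linked": True, "distance_cm": dist, "n_used": 150,
                })
                k += 2
        gmap = GeneticMap.from_arrays(ids, groups, pos)
        table = LDTable(pd.DataFrame(pairs_rows))
        res = ne_per_linkage_group(table, gmap, n=150)
        assert np.allclose(res["ne"], 60, rtol=1e-3)

    def test_sparse_group_flagged(self):
        panel = random_panel(n_lines=20, n_markers=4, missing=0.0, seed=2)
        gmap = GeneticMap.from_arrays(panel.marker_ids, ["A", "A", "A", "B"], [0, 5, 9, 0])
        tab = pairwise_r2_table(panel, gmap)
        res = ne_per_linkage_group(tab, gmap, n=20).set_index("linkage_group")
        assert res.loc["B", "flag"] == "too_few_pairs"
        assert np.isnan(res.loc["B", "ne"])
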