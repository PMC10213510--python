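"""Difference scores, paired t / r oracles, and the split-plot ANOVA."""

import numpy as np
import pytest
from scipy import stats as sps

from rhythmgap.stats import (
    CELL_ORDER,
    SubjectResult,
    correlation_table,
    difference_scores,
    paired_t_and_d,
    pearson_r,
    split_plot_anova,
)


def make_result(cells, group="young", sid="s0", battery=None):
    return SubjectResult(
        subject_id=sid,
        group=group,
        thresholds=dict(zip(CELL_ORDER, cells)),
        battery_scores=battery or {},
    )


# ---------------------------------------------------------------- oracles


def oracle_paired_t(x, y):
    """Paired t from the definition, no library calls."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / (var / n) ** 0.5
    return t, mean / var**0.5


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = (sum((a - mx) ** 2 for a in x) / (n - 1)) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / (n - 1)) ** 0.5
    return cov / (sx * sy)


def oracle_split_plot_ss(Y, groups):
    """Textbook mean-based SS decomposition for a balanced split-plot
    design: subjects nested in group A, crossed with B (3) x C (2).
    Returns the SS of every effect and error stratum."""
    levels = sorted(set(groups))
    Y = np.asarray(Y, float)
    n, p = Y.shape
    cells = Y.reshape(n, 3, 2)  # subject x B x C
    grand = cells.mean()
    ss = {}
    ga = {a: cells[np.array(groups) == a] for a in levels}
    # between-subject stratum
    subj_means = cells.mean(axis=(1, 2))
    a_means = {a: ga[a].mean() for a in levels}
    ss["age"] = 6 * sum(len(ga[a]) * (a_means[a] - grand) ** 2 for a in levels)
    ss["error_between"] = 6 * sum(
        (subj_means[i] - a_means[groups[i]]) ** 2 for i in range(n)
    )
    # B stratum
    b_means = cells.mean(axis=(0, 2))
    ab_means = {a: ga[a].mean(axis=(0, 2)) for a in levels}
    ss["rhythm"] = 2 * n * sum((b_means[j] - grand) ** 2 for j in range(3))
    ss["age_x_rhythm"] = 2 * sum(
        len(ga[a]) * (ab_means[a][j] - a_means[a] - b_means[j] + grand) ** 2
        for a in levels
        for j in range(3)
    )
    sb = cells.mean(axis=2)  # subject x B
    ss["error_rhythm"] = 2 * sum(
        (sb[i, j] - ab_means[groups[i]][j] - subj_means[i] + a_means[groups[i]]) ** 2
        for i in range(n)
        for j in range(3)
    )
    # C stratum
    c_means = cells.mean(axis=(0, 1))
    ac_means = {a: ga[a].mean(axis=(0, 1)) for a in levels}
    ss["direction"] = 3 * n * sum((c_means[k] - grand) ** 2 for k in range(2))
    ss["age_x_direction"] = 3 * sum(
        len(ga[a]) * (ac_means[a][k] - a_means[a] - c_means[k] + grand) ** 2
        for a in levels
        for k in range(2)
    )
    sc = cells.mean(axis=1)  # subject x C
    ss["error_direction"] = 3 * sum(
        (sc[i, k] - ac_means[groups[i]][k] - subj_means[i] + a_means[groups[i]]) ** 2
        for i in range(n)
        for k in range(2)
    )
    # BC stratum
    bc_means = cells.mean(axis=0)
    abc_means = {a: ga[a].mean(axis=0) for a in levels}
    ss["rhythm_x_direction"] = n * sum(
        (bc_means[j, k] - b_means[j] - c_means[k] + grand) ** 2
        for j in range(3)
        for k in range(2)
    )
    ss["age_x_rhythm_x_direction"] = sum(
        len(ga[a])
        * (
            abc_means[a][j, k]
            - ab_means[a][j]
            - ac_means[a][k]
            - bc_means[j, k]
            + a_means[a]
            + b_means[j]
            + c_means[k]
            - grand
        )
        ** 2
        for a in levels
        for j in range(3)
        for k in range(2)
    )
    ss["total"] = ((cells - grand) ** 2).sum()
    ss["error_rhythm_x_direction"] = ss["total"] - sum(
        v for k, v in ss.items() if k not in ("total", "error_rhythm_x_direction")
    )
    return ss


# ----------------------------------------------------------------- tests


class TestDifferenceScores:
    def test_flat_cells_give_zero(self):
        assert difference_scores(make_result([0.4] * 6)) == (0.0, 0.0)

    def test_group_mean_late_early(self):
        # cells at the reported young group means: late - early = 0.23
        cells = [0.30, 0.53, 0.30, 0.53, 0.30, 0.53]
        le, _ = difference_scores(make_result(cells))
        assert le == pytest.approx(0.23)

    def test_rhythm_difference(self):
        cells = [0.37, 0.37, 0.45, 0.45, 0.45, 0.45]
        _, rd = difference_scores(make_result(cells))
        assert rd == pytest.approx(0.08)

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError):
            SubjectResult("s0", "young", {CELL_ORDER[0]: 0.4})


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t_and_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.cohens_d == 0.0

    def test_constant_shift_degenerate(self):
        res = paired_t_and_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate
        assert np.isinf(res.cohens_d)

    def test_matches_definition_oracle(self, rng):
        x = rng.normal(0.4, 0.1, size=11)
        y = x + rng.normal(0.1, 0.08, size=11)
        res = paired_t_and_d(x, y)
        t_ref, d_ref = oracle_paired_t(list(x), list(y))
        assert res.t == pytest.approx(t_ref, abs=1e-9)
        assert res.cohens_d == pytest.approx(d_ref, abs=1e-9)
        assert res.df == 10
        # p from the central t distribution
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_ref), 10), abs=1e-12)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 4.0, 5.0]
        r, _ = pearson_r(x, x)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_matches_definition_oracle(self, rng):
        x = rng.normal(size=9)
        y = 0.3 * x + rng.normal(size=9)
        r, p = pearson_r(x, y)
        assert r == pytest.approx(oracle_pearson(list(x), list(y)), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSplitPlotAnova:
    def test_constant_data_has_zero_effect_ss(self):
        Y = np.full((8, 6), 0.42)
        groups = ["young"] * 4 + ["older"] * 4
        res = split_plot_anova(Y, groups)
        for effect in ("age", "rhythm", "direction", "age_x_direction"):
            assert res.effect(effect)["ss"] == pytest.approx(0.0, abs=1e-20)

    def test_pure_direction_by_group_interaction(self, rng):
        # young get +delta on late cells, older -delta: only the
        # direction x age interaction (among interactions) carries SS
        base = np.full((8, 6), 0.4)
        delta = np.tile([-0.05, 0.05], 3)
        Y = base + np.vstack([delta] * 4 + [-delta] * 4)
        groups = ["young"] * 4 + ["older"] * 4
        res = split_plot_anova(Y, groups)
        assert res.effect("age_x_direction")["ss"] > 1e-6
        for other in ("age_x_rhythm", "rhythm_x_direction", "age_x_rhythm_x_direction"):
            assert res.effect(other)["ss"] == pytest.approx(0.0, abs=1e-20)

    def test_ss_decomposition_matches_oracle(self, rng):
        Y = rng.normal(0.4, 0.15, size=(10, 6))
        groups = ["young"] * 5 + ["older"] * 5
        res = split_plot_anova(Y, groups)
        ref = oracle_split_plot_ss(Y, groups)
        for name in ref:
            if name == "total":
                continue
            assert res.effect(name)["ss"] == pytest.approx(ref[name], abs=1e-9), name

    def test_ss_conservation(self, rng):
        Y = rng.normal(0.4, 0.2, size=(12, 6))
        groups = ["young"] * 6 + ["older"] * 6
        res = split_plot_anova(Y, groups)
        total = ((Y - Y.mean()) ** 2).sum()
        assert res.table["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_gg_epsilon_within_bounds(self, rng):
        Y = rng.normal(0.4, 0.2, size=(11, 6))
        groups = ["young"] * 6 + ["older"] * 5
        res = split_plot_anova(Y, groups)
        eps = res.effect("rhythm")["epsilon"]
        assert 0.5 <= eps <= 1.0  # 1/(k-1) for the 3-level factor
        assert res.effect("direction")["epsilon"] == 1.0

    def test_partial_eta_squared_in_unit_interval(self, rng):
        Y = rng.normal(0.4, 0.2, size=(9, 6))
        groups = ["young"] * 5 + ["older"] * 4
        res = split_plot_anova(Y, groups)
        effects = res.table.dropna(subset=["partial_eta_sq"])
        assert ((effects["partial_eta_sq"] >= 0) & (effects["partial_eta_sq"] <= 1)).all()

    def test_unbalanced_cells_rejected(self):
        Y = np.full((4, 6), 0.4)
        Y[0, 2] = np.nan
        with pytest.raises(ValueError):
            split_plot_anova(Y, ["young", "young", "older", "older"])


class TestCorrelationTable:
    def test_layout_and_values(self, rng):
        results = []
        for i in range(9):
            cells = rng.normal(0.4, 0.1, size=6)
            battery = {"GAP": rng.normal(75, 8), "SC": rng.normal(0.04, 0.01),
                       "RD": rng.normal(1.5, 0.6), "WM": rng.normal(0.55, 0.1)}
            results.append(make_result(cells, group="older", sid=f"s{i}",
                                       battery=battery))
        table = correlation_table(results)
        assert list(table.index) == ["GAP", "SC", "RD", "WM"]
        gap = np.array([r.battery_scores["GAP"] for r in results])
        mt = np.array([r.mean_threshold for r in results])
        r_ref, _ = pearson_r(gap, mt)
        assert table.loc["GAP", "mean_threshold_r"] == pytest.approx(r_ref)
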