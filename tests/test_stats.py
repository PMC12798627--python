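import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from physiopipe.stats import (
    fdr_bh,
    holm,
    holm_posthoc_paired,
    mann_whitney_rbc,
    rm_anova_gg,
    wilcoxon_rbc,
)


# ---------------------------------------------------------------------------
# independent brute-force oracles


def wilcoxon_exact_oracle(d):
    """Two-sided signed-rank p by enumerating every sign assignment."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    r = sstats.rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    n = d.size
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(ri for s, ri in zip(signs, r) if s))
    dist = np.asarray(dist, dtype=float)
    return min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))


def mannwhitney_exact_oracle(x, y):
    """Two-sided U-test p by enumerating every group labeling."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = x.size
    r = sstats.rankdata(np.concatenate([x, y]))
    u_obs = r[:n1].sum() - n1 * (n1 + 1) / 2
    dist = [
        sum(c) - n1 * (n1 + 1) / 2 for c in itertools.combinations(r, n1)
    ]
    dist = np.asarray(dist, dtype=float)
    return min(1.0, 2 * min((dist <= u_obs).mean(), (dist >= u_obs).mean()))


def anova_ss_oracle(Y):
    """Within-subject ANOVA sums of squares by direct matrix computation."""
    n, k = Y.shape
    grand = Y.mean()
    ss_time = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((Y - grand) ** 2).sum()
    ss_err = ss_tot - ss_time - ss_subj
    df_time, df_err = k - 1, (n - 1) * (k - 1)
    F = (ss_time / df_time) / (ss_err / df_err)
    # GG epsilon from the double-centered covariance
    S = np.cov(Y.T, ddof=1)
    H = np.eye(k) - 1.0 / k
    Sc = H @ S @ H
    eps = np.trace(Sc) ** 2 / ((k - 1) * (Sc @ Sc).trace())
    ng2 = ss_time / (ss_time + ss_subj + ss_err)
    return F, (df_time, df_err), eps, ng2


def _long(Y, groups=None):
    n, k = Y.shape
    rows = []
    for i in range(n):
        for j in range(k):
            row = {"participant": f"s{i}", "timepoint": j + 1, "value": Y[i, j]}
            if groups is not None:
                row["tech"] = groups[i]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


class TestWilcoxon:
    def test_all_positive_differences_rbc_one(self):
        r = wilcoxon_rbc(np.zeros(6), np.arange(1.0, 7.0))
        assert r.effect_size == 1.0

    def test_symmetric_ranks_rbc_zero(self):
        r = wilcoxon_rbc(np.zeros(4), np.array([1.0, -1.0, 2.0, -2.0]))
        assert r.effect_size == 0.0

    def test_exact_p_matches_signflip_enumeration(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -6.0])
        r = wilcoxon_rbc(np.zeros(6), d)
        assert r.p_raw == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        pre = rng.normal(size=10)
        post = pre + rng.normal(0.5, 1.0, 10)
        r = wilcoxon_rbc(pre, post)
        sp = sstats.wilcoxon(post, pre, mode="exact")
        assert r.p_raw == pytest.approx(sp.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(8)
        pre = rng.normal(size=40)
        post = pre + rng.normal(0.3, 1.0, 40)
        r = wilcoxon_rbc(pre, post)
        sp = sstats.wilcoxon(post, pre, correction=True, mode="approx")
        assert r.p_raw == pytest.approx(sp.pvalue, rel=1e-6)

    def test_all_zero_differences_flagged(self):
        r = wilcoxon_rbc(np.ones(5), np.ones(5))
        assert np.isnan(r.p_raw) and "undefined" in r.extras["note"]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(-50, 50).filter(lambda v: v != 0),
                    min_size=5, max_size=11))
    def test_rbc_in_unit_interval_and_p_valid(self, diffs):
        d = np.asarray(diffs, dtype=float)
        r = wilcoxon_rbc(np.zeros(d.size), d)
        assert -1.0 <= r.effect_size <= 1.0
        assert 0.0 <= r.p_raw <= 1.0
        assert r.p_raw == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney U


class TestMannWhitney:
    def test_fully_separated_rbc_one(self):
        r = mann_whitney_rbc(np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0, 3.0]))
        assert r.effect_size == 1.0

    def test_identical_groups_rbc_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = mann_whitney_rbc(x, x)
        assert r.effect_size == 0.0

    def test_exact_p_matches_labeling_enumeration(self):
        x = np.array([2.1, 3.4, 1.2, 4.4])
        y = np.array([5.0, 2.8, 6.1, 3.9])
        r = mann_whitney_rbc(x, y)
        assert r.p_raw == pytest.approx(mannwhitney_exact_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(0.8, 1.0, 8)
        r = mann_whitney_rbc(x, y)
        sp = sstats.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert r.p_raw == pytest.approx(sp.pvalue, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_rbc(np.empty(0), np.ones(3))


# ---------------------------------------------------------------------------
# multiplicity


class TestCorrections:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)
        assert holm([0.03])[0] == pytest.approx(0.03)

    def test_bh_stepup_hand_computation(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_holm_stepdown_hand_computation(self):
        np.testing.assert_allclose(holm([0.001, 0.02, 0.04]), [0.003, 0.04, 0.04])

    def test_families_corrected_separately(self):
        p = [0.01, 0.02, 0.03, 0.04]
        fam = ["a", "a", "b", "b"]
        adj = fdr_bh(p, fam)
        np.testing.assert_allclose(adj, [0.02, 0.02, 0.04, 0.04])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_bh_monotone_and_bounded(self, ps):
        adj = fdr_bh(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([-0.1, 0.5])


# ---------------------------------------------------------------------------
# mixed rmANOVA


class TestRmAnova:
    def test_two_timepoints_epsilon_one(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(12, 2))
        res = rm_anova_gg(_long(Y), "time_only")
        r = res[0]
        assert r.extras["epsilon_gg"] == 1.0
        assert r.extras["p_uncorrected"] == pytest.approx(r.extras["p_gg"])

    def test_toy_table_matches_matrix_oracle(self):
        Y = np.array(
            [[3.0, 4.0, 7.0], [2.0, 4.0, 6.0], [5.0, 6.0, 8.0], [4.0, 4.0, 9.0]]
        )
        res = rm_anova_gg(_long(Y), "time_only")
        r = res[0]
        F, dfs, eps, ng2 = anova_ss_oracle(Y)
        assert r.statistic == pytest.approx(F)
        assert r.extras["epsilon_gg"] == pytest.approx(eps, abs=1e-9)
        assert r.effect_size == pytest.approx(ng2)
        # uncorrected dfs match the oracle's
        assert (r.df == pytest.approx(dfs)) or (
            r.df == pytest.approx((dfs[0] * eps, dfs[1] * eps))
        )

    def test_matches_pingouin_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(10, 4)) + np.linspace(0, 1, 4)
        df = _long(Y)
        r = rm_anova_gg(df, "time_only")[0]
        tab = pg.rm_anova(df, dv="value", within="timepoint",
                          subject="participant", detailed=True, effsize="ng2")
        assert r.statistic == pytest.approx(tab["F"][0])
        assert r.extras["p_uncorrected"] == pytest.approx(tab["p_unc"][0])
        assert r.effect_size == pytest.approx(tab["ng2"][0])
        assert r.extras["epsilon_gg"] == pytest.approx(tab["eps"][0])

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        groups = np.array(["A"] * 6 + ["B"] * 6)
        Y = rng.normal(size=(12, 3)) + (groups == "B")[:, None] * 0.7
        df = _long(Y, groups)
        res = {r.term: r for r in rm_anova_gg(df, "time_by_tech")}
        tab = pg.mixed_anova(df, dv="value", within="timepoint",
                             subject="participant", between="tech", effsize="ng2")
        tab = tab.set_index("Source")
        assert res["tech"].statistic == pytest.approx(tab.loc["tech", "F"])
        assert res["time"].statistic == pytest.approx(tab.loc["timepoint", "F"])
        assert res["time:tech"].statistic == pytest.approx(tab.loc["Interaction", "F"])
        for term, src in (("tech", "tech"), ("time", "timepoint")):
            assert res[term].effect_size == pytest.approx(tab.loc[src, "ng2"])

    def test_pure_between_shift_consistent_with_t_test(self):
        rng = np.random.default_rng(3)
        groups = np.array(["A"] * 8 + ["B"] * 8)
        Y = rng.normal(size=(16, 4), scale=0.2) + (groups == "B")[:, None] * 2.0
        res = {r.term: r for r in rm_anova_gg(_long(Y, groups), "time_by_tech")}
        # no time structure: time effect tiny, group effect matches t on means
        t, p_t = sstats.ttest_ind(Y[groups == "A"].mean(1), Y[groups == "B"].mean(1))
        assert res["tech"].statistic == pytest.approx(t**2, rel=1e-6)
        assert res["time"].p_raw > 0.05

    def test_three_way_model_reports_all_terms(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(16):
            tech = "MindGym" if i % 2 == 0 else "VR"
            stim = "Breathwork" if i % 4 < 2 else "Rain"
            for j in range(3):
                rows.append((f"s{i}", tech, stim, j + 1, rng.normal()))
        df = pd.DataFrame(rows, columns=["participant", "tech", "stim",
                                         "timepoint", "value"])
        terms = {r.term for r in rm_anova_gg(df, "time_by_tech_by_stim")}
        assert terms == {"tech", "stim", "tech:stim", "time", "time:tech",
                         "time:stim", "time:tech:stim"}

    def test_listwise_deletion_noted(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(8, 3))
        df = _long(Y)
        df = df.drop(df[(df.participant == "s0") & (df.timepoint == 2)].index)
        res = rm_anova_gg(df, "time_only")
        assert "listwise" in res[0].extras["notes"]


# ---------------------------------------------------------------------------
# Holm post-hocs


class TestPosthoc:
    def test_single_contrast_equals_raw(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(10, 2)) + [0.0, 1.0]
        res = holm_posthoc_paired(_long(Y), [(1, 2)])
        assert res[0].p_adjusted == pytest.approx(res[0].p_raw)

    def test_unit_shift_gives_cohens_d_one(self):
        base = np.arange(10.0)
        diff = np.array([0.0, 1.0, 2.0, -1.0, 1.0, 2.0, 1.0, 0.0, 1.0, 3.0])
        diff = (diff - diff.mean()) / diff.std(ddof=1) + 1.0  # mean 1, sd 1
        Y = np.column_stack([base, base + diff])
        res = holm_posthoc_paired(_long(Y), [(1, 2)])
        assert res[0].effect_size == pytest.approx(1.0)

    def test_holm_family_adjustment_and_zero_variance_flag(self):
        rng = np.random.default_rng(1)
        Y = np.column_stack(
            [rng.normal(size=12), rng.normal(1.0, 1.0, 12), rng.normal(2.0, 1.0, 12)]
        )
        res = holm_posthoc_paired(_long(Y), [(1, 2), (1, 3), (2, 3)])
        assert len(res) == 3
        finite = [r for r in res if np.isfinite(r.p_raw)]
        assert all(r.p_adjusted >= r.p_raw - 1e-12 for r in finite)

        Yc = np.column_stack([np.arange(6.0), np.arange(6.0) + 1.0])
        rc = holm_posthoc_paired(_long(Yc), [(1, 2)])
        assert "zero-variance" in rc[0].extras.get("note", "")
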