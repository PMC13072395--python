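"""Tests for the group-statistics layer, cross-checked against
from-scratch enumeration and sums-of-squares oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from slicephys import (
    StudySimParams,
    mann_whitney,
    power_check,
    rout_outliers,
    two_way_anova,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# independent oracles


def mw_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of all
    C(m+n, m) group assignments of the pooled sample."""
    pooled = sorted(x) + sorted(y)
    m = len(x)
    idx = range(len(pooled))

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in idx if i not in set(subset)]
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    us = [u_of(s) for s in itertools.combinations(idx, m)]
    n_tot = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / n_tot
    p_ge = sum(1 for u in us if u >= u_obs) / n_tot
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by enumeration of all 2^n sign
    assignments of the magnitude ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = float(ranks[d > 0].sum())
    n = len(d)
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    n_tot = len(ws)
    p_le = sum(1 for w in ws if w <= w_obs) / n_tot
    p_ge = sum(1 for w in ws if w >= w_obs) / n_tot
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def anova_ss_oracle(df):
    """Classical balanced 2x2 sums-of-squares decomposition by hand."""
    y = df["value"].to_numpy()
    grand = y.mean()
    cells = {k: g["value"].to_numpy() for k, g in df.groupby(["genotype", "treatment"])}
    n = len(next(iter(cells.values())))
    a_means = {a: df[df.genotype == a]["value"].mean() for a in df.genotype.unique()}
    b_means = {b: df[df.treatment == b]["value"].mean() for b in df.treatment.unique()}
    ss_a = 2 * n * sum((m - grand) ** 2 for m in a_means.values())
    ss_b = 2 * n * sum((m - grand) ** 2 for m in b_means.values())
    ss_ab = n * sum(
        (v.mean() - a_means[a] - b_means[b] + grand) ** 2 for (a, b), v in cells.items()
    )
    ss_res = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    df_res = 4 * (n - 1)
    ms_res = ss_res / df_res
    return {
        "genotype": ss_a / ms_res,
        "treatment": ss_b / ms_res,
        "interaction": ss_ab / ms_res,
        "ms_res": ms_res,
        "df_res": df_res,
    }


# ---------------------------------------------------------------------------
# ROUT


class TestRout:
    def test_gross_outlier_flagged(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.standard_normal(20), [10.0]])
            res = rout_outliers(x)
            if res.outlier_mask[-1] and res.outlier_mask.sum() == 1:
                hits += 1
        assert hits >= 38  # flagged, and only it, in >= 95% of draws

    def test_identical_values_none_flagged(self):
        res = rout_outliers(np.full(10, 3.14))
        assert res.outliers.size == 0

    def test_null_flag_rate_bounded(self):
        total, flagged = 0, 0
        for seed in range(300):
            rng = np.random.default_rng(1000 + seed)
            x = rng.standard_normal(20)
            res = rout_outliers(x, Q=0.01)
            total += x.size
            flagged += int(res.outlier_mask.sum())
        assert flagged / total <= 2 * 0.01

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = rout_outliers([1.0, 2.0])
        assert res.kept.size == 2


# ---------------------------------------------------------------------------
# rank tests


class TestMannWhitney:
    def test_textbook_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 6.0)

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        _, p = mann_whitney(x, x)
        assert p > 0.9

    def test_matches_enumeration_oracle_small_samples(self, rng):
        for m in range(2, 7):
            for n in range(2, 7):
                x = rng.normal(size=m)
                y = rng.normal(size=n)
                u_got, p_got = mann_whitney(x, y)
                u_want, p_want = mw_exact_oracle(list(x), list(y))
                assert p_got == pytest.approx(p_want, abs=1e-12)

    def test_exact_close_to_normal_approximation(self, rng):
        # m = n = 8 sits at the exact/approximate switch; the two must agree
        diffs = []
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p_exact = mann_whitney(x, y)
            from scipy.stats import mannwhitneyu

            p_approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            diffs.append(abs(p_exact - p_approx))
        assert max(diffs) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences_n5(self):
        w, p = wilcoxon_signed_rank([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
        assert w == 15.0
        assert p == pytest.approx(2.0 / 32.0)

    def test_no_change_p_one(self):
        x = [1.0, 2.0, 3.0]
        with pytest.warns(UserWarning, match="zero"):
            w, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    def test_sign_flip_antisymmetry(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _, p1 = wilcoxon_signed_rank(a, b)
        _, p2 = wilcoxon_signed_rank(b, a)
        assert p1 == pytest.approx(p2)

    def test_matches_enumeration_oracle(self, rng):
        for n in range(4, 11):
            d = rng.normal(size=n)
            w_got, p_got = wilcoxon_signed_rank(np.zeros(n), d)
            w_want, p_want = wilcoxon_exact_oracle(d)
            assert w_got == w_want
            assert p_got == pytest.approx(p_want, abs=1e-12)


# ---------------------------------------------------------------------------
# 2x2 ANOVA + LSD


def tidy(values):
    rows = []
    for (g, t), vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"unit_id": f"{g}_{t}_{i}", "genotype": g, "treatment": t, "value": v})
    return pd.DataFrame(rows)


class TestAnova:
    def test_all_equal_gives_zero_f(self):
        df = tidy({(g, t): [5.0, 5.0, 5.0] for g in ("WT", "3xTG") for t in ("control", "UCP4")})
        res = two_way_anova(df)
        for eff in ("genotype", "treatment", "interaction"):
            assert res.F(eff) == 0.0
            assert res.p(eff) == 1.0

    def test_balanced_f_matches_hand_decomposition(self, rng):
        df = tidy(
            {(g, t): rng.normal(size=6) for g in ("WT", "3xTG") for t in ("control", "UCP4")}
        )
        res = two_way_anova(df)
        want = anova_ss_oracle(df)
        for eff in ("genotype", "treatment", "interaction"):
            assert res.F(eff) == pytest.approx(want[eff], abs=1e-10)
        assert res.residual_ms == pytest.approx(want["ms_res"], abs=1e-10)
        assert res.residual_df == want["df_res"]

    def test_pure_additive_effects_zero_interaction(self):
        vals = {}
        for g, ge in (("WT", 0.0), ("3xTG", 2.0)):
            for t, te in (("control", 0.0), ("UCP4", 1.0)):
                vals[(g, t)] = [ge + te, ge + te, ge + te]
        res = two_way_anova(tidy(vals))
        assert res.F("interaction") == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_invariance(self, rng):
        df = tidy(
            {(g, t): rng.normal(size=5) for g in ("WT", "3xTG") for t in ("control", "UCP4")}
        )
        r1 = two_way_anova(df)
        df2 = df.assign(value=df.value + 100.0)
        r2 = two_way_anova(df2)
        for eff in ("genotype", "treatment", "interaction"):
            assert r1.F(eff) == pytest.approx(r2.F(eff), rel=1e-9)

    def test_lsd_equals_pooled_t_test(self, rng):
        from scipy.stats import t as tdist

        df = tidy(
            {(g, t): rng.normal(size=4) for g in ("WT", "3xTG") for t in ("control", "UCP4")}
        )
        res = two_way_anova(df)
        for row in res.lsd.itertuples():
            c1 = tuple(row.cell_1.split("/"))
            c2 = tuple(row.cell_2.split("/"))
            m1, m2 = res.cell_means[c1], res.cell_means[c2]
            se = math.sqrt(res.residual_ms * (1 / res.cell_ns[c1] + 1 / res.cell_ns[c2]))
            t_want = (m1 - m2) / se
            p_want = 2 * tdist.sf(abs(t_want), res.residual_df)
            assert row.t == pytest.approx(t_want)
            assert row.p == pytest.approx(p_want)

    def test_empty_cell_rejected(self):
        df = tidy({("WT", "control"): [1.0, 2.0], ("WT", "UCP4"): [1.0, 2.0],
                   ("3xTG", "control"): [1.0, 2.0]})
        with pytest.raises(ValueError, match="all four cells"):
            two_way_anova(df)

    def test_single_unit_cells_flagged(self):
        df = tidy({(g, t): [1.0 + hash((g, t)) % 3] for g in ("WT", "3xTG")
                   for t in ("control", "UCP4")})
        df = pd.concat([df, df.assign(unit_id=df.unit_id + "b", value=df.value + 0.5)])
        df = df.iloc[:-3]  # leave one cell with a single unit
        res = two_way_anova(df)
        assert any("insufficient_replication" in w for w in res.warnings)


class TestPowerCheck:
    def test_alpha_one_rejects_always(self):
        p = StudySimParams.from_folds(n_recordings=3, duration_s=10.0, fs=2000.0)
        rates = power_check(p, n_replicates=2, alpha=1.0, seed=1)
        assert rates["genotype"] == 1.0

    def test_large_effect_detected(self):
        p = StudySimParams.from_folds(
            rate_fold_genotype=3.0, n_recordings=8, duration_s=30.0, fs=2000.0
        )
        rates = power_check(p, n_replicates=5, seed=2)
        assert rates["genotype"] == 1.0
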