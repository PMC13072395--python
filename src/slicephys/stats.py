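"""Group statistics for per-recording / per-cell measurements.

The layer mirrors the analysis conventions of small factorial slice
studies: ROUT-style robust outlier removal, two-tailed Mann-Whitney and
Wilcoxon tests (exact for small samples), and 2x2 ANOVA (genotype x
treatment) followed by Fisher's LSD pairwise comparisons on the pooled
residual variance.  LSD p-values are uncorrected and are reported
regardless of the omnibus outcome, with the omnibus result attached —
they do not control the family-wise error rate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RoutResult",
    "AnovaResult",
    "rout_outliers",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "two_way_anova",
    "power_check",
]


# ---------------------------------------------------------------------------
# ROUT-style outlier removal (one-sample degenerate form)


@dataclass
class RoutResult:
    kept: np.ndarray
    outliers: np.ndarray
    outlier_mask: np.ndarray  # True where flagged, aligned with the input
    rsdr: float


def rout_outliers(values, Q: float = 0.01) -> RoutResult:
    """Robust, FDR-based outlier identification for one-sample group data.

    The regression form of ROUT degenerates, for a single group, to a
    robust location/scale fit: location = median, scale = RSDR estimated
    from the 68.27th percentile of absolute residuals with an n/(n-1)
    small-sample correction.  Each point's residual is converted to a
    t-like statistic on n-1 df and the resulting p-values are screened by
    Benjamini-Hochberg at false-discovery rate ``Q`` (default 1%, the
    customary setting).  Flagged points are removed.

    Fewer than 3 values: nothing is removed (with a warning).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        warnings.warn("fewer than 3 values; outlier removal skipped", stacklevel=2)
        return RoutResult(x, np.array([]), np.zeros(n, dtype=bool), np.nan)
    resid = x - np.median(x)
    p68 = float(np.percentile(np.abs(resid), 68.27))
    rsdr = p68 * n / (n - 1)
    if rsdr == 0:
        return RoutResult(x, np.array([]), np.zeros(n, dtype=bool), 0.0)
    t = np.abs(resid) / rsdr
    p = 2.0 * sps.t.sf(t, df=n - 1)
    # Benjamini-Hochberg screen at rate Q
    order = np.argsort(p)
    thresh = Q * (np.arange(1, n + 1)) / n
    below = p[order] <= thresh
    mask = np.zeros(n, dtype=bool)
    if below.any():
        k = int(np.flatnonzero(below).max())
        mask[order[: k + 1]] = True
    return RoutResult(x[~mask], x[mask], mask, rsdr)


# ---------------------------------------------------------------------------
# rank tests


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of the null rank distribution when both samples
    have at most 8 observations and there are no ties; otherwise the
    normal approximation with tie correction.  Returns (U of the first
    sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(before, after) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences are dropped (Wilcoxon's convention).  Exact p for at
    most 15 non-zero pairs without tied magnitudes, else the normal
    approximation.  Returns (W = sum of positive ranks, two-sided p).
    All-zero differences give (0, 1.0) with a warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("paired samples must have equal length")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 15 and not ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    # scipy reports min(W+, W-); convert to the sum of positive ranks
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    return w_pos, float(res.pvalue)


# ---------------------------------------------------------------------------
# 2x2 factorial ANOVA with Fisher's LSD


@dataclass
class AnovaResult:
    """F tests for genotype, treatment and their interaction, plus the
    pairwise Fisher's LSD table computed from the pooled residual MS."""

    table: pd.DataFrame            # index: genotype/treatment/interaction/residual
    lsd: pd.DataFrame              # pairwise simple effects, uncorrected
    residual_ms: float
    residual_df: float
    cell_means: pd.Series
    cell_ns: pd.Series
    warnings: tuple[str, ...] = ()

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])


def two_way_anova(table: pd.DataFrame, value: str = "value") -> AnovaResult:
    """2x2 ANOVA (genotype x treatment) with Fisher's LSD post hoc.

    ``table`` is tidy: one row per unit with columns ``genotype``,
    ``treatment`` and the value column.  Sums of squares are Type III
    (computed with sum-to-zero contrasts), which coincides with the
    classical decomposition in the balanced case.  Every cell must contain
    at least one unit and at least one cell two, so a residual df exists;
    fewer than 2 units per cell is reported as insufficient replication.

    Fisher's LSD compares all cell pairs with
    ``t = (m_i - m_j) / sqrt(MS_res * (1/n_i + 1/n_j))`` on the residual
    df, two-sided and uncorrected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.copy()
    for col in ("genotype", "treatment", value):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    df = df.rename(columns={value: "_y"})
    counts = df.groupby(["genotype", "treatment"], observed=True)["_y"].count()
    if counts.size < 4 or (counts == 0).any():
        raise ValueError("2x2 design requires observations in all four cells")
    warns = []
    if (counts < 2).any():
        warns.append("insufficient_replication: fewer than 2 units in some cell")

    model = smf.ols("_y ~ C(genotype, Sum) * C(treatment, Sum)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    res_df = float(aov.loc["Residual", "df"])
    # least-squares rounding residue (~1e-30 on exact-arithmetic inputs)
    # must not masquerade as a nonzero effect: sums of squares below
    # machine precision relative to the total variation are exactly zero
    y = df["_y"].to_numpy()
    ss_tol = max(float(((y - y.mean()) ** 2).sum()), 1.0) * 1e-12

    def ss_of(label):
        v = float(aov.loc[label, "sum_sq"])
        return 0.0 if v <= ss_tol else v

    ss_res = ss_of("Residual")
    res_ms = ss_res / res_df

    labels = {
        "genotype": "C(genotype, Sum)",
        "treatment": "C(treatment, Sum)",
        "interaction": "C(genotype, Sum):C(treatment, Sum)",
    }
    rows_out = {}
    for eff, label in labels.items():
        ss = ss_of(label)
        dfe = float(aov.loc[label, "df"])
        if res_ms > 0:
            f = (ss / dfe) / res_ms
            p = float(sps.f.sf(f, dfe, res_df))
        elif ss == 0.0:
            f, p = 0.0, 1.0  # no effect and no residual variation
        else:
            f, p = np.inf, 0.0  # exact effect with zero residual noise
        rows_out[eff] = {"F": f, "df": dfe, "p": p}
    out = pd.DataFrame(rows_out).T

    means = df.groupby(["genotype", "treatment"], observed=True)["_y"].mean()
    cells = list(means.index)
    rows = []
    for (c1, c2) in itertools.combinations(cells, 2):
        m1, m2 = means[c1], means[c2]
        n1, n2 = counts[c1], counts[c2]
        se = np.sqrt(res_ms * (1.0 / n1 + 1.0 / n2)) if res_ms > 0 else 0.0
        if se > 0:
            tstat = (m1 - m2) / se
            p = 2.0 * sps.t.sf(abs(tstat), df=res_df)
        else:
            tstat = 0.0 if np.isclose(m1, m2) else np.inf
            p = 1.0 if np.isclose(m1, m2) else 0.0
        rows.append(
            {"cell_1": "/".join(c1), "cell_2": "/".join(c2),
             "mean_diff": m1 - m2, "t": tstat, "df": res_df, "p": p}
        )
    lsd = pd.DataFrame(rows)
    return AnovaResult(
        table=out, lsd=lsd, residual_ms=res_ms, residual_df=res_df,
        cell_means=means, cell_ns=counts, warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# end-to-end power / type-I check on simulated studies


def power_check(
    sim_params,
    n_replicates: int = 200,
    alpha: float = 0.05,
    detect_params=None,
    seed: int = 0,
) -> dict[str, float]:
    """Rejection rates of the 2x2 ANOVA effects over replicate simulated
    studies run through the full detection pipeline.

    Each replicate draws a study from ``sim_params`` (re-seeded), detects
    SWRs in every recording, tabulates per-recording occurrence and tests
    it with :func:`two_way_anova`.  Under identical group parameters the
    genotype rejection rate estimates the type-I error at ``alpha``; with
    a genotype rate fold it estimates power.
    """
    from dataclasses import replace

    from .pipeline import occurrence_table
    from .ripples import RippleDetectParams, detect_swr
    from .simulate import simulate_study

    detect_params = detect_params or RippleDetectParams()
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    hits = {"genotype": 0, "treatment": 0, "interaction": 0}
    for rs in rep_seeds:
        study = simulate_study(replace(sim_params, seed=rs))
        catalogs = [
            (detect_swr(trace, detect_params, meta.recording_id), meta)
            for trace, meta, _ in study
        ]
        tab = occurrence_table(catalogs, exclude_no_activity=True)
        res = two_way_anova(tab, value="occurrence_hz")
        for eff in hits:
            if res.p(eff) < alpha:
                hits[eff] += 1
    return {eff: hits[eff] / n_replicates for eff in hits}
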