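"""ANOVA, Tukey HSD and relative isoform abundance.

One-way ANOVA and Tukey's multiple-comparison test are available both from
raw replicate values and from printed group summaries (mean, SEM, n) — the
form in which results are typically reported in figure captions.  The
summary path is exact: any raw data reproducing the summaries yields the
identical F and Tukey statistics, because the one-way decomposition depends
on the data only through per-group (mean, SD, n).

Tukey adjusted p-values use the studentized range distribution
(``scipy.stats.studentized_range``); unequal group sizes are handled by the
Tukey-Kramer harmonic-mean correction.  A two-way fixed-effects ANOVA (via
statsmodels OLS) covers genotype x histogram-bin designs, and
:func:`relative_abundance` converts paired per-animal measurements for two
isoform probes into percentage splits with group mean +/- SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary", "AnovaResult", "TukeyResult", "IsoformAbundance",
    "TwoWayAnovaResult", "anova_oneway", "anova_from_summary",
    "reconstruct_raw", "tukey_hsd", "anova_twoway", "relative_abundance",
    "summaries_from_raw",
]


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.group_label}: n must be >= 2")
        if self.sem < 0:
            raise ValueError(f"group {self.group_label}: sem must be >= 0")

    @property
    def sd(self) -> float:
        """Sample SD (ddof=1) implied by the SEM."""
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    ms_between: float


@dataclass
class TukeyResult:
    table: pd.DataFrame  # group_a, group_b, mean_diff, q_statistic, p_adjusted

    def p_for(self, a: str, b: str) -> float:
        t = self.table
        row = t[((t.group_a == a) & (t.group_b == b))
                | ((t.group_a == b) & (t.group_b == a))]
        if row.empty:
            raise KeyError(f"no pair ({a}, {b})")
        return float(row.p_adjusted.iloc[0])


@dataclass
class IsoformAbundance:
    pair_label: str
    pct_a: float
    pct_b: float
    sem_a: float
    per_replicate_pct_a: list[float] = field(default_factory=list)

    @property
    def sem_b(self) -> float:
        return self.sem_a


@dataclass
class TwoWayAnovaResult:
    table: pd.DataFrame  # term, sum_sq, df, F, p
    tukey_within_b: dict[str, TukeyResult] = field(default_factory=dict)

    def row(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]


# ---------------------------------------------------------------------------

def summaries_from_raw(groups: Sequence[Sequence[float]],
                       labels: Sequence[str] | None = None) -> list[GroupSummary]:
    labels = labels or [f"g{i}" for i in range(len(groups))]
    out = []
    for lab, g in zip(labels, groups):
        g = np.asarray(g, dtype=np.float64)
        out.append(GroupSummary(lab, float(g.mean()),
                                float(g.std(ddof=1) / np.sqrt(len(g))),
                                int(len(g))))
    return out


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA on raw replicate values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    return anova_from_summary(summaries_from_raw(arrs))


def anova_from_summary(summaries: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA computed from (mean, SEM, n) group summaries.

    SS_between is the n-weighted dispersion of group means around the grand
    mean; MS_within pools the per-group variances (n * sem^2) weighted by
    their degrees of freedom.  Identical to :func:`anova_oneway` on any raw
    data reproducing the summaries.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two group summaries")
    ns = np.array([s.n for s in summaries], dtype=np.float64)
    means = np.array([s.mean for s in summaries])
    variances = np.array([s.sd ** 2 for s in summaries])

    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    df_between = len(summaries) - 1
    df_within = int(ns.sum()) - len(summaries)
    ss_within = float(((ns - 1) * variances).sum())
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    if ms_within == 0.0:
        if ss_between == 0.0:
            warnings.warn("degenerate ANOVA: all groups identical; F = 0")
            return AnovaResult(0.0, df_between, df_within, 1.0, 0.0, 0.0)
        return AnovaResult(float("inf"), df_between, df_within, 0.0,
                           0.0, ms_between)
    F = ms_between / ms_within
    # survival function in log-safe form; sf already accumulates the tail
    p = float(sps.f.sf(F, df_between, df_within))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    if ss_between == 0.0:
        p = 1.0
    return AnovaResult(float(F), df_between, df_within, p,
                       float(ms_within), float(ms_between))


def reconstruct_raw(mean: float, sem: float, n: int) -> np.ndarray:
    """Exact symmetric raw vector with the given mean, SEM and n.

    m points at mean-d and m at mean+d (plus one at the mean when n is odd),
    with d chosen so the ddof=1 sample SD equals sem*sqrt(n) exactly.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    sd = sem * np.sqrt(n)
    m = n // 2
    d = sd * np.sqrt((n - 1) / (2 * m))
    vals = [mean - d] * m + ([mean] if n % 2 else []) + [mean + d] * m
    return np.array(vals, dtype=np.float64)


def tukey_hsd(summaries: Sequence[GroupSummary],
              anova: AnovaResult | None = None) -> TukeyResult:
    """All-pairs Tukey HSD from group summaries.

    q = |mean_a - mean_b| / sqrt(MS_within / n_h), with n_h the harmonic mean
    of the two group sizes (Tukey-Kramer); adjusted p from the studentized
    range distribution with k groups and the ANOVA within-group df.
    """
    if len(summaries) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    if anova is None:
        anova = anova_from_summary(summaries)
    k = len(summaries)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = summaries[i], summaries[j]
            diff = a.mean - b.mean
            n_h = 2.0 / (1.0 / a.n + 1.0 / b.n)
            if anova.ms_within == 0.0:
                q = float("inf") if diff != 0 else 0.0
            else:
                q = abs(diff) / np.sqrt(anova.ms_within / n_h)
            if q == 0.0:
                p = 1.0
            elif np.isinf(q):
                p = 0.0
            else:
                p = float(sps.studentized_range.sf(q, k, anova.df_within))
                p = min(max(p, 0.0), 1.0)
            rows.append({
                "group_a": a.group_label, "group_b": b.group_label,
                "mean_diff": float(diff), "q_statistic": float(q),
                "p_adjusted": p,
            })
    return TukeyResult(pd.DataFrame(rows))


def anova_twoway(
    factor_a_levels: Sequence[str],
    factor_b_levels: Sequence[str],
    cell_values: Sequence[Sequence[Sequence[float]]],
    *,
    tukey_a_within_b: bool = False,
) -> TwoWayAnovaResult:
    """Two-way fixed-effects ANOVA with interaction on a complete crossed
    design; ``cell_values[i][j]`` holds the replicates for level i of factor
    A and level j of factor B.  Optionally adds Tukey comparisons of factor A
    within each level of B, using the pooled residual MS.

    Note: when the responses are per-bin counts from the same cells (a
    genotype x dots-per-cell-bin histogram), the bins are not independent
    observations; the test is reported as specified, not corrected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    recs = []
    for i, a in enumerate(factor_a_levels):
        for j, b in enumerate(factor_b_levels):
            try:
                vals = cell_values[i][j]
            except (IndexError, KeyError):
                vals = None
            if vals is None or len(vals) == 0:
                raise ValueError(
                    f"missing cell ({a}, {b}): design must be complete"
                )
            for v in vals:
                recs.append({"A": a, "B": b, "value": float(v)})
    df = pd.DataFrame(recs)
    model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual designs warn
        tab = anova_lm(model, typ=2)
    name_map = {
        "C(A)": "factor_a", "C(B)": "factor_b",
        "C(A):C(B)": "interaction", "Residual": "residual",
    }
    out = pd.DataFrame({
        "term": [name_map.get(t, t) for t in tab.index],
        "sum_sq": tab["sum_sq"].to_numpy(),
        "df": tab["df"].to_numpy(),
        "F": tab["F"].to_numpy(),
        "p": tab["PR(>F)"].to_numpy(),
    })
    # degenerate designs leave O(eps) sums of squares; report F=0, p=1 there
    scale = max(float(((df.value - df.value.mean()) ** 2).sum()), 1.0)
    tiny = out.sum_sq.abs() < 1e-10 * scale
    out.loc[tiny & (out.term != "residual"), ["F", "p"]] = [0.0, 1.0]

    result = TwoWayAnovaResult(table=out)
    if tukey_a_within_b:
        resid = out[out.term == "residual"].iloc[0]
        ms_within = float(resid.sum_sq / resid.df)
        df_within = int(resid.df)
        k = len(factor_a_levels)
        for j, b in enumerate(factor_b_levels):
            rows = []
            for i1 in range(k):
                for i2 in range(i1 + 1, k):
                    g1 = np.asarray(cell_values[i1][j], dtype=np.float64)
                    g2 = np.asarray(cell_values[i2][j], dtype=np.float64)
                    diff = g1.mean() - g2.mean()
                    n_h = 2.0 / (1.0 / len(g1) + 1.0 / len(g2))
                    q = (abs(diff) / np.sqrt(ms_within / n_h)
                         if ms_within > 0 else
                         (0.0 if diff == 0 else float("inf")))
                    if q == 0:
                        p = 1.0
                    elif np.isinf(q):
                        p = 0.0
                    else:
                        p = float(sps.studentized_range.sf(q, k, df_within))
                    rows.append({
                        "group_a": factor_a_levels[i1],
                        "group_b": factor_a_levels[i2],
                        "mean_diff": float(diff), "q_statistic": float(q),
                        "p_adjusted": p,
                    })
            result.tukey_within_b[b] = TukeyResult(pd.DataFrame(rows))
    return result


def relative_abundance(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    pair_label: str = "A/B",
) -> IsoformAbundance:
    """Percent split between two isoforms from paired per-animal measures.

    Each animal contributes pct_a = 100*a/(a+b); animals with a+b = 0 are
    excluded with a warning.  Group mean +/- SEM over the remaining animals.
    """
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("counts_a and counts_b must be paired (same length)")
    total = a + b
    keep = total > 0
    if not keep.all():
        warnings.warn(
            f"excluded {int((~keep).sum())} animal(s) with zero total counts"
        )
    if not keep.any():
        raise ValueError("no animal has nonzero total counts")
    pct_a = 100.0 * a[keep] / total[keep]
    sem = (float(pct_a.std(ddof=1) / np.sqrt(len(pct_a)))
           if len(pct_a) > 1 else 0.0)
    return IsoformAbundance(
        pair_label=pair_label,
        pct_a=float(pct_a.mean()),
        pct_b=100.0 - float(pct_a.mean()),
        sem_a=sem,
        per_replicate_pct_a=[float(x) for x in pct_a],
    )
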