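"""Biomarker ratios, fold changes, and group statistics.

The comparisons mirror the study design: pooled-variance Student's t with
one-tailed p for two-group contrasts, one-way ANOVA with a Dunnett
post-hoc (many treatments against one control), and volcano tables of
log2 fold change against -log10 p across a metabolite panel. Clinically
motivated ratios (propionylcarnitine/acetylcarnitine "C3/C2",
methylcitrate/citrate) are simple per-sample quotients.

The one-tailed direction is a modeling input; when left to ``"auto"`` the
direction of the observed mean difference is used and the result is
flagged as post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements",
    "ComparisonResult",
    "RatioResult",
    "metabolite_ratio",
    "fold_change",
    "one_tailed_t_test",
    "one_way_anova",
    "dunnett_adjust",
    "dunnett_raw_pvalues",
    "volcano_table",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupedMeasurements:
    """Per-animal values for one metabolite/tissue/group."""

    metabolite: str
    tissue: str
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1 or not np.all(np.isfinite(v)):
            raise ValueError("values must be a non-empty finite 1-D vector")
        object.__setattr__(self, "values", v)


@dataclass
class ComparisonResult:
    """Two-group contrast: fold change (B/A) and a test of difference."""

    label: str
    fold_change: float
    log2_fold_change: float
    statistic: float
    p_value: float
    test_name: str
    n_a: int
    n_b: int
    direction: str = "auto"
    direction_post_hoc: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class RatioResult:
    numerator: str
    denominator: str
    ratios: np.ndarray = field(default_factory=lambda: np.array([]))


def metabolite_ratio(
    num: np.ndarray, den: np.ndarray, *, numerator: str = "num",
    denominator: str = "den",
) -> RatioResult:
    """Per-sample ratio of two paired metabolite vectors (den > 0)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator must be paired by sample")
    if np.any(den <= 0):
        raise ValueError("denominator values must be positive")
    return RatioResult(numerator, denominator, num / den)


def fold_change(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """mean(B)/mean(A) and its log2 (A is the reference group)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    ma = a.mean()
    if ma == 0:
        raise ValueError("reference group mean is zero")
    fc = b.mean() / ma
    if fc <= 0:
        raise ValueError("fold change undefined for non-positive means")
    return float(fc), float(np.log2(fc))


def one_tailed_t_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    direction: str = "auto",
) -> tuple[float, float, str, bool]:
    """Pooled-variance Student's t of B against A with one-tailed p.

    ``direction`` is ``"greater"`` (alternative: mean B > mean A),
    ``"less"``, or ``"auto"`` (take the observed direction; flagged post
    hoc). Identical groups give t = 0, p = 0.5. Returns
    (t, p, direction used, post-hoc flag).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    post_hoc = False
    if direction == "auto":
        direction = "greater" if b.mean() >= a.mean() else "less"
        post_hoc = True
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5, direction, post_hoc
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(b, a, equal_var=True, alternative=direction)
    return float(res.statistic), float(res.pvalue), direction, post_hoc


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F and p over >= 2 groups (each n >= 2).

    For two groups F equals the square of the two-sided pooled t.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ValueError("each group needs n >= 2")
    if all(g.var(ddof=1) == 0 for g in arrs):
        means = [g.mean() for g in arrs]
        if len(set(means)) == 1:
            return 0.0, 1.0
        raise ValueError("degenerate within-group variance")
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def _dunnett_t_stats(control: np.ndarray, treatments: list[np.ndarray]):
    """Many-to-one t statistics with the pooled MSE across all groups."""
    groups = [control] + list(treatments)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = int(ns.sum() - len(groups))
    if df <= 0 or sse <= 0:
        raise ValueError("degenerate variance for Dunnett statistics")
    mse = sse / df
    se = np.sqrt(mse * (1.0 / ns[1:] + 1.0 / ns[0]))
    return (means[1:] - means[0]) / se, ns, df


def dunnett_raw_pvalues(control: np.ndarray, treatments: list[np.ndarray]) -> np.ndarray:
    """Unadjusted two-sided p of each many-to-one t statistic (pooled MSE
    across all groups); the per-comparison baseline the Dunnett
    adjustment inflates."""
    control = np.asarray(control, dtype=float)
    treatments = [np.asarray(t, dtype=float) for t in treatments]
    t_obs, _, df = _dunnett_t_stats(control, treatments)
    return 2.0 * sps.t.sf(np.abs(t_obs), df)


def dunnett_adjust(
    control: np.ndarray,
    treatments: list[np.ndarray],
    n_mc: int = 10000,
    seed: int | None = None,
) -> np.ndarray:
    """Dunnett many-to-one adjusted p-values by Monte Carlo.

    Simulates the joint null of the k correlated two-sided t statistics
    (all groups resampled from one normal null, pooled MSE shared with the
    common control) and reports, per treatment,
    P(max_i |T_i^null| >= |t_obs|). Adjusted p is >= the raw two-sided p
    and <= the Bonferroni bound k*p up to Monte-Carlo error. Fixed seed
    gives bit-identical output. ``n_mc`` < 1000 is rejected as too coarse.
    """
    if len(treatments) < 1:
        raise ValueError("need at least one treatment group")
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    control = np.asarray(control, dtype=float)
    treatments = [np.asarray(t, dtype=float) for t in treatments]
    t_obs, ns, df = _dunnett_t_stats(control, treatments)
    rng = np.random.default_rng(seed)
    k = len(treatments)
    # simulate group means and pooled variance under the null in blocks
    max_abs = np.empty(n_mc)
    block = 20000
    done = 0
    while done < n_mc:
        m = min(block, n_mc - done)
        means = rng.standard_normal((m, k + 1)) / np.sqrt(ns)
        # pooled within-group SS is chi2 with df degrees of freedom
        s2 = rng.chisquare(df, size=m) / df
        se = np.sqrt(s2[:, None] * (1.0 / ns[1:] + 1.0 / ns[0]))
        t_null = (means[:, 1:] - means[:, :1]) / se
        max_abs[done : done + m] = np.abs(t_null).max(axis=1)
        done += m
    # (1 + count) / (1 + n_mc): MC p-value never exactly 0
    adj = (1.0 + (max_abs[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) / (
        1.0 + n_mc
    )
    return np.minimum(adj, 1.0)


def compare_groups(
    group_a: np.ndarray,
    group_b: np.ndarray,
    direction: str = "auto",
    label: str = "",
) -> ComparisonResult:
    """Fold change plus one-tailed Student's t in one record."""
    fc, lfc = fold_change(group_a, group_b)
    t, p, used, post_hoc = one_tailed_t_test(group_a, group_b, direction)
    return ComparisonResult(
        label=label,
        fold_change=fc,
        log2_fold_change=lfc,
        statistic=t,
        p_value=p,
        test_name="student_t_one_tailed",
        n_a=len(np.asarray(group_a)),
        n_b=len(np.asarray(group_b)),
        direction=used,
        direction_post_hoc=post_hoc,
    )


def volcano_table(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    """Volcano summary: one row per comparison, ranked by ascending p.

    Columns: metabolite, log2_fc, neg_log10_p, p_value, rank. Ties break
    by input order (stable sort); an empty input gives an empty table.
    """
    cols = ["metabolite", "log2_fc", "neg_log10_p", "p_value", "rank"]
    if not comparisons:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "metabolite": [c.label for c in comparisons],
            "log2_fc": [c.log2_fold_change for c in comparisons],
            "neg_log10_p": [
                0.0 if c.p_value >= 1.0 else -np.log10(c.p_value)
                for c in comparisons
            ],
            "p_value": [c.p_value for c in comparisons],
        }
    )
    df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[cols]
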