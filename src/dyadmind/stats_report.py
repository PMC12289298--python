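"""Paired nonparametric outcome battery and table-style reporting.

The study's analysis plan for every outcome measure is: remove MAD outliers,
check normality (Anderson-Darling), then run a one-sided paired test in the
hypothesized improvement direction — Wilcoxon signed-rank for non-normal
change scores, a one-tailed paired t test for normal ones — and report the
paired Cohen d, the mean difference with a 95% t CI, and Benjamini-Hochberg
FDR-adjusted p values within each declared outcome family.

The signed-rank and rank-sum statistics are computed here with the
tie-corrected normal approximation (and a 0.5 continuity correction in the
p value) so the z statistic the report prints is well defined; scipy's exact
routines serve as cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedSample",
    "EffectRow",
    "MeasurePlan",
    "remove_outliers_mad",
    "anderson_darling_normal",
    "signed_rank_one_sided",
    "rank_sum",
    "paired_t_one_sided",
    "cohens_d_paired",
    "mean_diff_ci",
    "spearman_corr",
    "bh_fdr",
    "outcome_table",
    "render_report",
]


@dataclass(frozen=True)
class PairedSample:
    """Complete (listwise) paired values for one measure and comparison."""

    measure: str
    pre: tuple
    after: tuple  # post or follow-up values, aligned with pre
    respondent: str = "parent"
    comparison: str = "post"  # "post" | "followup"

    def __post_init__(self) -> None:
        if len(self.pre) != len(self.after):
            raise ValueError("pre and after must be aligned")


@dataclass(frozen=True)
class MeasurePlan:
    """Analysis-plan row: test direction and FDR family for one measure.

    ``direction`` is the hypothesized improvement: ``"decrease"`` for symptom
    scales, ``"increase"`` for mindfulness and processing speed.
    """

    measure: str
    direction: str
    family: str = "default"
    respondent: str = "parent"

    def __post_init__(self) -> None:
        if self.direction not in ("decrease", "increase"):
            raise ValueError(f"direction must be decrease|increase, got {self.direction!r}")


@dataclass(frozen=True)
class EffectRow:
    """One outcome line of the summary table."""

    measure: str
    comparison: str
    n: int
    direction: str
    d: float
    mean_diff: float
    ci_lo: float
    ci_hi: float
    stat_name: str  # "z" | "t"
    statistic: float
    p_raw: float
    p_fdr: float
    normal: bool
    n_outliers_removed: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.mean_diff <= self.ci_hi):
            raise ValueError("CI must bracket the mean difference")
        if self.p_fdr + 1e-12 < self.p_raw:
            raise ValueError("adjusted p cannot be below raw p")


def remove_outliers_mad(x, k: float = 3.0):
    """Drop values more than ``k`` MADs from the median.

    Median and MAD come from the full input. Returns ``(kept, removed_idx)``.
    With MAD 0 but non-constant data, only exact-median matches are kept and
    a warning is emitted (the robust threshold is degenerate).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for MAD outlier screening")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    if mad == 0 and np.any(dev > 0):
        warnings.warn(
            "MAD is zero on non-constant data; keeping exact-median values only",
            stacklevel=2,
        )
        keep = dev == 0
    else:
        keep = dev <= k * mad
    removed = np.flatnonzero(~keep)
    return x[keep], removed


def anderson_darling_normal(x, alpha: float = 0.05) -> dict:
    """Anderson-Darling normality check with estimated mean and variance.

    Uses the case-3 statistic with the standard small-sample correction (as
    provided by :func:`scipy.stats.anderson`) and compares it against the
    critical value at the requested level. Samples smaller than 8, or with
    zero variance, are flagged degenerate and routed to rank tests
    (``normal=False``).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8 or np.all(x == x[0]):
        return {"statistic": float("nan"), "normal": False, "degenerate": True}
    with warnings.catch_warnings():
        # scipy >= 1.17 announces an API change for the p-value attributes;
        # the critical-value comparison used here is unaffected
        warnings.simplefilter("ignore", FutureWarning)
        res = sps.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float)
    idx = int(np.argmin(np.abs(levels - 100.0 * alpha)))
    crit = float(res.critical_values[idx])
    return {
        "statistic": float(res.statistic),
        "normal": bool(res.statistic < crit),
        "degenerate": False,
    }


def _signed_rank_stat(diffs: np.ndarray):
    """W+ with tie-corrected normal-approximation moments; zeros dropped."""
    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        return None
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    return w_plus, mu, var, n


def signed_rank_one_sided(pre, post, direction: str) -> dict:
    """One-sided Wilcoxon signed-rank test on paired values.

    ``direction`` is the hypothesized change of ``post`` relative to ``pre``
    (``"decrease"`` or ``"increase"``). Zero differences are dropped (the
    standard Wilcoxon zero handling); the p value uses the tie-corrected
    normal approximation with continuity correction. If every difference is
    zero, ``p=1`` is returned with ``degenerate=True``.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be decrease|increase")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("unpaired input")
    res = _signed_rank_stat(post - pre)
    if res is None:
        return {"z": 0.0, "p": 1.0, "n": 0, "degenerate": True}
    w_plus, mu, var, n = res
    sd = np.sqrt(var)
    z = (w_plus - mu) / sd if sd > 0 else 0.0
    if direction == "increase":  # evidence = large W+
        p = sps.norm.sf((w_plus - mu - 0.5) / sd)
    else:  # evidence = small W+
        p = sps.norm.cdf((w_plus - mu + 0.5) / sd)
    return {"z": float(z), "p": float(min(max(p, 0.0), 1.0)), "n": int(n), "degenerate": False}


def rank_sum(a, b, alternative: str = "two-sided") -> dict:
    """Wilcoxon rank-sum (Mann-Whitney) test, tie-corrected normal approximation.

    ``alternative`` is ``"two-sided"``, ``"greater"`` (a tends larger) or
    ``"less"``. Groups must each have at least 3 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    var = n1 * n2 * (n1 + n2 + 1) / 12.0
    _, counts = np.unique(pooled, return_counts=True)
    var -= n1 * n2 * float(np.sum(counts**3 - counts)) / (
        12.0 * (n1 + n2) * (n1 + n2 - 1)
    )
    if var <= 0:
        return {"z": 0.0, "p": 1.0, "degenerate": True}
    sd = np.sqrt(var)
    z = (w - mu) / sd
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf((abs(w - mu) - 0.5) / sd)
    elif alternative == "greater":
        p = sps.norm.sf((w - mu - 0.5) / sd)
    elif alternative == "less":
        p = sps.norm.cdf((w - mu + 0.5) / sd)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return {"z": float(z), "p": float(min(max(p, 0.0), 1.0)), "degenerate": False}


def paired_t_one_sided(pre, post, direction: str) -> dict:
    """One-tailed paired t test in the hypothesized improvement direction."""
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be decrease|increase")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 4:
        raise ValueError("need at least 4 complete pairs")
    diffs = post - pre
    if np.std(diffs, ddof=1) == 0:
        return {"t": float("nan"), "p": float("nan"), "degenerate": True}
    alt = "greater" if direction == "increase" else "less"
    res = sps.ttest_rel(post, pre, alternative=alt)
    return {"t": float(res.statistic), "p": float(res.pvalue), "degenerate": False}


def cohens_d_paired(pre, post) -> float:
    """Paired Cohen d: mean(post - pre) / SD(post - pre); sign carries direction."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("unpaired input")
    diffs = post - pre
    sd = np.std(diffs, ddof=1)
    if sd == 0:
        raise ValueError("zero SD of differences; paired d undefined")
    return float(np.mean(diffs) / sd)


def mean_diff_ci(differences, level: float = 0.95):
    """t-based CI on the mean difference: ``(mean, lo, hi)``."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(d.size))
    if se == 0:
        return mean, mean, mean
    half = float(sps.t.ppf(0.5 + level / 2.0, d.size - 1)) * se
    return mean, mean - half, mean + half


def spearman_corr(x, y) -> float:
    """Spearman rank correlation (Pearson on tie-averaged ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; rank correlation undefined")
    return float(sps.spearmanr(x, y).statistic)


def bh_fdr(pvals):
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def outcome_table(samples, plans, alpha: float = 0.05, mad_k: float = 3.0):
    """Run the full outcome battery over paired samples.

    For each sample (matched to its plan row by measure name): MAD outlier
    screening of the measure's pre and post values (a pair is dropped when
    either value is beyond ``mad_k`` MADs of its timepoint's median —
    screening the discrete change scores directly would trim far too
    aggressively), Anderson-Darling normality routing,
    the one-sided test in the planned direction (signed-rank if non-normal,
    paired t if normal), paired Cohen d and the mean-difference 95% CI; then
    BH-FDR adjustment of raw p values within each (family, comparison) group.

    Parameters
    ----------
    samples : iterable of PairedSample
    plans : iterable of MeasurePlan

    Returns
    -------
    pandas.DataFrame
        One row per measure x comparison, in a fixed column order,
        independent of input row order.
    """
    plan_by_measure = {p.measure: p for p in plans}
    rows = []
    for sample in sorted(samples, key=lambda s: (s.comparison, s.measure)):
        plan = plan_by_measure.get(sample.measure)
        if plan is None:
            warnings.warn(f"no plan for measure {sample.measure!r}; skipped", stacklevel=2)
            continue
        pre = np.asarray(sample.pre, dtype=float)
        after = np.asarray(sample.after, dtype=float)
        ok = ~(np.isnan(pre) | np.isnan(after))  # listwise deletion
        pre, after = pre[ok], after[ok]
        if pre.size < 4:
            warnings.warn(f"{sample.measure}: fewer than 4 complete pairs; skipped", stacklevel=2)
            continue
        _, out_pre = remove_outliers_mad(pre, k=mad_k)
        _, out_post = remove_outliers_mad(after, k=mad_k)
        removed = np.union1d(out_pre, out_post)
        pre = np.delete(pre, removed)
        after = np.delete(after, removed)
        diffs = after - pre
        if np.std(diffs, ddof=1) == 0:
            warnings.warn(f"{sample.measure}: zero change variance; skipped", stacklevel=2)
            continue
        ad = anderson_darling_normal(diffs, alpha=alpha)
        if ad["normal"]:
            test = paired_t_one_sided(pre, after, plan.direction)
            stat_name, stat = "t", test["t"]
        else:
            test = signed_rank_one_sided(pre, after, plan.direction)
            stat_name, stat = "z", test["z"]
        mean, lo, hi = mean_diff_ci(diffs)
        rows.append(
            {
                "measure": sample.measure,
                "comparison": sample.comparison,
                "respondent": sample.respondent,
                "family": plan.family,
                "n": int(pre.size),
                "direction": plan.direction,
                "d": cohens_d_paired(pre, after),
                "mean_diff": mean,
                "ci_lo": lo,
                "ci_hi": hi,
                "stat_name": stat_name,
                "statistic": stat,
                "p_raw": test["p"],
                "normal": bool(ad["normal"]),
                "n_outliers_removed": int(removed.size),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_fdr"] = np.nan
    for _, idx in table.groupby(["family", "comparison"]).groups.items():
        table.loc[idx, "p_fdr"] = bh_fdr(table.loc[idx, "p_raw"].to_numpy())
    return table.reset_index(drop=True)


def render_report(table: pd.DataFrame) -> str:
    """Human-readable summary of an outcome table."""
    if table.empty:
        return "No analyzable measures.\n"
    lines = ["Post- vs pre-intervention outcomes", "=" * 60]
    for _, r in table.iterrows():
        lines.append(
            f"{r.measure} ({r.respondent}, pre->{r.comparison}, n={r.n}): "
            f"d={r.d:+.2f}, mean diff {r.mean_diff:+.3g} "
            f"(95% CI {r.ci_lo:.3g} to {r.ci_hi:.3g}), "
            f"{r.stat_name}={r.statistic:.2f}, p={r.p_raw:.3g}, "
            f"fdr p={r.p_fdr:.3g} [{'t test' if r.normal else 'signed rank'}, "
            f"{r.direction}]"
        )
    return "\n".join(lines) + "\n"
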