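"""Benchmark statistics for labelled variant cohorts.

A disease-associated variant with at least one fired structural alert is a
true positive; a neutral variant with at least one alert is a false positive.
Performance is summarised as TPR = TP/NP, FPR = FP/NN, their ratio, the
Matthews correlation coefficient, and Wald 95% confidence intervals
(rate ± 1.96·sqrt(rate(1−rate)/N), clamped to [0, 1]).

Per-feature significance uses a one-tailed pooled two-proportion z-test
(H1: TPR > FPR) with Benjamini–Hochberg correction across the features.
Paired predictor comparisons use McNemar's test; distribution shifts use a
one-tailed Mann–Whitney U-test.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_engine import FEATURES, USED_FEATURES, AlertReport

__all__ = ["ConfusionCounts", "RateSummary", "rates", "proportion",
           "two_proportion_test_one_tailed", "benjamini_hochberg", "mcnemar",
           "mann_whitney_one_tailed", "benchmark_run"]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def np_(self) -> int:
        return self.tp + self.fn

    @property
    def nn(self) -> int:
        return self.fp + self.tn


@dataclasses.dataclass(frozen=True)
class RateSummary:
    tpr: float
    fpr: float
    ratio: float           # TPR/FPR; inf when FPR == 0
    mcc: float
    tpr_ci: tuple[float, float]
    fpr_ci: tuple[float, float]


def _wald_ci(rate: float, n: int) -> tuple[float, float]:
    half = Z95 * math.sqrt(rate * (1.0 - rate) / n)
    return (max(0.0, rate - half), min(1.0, rate + half))


def rates(c: ConfusionCounts) -> RateSummary:
    """TPR, FPR, TPR/FPR, MCC and Wald 95% CIs from a confusion table."""
    if c.np_ == 0 or c.nn == 0:
        raise ValueError("rates need at least one positive and one negative")
    tpr = c.tp / c.np_
    fpr = c.fp / c.nn
    ratio = math.inf if fpr == 0 else tpr / fpr
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return RateSummary(tpr, fpr, ratio, mcc, _wald_ci(tpr, c.np_), _wald_ci(fpr, c.nn))


def proportion(x: int, n: int) -> float:
    """Simple proportion x/n as a percentage (printed-precision helper)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * x / n


def two_proportion_test_one_tailed(x1: int, n1: int, x2: int, n2: int) -> float:
    """Pooled-variance z-test, upper-tail p for H1: p1 > p2.

    Degenerate pooled proportion (all successes or all failures) carries no
    evidence of a difference; p = 0.5 by convention."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.5
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return float(stats.norm.sf(z))


def benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """Step-up BH adjusted p-values, order preserved, capped at 1."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return [float(p) for p in adj]


EXACT_MCNEMAR_MAX = 25  # b + c below this -> exact binomial branch


def mcnemar(b: int, c: int) -> float:
    """Two-sided McNemar test on the discordant counts.

    Exact binomial for small b + c, chi-square with continuity correction
    otherwise."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if n < EXACT_MCNEMAR_MAX:
        return float(stats.binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue)
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


def mann_whitney_one_tailed(xs: Iterable[float], ys: Iterable[float]) -> float:
    """One-tailed Mann–Whitney U (H1: first sample stochastically smaller).

    Exact null distribution for small tie-free samples (both n ≤ 12),
    tie-corrected normal approximation otherwise."""
    xs = list(xs)
    ys = list(ys)
    if not xs or not ys:
        raise ValueError("both samples must be non-empty")
    no_ties = len(set(xs) | set(ys)) == len(xs) + len(ys)
    method = "exact" if (no_ties and max(len(xs), len(ys)) <= 12) else "asymptotic"
    res = stats.mannwhitneyu(xs, ys, alternative="less", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort benchmark
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["id", "chain", "position", "wt", "mut", "label", "MAF"]


def _counts_for(fired: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    disease = labels == "disease"
    return ConfusionCounts(
        tp=int((fired & disease).sum()),
        fp=int((fired & ~disease).sum()),
        tn=int((~fired & ~disease).sum()),
        fn=int((~fired & disease).sum()),
    )


def benchmark_run(variants: pd.DataFrame,
                  reports: Sequence[AlertReport]) -> pd.DataFrame:
    """Per-feature and overall rate table over a labelled cohort.

    ``variants`` needs columns ``label`` ("disease" | "neutral") and may carry
    ``MAF`` (empty/NaN allowed); one :class:`AlertReport` per row, same order.
    Returns a table with columns feature, TP, FP, TPR, FPR, ratio, MCC, CI
    bounds, p and p_adj, the overall row last.  FPR breakdown by MAF subset
    (common MAF ≥ 0.01, rare < 0.01, unknown missing) is attached as
    ``DataFrame.attrs['maf_fpr']``.
    """
    if len(variants) != len(reports):
        raise ValueError("one report per variant required")
    labels = variants["label"].to_numpy()
    bad = set(labels) - {"disease", "neutral"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")

    rows = []
    pvals = []
    fired_matrix = {f: np.array([r.verdicts[f] == "fired" for r in reports])
                    for f in FEATURES}
    overall = np.array([r.damaging for r in reports])

    for f in FEATURES:
        c = _counts_for(fired_matrix[f], labels)
        summary = rates(c)
        p = two_proportion_test_one_tailed(c.tp, c.np_, c.fp, c.nn)
        pvals.append(p)
        rows.append({"feature": f, "TP": c.tp, "FP": c.fp, "TPR": summary.tpr,
                     "FPR": summary.fpr, "ratio": summary.ratio, "MCC": summary.mcc,
                     "TPR_lo": summary.tpr_ci[0], "TPR_hi": summary.tpr_ci[1],
                     "FPR_lo": summary.fpr_ci[0], "FPR_hi": summary.fpr_ci[1],
                     "p": p, "used": f in USED_FEATURES})
    adj = benjamini_hochberg(pvals)
    for row, pa in zip(rows, adj):
        row["p_adj"] = pa

    c = _counts_for(overall, labels)
    summary = rates(c)
    p = two_proportion_test_one_tailed(c.tp, c.np_, c.fp, c.nn)
    rows.append({"feature": "overall", "TP": c.tp, "FP": c.fp, "TPR": summary.tpr,
                 "FPR": summary.fpr, "ratio": summary.ratio, "MCC": summary.mcc,
                 "TPR_lo": summary.tpr_ci[0], "TPR_hi": summary.tpr_ci[1],
                 "FPR_lo": summary.fpr_ci[0], "FPR_hi": summary.fpr_ci[1],
                 "p": p, "p_adj": p, "used": True})

    table = pd.DataFrame(rows)

    # MAF subset FPR breakdown over neutral variants
    maf = pd.to_numeric(variants.get("MAF"), errors="coerce") \
        if "MAF" in variants.columns else pd.Series([np.nan] * len(variants))
    neutral = labels == "neutral"
    subsets = {
        "common": neutral & (maf.to_numpy() >= 0.01),
        "rare": neutral & (maf.to_numpy() < 0.01),
        "unknown": neutral & np.isnan(maf.to_numpy()),
    }
    maf_rows = []
    for name, mask in subsets.items():
        n = int(mask.sum())
        fp = int((overall & mask).sum())
        maf_rows.append({"subset": name, "n": n,
                         "FPR": fp / n if n else float("nan")})
    table.attrs["maf_fpr"] = pd.DataFrame(maf_rows)
    return table
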