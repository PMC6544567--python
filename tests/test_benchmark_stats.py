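"""Cohort statistics: rates, tests, multiple-testing correction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from structalert.benchmark_stats import (ConfusionCounts, benchmark_run,
                                         benjamini_hochberg,
                                         mann_whitney_one_tailed, mcnemar,
                                         proportion, rates,
                                         two_proportion_test_one_tailed)
from structalert.feature_engine import FEATURES, AlertReport
from structalert.structure_io import VariantSpec


def test_rates_on_reference_cohort_counts():
    """1965 disease / 2134 neutral variants with 788 and 244 alerts."""
    c = ConfusionCounts(tp=788, fp=244, tn=2134 - 244, fn=1965 - 788)
    r = rates(c)
    assert round(100 * r.tpr, 1) == 40.1
    assert round(100 * r.fpr, 1) == 11.4
    assert round(r.tpr / r.fpr, 2) == 3.51
    assert round(r.mcc, 2) == 0.33
    lo, hi = r.tpr_ci
    assert lo < r.tpr < hi and hi - r.tpr == pytest.approx(
        1.959963984540054 * math.sqrt(r.tpr * (1 - r.tpr) / 1965))


def test_perfect_prediction_rates():
    r = rates(ConfusionCounts(tp=50, fp=0, tn=70, fn=0))
    assert r.tpr == 1.0 and r.fpr == 0.0 and r.mcc == 1.0
    assert math.isinf(r.ratio)


def test_mcc_matches_direct_formula():
    rng = np.random.default_rng(0)
    for _ in range(25):
        tp, fp, tn, fn = rng.integers(1, 500, size=4)
        r = rates(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
        expected = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert r.mcc == pytest.approx(expected)


def test_rates_requires_both_classes():
    with pytest.raises(ValueError):
        rates(ConfusionCounts(tp=1, fp=0, tn=0, fn=0))


def test_proportion_printed_precision():
    assert round(proportion(87, 115), 1) == 75.7
    assert round(proportion(30, 33), 1) == 90.9


def test_two_proportion_equal_gives_half():
    assert two_proportion_test_one_tailed(10, 100, 20, 200) == pytest.approx(0.5)


def test_two_proportion_matches_statsmodels():
    from statsmodels.stats.proportion import proportions_ztest
    rng = np.random.default_rng(1)
    for _ in range(20):
        n1, n2 = rng.integers(20, 400, size=2)
        x1 = rng.integers(1, n1)
        x2 = rng.integers(1, n2)
        mine = two_proportion_test_one_tailed(int(x1), int(n1), int(x2), int(n2))
        _, ref = proportions_ztest([x1, x2], [n1, n2], alternative="larger")
        assert mine == pytest.approx(ref, abs=1e-12)


def test_two_proportion_swap_symmetry():
    p = two_proportion_test_one_tailed(30, 100, 10, 100)
    q = two_proportion_test_one_tailed(10, 100, 30, 100)
    assert p + q == pytest.approx(1.0)


def test_two_proportion_degenerate_convention():
    assert two_proportion_test_one_tailed(0, 50, 0, 60) == 0.5
    assert two_proportion_test_one_tailed(50, 50, 60, 60) == 0.5


def _bh_oracle(pvals):
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * n / rank)
        adj[idx] = running
    return adj


def test_bh_single_and_equal():
    assert benjamini_hochberg([0.2]) == [0.2]
    assert benjamini_hochberg([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        p = rng.uniform(0, 1, size=17)
        assert benjamini_hochberg(p) == pytest.approx(_bh_oracle(p))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])


def test_bh_adjusted_at_least_raw_and_monotone():
    rng = np.random.default_rng(4)
    p = rng.uniform(0, 1, size=17)
    adj = np.array(benjamini_hochberg(p))
    assert np.all(adj >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_mcnemar_symmetry_and_binomial_tail():
    assert mcnemar(7, 7) == pytest.approx(1.0)
    assert mcnemar(10, 0) == pytest.approx(2 * 0.5 ** 10)
    assert mcnemar(0, 0) == 1.0


def test_mcnemar_branches_agree_near_boundary():
    # continuity-corrected chi-square vs exact binomial at moderate counts
    exact = float(stats.binomtest(14, 30, 0.5).pvalue)
    approx = mcnemar(16, 14)
    assert approx == pytest.approx(exact, rel=0.10)


def test_mcnemar_matches_statsmodels_exact():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
    table = [[0, 8], [3, 0]]
    ref = sm_mcnemar(table, exact=True).pvalue
    assert mcnemar(8, 3) == pytest.approx(ref)


def test_mann_whitney_identical_and_identity():
    xs = list(range(10))
    assert mann_whitney_one_tailed(xs, xs) == pytest.approx(0.5, abs=0.02)
    u1 = stats.mannwhitneyu(xs, [x + 0.5 for x in xs]).statistic
    u2 = stats.mannwhitneyu([x + 0.5 for x in xs], xs).statistic
    assert u1 + u2 == len(xs) ** 2


def test_mann_whitney_exact_small_sample():
    xs = list(range(10))
    ys = [x + 100 for x in xs]
    # enumeration: all xs below all ys -> U = 0; one-tailed exact p = 1/C(20,10)
    expected = 1.0 / math.comb(20, 10)
    assert mann_whitney_one_tailed(xs, ys) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

def _fake_report(fired, variant_id=0):
    verdicts = {f: ("fired" if f in fired else "clear") for f in FEATURES}
    v = VariantSpec("A", 1, "A", "G")
    return AlertReport(v, ("A", 1, ""), verdicts, {}, set())


def test_benchmark_all_neutral_no_alerts():
    table = pd.DataFrame({
        "id": [f"v{i}" for i in range(6)],
        "label": ["neutral"] * 3 + ["disease"] * 3,
        "MAF": [0.05, 0.001, np.nan, np.nan, np.nan, np.nan],
    })
    reports = [_fake_report(set()) for _ in range(6)]
    result = benchmark_run(table, reports)
    assert (result["FPR"] == 0).all()
    maf = result.attrs["maf_fpr"]
    assert maf["n"].sum() == 3


def test_benchmark_counts_and_labels():
    table = pd.DataFrame({
        "id": ["a", "b", "c", "d"],
        "label": ["disease", "disease", "neutral", "neutral"],
        "MAF": [np.nan] * 4,
    })
    reports = [_fake_report({"clash"}), _fake_report(set()),
               _fake_report({"clash"}), _fake_report(set())]
    result = benchmark_run(table, reports).set_index("feature")
    assert result.loc["clash", "TP"] == 1 and result.loc["clash", "FP"] == 1
    assert result.loc["overall", "TPR"] == 0.5
    bad = table.assign(label=["disease", "maybe", "neutral", "neutral"])
    with pytest.raises(ValueError):
        benchmark_run(bad, reports)


def test_benchmark_permutation_invariance():
    rng = np.random.default_rng(5)
    fired = [set() if rng.random() < 0.5 else {"clash"} for _ in range(30)]
    labels = ["disease" if rng.random() < 0.5 else "neutral" for _ in range(30)]
    table = pd.DataFrame({"id": range(30), "label": labels, "MAF": np.nan})
    reports = [_fake_report(f) for f in fired]
    base = benchmark_run(table, reports).set_index("feature")["TPR"]
    perm = rng.permutation(30)
    table2 = table.iloc[perm].reset_index(drop=True)
    reports2 = [reports[i] for i in perm]
    again = benchmark_run(table2, reports2).set_index("feature")["TPR"]
    assert (base == again).all()
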