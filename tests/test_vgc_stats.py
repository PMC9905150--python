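"""Observer-study statistics: pairing, paired tests, the VGC area and its
bootstrap, logistic acceptability, drift, ICC and the assembled report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import softgrid as sg
from softgrid.vgc_stats import _auc_from_hists, _score_hist


def make_table(rows):
    """rows: (observer, role, image, arm, question, score, order)."""
    return pd.DataFrame(
        rows,
        columns=["observer_id", "role", "image_id", "arm", "question",
                 "score", "review_order"],
    )


# ---------------------------------------------------------------------------
# pair_and_average
# ---------------------------------------------------------------------------

def test_pairing_single_observation():
    t = make_table([
        ("o1", "itu_consultant", "im1", "TRUEVIEW", "Q1", 4.0, 1),
        ("o1", "itu_consultant", "im1", "OEM", "Q1", 3.0, 2),
    ])
    pset = sg.pair_and_average(t, "Q1")
    np.testing.assert_array_equal(pset.diffs, [1.0])
    assert pset.n == 1


def test_pairing_averages_duplicates():
    t = make_table([
        ("o1", "itu_consultant", "im1", "TRUEVIEW", "Q1", 4.0, 1),
        ("o1", "itu_consultant", "im1", "TRUEVIEW", "Q1", 5.0, 3),
        ("o1", "itu_consultant", "im1", "OEM", "Q1", 3.0, 2),
    ])
    pset = sg.pair_and_average(t, "Q1")
    np.testing.assert_array_equal(pset.diffs, [1.5])


def test_pairing_duplicate_path_and_na_count():
    """Same-case duplicates paired by occurrence: 6 observers x 34 pairs,
    one NA response dropped, leaves n = 203."""
    design = sg.StudyDesign(duplicates_same_cases=True, na_probability=0.0)
    table = sg.generate_scores(design, sg.EffectModel(seed=4))
    q6 = table[table["question"] == "Q6"]
    assert len(q6) == 6 * 68
    pset = sg.pair_and_average(table, "Q6", pairing="duplicates")
    assert pset.n == 204
    # knock out one TRUEVIEW response that participates in a pair
    idx = q6[(q6["arm"] == "TRUEVIEW")].index[0]
    table2 = table.copy()
    table2.loc[idx, "score"] = np.nan
    pset2 = sg.pair_and_average(table2, "Q6", pairing="duplicates")
    assert pset2.n == 203


def test_pairing_empty_raises():
    t = make_table([
        ("o1", "itu_consultant", "im1", "TRUEVIEW", "Q1", 4.0, 1),
    ])
    with pytest.raises(sg.EmptySelectionError):
        sg.pair_and_average(t, "Q2")


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

def test_paired_t_symmetric_diffs():
    assert sg.paired_t(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(1.0)


def test_wilcoxon_all_positive_exact():
    """Five positive differences: exact one-sided 1/32, two-sided 1/16."""
    p = sg.wilcoxon_signed_rank(np.ones(5))
    assert p == pytest.approx(0.0625)


def test_wilcoxon_all_zero_degenerate():
    with pytest.raises(sg.DegenerateDataError):
        sg.wilcoxon_signed_rank(np.zeros(6))


def test_wilcoxon_matches_sign_flip_enumeration():
    """Exact two-sided p equals direct enumeration of all sign assignments
    (tie-free magnitudes, where every two-sided convention coincides)."""
    d = np.array([1.0, 2.0, 3.0, -4.0, 5.0, 7.0])
    p = sg.wilcoxon_signed_rank(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    dist = []
    for m in range(2**n):
        signs = [(m >> i) & 1 for i in range(n)]
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.asarray(dist)
    mu = ranks.sum() / 2
    p_exact = np.mean(np.abs(dist - mu) >= abs(w_obs - mu) - 1e-12)
    assert p == pytest.approx(p_exact, abs=1e-12)


# ---------------------------------------------------------------------------
# VGC AUC
# ---------------------------------------------------------------------------

def bruteforce_auc(oem, tv):
    """Independent cross-pair oracle: mean of win + half-tie indicators."""
    oem = np.asarray(oem, float)
    tv = np.asarray(tv, float)
    wins = (tv[:, None] > oem[None, :]).sum()
    ties = (tv[:, None] == oem[None, :]).sum()
    return (wins + 0.5 * ties) / (len(tv) * len(oem))


def test_auc_identical_multisets():
    _, auc = sg.vgc_auc([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert auc == pytest.approx(0.5)


def test_auc_complete_separation():
    _, auc = sg.vgc_auc([1, 1, 1], [5, 5, 5, 5])
    assert auc == pytest.approx(1.0)


def test_auc_worked_example_cross_pairs():
    """oem={1,2,2,3}, tv={2,3,3,4}: 11 wins and 4 ties over 16 cross-pairs,
    so auc = 13/16 (frozen from the brute-force oracle)."""
    oem, tv = [1, 2, 2, 3], [2, 3, 3, 4]
    assert bruteforce_auc(oem, tv) == pytest.approx(0.8125)
    _, auc = sg.vgc_auc(oem, tv)
    assert auc == pytest.approx(0.8125)


def test_auc_equals_rank_statistic_on_random_multisets():
    rng = np.random.default_rng(12)
    for _ in range(100):
        oem = rng.integers(1, 6, rng.integers(2, 40))
        tv = rng.integers(1, 6, rng.integers(2, 40))
        _, auc = sg.vgc_auc(oem, tv)
        assert auc == pytest.approx(bruteforce_auc(oem, tv), abs=1e-12)


def test_auc_antisymmetry():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a = rng.integers(1, 6, 25)
        b = rng.integers(1, 6, 25)
        _, ab = sg.vgc_auc(a, b)
        _, ba = sg.vgc_auc(b, a)
        assert ab + ba == pytest.approx(1.0, abs=1e-12)


def test_auc_curve_anchored_and_monotone():
    curve, _ = sg.vgc_auc([1, 2, 3], [3, 4, 5])
    assert tuple(curve[0]) == (0.0, 0.0)
    assert tuple(curve[-1]) == (1.0, 1.0)
    assert np.all(np.diff(curve[:, 0]) >= 0)
    assert np.all(np.diff(curve[:, 1]) >= 0)


def test_auc_empty_multiset_rejected():
    with pytest.raises(ValueError):
        sg.vgc_auc([], [1, 2])


def test_hist_supports_half_scores():
    h = _score_hist([1.0, 1.5, 5.0])
    assert h.sum() == 3
    assert _auc_from_hists(_score_hist([1.0]), _score_hist([1.5])) == 1.0


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def _two_arm_table(scores_oem, scores_tv, n_obs=1):
    rows = []
    for o in range(n_obs):
        for i, s in enumerate(scores_oem):
            rows.append((f"o{o}", "itu_consultant", f"im{i}", "OEM", "Q1", s, 2 * i + 1))
        for i, s in enumerate(scores_tv):
            rows.append((f"o{o}", "itu_consultant", f"im{i}", "TRUEVIEW", "Q1", s, 2 * i + 2))
    return make_table(rows)


def test_bootstrap_degenerate_scores_pin_half():
    t = _two_arm_table([3, 3, 3, 3], [3, 3, 3, 3])
    assert sg.bootstrap_ci(t, "Q1", n_boot=200, seed=1) == (0.5, 0.5)


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(8)
    t = _two_arm_table(rng.integers(1, 6, 20), rng.integers(1, 6, 20))
    a = sg.bootstrap_ci(t, "Q1", n_boot=500, seed=7)
    b = sg.bootstrap_ci(t, "Q1", n_boot=500, seed=7)
    assert a == b
    c = sg.bootstrap_ci(t, "Q1", n_boot=500, seed=8)
    assert a != c


def test_bootstrap_brackets_point_estimate():
    rng = np.random.default_rng(3)
    t = _two_arm_table(rng.integers(1, 5, 30), rng.integers(2, 6, 30), n_obs=3)
    sel = t.dropna(subset=["score"])
    _, auc = sg.vgc_auc(
        sel[sel.arm == "OEM"]["score"], sel[sel.arm == "TRUEVIEW"]["score"]
    )
    lo, hi = sg.bootstrap_ci(t, "Q1", n_boot=2000, seed=2)
    assert lo <= auc <= hi


# ---------------------------------------------------------------------------
# acceptability
# ---------------------------------------------------------------------------

def _acceptability_table(a, b, c, d):
    """a/b: TRUEVIEW acceptable/not; c/d: OEM acceptable/not."""
    rows = []
    k = 0
    for arm, acc, n in (("TRUEVIEW", 5, a), ("TRUEVIEW", 2, b),
                        ("OEM", 5, c), ("OEM", 2, d)):
        for _ in range(n):
            rows.append(("o1", "itu_consultant", f"im{k}", arm, "Q1", acc, k + 1))
            k += 1
    return make_table(rows)


def test_or_balanced_is_one():
    t = _acceptability_table(30, 30, 30, 30)
    r = sg.acceptability_or(t, "Q1")
    assert r.odds_ratio == pytest.approx(1.0, abs=1e-9)


def test_or_closed_form_2x2():
    r = sg.acceptability_or(_acceptability_table(40, 20, 20, 40), "Q1")
    assert r.odds_ratio == pytest.approx(4.0, rel=1e-6)
    assert r.ci95[0] < 4.0 < r.ci95[1]


def test_or_equals_cross_product_on_random_fixture():
    rng = np.random.default_rng(17)
    a, b, c, d = rng.integers(5, 60, 4)
    r = sg.acceptability_or(_acceptability_table(a, b, c, d), "Q1")
    assert r.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)


def test_or_non_estimable_flag():
    r = sg.acceptability_or(_acceptability_table(30, 0, 20, 20), "Q1")
    assert not r.estimable


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------

def test_drift_strictly_increasing_scores():
    rows = [("o1", "itu_consultant", f"im{i}", "OEM", "Q1", s, i + 1)
            for i, s in enumerate([1, 2, 3, 4, 5])]
    d = sg.spearman_drift(make_table(rows), "Q1")
    assert d.rho == pytest.approx(1.0)


def test_drift_constant_scores_degenerate():
    rows = [("o1", "itu_consultant", f"im{i}", "OEM", "Q1", 3, i + 1)
            for i in range(6)]
    d = sg.spearman_drift(make_table(rows), "Q1")
    assert d.degenerate and np.isnan(d.rho)


def test_drift_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(23)
    rows = []
    for o in range(2):
        orders = rng.permutation(10) + 1
        for i in range(10):
            rows.append((f"o{o}", "itu_registrar", f"im{i}", "OEM", "Q1",
                         int(rng.integers(1, 6)), int(orders[i])))
    t = make_table(rows)
    d = sg.spearman_drift(t, "Q1")
    # scalar oracle: midranks within observer, pooled Pearson
    xs, ys = [], []
    for o in ("o0", "o1"):
        grp = t[t.observer_id == o].sort_index()
        xs.extend(stats.rankdata(grp["score"]))
        ys.extend(stats.rankdata(grp["review_order"]))
    xs, ys = np.asarray(xs), np.asarray(ys)
    num = ((xs - xs.mean()) * (ys - ys.mean())).sum()
    den = np.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
    assert d.rho == pytest.approx(num / den, abs=1e-12)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_identical_raters_is_one():
    col = np.array([1.0, 2, 3, 4, 5, 3])
    m = np.column_stack([col, col, col])
    r = sg.icc_c1(m)
    assert r.icc == pytest.approx(1.0)


def test_icc_independent_noise_near_zero():
    rng = np.random.default_rng(31)
    m = rng.normal(size=(200, 6))
    r = sg.icc_c1(m)
    assert abs(r.icc) < 0.1


def test_icc_matches_scalar_anova_oracle():
    m = np.array([
        [4.0, 5.0, 4.0],
        [2.0, 3.0, 2.0],
        [5.0, 5.0, 4.0],
        [1.0, 2.0, 1.0],
        [3.0, 4.0, 4.0],
        [2.0, 2.0, 3.0],
    ])
    r = sg.icc_c1(m)
    n, k = m.shape
    grand = m.mean()
    ms_rows = k * sum((m[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    ms_cols = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    ss_err = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    ms_err = ss_err / ((n - 1) * (k - 1))
    expect = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    assert r.icc == pytest.approx(expect, abs=1e-10)


def test_icc_agrees_with_pingouin():
    """Independent implementation cross-check (ICC3 = two-way mixed/random
    consistency, single measure)."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(44)
    truth = rng.normal(size=30)
    m = truth[:, None] + rng.normal(0, 0.5, size=(30, 4))
    r = sg.icc_c1(m)
    df = pd.DataFrame(m, columns=list("abcd")).reset_index().melt(id_vars="index")
    icc = pingouin.intraclass_corr(
        data=df, targets="index", raters="variable", ratings="value"
    )
    ref = icc.loc[icc["Type"] == "ICC(C,1)", "ICC"].iloc[0]
    assert r.icc == pytest.approx(ref, abs=1e-9)


def test_icc_listwise_deletion_counted():
    m = np.array([[1.0, 2.0], [2.0, np.nan], [3.0, 4.0], [4.0, 5.0]])
    r = sg.icc_c1(m)
    assert r.n_dropped == 1 and r.n_rows == 3


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def test_full_report_empty_table_structured():
    rep = sg.full_report(pd.DataFrame(columns=list(sg.synth_io.SCORE_COLUMNS)))
    assert set(rep) == {"vgc", "acceptability", "drift", "consistency"}
    for df in rep.values():
        assert df.empty


def test_full_report_row_counts(null_scores):
    rep = sg.full_report(null_scores, n_boot=200, seed=0)
    assert len(rep["vgc"]) == 6 * 5
    assert len(rep["drift"]) == 6 * 3
    assert len(rep["consistency"]) == 6 * 3
    assert len(rep["acceptability"]) == 6
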