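"""Visual-grading observer-study statistics.

Paired ordinal image-quality scores (1-5 agreement scale, two processing
arms) are analyzed per scoring question and reviewer subgroup with:

* mean paired difference with a paired t-test and a Wilcoxon signed-rank test;
* the visual grading characteristic (VGC) curve and its area AUC_VGC — the
  ROC analogue for paired ordinal quality ratings, 0.5 meaning no preference
  — with a nonparametric bootstrap confidence interval (resampling images);
* a logistic model of diagnostic acceptability (score >= 4) giving an odds
  ratio for the treatment arm;
* Spearman correlation of score against review order (temporal drift); and
* the two-way random, consistency, single-measure intraclass correlation
  ICC(C,1) for inter-reviewer reliability.

A question/subgroup is flagged as showing *strong evidence* of a preference
only when the t-test, the Wilcoxon test, and the AUC confidence interval all
indicate the same direction at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ARMS",
    "QUESTIONS",
    "ROLES",
    "SUBGROUPS",
    "DegenerateDataError",
    "EmptySelectionError",
    "PairedDiffSet",
    "VGCResult",
    "AcceptabilityResult",
    "DriftResult",
    "ConsistencyResult",
    "pair_and_average",
    "paired_t",
    "wilcoxon_signed_rank",
    "vgc_curve",
    "vgc_auc",
    "bootstrap_ci",
    "acceptability_or",
    "spearman_drift",
    "icc_c1",
    "full_report",
]

ARMS = ("OEM", "TRUEVIEW")
QUESTIONS = ("Q1", "Q2", "Q3", "Q4", "Q5", "Q6")
ROLES = (
    "radiology_consultant",
    "radiology_registrar",
    "itu_consultant",
    "itu_registrar",
)
# subgroup name -> predicate on role
SUBGROUPS: dict[str, callable] = {
    "all_reviewers": lambda r: True,
    "consultants": lambda r: r.endswith("consultant"),
    "registrars": lambda r: r.endswith("registrar"),
    "radiologists": lambda r: r.startswith("radiology"),
    "itu_doctors": lambda r: r.startswith("itu"),
}


class DegenerateDataError(ValueError):
    """The statistic is undefined on this input (no variation/information)."""


class EmptySelectionError(ValueError):
    """A filter produced no usable pairs; raised rather than returning 0."""


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

@dataclass
class PairedDiffSet:
    """Per-(observer, image) arm differences for one question/subgroup."""

    diffs: np.ndarray
    n: int
    n_dropped_na: int = 0

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)
        if np.any(np.abs(self.diffs) > 4 + 1e-9):
            raise ValueError("score differences must lie in [-4, 4]")


def _subset(table: pd.DataFrame, question: str, subgroup: str) -> pd.DataFrame:
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    pred = SUBGROUPS[subgroup]
    sel = table[(table["question"] == question) & table["role"].map(pred)]
    return sel


def pair_and_average(
    table: pd.DataFrame,
    question: str,
    subgroup: str = "all_reviewers",
    pairing: str = "average",
) -> PairedDiffSet:
    """Form per-(observer, image) treatment-minus-comparator differences.

    ``pairing="average"`` (default) averages duplicate reviews of an image
    within an arm before differencing, giving one pair per (observer, image).
    ``pairing="duplicates"`` instead pairs the i-th review in one arm with the
    i-th review in the other (in review order), so an image duplicated in both
    arms contributes two pairs.  Pairs with a missing score on either side are
    dropped and counted.
    """
    sel = _subset(table, question, subgroup)
    if sel.empty:
        raise EmptySelectionError(f"no scores for {question}/{subgroup}")
    diffs: list[float] = []
    n_na = 0
    for (_, _), grp in sel.groupby(["observer_id", "image_id"], sort=True):
        tv = grp.loc[grp["arm"] == "TRUEVIEW"].sort_values("review_order")["score"]
        oem = grp.loc[grp["arm"] == "OEM"].sort_values("review_order")["score"]
        if tv.empty or oem.empty:
            continue
        if pairing == "average":
            t, o = tv.dropna(), oem.dropna()
            if t.empty or o.empty:
                n_na += 1
                continue
            n_na += int(tv.isna().sum() + oem.isna().sum() > 0) * 0  # averaged over
            diffs.append(float(t.mean() - o.mean()))
        elif pairing == "duplicates":
            k = min(len(tv), len(oem))
            for tval, oval in zip(tv.iloc[:k], oem.iloc[:k]):
                if pd.isna(tval) or pd.isna(oval):
                    n_na += 1
                    continue
                diffs.append(float(tval - oval))
        else:
            raise ValueError(f"unknown pairing {pairing!r}")
    if not diffs:
        raise EmptySelectionError(f"no usable pairs for {question}/{subgroup}")
    return PairedDiffSet(np.asarray(diffs), n=len(diffs), n_dropped_na=n_na)


# ---------------------------------------------------------------------------
# Paired tests
# ---------------------------------------------------------------------------

def paired_t(diffs: np.ndarray) -> float:
    """Two-sided paired t-test p-value for mean difference = 0."""
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValueError("paired t-test needs n >= 2")
    return float(stats.ttest_1samp(d, 0.0).pvalue)


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value, zeros discarded.

    Exact sign-permutation null for n <= ``exact_max_n`` nonzero differences,
    otherwise the normal approximation with midrank tie correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise DegenerateDataError("all differences are zero")
    method = "exact" if len(d) <= exact_max_n else "approx"
    return float(
        stats.wilcoxon(d, zero_method="wilcox", method=method).pvalue
    )


# ---------------------------------------------------------------------------
# VGC curve and area
# ---------------------------------------------------------------------------

def _score_hist(scores: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("empty score multiset")
    if np.any((arr < 1) | (arr > 5)):
        raise ValueError("scores must lie in 1..5")
    # duplicate-averaged scores may be half-integers; bin at 0.5 resolution
    idx = np.rint((arr - 1.0) * 2).astype(int)
    if np.any(np.abs((arr - 1.0) * 2 - idx) > 1e-9):
        raise ValueError("scores must be multiples of 0.5")
    return np.bincount(idx, minlength=9).astype(float)


def _auc_from_hists(h_oem: np.ndarray, h_tv: np.ndarray) -> float:
    """Tie-corrected rank statistic from 0.5-resolution score histograms."""
    n_o, n_t = h_oem.sum(), h_tv.sum()
    # P(tv > oem) + 0.5 P(tv == oem)
    cum_o = np.cumsum(h_oem)  # counts of oem <= level
    below = np.concatenate([[0.0], cum_o[:-1]])
    wins = float((h_tv * below).sum())
    ties = float((h_tv * h_oem).sum())
    return (wins + 0.5 * ties) / (n_t * n_o)


def vgc_curve(
    scores_oem: Iterable[float], scores_tv: Iterable[float]
) -> np.ndarray:
    """VGC operating points: (P(oem >= s), P(tv >= s)) over descending
    thresholds, anchored at (0,0) and (1,1).  Returns an (m, 2) array."""
    h_o = _score_hist(scores_oem)
    h_t = _score_hist(scores_tv)
    # survival at thresholds from the top level downwards
    x = np.cumsum(h_o[::-1]) / h_o.sum()
    y = np.cumsum(h_t[::-1]) / h_t.sum()
    pts = np.column_stack([np.concatenate([[0.0], x]), np.concatenate([[0.0], y])])
    if pts[-1, 0] != 1.0 or pts[-1, 1] != 1.0:
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def vgc_auc(
    scores_oem: Iterable[float], scores_tv: Iterable[float]
) -> tuple[np.ndarray, float]:
    """VGC curve and its trapezoidal area.

    The trapezoidal area of the anchored survival-vs-survival curve equals
    the tie-corrected cross-pair rank statistic
    (#[tv > oem] + 0.5 #[tv == oem]) / (n_tv * n_oem).
    """
    curve = vgc_curve(scores_oem, scores_tv)
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, auc


def _arm_scores(sel: pd.DataFrame, arm: str) -> np.ndarray:
    s = sel.loc[sel["arm"] == arm, "score"].dropna()
    return s.to_numpy(dtype=float)


def bootstrap_ci(
    table: pd.DataFrame,
    question: str,
    subgroup: str = "all_reviewers",
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for AUC_VGC, resampling images (cases).

    Image identities are resampled with replacement; each replicate pools the
    resampled images' scores (across observers within the subgroup) per arm
    and recomputes the AUC from score histograms.  Deterministic given seed.
    """
    sel = _subset(table, question, subgroup).dropna(subset=["score"])
    if sel.empty:
        raise EmptySelectionError(f"no scores for {question}/{subgroup}")
    images = np.asarray(sorted(sel["image_id"].unique()))
    if len(images) < 2:
        raise ValueError("bootstrap needs >= 2 distinct images")
    # per-image per-arm score histograms at 0.5 resolution
    h_oem = np.zeros((len(images), 9))
    h_tv = np.zeros((len(images), 9))
    pos = {img: i for i, img in enumerate(images)}
    for (img, arm), grp in sel.groupby(["image_id", "arm"], sort=False):
        h = _score_hist(grp["score"])
        (h_oem if arm == "OEM" else h_tv)[pos[img]] += h

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(images), size=(n_boot, len(images)))
    rep_o = h_oem[idx].sum(axis=1)  # (B, 9)
    rep_t = h_tv[idx].sum(axis=1)
    n_o = rep_o.sum(axis=1)
    n_t = rep_t.sum(axis=1)
    ok = (n_o > 0) & (n_t > 0)
    cum_o = np.cumsum(rep_o, axis=1)
    below = np.concatenate([np.zeros((n_boot, 1)), cum_o[:, :-1]], axis=1)
    wins = (rep_t * below).sum(axis=1)
    ties = (rep_t * rep_o).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        aucs = (wins + 0.5 * ties) / (n_t * n_o)
    aucs = aucs[ok]
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Acceptability, drift, consistency
# ---------------------------------------------------------------------------

@dataclass
class AcceptabilityResult:
    question: str
    odds_ratio: float
    ci95: tuple[float, float]
    estimable: bool = True


def acceptability_or(
    table: pd.DataFrame, question: str, subgroup: str = "all_reviewers"
) -> AcceptabilityResult:
    """Odds ratio that a region scores as diagnostically acceptable (>= 4).

    Logistic regression of [score >= 4] on an intercept and a treatment-arm
    indicator; the exponentiated arm coefficient with its Wald 95% CI.  With
    no other covariates this equals the 2x2 cross-product ratio.
    """
    sel = _subset(table, question, subgroup).dropna(subset=["score"])
    if sel.empty:
        raise EmptySelectionError(f"no scores for {question}/{subgroup}")
    y = (sel["score"] >= 4).to_numpy(dtype=float)
    arm = (sel["arm"] == "TRUEVIEW").to_numpy(dtype=float)
    for a in (0.0, 1.0):
        ya = y[arm == a]
        if len(ya) == 0 or ya.min() == ya.max():
            return AcceptabilityResult(question, np.nan, (np.nan, np.nan), False)
    x = sm.add_constant(arm)
    fit = sm.Logit(y, x).fit(disp=0)
    coef = fit.params[1]
    se = fit.bse[1]
    return AcceptabilityResult(
        question=question,
        odds_ratio=float(np.exp(coef)),
        ci95=(float(np.exp(coef - 1.959964 * se)), float(np.exp(coef + 1.959964 * se))),
    )


@dataclass
class DriftResult:
    question: str
    stratum: str
    rho: float
    p: float
    degenerate: bool = False


def spearman_drift(
    table: pd.DataFrame, question: str, stratum: str = "all"
) -> DriftResult:
    """Spearman correlation of score against review order (temporal drift).

    Ranks are computed within each observer (midranks for ties) and pooled
    before the correlation, so between-observer level differences do not
    masquerade as drift.  ``stratum`` restricts to one arm or pools both.
    """
    sel = table[table["question"] == question].dropna(subset=["score"])
    if stratum in ("TRUEVIEW", "OEM"):
        sel = sel[sel["arm"] == stratum]
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")
    if sel.empty:
        raise EmptySelectionError(f"no scores for {question}/{stratum}")
    rs, ro = [], []
    for _, grp in sel.groupby("observer_id", sort=True):
        if len(grp) < 2:
            continue
        rs.append(stats.rankdata(grp["score"].to_numpy(float)))
        ro.append(stats.rankdata(grp["review_order"].to_numpy(float)))
    if not rs:
        raise EmptySelectionError("no observer with >= 2 reviews")
    x = np.concatenate(rs)
    o = np.concatenate(ro)
    if np.ptp(x) == 0 or np.ptp(o) == 0:
        return DriftResult(question, stratum, np.nan, np.nan, degenerate=True)
    rho = float(np.corrcoef(x, o)[0, 1])
    n = len(x)
    # t approximation for the null rho = 0
    t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 1e-15))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return DriftResult(question, stratum, rho, p)


@dataclass
class ConsistencyResult:
    question: str
    stratum: str
    icc: float
    ci95: tuple[float, float]
    n_rows: int
    n_dropped: int = 0


def icc_c1(
    matrix: np.ndarray,
    question: str = "",
    stratum: str = "",
    alpha: float = 0.05,
) -> ConsistencyResult:
    """ICC(C,1): two-way random, consistency, single-measure reliability.

    From two-way ANOVA mean squares of an images x observers matrix:
    ICC = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err), with the standard
    F-distribution confidence interval.  Rows containing missing values are
    dropped (listwise deletion) and counted.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (images x observers)")
    keep = ~np.any(np.isnan(x), axis=1)
    n_dropped = int(np.count_nonzero(~keep))
    x = x[keep]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 images and >= 2 observers after deletion")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_tot = float(((x - grand) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_err <= 0:  # identical raters up to row effects
        icc = 1.0
        ci = (1.0, 1.0)
    else:
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        f_obs = ms_rows / ms_err
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci = ((f_l - 1) / (f_l + k - 1), (f_u - 1) / (f_u + k - 1))
    return ConsistencyResult(question, stratum, float(icc), ci, n, n_dropped)


def _consistency_matrix(
    table: pd.DataFrame, question: str, stratum: str
) -> np.ndarray:
    """Units x observers score matrix; units are (image, arm) reviews, with
    duplicate reviews averaged per cell.  NaN marks missing cells."""
    sel = table[table["question"] == question]
    if stratum in ("TRUEVIEW", "OEM"):
        sel = sel[sel["arm"] == stratum]
    pivot = sel.pivot_table(
        index=["image_id", "arm"],
        columns="observer_id",
        values="score",
        aggfunc="mean",
    )
    return pivot.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class VGCResult:
    """One row of the per-question, per-subgroup summary table."""

    question: str
    subgroup: str
    md: float
    sd: float
    n: int
    p_t: float
    p_w: float
    auc_vgc: float
    ci95: tuple[float, float]
    strong_evidence: bool = False


def _vgc_row(
    table: pd.DataFrame,
    question: str,
    subgroup: str,
    n_boot: int,
    seed: int,
    pairing: str,
) -> VGCResult:
    pset = pair_and_average(table, question, subgroup, pairing=pairing)
    md = float(pset.diffs.mean())
    sd = float(pset.diffs.std(ddof=1)) if pset.n > 1 else 0.0
    p_t = paired_t(pset.diffs) if pset.n >= 2 else np.nan
    try:
        p_w = wilcoxon_signed_rank(pset.diffs)
    except DegenerateDataError:
        p_w = np.nan
    sel = _subset(table, question, subgroup).dropna(subset=["score"])
    _, auc = vgc_auc(_arm_scores(sel, "OEM"), _arm_scores(sel, "TRUEVIEW"))
    ci = bootstrap_ci(table, question, subgroup, n_boot=n_boot, seed=seed)
    direction = np.sign(auc - 0.5)
    strong = bool(
        np.isfinite(p_t)
        and np.isfinite(p_w)
        and p_t < 0.05
        and p_w < 0.05
        and direction != 0
        and np.sign(md) == direction
        and (ci[0] > 0.5 if direction > 0 else ci[1] < 0.5)
    )
    return VGCResult(question, subgroup, md, sd, pset.n, p_t, p_w, auc, ci, strong)


def full_report(
    table: pd.DataFrame,
    subgroups: Sequence[str] = tuple(SUBGROUPS),
    n_boot: int = 5000,
    seed: int = 0,
    pairing: str = "average",
) -> dict[str, pd.DataFrame]:
    """Per-question, per-subgroup summary tables.

    Returns ``{"vgc": ..., "acceptability": ..., "drift": ..., "consistency":
    ...}``; questions/subgroups with no usable data yield no row, and an empty
    input yields structured empty tables.
    """
    vgc_rows, acc_rows, drift_rows, cons_rows = [], [], [], []
    questions = [q for q in QUESTIONS if not table.empty and q in set(table["question"])]
    for qi, q in enumerate(questions):
        for sg in subgroups:
            try:
                r = _vgc_row(table, q, sg, n_boot, seed + 1000 * qi, pairing)
            except (EmptySelectionError, ValueError):
                continue
            vgc_rows.append(
                dict(
                    question=q, subgroup=sg, md=r.md, sd=r.sd, n=r.n,
                    p_t=r.p_t, p_w=r.p_w, auc_vgc=r.auc_vgc,
                    ci_lo=r.ci95[0], ci_hi=r.ci95[1],
                    strong_evidence=r.strong_evidence,
                )
            )
        try:
            a = acceptability_or(table, q)
            acc_rows.append(
                dict(
                    question=q, odds_ratio=a.odds_ratio,
                    ci_lo=a.ci95[0], ci_hi=a.ci95[1], estimable=a.estimable,
                )
            )
        except EmptySelectionError:
            pass
        for stratum in ("all", "TRUEVIEW", "OEM"):
            try:
                d = spearman_drift(table, q, stratum)
                drift_rows.append(
                    dict(question=q, stratum=stratum, rho=d.rho, p=d.p,
                         degenerate=d.degenerate)
                )
            except EmptySelectionError:
                pass
            try:
                mat = _consistency_matrix(table, q, stratum)
                c = icc_c1(mat, q, stratum)
                cons_rows.append(
                    dict(question=q, stratum=stratum, icc=c.icc,
                         ci_lo=c.ci95[0], ci_hi=c.ci95[1],
                         n_rows=c.n_rows, n_dropped=c.n_dropped)
                )
            except ValueError:
                pass
    return {
        "vgc": pd.DataFrame(
            vgc_rows,
            columns=["question", "subgroup", "md", "sd", "n", "p_t", "p_w",
                     "auc_vgc", "ci_lo", "ci_hi", "strong_evidence"],
        ),
        "acceptability": pd.DataFrame(
            acc_rows,
            columns=["question", "odds_ratio", "ci_lo", "ci_hi", "estimable"],
        ),
        "drift": pd.DataFrame(
            drift_rows, columns=["question", "stratum", "rho", "p", "degenerate"]
        ),
        "consistency": pd.DataFrame(
            cons_rows,
            columns=["question", "stratum", "icc", "ci_lo", "ci_hi",
                     "n_rows", "n_dropped"],
        ),
    }
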