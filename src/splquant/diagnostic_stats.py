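"""Diagnostic statistics for two-group biomarker studies.

Implements the standard reporting chain for imaging-biomarker papers:

* two-reader agreement via the intraclass correlation coefficient ICC(2,1)
  (two-way random effects, absolute agreement, single measurement), with the
  conventional category labels (>=0.75 excellent, 0.60-0.75 good, 0.40-0.60
  fair, <0.40 poor);
* normality-gated two-group comparison: Shapiro-Wilk on each group, Student's
  t when both pass, Mann-Whitney U otherwise (all tests two-sided);
* empirical ROC analysis with a DeLong-variance 95% CI on the AUC and the
  Youden-index (sens + spec - 1) optimal cutoff;
* the DeLong test for comparing two correlated (same-subject) AUCs;
* a two-stage logistic screen: univariate odds ratios per candidate, those
  with p < 0.1 entering one multivariate model whose predicted probability
  serves as a combined diagnostic score.

No multiple-testing correction is applied anywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ICCResult",
    "GroupComparisonResult",
    "ROCResult",
    "DeLongResult",
    "LogisticScreenResult",
    "icc_two_reader",
    "icc_category",
    "compare_groups",
    "roc_analysis",
    "delong_test",
    "logistic_screen",
]


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc_category(icc: float) -> str:
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


@dataclass
class ICCResult:
    icc: float
    category: Literal["excellent", "good", "fair", "poor"]


def icc_two_reader(
    values_reader1: Sequence[float],
    values_reader2: Sequence[float],
    model: Literal["absolute_agreement", "consistency"] = "absolute_agreement",
) -> ICCResult:
    """Inter-reader reliability of paired measurements.

    Default is ICC(2,1): two-way random effects, absolute agreement, single
    measurement — both readers rate every lesion and the question is whether
    their raw values are interchangeable, so systematic offsets are
    penalised.  ``model='consistency'`` gives ICC(3,1) instead.
    """
    x = np.asarray(values_reader1, dtype=float)
    y = np.asarray(values_reader2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("readers must supply equal-length 1D measurements")
    n = x.size
    if n < 3:
        raise ValueError("ICC needs at least 3 paired measurements")

    data = np.column_stack([x, y])  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if model == "absolute_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC model: {model!r}")
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    icc = float((msr - mse) / denom)
    return ICCResult(icc=icc, category=icc_category(icc))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    group_names: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    test_used: Literal["student_t", "welch_t", "mann_whitney_u"]
    statistic: float
    p_two_sided: float
    shapiro_p: tuple[float, float] | None = None


def compare_groups(
    values: Sequence[float],
    labels: Sequence,
    normality_alpha: float = 0.05,
    force_test: Literal["student_t", "mann_whitney_u"] | None = None,
    welch: bool = False,
) -> GroupComparisonResult:
    """Two-group location comparison with a per-group Shapiro-Wilk gate.

    Both groups normal at ``normality_alpha`` -> Student's t (pooled variance
    by default, Welch with ``welch=True``); otherwise Mann-Whitney U.  The
    branch taken is recorded; ``force_test`` bypasses the gate (useful when
    reproducing a published per-parameter test assignment).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise ValueError("values and labels must align")
    groups = pd.unique(lab)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {len(groups)}")
    a, b = v[lab == groups[0]], v[lab == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(v) == 0:
        raise ValueError("constant data: comparison undefined")

    shapiro_p = None
    if force_test is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pa = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
            pb = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
        shapiro_p = (float(pa), float(pb))
        branch = "t" if (pa > normality_alpha and pb > normality_alpha) else "u"
    else:
        branch = "t" if force_test == "student_t" else "u"

    if branch == "t":
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test_used = "welch_t" if welch else "student_t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test_used = "mann_whitney_u"

    return GroupComparisonResult(
        group_names=(str(groups[0]), str(groups[1])),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        ns=(len(a), len(b)),
        test_used=test_used,
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        shapiro_p=shapiro_p,
    )


# ---------------------------------------------------------------------------
# ROC / Youden / DeLong
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values via midranks (ties count half)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n  # P(score_pos > score_neg) per positive
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    youden: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: Literal["higher", "lower"]
    auc_se: float

    def summary(self) -> str:
        rule = ">" if self.direction == "higher" else "<="
        return (
            f"AUC {self.auc:.4f} (95% CI {self.ci95[0]:.4f}-{self.ci95[1]:.4f}); "
            f"Youden {self.youden:.4f} at cutoff {self.cutoff:.4g} "
            f"(positive if marker {rule} cutoff); "
            f"sensitivity {self.sensitivity:.4f}, specificity {self.specificity:.4f}"
        )


def _binary_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    if set(classes.tolist()) == {0, 1}:
        return y.astype(int)
    # positive class = lexicographically larger label, recorded implicitly
    return (y == classes[1]).astype(int)


def roc_analysis(scores: Sequence[float], labels: Sequence) -> ROCResult:
    """Empirical ROC with DeLong CI and the Youden-index optimal cutoff.

    The AUC is the Mann-Whitney probability with ties counted half.  Marker
    direction is auto-chosen so AUC >= 0.5 and reported: 'higher' means
    larger scores indicate the positive class.  The cutoff maximises
    sensitivity + specificity - 1 over the observed score values; Youden ties
    are broken toward the cutoff with higher specificity (then the more
    extreme cutoff) so reporting is deterministic.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")

    auc_hi, _, _ = _placements(s, y)
    direction: Literal["higher", "lower"] = "higher" if auc_hi >= 0.5 else "lower"
    work = s if direction == "higher" else -s

    auc, v10, v01 = _placements(work, y)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - 1.959964 * se), min(1.0, auc + 1.959964 * se))

    # Youden scan: positive if working score >= cutoff, over observed values
    pos_sorted = np.sort(work[y == 1])
    neg_sorted = np.sort(work[y == 0])
    cuts = np.unique(work)
    sens = 1.0 - np.searchsorted(pos_sorted, cuts, side="left") / m
    spec = np.searchsorted(neg_sorted, cuts, side="left") / n
    youden = sens + spec - 1.0
    best = youden.max()
    tied = np.flatnonzero(youden >= best - 1e-12)
    tied = tied[np.argsort(spec[tied], kind="stable")]
    pick = tied[-1]  # highest specificity; ties resolve to the larger cutoff
    cutoff_work = float(cuts[pick])
    cutoff = cutoff_work if direction == "higher" else -cutoff_work

    return ROCResult(
        auc=auc,
        ci95=ci,
        youden=float(youden[pick]),
        cutoff=cutoff,
        sensitivity=float(sens[pick]),
        specificity=float(spec[pick]),
        direction=direction,
        auc_se=se,
    )


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    auc_diff: float
    z: float
    p: float
    degenerate: bool = False


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence
) -> DeLongResult:
    """DeLong comparison of two correlated AUCs measured on the same subjects.

    The covariance of the paired AUC estimates is built from the placement
    values of each marker; the AUC difference is then tested with a two-sided
    normal test.  A degenerate (zero) variance — e.g. identical markers — is
    flagged and reported as no evidence of a difference (p = 1).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _binary_labels(labels)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValueError("scores and labels must align")

    auc_a, v10a, v01a = _placements(sa, y)
    auc_b, v10b, v01b = _placements(sb, y)
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise ValueError("need at least two subjects per class")
    s10 = np.cov(np.vstack([v10a, v10b]))  # 2x2
    s01 = np.cov(np.vstack([v01a, v01b]))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var_diff <= 0:
        return DeLongResult(auc_a, auc_b, diff, z=0.0, p=1.0, degenerate=True)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, float(diff), float(z), float(p))


# ---------------------------------------------------------------------------
# Logistic screen
# ---------------------------------------------------------------------------

@dataclass
class LogisticScreenResult:
    """Univariate screen -> multivariate model -> combined score.

    ``univariate`` / ``multivariate`` are DataFrames indexed by covariate
    with columns [or, ci_low, ci_high, p]; ``selected`` lists candidates with
    univariate p below the selection threshold (separation-flagged candidates
    excluded); ``combined_score`` holds the multivariate model's predicted
    probability per subject, directly usable as a ROC marker.
    """

    univariate: pd.DataFrame
    selected: list[str]
    multivariate: pd.DataFrame | None
    combined_score: np.ndarray | None
    separation_flags: list[str] = field(default_factory=list)
    selection_alpha: float = 0.1

    def summary(self) -> str:
        out = ["Univariate logistic screen", "--------------------------",
               self.univariate.to_string(float_format=lambda v: f"{v:.4g}")]
        out.append(f"\nSelected (p < {self.selection_alpha}): {self.selected or 'none'}")
        if self.separation_flags:
            out.append(f"Separation-flagged, excluded: {self.separation_flags}")
        if self.multivariate is not None:
            out += ["\nMultivariate model", "------------------",
                    self.multivariate.to_string(float_format=lambda v: f"{v:.4g}")]
        return "\n".join(out)


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray] | None:
    """Fit a logistic model; return (OR table, predicted probs) or None on
    separation / non-convergence."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None
    params = fit.params.drop("const")
    bse = fit.bse.drop("const")
    if not np.all(np.isfinite(fit.bse)) or np.any(bse > 50) or not fit.mle_retvals.get(
        "converged", True
    ):
        return None
    ci = fit.conf_int().drop(index="const")
    table = pd.DataFrame(
        {
            "or": np.exp(params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": fit.pvalues.drop("const"),
        }
    )
    return table, np.asarray(fit.predict(Xc), dtype=float)


def logistic_screen(
    table: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    selection_alpha: float = 0.1,
) -> LogisticScreenResult:
    """Univariate-then-multivariate logistic screening of candidate predictors.

    Each candidate is fitted alone against the binary ``outcome`` (odds ratio
    per unit, 95% Wald CI, p-value); candidates with univariate p below
    ``selection_alpha`` enter a single multivariate fit whose predicted
    probabilities form the combined diagnostic score.  Candidates with
    perfect separation (or non-convergent fits) are flagged and kept out of
    the multivariate model.
    """
    missing = [c for c in list(candidates) + [outcome] if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    y = _binary_labels(table[outcome].to_numpy())

    rows, flags = {}, []
    for cand in candidates:
        res = _fit_logit(y, table[[cand]].astype(float))
        if res is None:
            flags.append(cand)
            rows[cand] = {"or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
        else:
            rows[cand] = res[0].loc[cand].to_dict()
    uni = pd.DataFrame.from_dict(rows, orient="index")[["or", "ci_low", "ci_high", "p"]]

    selected = [c for c in candidates if c not in flags and uni.loc[c, "p"] < selection_alpha]
    multi, score = None, None
    if selected:
        res = _fit_logit(y, table[selected].astype(float))
        if res is not None:
            multi, score = res
    return LogisticScreenResult(
        univariate=uni,
        selected=selected,
        multivariate=multi,
        combined_score=score,
        separation_flags=flags,
        selection_alpha=selection_alpha,
    )
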