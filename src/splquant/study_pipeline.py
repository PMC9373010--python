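"""End-to-end cohort analysis: exclusions, grading, and the reporting chain.

``CohortStudy`` is the top-level model object: built from a per-patient
cohort table (one row per lesion, reader columns for the hand-measured
diffusion parameters, workstation columns for the PET metrics), its
``fit()`` runs the full analysis —

1. screening exclusions (records carrying any exclusion flag are dropped,
   with a per-flag tally);
2. histopathological grade grouping of malignant lesions (grade 3 and small
   cell carcinoma = high-grade; grades 1-2 and bronchial adenoma =
   non-high-grade);
3. reader averaging of ADC/MD/MK and two-reader ICC per parameter;
4. per-parameter group comparisons for both contrasts (malignant vs benign;
   high- vs non-high-grade within malignant);
5. the univariate -> multivariate logistic screen for malignancy and ROC
   analysis of every parameter plus the combined (multivariate-probability)
   score, with DeLong comparisons of the combined score against each
   imaging parameter —

and returns a ``StudyReport`` whose tables mirror the familiar four-table
layout of diagnostic-imaging papers (group stats, logistic screen, ROC per
contrast).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .diagnostic_stats import (
    compare_groups,
    delong_test,
    icc_two_reader,
    logistic_screen,
    roc_analysis,
)

__all__ = [
    "StudyConfig",
    "CohortStudy",
    "StudyReport",
    "apply_exclusions",
    "assign_grade_group",
    "run_study",
    "IMAGING_PARAMS",
    "READER_PARAMS",
]

READER_PARAMS = ("adc", "md", "mk")
IMAGING_PARAMS = ("adc", "md", "mk", "suvmax", "mtv", "tlg")
LOGISTIC_CANDIDATES = ("age", "sex", "smoking", "diameter_cm") + IMAGING_PARAMS


# ---------------------------------------------------------------------------
# Screening and grading
# ---------------------------------------------------------------------------

def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop flagged records; tally exclusions per flag category.

    ``exclusion_flags`` holds ';'-separated flags (empty/missing = retained).
    A record with several flags is excluded once but appears in every flag's
    tally, so tallies may sum to more than the number excluded.
    """
    if "exclusion_flags" not in records.columns:
        return records.copy(), {}
    flags = records["exclusion_flags"].fillna("").astype(str)
    flag_lists = flags.apply(lambda s: [f for f in s.split(";") if f])
    tally: dict[str, int] = {}
    for fl in flag_lists:
        for f in fl:
            tally[f] = tally.get(f, 0) + 1
    retained = records[flag_lists.str.len() == 0].reset_index(drop=True)
    return retained, tally


def assign_grade_group(record: Mapping) -> str | None:
    """Map one malignant record to {'high_grade', 'non_high_grade'}; benign -> None.

    Uses the explicit grade when present; otherwise the pathology label:
    small cell carcinoma counts as grade 3, bronchial adenoma as grade 1,
    and 'poorly/moderately/well (or highly) differentiated' map to grades
    3/2/1.
    """
    group = record.get("group")
    malignant = bool(record.get("malignant", group == "malignant"))
    if not malignant:
        return None
    grade = record.get("grade")
    if grade in (None, "") or (isinstance(grade, float) and np.isnan(grade)):
        grade = None
    if grade is None:
        path = str(record.get("pathology", "")).lower()
        if "small cell" in path:
            grade = 3
        elif "bronchial adenoma" in path:
            grade = 1
        elif "poorly differentiated" in path:
            grade = 3
        elif "moderately differentiated" in path:
            grade = 2
        elif "well differentiated" in path or "highly differentiated" in path:
            grade = 1
        else:
            raise ValueError(
                f"malignant record without grade or recognizable pathology: {path!r}"
            )
    grade = int(float(grade))
    if grade not in (1, 2, 3):
        raise ValueError(f"grade must be 1, 2 or 3, got {grade}")
    return "high_grade" if grade == 3 else "non_high_grade"


# ---------------------------------------------------------------------------
# Configuration and report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Analysis knobs with their conventional defaults."""

    bvalues: tuple[float, ...] = (0.0, 500.0, 1000.0, 2000.0)
    threshold_fraction: float = 0.40
    normality_alpha: float = 0.05
    selection_alpha: float = 0.10
    icc_model: Literal["absolute_agreement", "consistency"] = "absolute_agreement"
    youden_tiebreak: Literal["higher_specificity"] = "higher_specificity"
    #: optional per-parameter override of the t-vs-U normality gate,
    #: e.g. {"adc": "mann_whitney_u"} to pin a published test assignment
    test_overrides: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "bvalues" in raw:
            raw["bvalues"] = tuple(float(b) for b in raw["bvalues"])
        return cls(**raw)


@dataclass
class StudyReport:
    """Results container: one table per reporting stage, JSON/CSV-serialisable."""

    exclusion_tally: dict[str, int]
    n_screened: int
    n_retained: int
    icc: pd.DataFrame
    group_comparison: pd.DataFrame
    logistic: pd.DataFrame
    roc_malignancy: pd.DataFrame
    roc_grade: pd.DataFrame
    delong_combined: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Internal consistency: Youden identity per ROC row; every
        multivariate covariate appears among univariate p < alpha rows."""
        for table in (self.roc_malignancy, self.roc_grade):
            if len(table) == 0:
                continue
            resid = table["youden"] - (
                table["sensitivity"] + table["specificity"] - 1.0
            )
            if not np.allclose(resid, 0.0, atol=1e-12):
                raise AssertionError("Youden identity violated in ROC table")
        multi = self.logistic[self.logistic["stage"] == "multivariate"]
        uni = self.logistic[self.logistic["stage"] == "univariate"]
        selected_ok = set(uni.loc[uni["selected"] == True, "parameter"])  # noqa: E712
        if not set(multi["parameter"]).issubset(selected_ok):
            raise AssertionError("multivariate covariate outside the selected set")

    def to_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "n_retained": self.n_retained,
            "exclusion_tally": self.exclusion_tally,
            "icc": self.icc.to_dict(orient="records"),
            "group_comparison": self.group_comparison.to_dict(orient="records"),
            "logistic": self.logistic.to_dict(orient="records"),
            "roc_malignancy": self.roc_malignancy.to_dict(orient="records"),
            "roc_grade": self.roc_grade.to_dict(orient="records"),
            "delong_combined": self.delong_combined.to_dict(orient="records"),
            "notes": self.notes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        for name in (
            "icc",
            "group_comparison",
            "logistic",
            "roc_malignancy",
            "roc_grade",
            "delong_combined",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    def summary(self) -> str:
        ff = lambda v: f"{v:.4g}"  # noqa: E731
        parts = [
            f"Cohort study report: {self.n_retained} retained of "
            f"{self.n_screened} screened (excluded per flag: {self.exclusion_tally or 'none'})",
            "\nInter-reader agreement (ICC)",
            self.icc.to_string(index=False, float_format=ff),
            "\nGroup comparisons",
            self.group_comparison.to_string(index=False, float_format=ff),
            "\nLogistic screen (malignant vs benign)",
            self.logistic.to_string(index=False, float_format=ff),
            "\nROC: malignant vs benign",
            self.roc_malignancy.to_string(index=False, float_format=ff),
            "\nROC: high-grade vs non-high-grade (malignant only)",
            self.roc_grade.to_string(index=False, float_format=ff),
            "\nDeLong: combined score vs single parameters",
            self.delong_combined.to_string(index=False, float_format=ff),
        ]
        if self.notes:
            parts += ["\nNotes:"] + [f"  - {n}" for n in self.notes]
        return "\n".join(parts)


# ---------------------------------------------------------------------------
# The study model
# ---------------------------------------------------------------------------

def _roc_row(param: str, scores: np.ndarray, labels: np.ndarray) -> dict:
    r = roc_analysis(scores, labels)
    # p-value for AUC != 0.5 from the DeLong standard error
    from scipy import stats as _st

    p_auc = (
        2.0 * _st.norm.sf(abs(r.auc - 0.5) / r.auc_se) if r.auc_se > 0 else 0.0
    )
    return {
        "parameter": param,
        "auc": r.auc,
        "ci_low": r.ci95[0],
        "ci_high": r.ci95[1],
        "p_value": p_auc,
        "youden": r.youden,
        "cutoff": r.cutoff,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
        "direction": r.direction,
    }


class CohortStudy:
    """Full diagnostic study of a lesion cohort table.

    Parameters
    ----------
    cohort
        Per-patient table with columns patient_id, age, sex, smoking,
        diameter_cm, pathology, grade, group, ``{adc,md,mk}_reader{1,2}``,
        suvmax, mtv, tlg and optionally exclusion_flags.
    config
        Analysis settings (``StudyConfig``).
    """

    def __init__(self, cohort: pd.DataFrame, config: StudyConfig | None = None):
        self.config = config or StudyConfig()
        self.raw = cohort.copy()
        required = [f"{p}_reader{r}" for p in READER_PARAMS for r in (1, 2)] + [
            "suvmax", "mtv", "tlg", "group",
        ]
        missing = [c for c in required if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")

    @classmethod
    def from_csv(cls, path, config: StudyConfig | None = None) -> "CohortStudy":
        return cls(pd.read_csv(path, keep_default_na=False, na_values=[]), config)

    # -- pieces ------------------------------------------------------------
    def _prepare(self) -> tuple[pd.DataFrame, dict[str, int], int]:
        retained, tally = apply_exclusions(self.raw)
        n_screened = len(self.raw)
        df = retained.copy()
        for p in READER_PARAMS:
            df[p] = 0.5 * (
                df[f"{p}_reader1"].astype(float) + df[f"{p}_reader2"].astype(float)
            )
        for p in ("suvmax", "mtv", "tlg", "age", "diameter_cm"):
            if p in df.columns:
                df[p] = df[p].astype(float)
        df["malignant"] = (df["group"] == "malignant").astype(int)
        df["grade_group"] = [
            assign_grade_group(rec) for rec in df.to_dict(orient="records")
        ]
        return df, tally, n_screened

    def fit(self) -> StudyReport:
        cfg = self.config
        df, tally, n_screened = self._prepare()
        if df["malignant"].nunique() < 2:
            raise ValueError("cohort must contain both benign and malignant lesions")
        notes = ["no multiple-testing correction applied; all tests two-sided"]

        # inter-reader agreement
        icc_rows = []
        for p in READER_PARAMS:
            r = icc_two_reader(
                df[f"{p}_reader1"].astype(float),
                df[f"{p}_reader2"].astype(float),
                model=cfg.icc_model,
            )
            icc_rows.append({"parameter": p, "icc": r.icc, "category": r.category})
        icc_table = pd.DataFrame(icc_rows)

        # group comparisons for both contrasts
        malignant = df[df["malignant"] == 1]
        contrasts = {
            "malignant_vs_benign": (df, df["group"].to_numpy()),
            "high_vs_non_high": (malignant, malignant["grade_group"].to_numpy()),
        }
        cmp_rows = []
        for contrast, (sub, labels) in contrasts.items():
            if len(pd.unique(labels)) < 2:
                continue
            for p in IMAGING_PARAMS:
                force = cfg.test_overrides.get(p)
                res = compare_groups(
                    sub[p].to_numpy(), labels,
                    normality_alpha=cfg.normality_alpha, force_test=force,
                )
                g0, g1 = res.group_names
                cmp_rows.append(
                    {
                        "contrast": contrast,
                        "parameter": p,
                        "group1": g0,
                        "mean1": res.means[0],
                        "sd1": res.sds[0],
                        "n1": res.ns[0],
                        "group2": g1,
                        "mean2": res.means[1],
                        "sd2": res.sds[1],
                        "n2": res.ns[1],
                        "test_used": res.test_used,
                        "p_value": res.p_two_sided,
                    }
                )
        cmp_table = pd.DataFrame(cmp_rows)

        # logistic screen for malignancy
        ldf = df.copy()
        ldf["sex"] = (ldf["sex"] == "male").astype(int)
        ldf["smoking"] = ldf["smoking"].astype(bool).astype(int)
        screen = logistic_screen(
            ldf, "malignant", list(LOGISTIC_CANDIDATES),
            selection_alpha=cfg.selection_alpha,
        )
        log_rows = []
        for cand in LOGISTIC_CANDIDATES:
            row = screen.univariate.loc[cand]
            log_rows.append(
                {
                    "stage": "univariate", "parameter": cand,
                    "or": row["or"], "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"], "p_value": row["p"],
                    "selected": cand in screen.selected,
                }
            )
        if screen.multivariate is not None:
            for cand, row in screen.multivariate.iterrows():
                log_rows.append(
                    {
                        "stage": "multivariate", "parameter": cand,
                        "or": row["or"], "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"], "p_value": row["p"],
                        "selected": True,
                    }
                )
        else:
            notes.append("no multivariate model (empty or unfittable selected set)")
        if screen.separation_flags:
            notes.append(f"separation-flagged candidates: {screen.separation_flags}")
        log_table = pd.DataFrame(log_rows)

        # ROC per parameter, both contrasts; combined score for malignancy
        y_mal = df["malignant"].to_numpy()
        roc_by_param = {p: _roc_row(p, df[p].to_numpy(), y_mal) for p in IMAGING_PARAMS}
        roc_mal_rows = list(roc_by_param.values())
        delong_rows = []
        if screen.combined_score is not None:
            roc_mal_rows.insert(
                0, _roc_row("combined", np.asarray(screen.combined_score), y_mal)
            )
            for p in IMAGING_PARAMS:
                # orient each marker toward its positive direction so the
                # DeLong comparison is between the reported (>= 0.5) AUCs
                sign = 1.0 if roc_by_param[p]["direction"] == "higher" else -1.0
                d = delong_test(screen.combined_score, sign * df[p].to_numpy(), y_mal)
                delong_rows.append(
                    {
                        "parameter": p,
                        "auc_combined": d.auc_a,
                        "auc_parameter": d.auc_b,
                        "p_value": d.p,
                        "degenerate": d.degenerate,
                    }
                )
        roc_mal = pd.DataFrame(roc_mal_rows)

        roc_grade_rows = []
        gg = malignant["grade_group"].to_numpy()
        if len(pd.unique(gg)) == 2:
            y_gr = (gg == "high_grade").astype(int)
            roc_grade_rows = [
                _roc_row(p, malignant[p].to_numpy(), y_gr) for p in IMAGING_PARAMS
            ]
        roc_grade = pd.DataFrame(roc_grade_rows)

        report = StudyReport(
            exclusion_tally=tally,
            n_screened=n_screened,
            n_retained=len(df),
            icc=icc_table,
            group_comparison=cmp_table,
            logistic=log_table,
            roc_malignancy=roc_mal,
            roc_grade=roc_grade,
            delong_combined=pd.DataFrame(delong_rows),
            notes=notes,
        )
        report.validate()
        return report


def run_study(cohort: pd.DataFrame, config: StudyConfig | None = None) -> StudyReport:
    """Convenience wrapper: ``CohortStudy(cohort, config).fit()``."""
    return CohortStudy(cohort, config).fit()
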