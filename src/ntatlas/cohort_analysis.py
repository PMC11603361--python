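"""Cohort-level outcome statistics.

Quality-of-life (QoL) stratification and binarization, ROC curves with
Youden-optimal cutoffs for lesion volume, accumulated dose volume (ADV) and
NTC, Kruskal-Wallis group tests, Fisher exact 2x2 association tests, ordinary
least-squares trend fits, and adverse-effect summaries.

Cutoff convention: classification against the published operating points uses
strict inequalities — favorable iff lesion volume < 127.4 mm^3, ADV <
0.0594 cc, NTC > 0.544.  ROC cutoffs are reported as midpoints between the
two adjacent observed values at the Youden optimum, in the favorable
direction.  Missing data are handled complete-case per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AE_FLAGS",
    "PatientRecord",
    "ROCResult",
    "GroupTestResult",
    "Cutoffs",
    "binarize_qol",
    "roc_youden",
    "youden_index",
    "kruskal_wallis",
    "fisher_exact_2x2",
    "linear_r2",
    "classify_by_cutoffs",
    "ae_summary",
    "analyze_cohort",
    "cohort_to_dataframe",
    "cohort_from_dataframe",
]

AE_FLAGS = (
    "gait_ataxia",
    "limb_ataxia_weakness",
    "dysarthria",
    "taste_smell",
    "tongue_numbness",
    "limb_numbness",
    "dysphagia",
    "fatigue",
    "cognitive_behavioral",
)

QOL_CATEGORIES = ("better", "same", "worse")


@dataclass
class PatientRecord:
    """One treated patient's outcome, lesion and treatment covariates.

    CRST sub-scores follow the treated-hand / function-only conventions
    (part A treated hand only; part B treated hand only, no pouring; part C
    function only).  ``None`` marks a missing value.
    """

    id: str
    qol: str  # better | same | worse
    lesion_volume_mm3: float | None = None
    adv_cc: float | None = None
    ntc: float | None = None
    sdr: float | None = None
    crst_a_pre: float | None = None
    crst_a_post: float | None = None
    crst_b_pre: float | None = None
    crst_b_post: float | None = None
    crst_c_pre: float | None = None
    crst_c_post: float | None = None
    subjective_suppression_pct: float | None = None
    ae_flags: frozenset = frozenset()
    persistent_ae: bool = False
    followup_days: float | None = None

    def __post_init__(self):
        if self.qol not in QOL_CATEGORIES:
            raise ValueError(f"qol must be one of {QOL_CATEGORIES}, got {self.qol!r}")
        if self.ntc is not None and not (0.0 <= self.ntc <= 1.0):
            raise ValueError("ntc must lie in [0, 1]")
        for name in ("lesion_volume_mm3", "adv_cc", "sdr", "followup_days"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        unknown = set(self.ae_flags) - set(AE_FLAGS)
        if unknown:
            raise ValueError(f"unknown AE flags: {sorted(unknown)}")
        object.__setattr__(self, "ae_flags", frozenset(self.ae_flags))


@dataclass
class ROCResult:
    direction: str  # low_is_positive | high_is_positive
    thresholds: np.ndarray  # candidate cutoffs (value scale, midpoints + sentinels)
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    cutoff_direction: str  # "<" (favor low) or ">" (favor high), positive side

    @property
    def cutoff_label(self) -> str:
        return f"{self.cutoff_direction}{self.optimal_cutoff:g}"


@dataclass
class GroupTestResult:
    statistic: float
    dof: int
    p_value: float
    group_sizes: tuple


@dataclass(frozen=True)
class Cutoffs:
    """Published operating points (strict inequalities, favorable direction)."""

    lesion_mm3: float = 127.4
    adv_cc: float = 0.0594
    ntc: float = 0.544


def binarize_qol(r: PatientRecord) -> str:
    """Collapse better/same into one group: better, same -> better_same; worse -> worse."""
    if r.qol not in QOL_CATEGORIES:
        raise ValueError(f"missing or invalid qol: {r.qol!r}")
    return "worse" if r.qol == "worse" else "better_same"


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


def roc_youden(values, labels, direction: str = "high_is_positive") -> ROCResult:
    """ROC sweep with trapezoid AUC and the Youden-optimal cutoff.

    ``labels`` are binary with 1 the positive class; ``direction`` states
    whether low or high values indicate the positive class.  Candidate cutoffs
    are the midpoints between consecutive distinct observed values plus
    sentinels beyond the extremes, with a strict comparison in the positive
    direction (value < cutoff for ``low_is_positive``, value > cutoff for
    ``high_is_positive``).  The optimum maximizes J = sens + spec - 1; ties go
    to the higher specificity, then to the cutoff predicting fewer positives.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be matching 1-D sequences")
    if np.any(np.isnan(values)):
        raise ValueError("missing values are not allowed; drop them first (complete-case)")
    if direction not in ("low_is_positive", "high_is_positive"):
        raise ValueError("direction must be 'low_is_positive' or 'high_is_positive'")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    span = max(1.0, uniq[-1] - uniq[0])
    cuts = np.concatenate(([uniq[0] - span], mids, [uniq[-1] + span]))

    if direction == "low_is_positive":
        pred = values[None, :] < cuts[:, None]
    else:
        pred = values[None, :] > cuts[:, None]
    tpr = (pred & pos[None, :]).sum(axis=1) / n_pos
    fpr = (pred & ~pos[None, :]).sum(axis=1) / n_neg

    order = np.lexsort((tpr, fpr))  # ROC curve: fpr ascending, tpr rising within ties
    fpr_s, tpr_s = fpr[order], tpr[order]
    auc = float(np.trapezoid(tpr_s, fpr_s))

    j = tpr - fpr
    # ties: higher specificity (lower fpr), then fewer predicted positives
    n_pred = pred.sum(axis=1)
    best = np.lexsort((n_pred, fpr, -j))[0]
    return ROCResult(
        direction=direction,
        thresholds=cuts,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        optimal_cutoff=float(cuts[best]),
        youden_j=float(j[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        cutoff_direction="<" if direction == "low_is_positive" else ">",
    )


def kruskal_wallis(groups, pad_to_min_n: int | None = None) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 dof).

    ``pad_to_min_n`` opts into the mean-padding variant: any group smaller
    than the stated minimum is padded with copies of its own mean until it
    reaches that size.  The padding is statistically irregular and off by
    default; it exists only to replicate a published analysis convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty groups are not allowed")
    sizes = tuple(int(g.size) for g in groups)
    if pad_to_min_n is not None:
        groups = [
            np.concatenate([g, np.full(max(0, pad_to_min_n - g.size), g.mean())])
            for g in groups
        ]
    dof = len(groups) - 1
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return GroupTestResult(statistic=0.0, dof=dof, p_value=1.0, group_sizes=sizes)
    h, p = stats.kruskal(*groups)
    return GroupTestResult(statistic=float(h), dof=dof, p_value=float(p), group_sizes=sizes)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: hypergeometric mass of tables (fixed margins)
    no more probable than the observed one."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def linear_r2(x, y) -> tuple[float, float, float]:
    """OLS fit y ~ x; returns (slope, intercept, R^2 = squared Pearson r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matching x/y with n >= 3")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def classify_by_cutoffs(r: PatientRecord, cutoffs: Cutoffs = Cutoffs()) -> dict:
    """Per-variable favorable/unfavorable flags against the published cutoffs.

    Strict inequalities: favorable iff lesion volume < cutoff, ADV < cutoff,
    NTC > cutoff; boundary values are unfavorable.  Missing variables yield
    None; all-missing raises.
    """
    flags = {
        "lesion_volume_mm3": None if r.lesion_volume_mm3 is None
        else bool(r.lesion_volume_mm3 < cutoffs.lesion_mm3),
        "adv_cc": None if r.adv_cc is None else bool(r.adv_cc < cutoffs.adv_cc),
        "ntc": None if r.ntc is None else bool(r.ntc > cutoffs.ntc),
    }
    present = {k: v for k, v in flags.items() if v is not None}
    if not present:
        raise ValueError("all classifier variables are missing")
    return {
        "flags": flags,
        "n_favorable": sum(present.values()),
        "n_present": len(present),
        "all_favorable": all(present.values()),
    }


def ae_summary(cohort) -> pd.DataFrame:
    """Per-AE counts and QoL-category fractions, ranked by worse-fraction.

    Each row covers one adverse-effect flag experienced by at least one
    patient: the number experiencing it and the fraction of those in each QoL
    category, sorted by the worse fraction descending.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    for flag in AE_FLAGS:
        with_flag = [r for r in cohort if flag in r.ae_flags]
        n = len(with_flag)
        if n == 0:
            continue
        counts = {q: sum(1 for r in with_flag if r.qol == q) for q in QOL_CATEGORIES}
        rows.append(
            {
                "ae": flag,
                "n": n,
                "worse_fraction": counts["worse"] / n,
                "same_fraction": counts["same"] / n,
                "better_fraction": counts["better"] / n,
            }
        )
    df = pd.DataFrame(rows, columns=["ae", "n", "worse_fraction", "same_fraction", "better_fraction"])
    return df.sort_values(["worse_fraction", "n"], ascending=[False, False]).reset_index(drop=True)


def _complete_case(cohort, attr):
    vals, labels = [], []
    for r in cohort:
        v = getattr(r, attr)
        if v is None:
            continue
        vals.append(float(v))
        labels.append(1 if binarize_qol(r) == "better_same" else 0)
    return np.array(vals), np.array(labels)


def analyze_cohort(cohort, cutoffs: Cutoffs = Cutoffs()) -> dict:
    """Full cohort report: ROC/Youden per predictor, QoL group tests on the
    predictors, AE summary, and the persistent-AE vs binarized-QoL exact test.

    The positive class throughout is the "better/same" QoL group; lesion
    volume and ADV enter with ``low_is_positive``, NTC with
    ``high_is_positive``.
    """
    cohort = list(cohort)
    report: dict = {"n_patients": len(cohort)}
    qol_counts = {q: sum(1 for r in cohort if r.qol == q) for q in QOL_CATEGORIES}
    report["qol_counts"] = qol_counts

    roc_spec = {
        "lesion_volume_mm3": "low_is_positive",
        "adv_cc": "low_is_positive",
        "ntc": "high_is_positive",
    }
    report["roc"] = {}
    report["group_tests"] = {}
    for attr, direction in roc_spec.items():
        vals, labels = _complete_case(cohort, attr)
        entry: dict = {"n_complete": int(vals.size)}
        if vals.size and 0 < labels.sum() < labels.size:
            roc = roc_youden(vals, labels, direction)
            entry.update(
                auc=roc.auc,
                youden_j=roc.youden_j,
                sensitivity=roc.sensitivity,
                specificity=roc.specificity,
                optimal_cutoff=roc.optimal_cutoff,
                cutoff_label=roc.cutoff_label,
            )
        report["roc"][attr] = entry
        by_group = [
            [float(getattr(r, attr)) for r in cohort if r.qol == q and getattr(r, attr) is not None]
            for q in QOL_CATEGORIES
        ]
        if all(len(g) > 0 for g in by_group):
            gt = kruskal_wallis(by_group)
            report["group_tests"][attr] = asdict(gt)

    ae_df = ae_summary(cohort)
    report["ae_summary"] = ae_df.to_dict(orient="records")
    ae_w = sum(1 for r in cohort if r.persistent_ae and binarize_qol(r) == "worse")
    ae_bs = sum(1 for r in cohort if r.persistent_ae and binarize_qol(r) == "better_same")
    no_w = sum(1 for r in cohort if not r.persistent_ae and binarize_qol(r) == "worse")
    no_bs = sum(1 for r in cohort if not r.persistent_ae and binarize_qol(r) == "better_same")
    table = [[ae_w, ae_bs], [no_w, no_bs]]
    report["persistent_ae_vs_qol"] = {
        "table": table,
        "p_value": fisher_exact_2x2(np.array(table)) if sum(map(sum, table)) else None,
    }
    report["classification"] = {
        r.id: classify_by_cutoffs(r, cutoffs)["flags"]
        for r in cohort
        if any(v is not None for v in (r.lesion_volume_mm3, r.adv_cc, r.ntc))
    }
    return report


# ---------------------------------------------------------------------------
# cohort CSV round-trip

_CSV_COLUMNS = [
    "id", "qol", "lesion_volume_mm3", "adv_cc", "ntc", "sdr",
    "crst_a_pre", "crst_a_post", "crst_b_pre", "crst_b_post",
    "crst_c_pre", "crst_c_post", "subjective_suppression_pct",
    "ae_flags", "persistent_ae", "followup_days",
]


def cohort_to_dataframe(cohort) -> pd.DataFrame:
    rows = []
    for r in cohort:
        d = asdict(r)
        d["ae_flags"] = ";".join(sorted(r.ae_flags))
        rows.append(d)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def cohort_from_dataframe(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _CSV_COLUMNS:
            v = row.get(col)
            if col == "ae_flags":
                v = frozenset() if pd.isna(v) or v == "" else frozenset(str(v).split(";"))
            elif col == "persistent_ae":
                v = bool(v)
            elif col in ("id", "qol"):
                v = str(v)
            else:
                v = None if pd.isna(v) else float(v)
            kwargs[col] = v
        records.append(PatientRecord(**kwargs))
    return records
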