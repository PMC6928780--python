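"""Clinical validation statistics for a paired tumor/peritumor cohort.

Covers the small-statistics toolbox of a single-gene expression study:
2^-ddCt relative qPCR quantification, paired t-tests overall and by
molecular subtype, the fraction of patients with tumor-downregulated
expression, contingency association tests for clinicopathological tables,
Kaplan-Meier curves with the log-rank test on an expression split, and the
ellipsoid xenograft tumor-volume formula X*Y^2/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "ClinicalCohort",
    "KmCurve",
    "PairedTestResult",
    "AssociationResult",
    "ddct_fold_change",
    "paired_group_test",
    "paired_tests_by_subtype",
    "fraction_downregulated",
    "association_test",
    "km_logrank",
    "tumor_volume",
]

SUBTYPES = ("LuminalA", "LuminalB", "HER2", "TNBC")

COHORT_COLUMNS = ("patient_id", "subtype", "tumor", "peritumor")


@dataclass
class ClinicalCohort:
    """Paired tumor/peritumor cohort with optional survival follow-up.

    ``data`` must have columns ``patient_id, subtype, tumor, peritumor`` and
    may have ``time`` (months) and ``event`` (1 = death observed). Tumor and
    peritumor expression are on a log scale.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.data["patient_id"].duplicated().any():
            raise ValueError("duplicate patient ids")
        for col in ("tumor", "peritumor"):
            if not np.all(np.isfinite(self.data[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite values in column {col!r}")
        if self.has_survival:
            t = self.data["time"].to_numpy(dtype=float)
            e = self.data["event"].to_numpy()
            if np.any(t < 0):
                raise ValueError("survival times must be >= 0")
            if not set(np.unique(e)) <= {0, 1}:
                raise ValueError("event flags must be 0 or 1")

    @property
    def has_survival(self) -> bool:
        return {"time", "event"} <= set(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_tsv(cls, path) -> "ClinicalCohort":
        return cls(pd.read_csv(path, sep="\t"))


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR fold change by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    fold = 2^-ddCt. Earlier amplification of the target in the case (lower
    Ct) gives fold > 1.
    """
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


@dataclass(frozen=True)
class PairedTestResult:
    subtype: str  # subtype name or "overall"
    n: int
    mean_difference: float  # mean(tumor - peritumor)
    t_statistic: float
    p_value: float  # NaN when the differences have zero variance


def paired_group_test(
    cohort: ClinicalCohort, subtype: str | None = None
) -> PairedTestResult:
    """Paired two-sided t-test of tumor vs peritumor log expression.

    ``subtype=None`` tests the whole cohort. With zero variance of the
    paired differences the t statistic is undefined; the p-value is reported
    as NaN with a warning.
    """
    df = cohort.data
    if subtype is not None:
        df = df[df["subtype"] == subtype]
    if len(df) < 2:
        raise ValueError(
            f"need >= 2 pairs for subtype {subtype!r}, have {len(df)}"
        )
    diff = df["tumor"].to_numpy(dtype=float) - df["peritumor"].to_numpy(dtype=float)
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        if np.allclose(diff, 0.0):
            warnings.warn(
                "paired differences are identically zero; t-test undefined",
                stacklevel=2,
            )
            return PairedTestResult(subtype or "overall", len(df), 0.0,
                                    float("nan"), float("nan"))
        warnings.warn(
            "paired differences have zero variance; t-test undefined",
            stacklevel=2,
        )
        return PairedTestResult(subtype or "overall", len(df), mean_diff,
                                float("nan"), float("nan"))
    t, p = stats.ttest_rel(df["tumor"], df["peritumor"])
    return PairedTestResult(subtype or "overall", len(df), mean_diff,
                            float(t), float(p))


def paired_tests_by_subtype(cohort: ClinicalCohort) -> list[PairedTestResult]:
    """Overall paired test plus one per subtype present (>= 2 pairs)."""
    out = [paired_group_test(cohort)]
    for s in sorted(cohort.data["subtype"].unique()):
        if (cohort.data["subtype"] == s).sum() >= 2:
            out.append(paired_group_test(cohort, subtype=s))
    return out


def fraction_downregulated(cohort: ClinicalCohort) -> float:
    """Fraction of pairs with tumor expression strictly below peritumor.

    Ties count as not downregulated (conservative)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    down = cohort.data["tumor"].to_numpy() < cohort.data["peritumor"].to_numpy()
    return float(down.mean())


@dataclass(frozen=True)
class AssociationResult:
    statistic: float  # chi-square (NaN for Fisher)
    df: int
    p_value: float
    method: str  # "chi2" or "fisher"


def association_test(counts) -> AssociationResult:
    """Association in a 2 x k contingency table.

    Pearson chi-square without continuity correction; for a 2x2 table with
    any expected cell below 5 the two-sided Fisher exact test is used
    instead (the chi-square approximation is unreliable there).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margins: a row or column sums to zero")

    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and np.any(expected < 5):
        _, p_fisher = stats.fisher_exact(table, alternative="two-sided")
        return AssociationResult(float("nan"), 1, float(p_fisher), "fisher")
    return AssociationResult(float(chi2), int(dof), float(p), "chi2")


@dataclass
class KmCurve:
    """Kaplan-Meier product-limit curve for one group."""

    label: str
    times: np.ndarray  # event/censor times where the estimate changes
    survival: np.ndarray  # S(t), starting from 1 and nonincreasing
    at_risk: np.ndarray  # number at risk just before each time


def _km_curve(times: np.ndarray, events: np.ndarray, label: str) -> KmCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf[label].to_numpy(dtype=float)
    at_risk = np.array(
        [np.count_nonzero(times >= t) for t in grid], dtype=int
    )
    return KmCurve(label=label, times=grid, survival=surv, at_risk=at_risk)


def km_logrank(
    cohort: ClinicalCohort, split: str = "median", quantile: float | None = None
) -> tuple[KmCurve, KmCurve, float, float]:
    """Kaplan-Meier curves and log-rank test for high vs low tumor expression.

    ``split='median'`` puts samples strictly above the median in the high
    group; ``split='quantile'`` with ``quantile=q`` uses the q-th upper
    quantile cut instead. Returns (high curve, low curve, log-rank
    chi-square, p). With zero events the test is undefined and chi-square/p
    are NaN.
    """
    if not cohort.has_survival:
        raise ValueError("cohort has no time/event columns")
    df = cohort.data
    expr = df["tumor"].to_numpy(dtype=float)
    if split == "median":
        cut = float(np.median(expr))
    elif split == "quantile":
        if quantile is None or not (0 < quantile < 1):
            raise ValueError("quantile split needs 0 < quantile < 1")
        cut = float(np.quantile(expr, 1.0 - quantile))
    else:
        raise ValueError(f"unknown split {split!r}")
    high = expr > cut
    if high.all() or not high.any():
        raise ValueError("expression split leaves a group empty")

    t = df["time"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=int)
    curve_high = _km_curve(t[high], e[high], "high")
    curve_low = _km_curve(t[~high], e[~high], "low")
    if e.sum() == 0:
        warnings.warn("no events observed; log-rank test undefined", stacklevel=2)
        return curve_high, curve_low, float("nan"), float("nan")
    res = logrank_test(t[high], t[~high], event_observed_A=e[high],
                       event_observed_B=e[~high])
    return curve_high, curve_low, float(res.test_statistic), float(res.p_value)


def tumor_volume(longest: float, shortest: float) -> float:
    """Xenograft tumor volume X * Y^2 / 2 from caliper diameters (mm).

    X is the longest and Y the shortest diameter; if passed swapped a
    warning is raised and the axes are sorted before computing.
    """
    if longest < 0 or shortest < 0:
        raise ValueError("diameters must be >= 0")
    if longest < shortest:
        warnings.warn("longest < shortest; swapping axes", stacklevel=2)
        longest, shortest = shortest, longest
    return float(longest * shortest**2 / 2.0)
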