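"""Scoring the algorithm against survey self-report.

The reference standard is the survey answer to "do you have a primary care
provider?". The algorithm's verdict (attached vs uncertainly attached) is
cross-tabulated against it; sensitivity, specificity, PPV and NPV follow,
computed in exact rational arithmetic and rounded half-up to one decimal
only at the end (the convention of printed validation tables).

Also here: the development/validation cohort split by survey date, and the
CoC cut-point sensitivity analysis comparing classification at two
thresholds with a two-sample proportion z-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping

import pandas as pd
from statsmodels.stats.proportion import proportions_ztest


def round_half_up_1(x: Fraction | float) -> float:
    """Round to one decimal, half-up (not banker's)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table: positive = algorithm attached; reference = reports a PCP."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_unlinked: int = 0  # respondents without an algorithm result, excluded

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn, self.n_unlinked) < 0:
            raise ValueError("cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def attached_total(self) -> int:
        return self.tp + self.fp

    @property
    def uncertain_total(self) -> int:
        return self.fn + self.tn

    @property
    def reference_positive_total(self) -> int:
        return self.tp + self.fn

    @property
    def reference_negative_total(self) -> int:
        return self.fp + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "n": self.n,
            "n_unlinked": self.n_unlinked,
        }


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages to one decimal; None where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def confusion(results: pd.DataFrame, survey: pd.DataFrame) -> ConfusionTable:
    """Cross-tabulate algorithm verdicts against survey self-report.

    Joins on ``respondent_id`` = ``patient_id``. Respondents without an
    algorithm result are excluded and counted in ``n_unlinked`` (the linkage
    shortfall); duplicate survey rows per respondent keep the first.
    """
    sv = survey.drop_duplicates("respondent_id")
    merged = sv.merge(
        results[["patient_id", "category"]],
        left_on="respondent_id",
        right_on="patient_id",
        how="left",
    )
    linked = merged["category"].notna()
    m = merged[linked]
    algo_pos = m["category"] == "attached"
    ref_pos = m["has_pcp"].astype(bool)
    return ConfusionTable(
        tp=int((algo_pos & ref_pos).sum()),
        fp=int((algo_pos & ~ref_pos).sum()),
        fn=int((~algo_pos & ref_pos).sum()),
        tn=int((~algo_pos & ~ref_pos).sum()),
        n_unlinked=int((~linked).sum()),
    )


def metrics(table: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV as one-decimal percentages.

    A metric whose denominator is zero is reported as None (absent), never
    as 0.
    """

    def ratio(num: int, den: int) -> float | None:
        if den == 0:
            return None
        return round_half_up_1(Fraction(100 * num, den))

    return DiagnosticMetrics(
        sensitivity=ratio(table.tp, table.tp + table.fn),
        specificity=ratio(table.tn, table.fp + table.tn),
        ppv=ratio(table.tp, table.tp + table.fp),
        npv=ratio(table.tn, table.fn + table.tn),
    )


def split_cohort(survey: pd.DataFrame, cutoff_date) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Development (< cutoff) / validation (>= cutoff) split by survey date.

    Disjoint and exhaustive by construction.
    """
    cutoff = pd.Timestamp(cutoff_date)
    before = survey["survey_date"] < cutoff
    return survey[before].reset_index(drop=True), survey[~before].reset_index(drop=True)


@dataclass(frozen=True)
class ThresholdArm:
    """Classification proportions at one CoC cut-point."""

    threshold: float
    n_reference_positive: int
    n_reference_negative: int
    true_positive_n: int  # attached among respondents reporting a PCP
    true_negative_n: int  # uncertain among respondents reporting no PCP

    @property
    def true_positive_prop(self) -> float:
        return self.true_positive_n / self.n_reference_positive if self.n_reference_positive else float("nan")

    @property
    def true_negative_prop(self) -> float:
        return self.true_negative_n / self.n_reference_negative if self.n_reference_negative else float("nan")


@dataclass(frozen=True)
class ThresholdComparison:
    """Two-arm cut-point comparison with two-sample proportion z-tests."""

    arms: tuple[ThresholdArm, ThresholdArm]
    tn_z: float
    tn_pvalue: float
    tp_z: float
    tp_pvalue: float
    alpha: float = 0.001

    @property
    def tn_significant(self) -> bool:
        return self.tn_pvalue < self.alpha

    @property
    def tp_significant(self) -> bool:
        return self.tp_pvalue < self.alpha

    def to_dict(self) -> dict:
        return {
            "arms": [
                {
                    "threshold": a.threshold,
                    "true_positive_prop": a.true_positive_prop,
                    "true_negative_prop": a.true_negative_prop,
                    "true_positive_n": a.true_positive_n,
                    "true_negative_n": a.true_negative_n,
                    "n_reference_positive": a.n_reference_positive,
                    "n_reference_negative": a.n_reference_negative,
                }
                for a in self.arms
            ],
            "tn_z": self.tn_z,
            "tn_pvalue": self.tn_pvalue,
            "tn_significant": self.tn_significant,
            "tp_z": self.tp_z,
            "tp_pvalue": self.tp_pvalue,
            "tp_significant": self.tp_significant,
            "alpha": self.alpha,
        }


def _arm(results: pd.DataFrame, survey: pd.DataFrame, threshold: float) -> ThresholdArm:
    table = confusion(results, survey)
    return ThresholdArm(
        threshold=threshold,
        n_reference_positive=table.reference_positive_total,
        n_reference_negative=table.reference_negative_total,
        true_positive_n=table.tp,
        true_negative_n=table.tn,
    )


def compare_thresholds(
    data: Mapping[str, pd.DataFrame],
    survey: pd.DataFrame,
    index_dates: pd.Series,
    thresholds: tuple[float, float] = (0.10, 0.25),
    config=None,
    alpha: float = 0.001,
) -> ThresholdComparison:
    """Run attachment at two CoC cut-points and compare classification.

    Per arm: the proportion of respondents reporting **no** PCP who the
    algorithm calls uncertain (true-negative proportion) and the proportion
    reporting a PCP who it calls attached (true-positive proportion).
    Proportions are compared between arms with two-sample z-tests on the
    counts; significance at ``alpha`` (default 0.001).
    """
    from .attachment import AttachmentConfig, run_attachment, with_threshold

    t1, t2 = thresholds
    if config is None:
        config = AttachmentConfig()
    arms = []
    for t in (t1, t2):
        results, _ = run_attachment(data, index_dates, with_threshold(config, t))
        arms.append(_arm(results, survey, t))
    a, b = arms

    def ztest(x1, n1, x2, n2):
        if min(n1, n2) == 0 or (x1 == x2 and n1 == n2):
            return 0.0, 1.0
        stat, p = proportions_ztest([x1, x2], [n1, n2])
        if pd.isna(stat):  # identical degenerate proportions (0/0% or 100/100%)
            return 0.0, 1.0
        return float(stat), float(p)

    tn_z, tn_p = ztest(a.true_negative_n, a.n_reference_negative, b.true_negative_n, b.n_reference_negative)
    tp_z, tp_p = ztest(a.true_positive_n, a.n_reference_positive, b.true_positive_n, b.n_reference_positive)
    return ThresholdComparison(arms=(a, b), tn_z=tn_z, tn_pvalue=tn_p, tp_z=tp_z, tp_pvalue=tp_p, alpha=alpha)
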