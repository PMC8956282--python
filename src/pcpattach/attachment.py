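"""The hierarchical attachment engine.

A person is *attached* to a PCP if (evaluated strictly in this order):

1. **PEM** — a formal enrollment (roster) interval covers their index date;
2. **CHC** — they had at least one community health centre visit in the
   lookback window;
3. **VIRTUAL** — their plurality provider (virtual enrollment over windowed
   core visits) has an adequate continuity-of-care index.

Otherwise they are *uncertainly attached* (step NONE). For population
application a pluggable pediatric hook may additionally attach children
under 19 who fall through the three adult steps (step PEDIATRIC); the
pediatric rules themselves are external.

Virtual enrollment and the provider CoC index are computed over the **full
population's** claims in a three-pass design, so a cohort member is judged
against population-level provider continuity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import pandas as pd

from .admin_data import active_roster_at
from .attribution import classify_coc, compute_coc, virtual_enroll_all
from .core_visits import DEFAULT_CORE_CODES, dedup_daily, filter_core, in_window_per_patient

CATEGORIES = ("attached", "uncertainly_attached")
STEPS = ("PEM", "CHC", "VIRTUAL", "PEDIATRIC", "NONE")
ATTACHED_STEPS = frozenset({"PEM", "CHC", "VIRTUAL", "PEDIATRIC"})

RESULT_COLUMNS = ["patient_id", "category", "step", "provider_id", "provider_coc"]


@dataclass(frozen=True)
class AttachmentConfig:
    """Tunable constants of the attachment algorithm."""

    core_codes: frozenset = DEFAULT_CORE_CODES
    lookback_days: int = 730
    coc_threshold: float = 0.10
    coc_comparator: str = "strict_greater"
    coc_mode: str = "patient"
    pediatric_age_cutoff: int = 19
    pediatric_hook: Callable | None = None

    def __post_init__(self):
        if not (0.0 < self.coc_threshold < 1.0):
            raise ValueError("coc_threshold must be in (0, 1)")
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive")


@dataclass(frozen=True)
class AttachmentResult:
    """The algorithm's verdict for one person."""

    patient_id: str
    category: str
    step: str
    provider_id: str | None = None
    provider_coc: float | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES or self.step not in STEPS:
            raise ValueError("invalid category or step")
        if (self.category == "attached") != (self.step in ATTACHED_STEPS):
            raise ValueError("category attached iff step is an attaching step")
        if self.step == "VIRTUAL" and self.provider_coc is None:
            raise ValueError("VIRTUAL attachment requires the provider's CoC")


@dataclass
class FlowReport:
    """Counts and percentages entering/leaving each hierarchy step."""

    cohort_n: int
    step_counts: dict = field(default_factory=dict)

    @property
    def attached_n(self) -> int:
        return sum(self.step_counts.get(s, 0) for s in ATTACHED_STEPS)

    @property
    def uncertain_n(self) -> int:
        return self.step_counts.get("NONE", 0)

    def pct(self, count: int) -> float:
        """Share of the cohort, in percent to one decimal (half-up)."""
        return share_pct(count, self.cohort_n)

    @property
    def attached_pct(self) -> float:
        return self.pct(self.attached_n)

    @property
    def uncertain_pct(self) -> float:
        return self.pct(self.uncertain_n)

    @property
    def remainder_after_chc_n(self) -> int:
        """Cohort members reaching the virtual-enrollment step."""
        return self.cohort_n - self.step_counts.get("PEM", 0) - self.step_counts.get("CHC", 0)

    @property
    def virtual_of_remainder_pct(self) -> float:
        return share_pct(self.step_counts.get("VIRTUAL", 0), self.remainder_after_chc_n)

    def to_dict(self) -> dict:
        return {
            "cohort_n": self.cohort_n,
            "step_counts": dict(self.step_counts),
            "step_pct": {s: self.pct(c) for s, c in self.step_counts.items()},
            "attached_n": self.attached_n,
            "attached_pct": self.attached_pct,
            "uncertain_n": self.uncertain_n,
            "uncertain_pct": self.uncertain_pct,
            "virtual_of_remainder_pct": self.virtual_of_remainder_pct,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"cohort: {self.cohort_n}"]
        entering = self.cohort_n
        for step in ("PEM", "CHC", "VIRTUAL", "PEDIATRIC"):
            c = self.step_counts.get(step, 0)
            if step == "PEDIATRIC" and c == 0:
                continue
            lines.append(f"  step {step:<9} entering {entering:>8}  attached {c:>8} ({self.pct(c):.1f}% of cohort)")
            entering -= c
        lines.append(f"  uncertainly attached: {self.uncertain_n} ({self.uncertain_pct:.1f}%)")
        lines.append(f"  attached overall:     {self.attached_n} ({self.attached_pct:.1f}%)")
        return "\n".join(lines)

    @classmethod
    def from_counts(cls, cohort_n: int, **step_counts: int) -> "FlowReport":
        unknown = set(step_counts) - set(STEPS)
        if unknown:
            raise ValueError(f"unknown steps: {sorted(unknown)}")
        return cls(cohort_n=cohort_n, step_counts=dict(step_counts))


def share_pct(count: int, total: int) -> float:
    """Percentage to one decimal, half-up — the printed-report convention."""
    if total == 0:
        return 0.0
    return round_half_up_1_exact(int(count), int(total))


def round_half_up_1_exact(num: int, den: int) -> float:
    """Exact-rational percentage num/den rounded half-up to one decimal."""
    from decimal import ROUND_HALF_UP, Decimal

    return float((Decimal(100 * num) / Decimal(den)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def attach_one(
    patient_id: str,
    index_date: pd.Timestamp,
    roster: pd.DataFrame,
    chc_visits: pd.DataFrame,
    enrollment,
    coc_lookup: Mapping[str, float],
    config: AttachmentConfig = AttachmentConfig(),
) -> AttachmentResult:
    """Classify a single person; reference path for the vectorized engine.

    ``enrollment`` is that person's :class:`~pcpattach.attribution.VirtualEnrollment`
    (or None for zero windowed visits); ``coc_lookup`` maps provider_id to
    its population-level CoC index.
    """
    index_date = pd.Timestamp(index_date)

    pem = active_roster_at(roster[roster["patient_id"] == patient_id], pd.Series({patient_id: index_date}))
    if len(pem):
        return AttachmentResult(patient_id, "attached", "PEM", provider_id=pem.iloc[0])

    lo = index_date - pd.Timedelta(days=config.lookback_days)
    mine = chc_visits[chc_visits["patient_id"] == patient_id]
    if ((mine["visit_date"] > lo) & (mine["visit_date"] <= index_date)).any():
        return AttachmentResult(patient_id, "attached", "CHC")

    if enrollment is not None and enrollment.provider_id is not None:
        if enrollment.provider_id not in coc_lookup:
            raise KeyError(f"provider {enrollment.provider_id} missing from CoC lookup")
        coc = coc_lookup[enrollment.provider_id]
        if classify_coc(coc, config.coc_threshold, config.coc_comparator) == "adequate":
            return AttachmentResult(
                patient_id, "attached", "VIRTUAL", provider_id=enrollment.provider_id, provider_coc=coc
            )
    return AttachmentResult(patient_id, "uncertainly_attached", "NONE")


def resolve_index_dates(
    persons: pd.DataFrame,
    survey: pd.DataFrame | None = None,
    policy: str = "fixed",
    fixed_date=None,
) -> pd.Series:
    """Per-person index dates under the chosen anchoring policy.

    ``policy="survey"``: each respondent's survey date; persons absent from
    the survey fall back to ``fixed_date`` (default: the latest survey date),
    so population-wide attribution stays computable. ``policy="fixed"``:
    everyone anchored at ``fixed_date``.
    """
    pids = persons["patient_id"]
    if policy == "fixed":
        if fixed_date is None:
            raise ValueError("fixed index policy requires a date")
        return pd.Series(pd.Timestamp(fixed_date), index=pids.tolist())
    if policy != "survey":
        raise ValueError("policy must be 'survey' or 'fixed'")
    if survey is None or survey.empty:
        raise ValueError("survey index policy requires survey data")
    fallback = pd.Timestamp(fixed_date) if fixed_date is not None else survey["survey_date"].max()
    per = survey.drop_duplicates("respondent_id").set_index("respondent_id")["survey_date"]
    out = per.reindex(pids).fillna(fallback)
    out.index = pids.tolist()
    return out


def run_attachment(
    data: Mapping[str, pd.DataFrame],
    index_dates: pd.Series,
    config: AttachmentConfig = AttachmentConfig(),
) -> tuple[pd.DataFrame, FlowReport]:
    """Run the full three-pass algorithm over a dataset bundle.

    ``data`` needs keys ``claims, roster, chc, persons`` (``hospital`` and
    ``survey`` are not consulted here). ``index_dates`` maps every cohort
    patient_id to its index date (see :func:`resolve_index_dates`).

    Pass 1 virtually enrolls the full population from windowed core visits;
    pass 2 computes every provider's CoC index over those same visits;
    pass 3 classifies each cohort member through the hierarchy. Returns the
    per-person results table (sorted by patient_id, row-order independent)
    and a :class:`FlowReport`.
    """
    persons = data["persons"]
    cohort = persons["patient_id"].tolist()
    missing_idx = [p for p in cohort if p not in index_dates.index]
    if missing_idx:
        raise ValueError(f"no index date for {len(missing_idx)} cohort member(s)")

    visits = dedup_daily(filter_core(data["claims"], config.core_codes))
    windowed = in_window_per_patient(visits, index_dates, config.lookback_days)

    enrollments = virtual_enroll_all(windowed)
    coc = compute_coc(enrollments, windowed, mode=config.coc_mode)
    adequate = {
        row.provider_id
        for row in coc.itertuples()
        if classify_coc(row.coc_index, config.coc_threshold, config.coc_comparator) == "adequate"
    }
    coc_by_provider = coc.set_index("provider_id")["coc_index"]

    pem_provider = active_roster_at(data["roster"], index_dates)

    chc = data["chc"].merge(
        index_dates.rename("index_date").rename_axis("patient_id").reset_index(),
        on="patient_id",
        how="inner",
    )
    lo = chc["index_date"] - pd.Timedelta(days=config.lookback_days)
    chc_in = set(chc.loc[(chc["visit_date"] > lo) & (chc["visit_date"] <= chc["index_date"]), "patient_id"])

    enr = enrollments.set_index("patient_id")

    res = pd.DataFrame({"patient_id": sorted(cohort)})
    res["step"] = "NONE"
    res["provider_id"] = None
    res["provider_coc"] = pd.NA

    is_pem = res["patient_id"].isin(pem_provider.index)
    res.loc[is_pem, "step"] = "PEM"
    res.loc[is_pem, "provider_id"] = pem_provider.reindex(res.loc[is_pem, "patient_id"]).to_numpy()

    is_chc = ~is_pem & res["patient_id"].isin(chc_in)
    res.loc[is_chc, "step"] = "CHC"

    rest = ~is_pem & ~is_chc
    enrolled_provider = enr["provider_id"].reindex(res["patient_id"])
    is_virtual = rest & enrolled_provider.isin(adequate).to_numpy()
    res.loc[is_virtual, "step"] = "VIRTUAL"
    vp = enrolled_provider[is_virtual.to_numpy()]
    res.loc[is_virtual, "provider_id"] = vp.to_numpy()
    res.loc[is_virtual, "provider_coc"] = coc_by_provider.reindex(vp).to_numpy()

    if config.pediatric_hook is not None:
        res = _apply_pediatric_hook(res, persons, index_dates, config)

    res["category"] = res["step"].map(
        lambda s: "attached" if s in ATTACHED_STEPS else "uncertainly_attached"
    )
    res = res[RESULT_COLUMNS].reset_index(drop=True)

    counts = res["step"].value_counts().to_dict()
    report = FlowReport.from_counts(len(res), **{s: int(counts.get(s, 0)) for s in STEPS if counts.get(s)})
    return res, report


def age_at(birth_date, on_date) -> int:
    """Completed years of age on a date."""
    b, d = pd.Timestamp(birth_date), pd.Timestamp(on_date)
    years = d.year - b.year - ((d.month, d.day) < (b.month, b.day))
    return int(years)


def pediatric_hook_apply(
    person: pd.Series,
    default: AttachmentResult,
    index_date,
    hook: Callable | None,
    age_cutoff: int = 19,
) -> AttachmentResult:
    """Delegate an uncertainly attached child to the pediatric algorithm.

    Identity when no hook is registered. The hook receives ``(person,
    default_result)`` and returns either a provider_id (str, meaning attach),
    or None (leave uncertain). Raises if the person is not under the cutoff
    or the default is not uncertain; hook exceptions propagate with context.
    """
    if default.category != "uncertainly_attached":
        raise ValueError("pediatric hook applies only to uncertainly attached defaults")
    if age_at(person["birth_date"], index_date) >= age_cutoff:
        raise ValueError(
            f"pediatric hook applied to person {person['patient_id']} aged >= {age_cutoff}"
        )
    if hook is None:
        return default
    try:
        provider = hook(person, default)
    except Exception as exc:  # re-raise with the person attached for triage
        raise RuntimeError(f"pediatric hook failed for {person['patient_id']}: {exc}") from exc
    if provider is None:
        return default
    return AttachmentResult(default.patient_id, "attached", "PEDIATRIC", provider_id=provider)


def _apply_pediatric_hook(
    res: pd.DataFrame, persons: pd.DataFrame, index_dates: pd.Series, config: AttachmentConfig
) -> pd.DataFrame:
    per = persons.set_index("patient_id")
    for i in res.index[res["step"] == "NONE"]:
        pid = res.at[i, "patient_id"]
        person = per.loc[pid]
        person = pd.concat([pd.Series({"patient_id": pid}), person])
        idx = index_dates[pid]
        if age_at(person["birth_date"], idx) >= config.pediatric_age_cutoff:
            continue
        default = AttachmentResult(pid, "uncertainly_attached", "NONE")
        out = pediatric_hook_apply(person, default, idx, config.pediatric_hook, config.pediatric_age_cutoff)
        if out.step == "PEDIATRIC":
            res.at[i, "step"] = "PEDIATRIC"
            res.at[i, "provider_id"] = out.provider_id
    return res


def audit_uncertain(
    results: pd.DataFrame,
    claims: pd.DataFrame,
    hospital: pd.DataFrame,
    index_dates: pd.Series,
    config: AttachmentConfig = AttachmentConfig(),
) -> pd.DataFrame:
    """Healthcare-use audit of the uncertainly attached.

    One row per uncertainly attached person: did they have any windowed core
    primary-care visit, and any windowed hospital-based use (ED visit or
    admission)? Uses the same per-person windows as attribution.
    """
    uncertain = results.loc[results["category"] == "uncertainly_attached", "patient_id"]
    visits = dedup_daily(filter_core(claims, config.core_codes))
    windowed = in_window_per_patient(visits, index_dates, config.lookback_days)
    have_core = set(windowed["patient_id"])

    hosp = hospital.rename(columns={"encounter_date": "service_date"})[["patient_id", "service_date"]]
    hosp_windowed = in_window_per_patient(hosp, index_dates, config.lookback_days)
    have_hosp = set(hosp_windowed["patient_id"])

    out = pd.DataFrame({"patient_id": sorted(uncertain)})
    out["any_core_visit"] = out["patient_id"].isin(have_core)
    out["any_hospital_use"] = out["patient_id"].isin(have_hosp)
    return out


def with_threshold(config: AttachmentConfig, threshold: float) -> AttachmentConfig:
    return replace(config, coc_threshold=threshold)
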