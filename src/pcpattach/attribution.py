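"""Virtual enrollment by plurality of visits, and the provider CoC index.

A non-rostered patient is *virtually enrolled* to the provider who received
the plurality of their windowed core visits. The provider continuity-of-care
(CoC) index guards against attributing patients to episodic, walk-in-style
practices: for each provider it is

    CoC = (# patients virtually enrolled to the provider)
          / (# unique patients the provider saw in the window)

A walk-in clinic physician sees many unique patients but is the plurality
provider for few of them, so their CoC is low; patients whose plurality
provider has a low CoC are not attached through virtual enrollment.

Ties in the plurality are broken by most recent visit to the tied provider,
then by lexicographically smallest provider id — deterministic and
independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

COC_MODES = ("patient", "visit")
COMPARATORS = ("strict_greater", "greater_equal")


@dataclass(frozen=True)
class VirtualEnrollment:
    patient_id: str
    provider_id: str | None
    visit_count_to_provider: int
    total_core_visits: int

    def __post_init__(self):
        if self.visit_count_to_provider > self.total_core_visits:
            raise ValueError("visit_count_to_provider exceeds total_core_visits")
        if (self.provider_id is None) != (self.total_core_visits == 0):
            raise ValueError("provider_id must be None exactly when there are no visits")


@dataclass(frozen=True)
class ProviderCoC:
    provider_id: str
    n_virtual: int
    n_unique_patients: int
    coc_index: float

    def __post_init__(self):
        if self.n_virtual > self.n_unique_patients:
            raise ValueError("n_virtual exceeds n_unique_patients")


def virtual_enroll(patient_visits: pd.DataFrame, patient_id: str | None = None) -> VirtualEnrollment:
    """Plurality provider for one patient's windowed core visits.

    Zero visits is a legal degenerate case (``provider_id=None, 0 of 0``)
    provided ``patient_id`` is supplied so the owner is known.
    """
    pids = patient_visits["patient_id"].unique()
    if len(pids) > 1:
        raise ValueError(f"visits from multiple patients: {sorted(pids)}")
    if patient_id is not None and len(pids) and pids[0] != patient_id:
        raise ValueError(f"visits belong to {pids[0]}, not {patient_id}")
    if len(patient_visits) == 0:
        if patient_id is None:
            raise ValueError("empty visits: pass patient_id for the zero-visit degenerate case")
        return VirtualEnrollment(patient_id, None, 0, 0)
    per = (
        patient_visits.groupby("provider_id")["service_date"]
        .agg(n="count", last="max")
        .reset_index()
    )
    per = per.sort_values(["n", "last", "provider_id"], ascending=[False, False, True])
    top = per.iloc[0]
    return VirtualEnrollment(
        patient_id=pids[0],
        provider_id=top["provider_id"],
        visit_count_to_provider=int(top["n"]),
        total_core_visits=int(len(patient_visits)),
    )


def virtual_enroll_all(visits: pd.DataFrame) -> pd.DataFrame:
    """Vectorized plurality enrollment for every patient with >=1 visit.

    Returns columns ``patient_id, provider_id, visit_count_to_provider,
    total_core_visits``; patients with zero windowed visits simply do not
    appear (they are unenrollable).
    """
    if visits.empty:
        return pd.DataFrame(
            columns=["patient_id", "provider_id", "visit_count_to_provider", "total_core_visits"]
        )
    per = (
        visits.groupby(["patient_id", "provider_id"])["service_date"]
        .agg(n="count", last="max")
        .reset_index()
    )
    per = per.sort_values(
        ["patient_id", "n", "last", "provider_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    chosen = per.groupby("patient_id", sort=True).first().reset_index()
    totals = visits.groupby("patient_id").size().rename("total_core_visits")
    out = chosen.merge(totals, on="patient_id")
    out = out.rename(columns={"n": "visit_count_to_provider"})
    out["visit_count_to_provider"] = out["visit_count_to_provider"].astype(int)
    out["total_core_visits"] = out["total_core_visits"].astype(int)
    return out[["patient_id", "provider_id", "visit_count_to_provider", "total_core_visits"]]


def compute_coc(
    enrollments: pd.DataFrame, windowed_visits: pd.DataFrame, mode: str = "patient"
) -> pd.DataFrame:
    """Provider CoC over the full population's windowed core visits.

    ``mode="patient"`` (primary): enrolled-patient count over unique-patient
    count. ``mode="visit"`` (sensitivity analysis): core visits made to the
    provider by its virtually enrolled patients over all core visits the
    provider received.

    Returns columns ``provider_id, n_virtual, n_unique_patients, coc_index``
    with one row per provider seen in ``windowed_visits``.
    """
    if mode not in COC_MODES:
        raise ValueError(f"mode must be one of {COC_MODES}")
    if windowed_visits.empty:
        return pd.DataFrame(columns=["provider_id", "n_virtual", "n_unique_patients", "coc_index"])

    seen_providers = set(windowed_visits["provider_id"])
    if len(enrollments):
        missing = set(enrollments["provider_id"]) - seen_providers
        if missing:
            raise ValueError(f"enrollment references providers absent from visits: {sorted(missing)[:5]}")

    uniq = (
        windowed_visits.groupby("provider_id")["patient_id"].nunique().rename("n_unique_patients")
    )
    nvirt = (
        enrollments.groupby("provider_id").size().rename("n_virtual")
        if len(enrollments)
        else pd.Series(dtype="int64", name="n_virtual")
    )
    out = pd.concat([uniq, nvirt], axis=1).fillna(0)
    out["n_virtual"] = out["n_virtual"].astype(int)
    out["n_unique_patients"] = out["n_unique_patients"].astype(int)

    if mode == "patient":
        out["coc_index"] = out["n_virtual"] / out["n_unique_patients"]
    else:
        pair = enrollments[["patient_id", "provider_id"]]
        own = windowed_visits.merge(pair, on=["patient_id", "provider_id"], how="inner")
        own_visits = own.groupby("provider_id").size().rename("own")
        all_visits = windowed_visits.groupby("provider_id").size().rename("all")
        ratio = pd.concat([own_visits, all_visits], axis=1).fillna(0)
        out["coc_index"] = (ratio["own"] / ratio["all"]).reindex(out.index).fillna(0.0)

    return out.rename_axis("provider_id").reset_index().sort_values("provider_id").reset_index(drop=True)


def classify_coc(coc_index: float, threshold: float = 0.10, comparator: str = "strict_greater") -> str:
    """``"adequate"`` or ``"low"`` continuity for one provider.

    Default comparator: adequate iff ``coc_index > threshold`` — a provider
    with CoC exactly at the threshold is low-continuity.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if comparator not in COMPARATORS:
        raise ValueError(f"comparator must be one of {COMPARATORS}")
    if comparator == "strict_greater":
        return "adequate" if coc_index > threshold else "low"
    return "adequate" if coc_index >= threshold else "low"
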