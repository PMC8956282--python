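"""Synthetic health-administrative-data generator.

Emulates the statistical structure the attachment algorithm assumes, with
known ground truth:

* a provider population mixing high-continuity practices with a few
  high-volume, walk-in-style providers;
* truly attached patients whose core visits concentrate on one usual
  provider — split into *regular* users (at least one usual-provider visit
  in the window, plus occasional stray visits, mostly to walk-in clinics)
  and *low* users (sparse visits, often none), with the regular share
  higher among the formally rostered;
* truly unattached patients with scattered episodic visits drawn
  preferentially from walk-in providers — who therefore accumulate many
  unique patients but few pluralities, making their CoC index low by
  construction;
* roster records covering a configurable share of the truly attached;
* CHC users drawn from the attached non-rostered pool (their primary care
  lives outside fee-for-service billing, so they emit no claims);
* survey self-report equal to the truth flipped with configurable
  misreport rates.

All randomness flows from one integer seed through a fixed stage-splitting
scheme (:data:`STAGES`), so adding a stage never perturbs earlier ones and
regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .admin_data import SCHEMAS, read_table, write_table
from .core_visits import DEFAULT_CORE_CODES

STAGES = (
    "patients",
    "survey_dates",
    "roster",
    "chc",
    "visits",
    "stray",
    "episodic",
    "hospital",
    "survey_answers",
    "noncore",
    "persons",
)

_FRACTION_FIELDS = (
    "walk_in_provider_fraction",
    "roster_coverage",
    "chc_fraction",
    "true_attached_fraction",
    "low_use_fraction_rostered",
    "low_use_fraction_unrostered",
    "stray_walk_in_pref",
    "episodic_walk_in_pref",
    "admission_fraction",
    "survey_misreport_yes_given_unattached",
    "survey_misreport_no_given_attached",
)
_RATE_FIELDS = (
    "mean_visits_usual",
    "mean_stray_visits",
    "mean_episodic_visits",
    "mean_visits_low",
    "hospital_rate_attached",
    "hospital_rate_unattached",
    "noncore_claim_rate",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic scenario.

    Roster coverage applies to the truly attached; the CHC fraction to the
    whole cohort. Visit counts are Poisson (regular users' usual-provider
    counts are zero-truncated: an attached patient in active care sees
    their provider at least once over the window).
    """

    n_patients: int = 10_000
    n_providers: int = 100
    walk_in_provider_fraction: float = 0.03
    roster_coverage: float = 0.814
    chc_fraction: float = 0.015
    true_attached_fraction: float = 0.948
    mean_visits_usual: float = 4.0
    mean_stray_visits: float = 2.0
    mean_episodic_visits: float = 0.9
    low_use_fraction_rostered: float = 0.2
    low_use_fraction_unrostered: float = 0.8
    mean_visits_low: float = 0.35
    stray_walk_in_pref: float = 0.85
    episodic_walk_in_pref: float = 0.8
    hospital_rate_attached: float = 0.25
    hospital_rate_unattached: float = 0.5
    admission_fraction: float = 0.2
    noncore_claim_rate: float = 0.3
    survey_misreport_yes_given_unattached: float = 0.25
    survey_misreport_no_given_attached: float = 0.02
    lookback_days: int = 730
    survey_start: str = "2016-10-01"
    survey_end: str = "2018-09-30"
    core_codes: tuple = tuple(sorted(DEFAULT_CORE_CODES))
    seed: int = 20201

    def __post_init__(self):
        if self.n_patients < 1 or self.n_providers < 1:
            raise ValueError("need n_patients >= 1 and n_providers >= 1")
        if self.true_attached_fraction == 0.0 and self.roster_coverage > 0.0:
            raise ValueError("infeasible: roster_coverage > 0 with no truly attached patients")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_visits_usual < 1.0:
            raise ValueError("mean_visits_usual is zero-truncated; needs mean >= 1")
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive")
        if pd.Timestamp(self.survey_end) < pd.Timestamp(self.survey_start):
            raise ValueError("survey_end before survey_start")

    @property
    def n_walk_in(self) -> int:
        return int(round(self.walk_in_provider_fraction * self.n_providers))

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["core_codes"] = list(self.core_codes)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "core_codes" in d:
            d["core_codes"] = tuple(sorted(d["core_codes"]))
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ScenarioConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class DatasetBundle:
    """The six administrative tables plus ground truth and provider roles."""

    persons: pd.DataFrame
    claims: pd.DataFrame
    roster: pd.DataFrame
    chc: pd.DataFrame
    hospital: pd.DataFrame
    survey: pd.DataFrame
    providers: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def data(self) -> dict:
        return {
            "persons": self.persons,
            "claims": self.claims,
            "roster": self.roster,
            "chc": self.chc,
            "hospital": self.hospital,
            "survey": self.survey,
        }

    def survey_index_dates(self) -> pd.Series:
        from .attachment import resolve_index_dates

        return resolve_index_dates(self.persons, self.survey, policy="survey")

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in SCHEMAS:
            write_table(getattr(self, name), directory / f"{name}.csv", name)
        if len(self.providers):
            self.providers.to_csv(directory / "providers.csv", index=False)
        if len(self.truth):
            self.truth.to_csv(directory / "truth.csv", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "DatasetBundle":
        directory = Path(directory)
        tables = {name: read_table(directory / f"{name}.csv", name) for name in SCHEMAS}
        providers = truth = pd.DataFrame()
        if (directory / "providers.csv").exists():
            providers = pd.read_csv(directory / "providers.csv", dtype={"provider_id": str})
        if (directory / "truth.csv").exists():
            truth = pd.read_csv(directory / "truth.csv", dtype={"patient_id": str, "usual_provider_id": str})
        return cls(providers=providers, truth=truth, **tables)



def _ns(dates) -> pd.DatetimeIndex:
    """Calendar-day dates as nanosecond datetimes (the table dialect's dtype)."""
    return pd.to_datetime(dates).astype("datetime64[ns]")

def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: np.random.default_rng(child) for name, child in zip(STAGES, children)}


def _dates_in_window(index_dates: np.ndarray, counts: np.ndarray, lookback: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Repeat per-patient index dates by counts; draw day offsets in [0, lookback)."""
    rep = np.repeat(index_dates, counts)
    offsets = rng.integers(0, lookback, size=rep.size)
    return rep - offsets.astype("timedelta64[D]"), rep


def generate(config: ScenarioConfig) -> DatasetBundle:
    """Generate a full dataset bundle with ground-truth labels.

    Raises ``ValueError`` for infeasible configurations (e.g. the CHC
    fraction exceeds the attached non-rostered pool, or attached patients
    exist but every provider is walk-in-style).
    """
    n = config.n_patients
    rng = _rngs(config.seed)
    lookback = config.lookback_days

    pad_p = max(5, len(str(n)))
    patient_ids = np.array([f"S{i:0{pad_p}d}" for i in range(1, n + 1)])
    pad_d = max(3, len(str(config.n_providers)))
    provider_ids = np.array([f"D{i:0{pad_d}d}" for i in range(1, config.n_providers + 1)])
    n_walk = config.n_walk_in
    is_walk_in = np.zeros(config.n_providers, dtype=bool)
    if n_walk:
        is_walk_in[-n_walk:] = True  # the last ids are the walk-in-style providers
    regular_idx = np.flatnonzero(~is_walk_in)
    walk_idx = np.flatnonzero(is_walk_in)

    r = rng["patients"]
    attached = r.random(n) < config.true_attached_fraction
    if attached.any() and regular_idx.size == 0:
        raise ValueError("infeasible: attached patients but no regular (non-walk-in) providers")
    usual = np.full(n, -1)
    if attached.any():
        usual[attached] = r.choice(regular_idx, size=int(attached.sum()))

    r = rng["roster"]
    rostered = attached & (r.random(n) < config.roster_coverage)

    r = rng["chc"]
    n_chc = int(round(config.chc_fraction * n))
    pool = np.flatnonzero(attached & ~rostered)
    if n_chc > pool.size:
        raise ValueError(
            f"infeasible: chc_fraction needs {n_chc} attached non-rostered patients, pool has {pool.size}"
        )
    chc_user = np.zeros(n, dtype=bool)
    if n_chc:
        chc_user[r.choice(pool, size=n_chc, replace=False)] = True
    usual[chc_user] = -1  # CHC users' primary care is outside fee-for-service billing

    # usage class: regular users are guaranteed >=1 usual visit; the regular
    # share is higher among the rostered (engaged patients get rostered)
    low_frac = np.where(rostered, config.low_use_fraction_rostered, config.low_use_fraction_unrostered)
    low_user = attached & ~chc_user & (rng["patients"].random(n) < low_frac)
    regular_user = attached & ~chc_user & ~low_user

    usage_class = np.where(
        ~attached, "episodic", np.where(chc_user, "chc", np.where(low_user, "low", "regular"))
    )

    r = rng["survey_dates"]
    start = np.datetime64(config.survey_start, "D")
    end = np.datetime64(config.survey_end, "D")
    span = int((end - start) / np.timedelta64(1, "D")) + 1
    survey_dates = start + r.integers(0, span, size=n).astype("timedelta64[D]")

    # --- usual-provider core visits -------------------------------------
    r = rng["visits"]
    n_usual = np.zeros(n, dtype=int)
    n_usual[regular_user] = 1 + r.poisson(config.mean_visits_usual - 1.0, size=int(regular_user.sum()))
    n_usual[low_user] = r.poisson(config.mean_visits_low, size=int(low_user.sum()))
    usual_dates, _ = _dates_in_window(survey_dates, n_usual, lookback, r)
    usual_pat = np.repeat(np.arange(n), n_usual)
    usual_prov = usual[usual_pat]

    # --- stray visits (regular users only, mostly to walk-ins) ----------
    r = rng["stray"]
    n_stray = np.zeros(n, dtype=int)
    n_stray[regular_user] = r.poisson(config.mean_stray_visits, size=int(regular_user.sum()))
    stray_pat = np.repeat(np.arange(n), n_stray)
    stray_prov = _pick_providers(
        r, stray_pat.size, walk_idx, regular_idx, config.stray_walk_in_pref
    )
    stray_dates, _ = _dates_in_window(survey_dates, n_stray, lookback, r)

    # --- episodic visits (unattached) ------------------------------------
    r = rng["episodic"]
    n_epi = np.zeros(n, dtype=int)
    n_epi[~attached] = r.poisson(config.mean_episodic_visits, size=int((~attached).sum()))
    epi_pat = np.repeat(np.arange(n), n_epi)
    epi_prov = _pick_providers(r, epi_pat.size, walk_idx, regular_idx, config.episodic_walk_in_pref)
    epi_dates, _ = _dates_in_window(survey_dates, n_epi, lookback, r)

    core_pat = np.concatenate([usual_pat, stray_pat, epi_pat])
    core_prov = np.concatenate([usual_prov, stray_prov, epi_prov])
    core_dates = np.concatenate([usual_dates, stray_dates, epi_dates])
    codes = np.array(config.core_codes)
    core_codes = codes[rng["visits"].integers(0, codes.size, size=core_pat.size)]

    # --- non-core / non-office claims (exercise the core filter) --------
    r = rng["noncore"]
    n_nc = r.poisson(config.noncore_claim_rate, size=n)
    nc_pat = np.repeat(np.arange(n), n_nc)
    nc_prov_idx = r.integers(0, config.n_providers, size=nc_pat.size)
    nc_dates, _ = _dates_in_window(survey_dates, n_nc, lookback, r)
    kind = r.integers(0, 3, size=nc_pat.size)
    nc_codes = np.where(kind == 0, "X999", codes[r.integers(0, codes.size, size=nc_pat.size)])
    nc_setting = np.select(
        [kind == 0, kind == 1], ["office", "emergency_department"], default="nursing_home"
    )

    claims = pd.DataFrame(
        {
            "patient_id": np.concatenate([patient_ids[core_pat], patient_ids[nc_pat]]),
            "provider_id": np.concatenate([provider_ids[core_prov], provider_ids[nc_prov_idx]]),
            "service_date": _ns(np.concatenate([core_dates, nc_dates])),
            "service_code": np.concatenate([core_codes, nc_codes]),
            "setting": np.concatenate([np.full(core_pat.size, "office"), nc_setting]),
        }
    )

    # --- roster ----------------------------------------------------------
    r = rng["roster"]
    ros_idx = np.flatnonzero(rostered)
    back = lookback + 1 + r.integers(0, 1500, size=ros_idx.size)
    roster = pd.DataFrame(
        {
            "patient_id": patient_ids[ros_idx],
            "provider_id": provider_ids[usual[ros_idx]],
            "start_date": _ns(survey_dates[ros_idx] - back.astype("timedelta64[D]")),
            "end_date": pd.NaT,
        }
    )

    # --- CHC visits -------------------------------------------------------
    r = rng["chc"]
    chc_idx = np.flatnonzero(chc_user)
    n_chc_visits = 1 + r.poisson(1.0, size=chc_idx.size)
    chc_dates, _ = _dates_in_window(survey_dates[chc_idx], n_chc_visits, lookback, r)
    chc_df = pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids[chc_idx], n_chc_visits),
            "visit_date": _ns(chc_dates),
        }
    )

    # --- hospital-based use ----------------------------------------------
    r = rng["hospital"]
    hosp_rate = np.where(attached, config.hospital_rate_attached, config.hospital_rate_unattached)
    n_hosp = r.poisson(hosp_rate)
    hosp_pat = np.repeat(np.arange(n), n_hosp)
    hosp_dates, _ = _dates_in_window(survey_dates, n_hosp, lookback, r)
    hosp_type = np.where(r.random(hosp_pat.size) < config.admission_fraction, "admission", "ed_visit")
    hospital = pd.DataFrame(
        {
            "patient_id": patient_ids[hosp_pat],
            "encounter_date": _ns(hosp_dates),
            "encounter_type": hosp_type,
        }
    )

    # --- survey (truth flipped with the misreport rates) -----------------
    r = rng["survey_answers"]
    u = r.random(n)
    has_pcp = np.where(
        attached,
        u >= config.survey_misreport_no_given_attached,
        u < config.survey_misreport_yes_given_unattached,
    )
    ages = rng["persons"].integers(16, 91, size=n)
    survey = pd.DataFrame(
        {
            "respondent_id": patient_ids,
            "survey_date": _ns(survey_dates),
            "has_pcp": has_pcp,
            "age_years": ages.astype("int64"),
        }
    )

    # --- persons ----------------------------------------------------------
    r = rng["persons"]
    birth_offset = ages * 365 + r.integers(0, 365, size=n)
    persons = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "birth_date": _ns(survey_dates - birth_offset.astype("timedelta64[D]")),
            "sex": np.where(r.random(n) < 0.5, "F", "M"),
        }
    )

    providers = pd.DataFrame({"provider_id": provider_ids, "is_walk_in": is_walk_in})
    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "truly_attached": attached,
            "usual_provider_id": np.where(usual >= 0, provider_ids[np.clip(usual, 0, None)], ""),
            "rostered": rostered,
            "chc_user": chc_user,
            "usage_class": usage_class,
        }
    )

    return DatasetBundle(
        persons=persons,
        claims=claims,
        roster=roster,
        chc=chc_df,
        hospital=hospital,
        survey=survey,
        providers=providers,
        truth=truth,
    )


def _pick_providers(rng, size: int, walk_idx: np.ndarray, regular_idx: np.ndarray, walk_pref: float) -> np.ndarray:
    """Walk-in provider with probability ``walk_pref`` (uniform within group)."""
    if size == 0:
        return np.empty(0, dtype=int)
    if walk_idx.size == 0:
        return rng.choice(regular_idx, size=size)
    if regular_idx.size == 0:
        return rng.choice(walk_idx, size=size)
    to_walk = rng.random(size) < walk_pref
    out = np.empty(size, dtype=int)
    out[to_walk] = rng.choice(walk_idx, size=int(to_walk.sum()))
    out[~to_walk] = rng.choice(regular_idx, size=int((~to_walk).sum()))
    return out


def preset_paper_like(n_patients: int = 10_000, seed: int = 20201) -> ScenarioConfig:
    """The study-population preset.

    Defaults reproduce the step marginals of a large rostered primary-care
    system: ~94.8% of people reporting a PCP, ~81.4% of the cohort caught by
    formal enrollment (0.948 x 0.859 roster coverage of the attached), 1.5%
    by CHC use, and roughly a third of the remainder virtually enrolled to
    an adequate-continuity provider, for ~88.6% attached overall.
    """
    return ScenarioConfig(n_patients=n_patients, roster_coverage=0.859, seed=seed)


def preset_full_separation(base: ScenarioConfig | None = None) -> ScenarioConfig:
    """Fully separated variant: behaviour determines attachment exactly.

    No misreporting, no stray or episodic visits, no walk-in providers, and
    every attached patient in active care (>=1 usual-provider visit). Under
    this configuration the algorithm recovers ground truth exactly.
    """
    base = base if base is not None else preset_paper_like()
    return replace(
        base,
        walk_in_provider_fraction=0.0,
        mean_stray_visits=0.0,
        mean_episodic_visits=0.0,
        low_use_fraction_rostered=0.0,
        low_use_fraction_unrostered=0.0,
        survey_misreport_yes_given_unattached=0.0,
        survey_misreport_no_given_attached=0.0,
    )


def preset_degraded(level: float, n_patients: int = 10_000, seed: int = 20201) -> ScenarioConfig:
    """Interpolate the degradation path from full separation to the preset.

    ``level`` in [0, 1] linearly scales the misreport rates, stray and
    episodic visit rates, low-use shares and walk-in provider fraction from
    zero (full separation; perfect recovery) up to the preset defaults.
    """
    if not (0.0 <= level <= 1.0):
        raise ValueError("level must be in [0, 1]")
    base = preset_paper_like(n_patients=n_patients, seed=seed)
    sep = preset_full_separation(base)
    scaled = {
        name: (1 - level) * getattr(sep, name) + level * getattr(base, name)
        for name in (
            "walk_in_provider_fraction",
            "mean_stray_visits",
            "mean_episodic_visits",
            "low_use_fraction_rostered",
            "low_use_fraction_unrostered",
            "survey_misreport_yes_given_unattached",
            "survey_misreport_no_given_attached",
        )
    }
    return replace(base, **scaled)
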