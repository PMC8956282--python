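"""Reduce raw claims to deduplicated core primary-care visits in a window.

A *core visit* is a claim whose service code is on the configured
comprehensive-primary-care list and that was billed in an office setting
(ED and nursing-home encounter claims never attribute a patient to a PCP).
At most one visit per patient per provider per day is counted, and only
visits inside the lookback window — by default the two years (730 days)
ending on the index date — enter attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Toy default service-code list for comprehensive primary care. The real
#: list is jurisdiction-specific configuration; any non-empty set works.
DEFAULT_CORE_CODES = frozenset({"A001", "A003", "A007", "K013"})

VISIT_COLUMNS = ["patient_id", "provider_id", "service_date"]


@dataclass(frozen=True)
class WindowSpec:
    """Lookback window ``(index_date - lookback_days, index_date]``."""

    index_date: pd.Timestamp
    lookback_days: int = 730

    def __post_init__(self):
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive")
        object.__setattr__(self, "index_date", pd.Timestamp(self.index_date))

    @property
    def start_exclusive(self) -> pd.Timestamp:
        return self.index_date - pd.Timedelta(days=self.lookback_days)


def filter_core(claims: pd.DataFrame, core_codes) -> pd.DataFrame:
    """Retain office-setting claims whose service code is on the core list."""
    core_codes = frozenset(core_codes)
    if not core_codes:
        raise ValueError("core_codes must be non-empty")
    mask = claims["service_code"].isin(core_codes) & (claims["setting"] == "office")
    return claims[mask]


def dedup_daily(claims: pd.DataFrame) -> pd.DataFrame:
    """One core visit per distinct (patient, provider, service day); idempotent."""
    return (
        claims[VISIT_COLUMNS]
        .drop_duplicates(subset=VISIT_COLUMNS)
        .reset_index(drop=True)
    )


def in_window(visits: pd.DataFrame, window: WindowSpec) -> pd.DataFrame:
    """Visits with ``index_date - lookback < service_date <= index_date``."""
    d = visits["service_date"]
    mask = (d > window.start_exclusive) & (d <= window.index_date)
    return visits[mask]


def in_window_per_patient(
    visits: pd.DataFrame, index_dates: pd.Series, lookback_days: int = 730
) -> pd.DataFrame:
    """Apply each patient's own lookback window.

    ``index_dates`` maps patient_id -> index Timestamp. Visits by patients
    without an index date are dropped. Same half-open convention as
    :func:`in_window`.
    """
    if lookback_days <= 0:
        raise ValueError("lookback_days must be positive")
    idx = index_dates.rename("index_date").rename_axis("patient_id").reset_index()
    merged = visits.merge(idx, on="patient_id", how="inner")
    lo = merged["index_date"] - pd.Timedelta(days=lookback_days)
    mask = (merged["service_date"] > lo) & (merged["service_date"] <= merged["index_date"])
    return merged.loc[mask, list(visits.columns)].reset_index(drop=True)
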