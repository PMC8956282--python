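"""Independent brute-force reference implementations used as test oracles.

Everything here is plain-Python row scanning and counting — deliberately
naive, shared by the unit and acceptance suites, and kept free of the
library code paths it checks.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import pandas as pd


def brute_filter_core(rows: list[dict], core_codes: set) -> list[dict]:
    return [r for r in rows if r["service_code"] in core_codes and r["setting"] == "office"]


def brute_distinct_visits(rows: list[dict]) -> set[tuple]:
    return {(r["patient_id"], r["provider_id"], r["service_date"]) for r in rows}


def brute_in_window(rows: list[dict], index_date, lookback_days: int) -> list[dict]:
    idx = pd.Timestamp(index_date)
    lo = idx - pd.Timedelta(days=lookback_days)
    return [r for r in rows if lo < pd.Timestamp(r["service_date"]) <= idx]


def brute_plurality(visits: list[tuple]) -> str | None:
    """Plurality provider from (provider_id, date) pairs.

    Ties broken by most recent visit to the tied provider, then smallest
    provider id — implemented as an explicit max over a sort key.
    """
    if not visits:
        return None
    count: Counter = Counter(p for p, _ in visits)
    last: dict = {}
    for p, d in visits:
        d = pd.Timestamp(d)
        last[p] = max(last.get(p, d), d)
    return max(count, key=lambda p: (count[p], last[p], _NegStr(p)))


class _NegStr:
    """Reverses string ordering so max() prefers the lexicographically smallest."""

    def __init__(self, s):
        self.s = s

    def __lt__(self, other):
        return self.s > other.s

    def __eq__(self, other):
        return self.s == other.s


def brute_coc(visit_rows: list[dict]) -> dict[str, tuple[int, int, float]]:
    """provider -> (n_virtual, n_unique, coc) from patient/provider/date rows."""
    by_patient: dict[str, list[tuple]] = defaultdict(list)
    uniques: dict[str, set] = defaultdict(set)
    for r in visit_rows:
        by_patient[r["patient_id"]].append((r["provider_id"], r["service_date"]))
        uniques[r["provider_id"]].add(r["patient_id"])
    virtual: Counter = Counter(brute_plurality(v) for v in by_patient.values())
    return {
        prov: (virtual.get(prov, 0), len(pats), virtual.get(prov, 0) / len(pats))
        for prov, pats in uniques.items()
    }


def brute_attach(
    patient_ids: list[str],
    index_dates: dict,
    roster_rows: list[dict],
    chc_rows: list[dict],
    claim_rows: list[dict],
    core_codes: set,
    lookback_days: int = 730,
    threshold: float = 0.10,
    comparator: str = "strict_greater",
) -> dict[str, str]:
    """Straight-line re-implementation of the three hierarchy rules.

    Returns patient_id -> step in {PEM, CHC, VIRTUAL, NONE}.
    """
    visit_rows = [
        dict(r) for r in brute_filter_core(claim_rows, core_codes)
    ]
    seen = set()
    deduped = []
    for r in visit_rows:
        key = (r["patient_id"], r["provider_id"], pd.Timestamp(r["service_date"]))
        if key not in seen:
            seen.add(key)
            deduped.append(r)
    windowed = [
        r
        for r in deduped
        if r["patient_id"] in index_dates
        and index_dates[r["patient_id"]] - pd.Timedelta(days=lookback_days)
        < pd.Timestamp(r["service_date"])
        <= index_dates[r["patient_id"]]
    ]
    coc = brute_coc(windowed)
    by_patient: dict[str, list[tuple]] = defaultdict(list)
    for r in windowed:
        by_patient[r["patient_id"]].append((r["provider_id"], r["service_date"]))

    out = {}
    for pid in patient_ids:
        idx = index_dates[pid]
        pem = False
        for r in roster_rows:
            if r["patient_id"] != pid:
                continue
            end = r["end_date"]
            open_end = end is None or pd.isna(end)
            if pd.Timestamp(r["start_date"]) <= idx and (open_end or pd.Timestamp(end) >= idx):
                pem = True
        if pem:
            out[pid] = "PEM"
            continue
        lo = idx - pd.Timedelta(days=lookback_days)
        if any(
            r["patient_id"] == pid and lo < pd.Timestamp(r["visit_date"]) <= idx for r in chc_rows
        ):
            out[pid] = "CHC"
            continue
        plur = brute_plurality(by_patient.get(pid, []))
        if plur is not None:
            c = coc[plur][2]
            adequate = c > threshold if comparator == "strict_greater" else c >= threshold
            if adequate:
                out[pid] = "VIRTUAL"
                continue
        out[pid] = "NONE"
    return out


def brute_confusion(results_rows: list[dict], survey_rows: list[dict]) -> tuple[int, int, int, int]:
    verdict = {r["patient_id"]: r["category"] for r in results_rows}
    tp = fp = fn = tn = 0
    for s in survey_rows:
        v = verdict.get(s["respondent_id"])
        if v is None:
            continue
        pos, ref = v == "attached", bool(s["has_pcp"])
        tp += pos and ref
        fp += pos and not ref
        fn += (not pos) and ref
        tn += (not pos) and not ref
    return tp, fp, fn, tn


def int_pct_half_up(num: int, den: int) -> float:
    """Percentage to one decimal via pure integer arithmetic, half-up."""
    q, r = divmod(1000 * num, den)
    if 2 * r >= den:
        q += 1
    return q / 10
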