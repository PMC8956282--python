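import numpy as np
import pandas as pd
import pytest

from pcpattach.attachment import (
    AttachmentConfig,
    AttachmentResult,
    FlowReport,
    age_at,
    attach_one,
    audit_uncertain,
    pediatric_hook_apply,
    resolve_index_dates,
    run_attachment,
    with_threshold,
)
from pcpattach.attribution import VirtualEnrollment
from pcpattach.synthetic import ScenarioConfig, generate

from _oracles import brute_attach

INDEX = pd.Timestamp("2018-01-01")
EMPTY_ROSTER = pd.DataFrame(columns=["patient_id", "provider_id", "start_date", "end_date"])
EMPTY_CHC = pd.DataFrame(columns=["patient_id", "visit_date"])


def roster_row(pid, prov, start="2015-01-01", end=None):
    return pd.DataFrame(
        {
            "patient_id": [pid],
            "provider_id": [prov],
            "start_date": [pd.Timestamp(start)],
            "end_date": [pd.Timestamp(end) if end else pd.NaT],
        }
    )


def test_rostered_patient_with_zero_visits_is_pem_attached():
    res = attach_one("P1", INDEX, roster_row("P1", "D1"), EMPTY_CHC, None, {})
    assert (res.category, res.step, res.provider_id) == ("attached", "PEM", "D1")


def test_low_coc_plurality_provider_leaves_patient_uncertain():
    enr = VirtualEnrollment("P1", "D9", 4, 5)
    res = attach_one("P1", INDEX, EMPTY_ROSTER, EMPTY_CHC, enr, {"D9": 0.05})
    assert (res.category, res.step) == ("uncertainly_attached", "NONE")


def test_chc_fires_before_virtual_even_when_virtual_would_attach():
    chc = pd.DataFrame({"patient_id": ["P1"], "visit_date": [INDEX - pd.Timedelta(days=100)]})
    enr = VirtualEnrollment("P1", "D9", 4, 5)
    res = attach_one("P1", INDEX, EMPTY_ROSTER, chc, enr, {"D9": 0.9})
    assert res.step == "CHC"
    # hierarchy order against brute-force rule evaluation
    assert (
        brute_attach(
            ["P1"],
            {"P1": INDEX},
            [],
            [{"patient_id": "P1", "visit_date": INDEX - pd.Timedelta(days=100)}],
            [
                {"patient_id": "P1", "provider_id": "D9", "service_date": INDEX - pd.Timedelta(days=d), "service_code": "A001", "setting": "office"}
                for d in range(1, 6)
            ],
            {"A001"},
        )["P1"]
        == "CHC"
    )


def test_missing_coc_for_enrolled_provider_raises():
    enr = VirtualEnrollment("P1", "D9", 1, 1)
    with pytest.raises(KeyError):
        attach_one("P1", INDEX, EMPTY_ROSTER, EMPTY_CHC, enr, {})


def test_invalid_result_combinations_rejected():
    with pytest.raises(ValueError):
        AttachmentResult("P1", "attached", "NONE")
    with pytest.raises(ValueError):
        AttachmentResult("P1", "uncertainly_attached", "PEM")
    with pytest.raises(ValueError):
        AttachmentResult("P1", "attached", "VIRTUAL", provider_id="D1", provider_coc=None)


def test_engine_matches_straight_line_reimplementation():
    bundle = generate(ScenarioConfig(n_patients=500, n_providers=10, walk_in_provider_fraction=0.2, seed=101))
    idx = bundle.survey_index_dates()
    config = AttachmentConfig(core_codes=frozenset(ScenarioConfig().core_codes))
    results, flow = run_attachment(bundle.data(), idx, config)

    expected = brute_attach(
        bundle.persons["patient_id"].tolist(),
        idx.to_dict(),
        bundle.roster.to_dict("records"),
        bundle.chc.to_dict("records"),
        bundle.claims.to_dict("records"),
        set(ScenarioConfig().core_codes),
    )
    got = results.set_index("patient_id")["step"].to_dict()
    assert got == expected
    for step, count in pd.Series(list(expected.values())).value_counts().items():
        assert flow.step_counts.get(step, 0) == count


def test_partition_and_flow_counts(midsize_run):
    _, _, results, flow = midsize_run
    assert len(results) == flow.cohort_n
    assert flow.attached_n + flow.uncertain_n == flow.cohort_n
    assert sum(flow.step_counts.values()) == flow.cohort_n
    assert set(results["category"]) <= {"attached", "uncertainly_attached"}
    assert (results["category"].value_counts().get("attached", 0)) == flow.attached_n


def test_all_rostered_cohort_attaches_entirely_at_pem():
    persons = pd.DataFrame(
        {"patient_id": ["P1", "P2"], "birth_date": pd.Timestamp("1980-06-01"), "sex": "F"}
    )
    roster = pd.concat([roster_row("P1", "D1"), roster_row("P2", "D1")], ignore_index=True)
    data = {
        "persons": persons,
        "roster": roster,
        "claims": pd.DataFrame(columns=["patient_id", "provider_id", "service_date", "service_code", "setting"]),
        "chc": EMPTY_CHC,
    }
    idx = resolve_index_dates(persons, policy="fixed", fixed_date=INDEX)
    results, flow = run_attachment(data, idx)
    assert flow.step_counts == {"PEM": 2}
    assert flow.attached_pct == 100.0


def test_empty_cohort_yields_empty_results_and_zero_flow():
    persons = pd.DataFrame(columns=["patient_id", "birth_date", "sex"])
    data = {
        "persons": persons,
        "roster": EMPTY_ROSTER,
        "claims": pd.DataFrame(columns=["patient_id", "provider_id", "service_date", "service_code", "setting"]),
        "chc": EMPTY_CHC,
    }
    results, flow = run_attachment(data, pd.Series(dtype="datetime64[ns]"))
    assert len(results) == 0
    assert flow.cohort_n == 0 and flow.attached_n == 0 and flow.uncertain_n == 0


def test_results_are_invariant_to_input_row_order(tiny_bundle):
    idx = tiny_bundle.survey_index_dates()
    base, _ = run_attachment(tiny_bundle.data(), idx)
    rng = np.random.default_rng(0)
    shuffled = {
        name: df.sample(frac=1.0, random_state=int(rng.integers(1 << 16))).reset_index(drop=True)
        for name, df in tiny_bundle.data().items()
    }
    again, _ = run_attachment(shuffled, idx)
    pd.testing.assert_frame_equal(base, again)


def test_adding_claims_never_changes_a_pem_attached_person(tiny_bundle):
    idx = tiny_bundle.survey_index_dates()
    base, _ = run_attachment(tiny_bundle.data(), idx)
    pem_ids = set(base.loc[base["step"] == "PEM", "patient_id"])
    some = sorted(pem_ids)[:5]
    extra = pd.DataFrame(
        {
            "patient_id": some,
            "provider_id": "D012",
            "service_date": idx[some].values - pd.Timedelta(days=3),
            "service_code": "A001",
            "setting": "office",
        }
    )
    data = dict(tiny_bundle.data())
    data["claims"] = pd.concat([data["claims"], extra], ignore_index=True)
    after, _ = run_attachment(data, idx)
    merged = base.merge(after, on="patient_id", suffixes=("_a", "_b"))
    pem = merged[merged["patient_id"].isin(pem_ids)]
    assert (pem["step_a"] == pem["step_b"]).all()
    assert (pem["provider_id_a"] == pem["provider_id_b"]).all()


def test_removing_roster_records_only_moves_people_down_the_hierarchy(tiny_bundle):
    idx = tiny_bundle.survey_index_dates()
    base, _ = run_attachment(tiny_bundle.data(), idx)
    data = dict(tiny_bundle.data())
    data["roster"] = data["roster"].iloc[: len(data["roster"]) // 2]
    after, _ = run_attachment(data, idx)
    order = {"PEM": 0, "CHC": 1, "VIRTUAL": 2, "PEDIATRIC": 3, "NONE": 4}
    merged = base.merge(after, on="patient_id", suffixes=("_a", "_b"))
    assert (merged["step_b"].map(order) >= merged["step_a"].map(order)).all()


def test_attached_set_shrinks_as_threshold_rises(midsize_run):
    bundle, idx, _, _ = midsize_run
    sets = []
    for t in (0.05, 0.10, 0.25, 0.60):
        res, _ = run_attachment(bundle.data(), idx, with_threshold(AttachmentConfig(), t))
        sets.append(set(res.loc[res["category"] == "attached", "patient_id"]))
    for small, big in zip(sets[1:], sets[:-1]):
        assert small <= big


def test_audit_flags_match_per_person_brute_scan(tiny_bundle):
    idx = tiny_bundle.survey_index_dates()
    results, _ = run_attachment(tiny_bundle.data(), idx)
    audit = audit_uncertain(results, tiny_bundle.claims, tiny_bundle.hospital, idx)
    uncertain = set(results.loc[results["category"] == "uncertainly_attached", "patient_id"])
    assert set(audit["patient_id"]) == uncertain
    core_codes = AttachmentConfig().core_codes
    for row in audit.itertuples():
        pid = row.patient_id
        lo = idx[pid] - pd.Timedelta(days=730)
        mine = tiny_bundle.claims[tiny_bundle.claims["patient_id"] == pid]
        has_core = (
            mine["service_code"].isin(core_codes)
            & (mine["setting"] == "office")
            & (mine["service_date"] > lo)
            & (mine["service_date"] <= idx[pid])
        ).any()
        hosp = tiny_bundle.hospital[tiny_bundle.hospital["patient_id"] == pid]
        has_hosp = ((hosp["encounter_date"] > lo) & (hosp["encounter_date"] <= idx[pid])).any()
        assert row.any_core_visit == has_core
        assert row.any_hospital_use == has_hosp


CHILD = pd.Series({"patient_id": "K1", "birth_date": pd.Timestamp("2005-03-01")})
ADULT = pd.Series({"patient_id": "A1", "birth_date": pd.Timestamp("1970-03-01")})
UNCERTAIN_K = AttachmentResult("K1", "uncertainly_attached", "NONE")


def test_pediatric_hook_identity_when_unset():
    assert pediatric_hook_apply(CHILD, UNCERTAIN_K, INDEX, None) == UNCERTAIN_K


def test_pediatric_hook_attaches_with_step_pediatric():
    out = pediatric_hook_apply(CHILD, UNCERTAIN_K, INDEX, lambda person, default: "D7")
    assert (out.category, out.step, out.provider_id) == ("attached", "PEDIATRIC", "D7")


def test_pediatric_hook_rejects_adults_and_attached_defaults():
    with pytest.raises(ValueError):
        pediatric_hook_apply(ADULT, AttachmentResult("A1", "uncertainly_attached", "NONE"), INDEX, None)
    with pytest.raises(ValueError):
        pediatric_hook_apply(CHILD, AttachmentResult("K1", "attached", "PEM"), INDEX, None)


def test_pediatric_hook_errors_carry_person_context():
    def boom(person, default):
        raise RuntimeError("no data")

    with pytest.raises(RuntimeError, match="K1"):
        pediatric_hook_apply(CHILD, UNCERTAIN_K, INDEX, boom)


def test_run_attachment_applies_pediatric_hook_to_uncertain_children():
    persons = pd.DataFrame(
        {
            "patient_id": ["K1", "A1"],
            "birth_date": [pd.Timestamp("2010-01-01"), pd.Timestamp("1970-01-01")],
            "sex": ["F", "M"],
        }
    )
    data = {
        "persons": persons,
        "roster": EMPTY_ROSTER,
        "claims": pd.DataFrame(columns=["patient_id", "provider_id", "service_date", "service_code", "setting"]),
        "chc": EMPTY_CHC,
    }
    idx = resolve_index_dates(persons, policy="fixed", fixed_date=INDEX)
    config = AttachmentConfig(pediatric_hook=lambda person, default: "D5")
    results, flow = run_attachment(data, idx, config)
    by_id = results.set_index("patient_id")
    assert by_id.loc["K1", "step"] == "PEDIATRIC"
    assert by_id.loc["A1", "step"] == "NONE"
    assert flow.step_counts == {"PEDIATRIC": 1, "NONE": 1}


def test_age_at_counts_completed_years():
    assert age_at("2000-06-15", "2019-06-14") == 18
    assert age_at("2000-06-15", "2019-06-15") == 19


def test_flow_report_percentage_arithmetic():
    flow = FlowReport.from_counts(200, PEM=150, CHC=10, VIRTUAL=20, NONE=20)
    assert flow.attached_n == 180
    assert flow.attached_pct == 90.0
    assert flow.uncertain_pct == 10.0
    assert flow.remainder_after_chc_n == 40
    assert flow.virtual_of_remainder_pct == 50.0
    with pytest.raises(ValueError):
        FlowReport.from_counts(10, BOGUS=1)
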