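# Methods

## The attribution model

`pcpattach` operationalizes "having a primary care provider" from three
administrative signals, evaluated as a strict hierarchy: formal enrollment
(rostering), community health centre use, and plurality-of-visits virtual
enrollment gated by a provider continuity-of-care (CoC) index. The ordering
encodes trust in the signals: rostering is the payment system's own record
of attachment and needs no visits at all; CHC encounters identify patients
whose primary care is delivered outside fee-for-service billing; billing
claims are consulted only for everyone else. The first satisfied step fires
and later steps are never consulted, so a rostered patient's claims can
never change their verdict.

Key modelling assumptions:

* **Point-in-time rostering.** A roster interval attaches a person iff it
  covers the index date, not "any time in the window" — enrollment is read
  as the system's *current* attachment state. Overlapping intervals (an
  integrity finding) are resolved by keeping the latest start date.
* **Core visits only.** Attribution counts only services on a configured
  comprehensive-primary-care code list, billed in an office setting. ED and
  nursing-home encounter claims are excluded: a physician seen only in
  those settings is not acting as the patient's PCP. At most one visit per
  patient–provider–day counts.
* **Half-open window.** The lookback window is `(t − 730 d, t]`: a visit on
  the index date counts, a visit exactly 730 days earlier does not. "Two
  years" is 730 days; leap-day drift is accepted. For survey validation the
  index date is each respondent's survey date; for population application a
  single fixed date. Persons without a survey date under the survey policy
  fall back to the latest survey date, so population-wide CoC denominators
  stay computable.
* **Population-level CoC.** Virtual enrollment and CoC are computed over
  the full population's windowed visits (every patient with ≥ 1 visit is
  the numerator of exactly one provider, rostered or not); the cohort being
  classified is then judged against these population-level values. The
  primary CoC definition is the patient-count ratio (enrolled patients over
  unique patients seen). A visit-based alternative — the provider's core
  visits coming from its own enrollees over all its core visits — is
  available as `coc_mode="visit"` for sensitivity analysis; the two agree
  in ranking providers but not numerically.
* **Ties.** Plurality ties break by most recent visit to the tied provider
  (the most recent relationship wins), then smallest provider id. This is
  deterministic and row-order independent; results are byte-identical
  across input permutations.
* **Threshold comparator.** Default `strict_greater`: a provider with CoC
  exactly at the 10 % threshold is low-continuity and does not attach its
  enrollees. The inclusive comparator is available because with exact ties
  the choice matters; with continuous data it is measure-zero.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `lookback_days` | 730 | attribution window length (days) |
| `coc_threshold` | 0.10 | minimum provider CoC for virtual attachment (0.25 is the standard sensitivity cut-point) |
| `coc_comparator` | `strict_greater` | adequacy at exactly the threshold |
| `coc_mode` | `patient` | patient-count vs visit-count CoC |
| `core_codes` | 4-code toy list | jurisdiction-specific configuration |
| `pediatric_age_cutoff` | 19 | hook eligibility for population application |

The pediatric algorithm itself lives in external work; the hook receives
`(person, default_result)` and may return a provider id. With no hook the
engine is the pure three-step adult algorithm.

## The synthetic generator

The generator emulates the joint structure the algorithm relies on, not any
real person's data. One seed drives a fixed stage-splitting scheme
(`SeedSequence.spawn`, one child stream per stage), so regeneration is
byte-identical and adding a stage never perturbs earlier ones.

Structure and defaults (all configurable via `ScenarioConfig`):

* ~94.8 % of patients are truly attached (`true_attached_fraction`),
  matching the self-report rate large population surveys find.
* Roster coverage 0.814 of the truly attached; the study-population preset
  (`preset_paper_like`) raises it to 0.859 so the *cohort-level* rostered
  share lands at 0.948 × 0.859 ≈ 81.4 %.
* CHC users (1.5 % of the cohort) are drawn from the attached non-rostered
  pool and emit no billing claims — their care is salaried, outside
  fee-for-service data. They receive 1 + Poisson(1) CHC visits in window.
* Attached usage is heterogeneous: *regular* users make
  1 + Poisson(`mean_visits_usual` − 1) visits to their usual provider
  (zero-truncated: active patients are seen at least once in two years)
  plus Poisson(`mean_stray_visits`) stray visits, 85 % to walk-in
  providers; *low* users make Poisson(0.35) usual visits and no strays.
  The regular share is 80 % among the rostered but only 20 % among the
  unrostered attached. This heterogeneity is what makes only ~a third of
  the non-rostered remainder virtually attachable — people with a PCP they
  rarely see are real and invisible to claims — and what gives walk-in
  providers a large pure-denominator clientele.
* Unattached patients make Poisson(0.9) episodic visits, 80 % to walk-in
  providers. With the preset's 3 walk-in providers among 100, walk-in CoC
  comes out ≈ 0.07 (far below the 10 % gate) versus ≈ 0.75 for regular
  providers.
* Survey answers are the truth flipped with misreport rates 0.25
  (unattached claiming a PCP — plausible for walk-in regulars) and 0.02
  (attached denying one).
* Hospital encounters (ED visits and admissions) arrive at flat Poisson
  rates, higher for the unattached, giving the uncertain-attachment audit
  signal. Non-core and non-office claims are generated at a low rate purely
  to exercise the core-visit filter.
* All event dates fall inside each patient's own window; every bundle
  passes referential integrity by construction.

`preset_full_separation` removes misreporting, strays, episodic visits,
low-use heterogeneity and walk-in providers; under it behaviour determines
attachment exactly and the algorithm provably recovers ground truth
(all four metrics 100.0). `preset_degraded(level)` linearly interpolates
those parameters between the separated and default presets; metric means
over a seed grid decline monotonically along the path.

What the generator does **not** emulate: seasonality and secular trends in
visit rates, provider panel-size heterogeneity, patient switching and
roster churn (all roster intervals are open-ended), geographic structure,
correlated misreporting, and pediatric populations (ages are 16–90).
Passing tests therefore demonstrate algorithmic correctness and calibrated
behaviour under the stated statistical structure, not performance on real
claims.

## Numerical and reporting choices

* Diagnostic metrics use exact rational arithmetic (`fractions.Fraction`)
  with a single final rounding, half-up to one decimal
  (`decimal.ROUND_HALF_UP`) — matching printed validation tables rather
  than banker's rounding. Zero-denominator metrics are reported as absent,
  never 0. Flow percentages use the same convention.
* The cut-point comparison uses the two-sample proportion z-test
  (`statsmodels.stats.proportion.proportions_ztest`), significance at
  0.001. Note that with a fixed comparator the attached set at a higher
  threshold is a subset of the attached set at a lower one, so the
  true-negative proportion (uncertain among no-PCP reporters) can only
  rise with the cut-point, while the true-positive proportion can only
  fall; what *concentrates* at the lower cut-point is the share of no-PCP
  reporters within the (smaller) uncertain group.
* Degenerate inputs: an empty cohort yields empty results and an all-zero
  flow report; a patient with zero windowed visits has no virtual
  enrollment (provider `None`, 0 of 0) and can still be attached by roster
  or CHC; persons absent from every event table classify as uncertainly
  attached — required for population application.
* Problem sizes in the shipped checks: exact-recovery at n = 5,000,
  marginal calibration at n = 10,000 (binomial standard error ≈ 0.4
  points, far inside the ±3-point bands), degradation grid at
  10 seeds × 3 levels × n = 2,000.

## Known limitations

Claims-invisible care (nurse practitioners, interprofessional teams)
cannot attach anyone; walk-in visits are not separately flagged in claims,
only inferred through provider CoC; specificity and NPV are intrinsically
modest because healthy attached people generate no claims; and the CoC
gate misbehaves for providers whose true continuity sits near the
threshold — the 10 %/25 % comparison quantifies that sensitivity.
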