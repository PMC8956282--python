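# pcpattach

Classify every person in a population as **attached** or **uncertainly
attached** to a primary care provider (PCP) using only routinely collected
health administrative data, and validate that classification against survey
self-report.

Lack of a consistent primary care relationship is associated with worse
quality of care and higher emergency-department use, but surveys that ask
"do you have a family doctor?" are expensive, slow and biased by response
rates. `pcpattach` implements a hierarchical attribution algorithm that
needs only physician billing claims, formal enrollment (rostering) records,
and community health centre (CHC) encounter data — the tables every
single-payer system already collects — so health-system planners can
estimate attachment for the whole population, repeatedly and cheaply.

## The algorithm

For each person, evaluated strictly in order at an index date *t* with a
two-year (730-day) lookback window *W = (t − 730 d, t]*:

1. **PEM** — attached if a formal enrollment interval covers *t*
   (enrollment is the system's own record of attachment);
2. **CHC** — attached if they had ≥ 1 community health centre visit in *W*
   (CHC physicians are salaried, so no billing claims exist for them);
3. **Virtual enrollment** — from billing claims, keep *core* primary-care
   visits (a configurable comprehensive-care service-code list, office
   setting only, at most one visit per patient–provider–day), restrict to
   *W*, and assign each person to the provider *p* with the **plurality** of
   their visits (ties → most recent visit, then smallest provider id). The
   person is attached to *p* only if *p*'s **continuity-of-care index**

   CoC(*p*) = (# patients whose plurality provider is *p*) / (# unique patients *p* saw in *W*)

   exceeds a cut-point (default 10 %). This gate stops attribution to
   walk-in-style providers, who see many unique patients but hold few
   pluralities.

Anyone left over is *uncertainly attached* — deliberately not "unattached",
because many still use episodic care. Virtual enrollment and CoC are always
computed over the **full population's** claims, then individual cohort
members are classified. A pluggable hook can additionally attach children
under 19 via an external pediatric access algorithm.

The validation harness scores the verdicts against survey self-report
(sensitivity, specificity, PPV, NPV in exact rational arithmetic, half-up
to one decimal), splits cohorts into development/validation periods, and
compares CoC cut-points (e.g. 10 % vs 25 %) with two-sample proportion
z-tests. A synthetic administrative-data generator with known ground truth
makes the whole pipeline testable without access to real health data.

## Worked example

```python
from pcpattach import run_attachment, confusion, metrics
from pcpattach.synthetic import generate, preset_paper_like

bundle = generate(preset_paper_like(n_patients=10_000, seed=20201))
results, flow = run_attachment(bundle.data(), bundle.survey_index_dates())
print(flow.to_text())
print(metrics(confusion(results, bundle.survey)).to_dict())
```

prints

```
cohort: 10000
  step PEM       entering    10000  attached     8122 (81.2% of cohort)
  step CHC       entering     1878  attached      150 (1.5% of cohort)
  step VIRTUAL   entering     1728  attached      552 (5.5% of cohort)
  uncertainly attached: 1176 (11.8%)
  attached overall:     8824 (88.2%)
{'sensitivity': 91.3, 'specificity': 61.9, 'ppv': 97.5, 'npv': 30.4}
```

Read: 81.2 % of the synthetic cohort is caught by formal rostering, 1.5 %
by CHC use, and 552 of the 1,728 people reaching the plurality step (32 %)
are virtually enrolled to an adequate-continuity provider, for 88.2 %
attached overall. Against self-report the classifier finds 91.3 % of people
who say they have a PCP (sensitivity) and 61.9 % of people who say they do
not (specificity); the asymmetry is structural — people with a PCP they
rarely visit are invisible to claims data.

The same pipeline is scriptable from a shell:

```sh
pcpattach simulate --n-patients 10000 --seed 20201 --out data/
pcpattach attach   --data data/ --out run/
pcpattach validate --data data/ --out run/ --compare-thresholds 0.10,0.25
pcpattach report   --run run/
```

Every run writes a `manifest.json` (config hash, seed, version) sufficient
to reproduce it exactly.

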