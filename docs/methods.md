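# Methods

## The screening model

The digital alert operationalizes sepsis-3 — suspected infection plus acute
organ dysfunction — as a conjunction of six digitally obtainable criteria
inside the first 6 hours of ED presentation. Suspected infection is the
standard cultures-plus-antibiotics pairing; organ dysfunction is a *modified*
SOFA: each of the six organ systems is reduced to a single binary threshold
(P/F < 400, GCS < 15, MAP < 70 or any vasopressor, bilirubin > 1.2,
platelets < 150, creatinine > 1.2) rather than the graded 0–4 sub-score. The
required-labs criterion (hemoglobin, lactate, sodium) carries no diagnostic
weight; it exists because those assays guarantee that heparin, EDTA and
sodium-fluoride tubes were drawn and will therefore have remnants.

Window semantics are half-open, [0, 360) minutes from arrival, and the
conjunction is cumulative: a flag fires once every criterion has been
satisfied at some point in the window, at the minute the last one is first
satisfied. The alternative — requiring simultaneous satisfaction — is not
digitally meaningful for lab results, which remain "obtained" once resulted.

Each element is evaluated on the *worst* in-window value (min for P/F, GCS,
MAP, platelets; max for bilirubin, creatinine). First-versus-worst is not
dictated by the alert's definition; worst-in-window was chosen because it is
the convention of SOFA scoring itself and makes the alert monotone: adding
an organ-dysfunction-qualifying event can never un-flag an encounter (a
property the test suite asserts).

Derived quantities: MAP = (systolic + 2·diastolic)/3 at timestamps where
both pressures coincide, with directly charted MAP taking precedence at its
own timestamp; P/F pairs each PaO₂ with the latest FiO₂ charted at or before
it (earliest after, otherwise), imputing 0.21 only when an oxygen-device
event explicitly records room air. No P/F is formed without a measured PaO₂.

### Full-SOFA adjudication

The adjudication oracle scores the standard Sepsis-3 grid
(`src/vespre/data/sofa_grid.json`) on worst-in-window values; organs without
data score 0, as chart reviewers treat unmeasured organ systems in a 6-hour
ED window. Two deliberate simplifications, both conservative
(score-lowering): cardiovascular sub-scores 3–4 require catecholamine dose
rates the event model does not carry, so any vasopressor administration
scores a flat 2; respiration sub-scores 3–4 conventionally require
ventilatory support, which is likewise not modelled, so the grid scores on
P/F alone. The element thresholds were aligned with the grid's 1-point bands
(e.g. bilirubin element > 1.2 vs grid band ≥ 1.2), which yields the
coherence invariant *adjudicated SOFA ≥ number of triggered modified
elements*; in particular every flagged encounter has SOFA ≥ 1. The fraction
of flagged encounters with SOFA ≥ 2 (the sepsis-3 bar) is data-dependent and
is reported, never asserted.

## The synthetic generator

The generator emulates a single-centre ED population enriched for sepsis. It
reproduces, as configurable defaults, the marginal distributions of the
characterized cohort: age N(59, 17²) truncated to [18, 105] (minors are
generated separately, at 2%, as negative controls for the age criterion);
56% male; Elixhauser count N(4.0, 2.3²) truncated at 0 (truncation shifts
the realized mean up by ≈ 0.2 — tests allow for this); 29 vitals/labs drawn
from normal (mean/SD variables) or log-normal (median/IQR variables,
σ = (ln q₃ − ln q₁)/(2·0.6745)) marginals. Missingness is applied per
variable, completely at random, at rates chosen so that 23 of the 29
variables fall below 25% missing (arterial gases, bands, ESR, troponin and
CRP are the realistically sparse ones); these rates are package
configuration, not reported values.

Ground truth is generated by construction. Each encounter first draws an
intent for every alert criterion — true-sepsis encounters (prevalence 0.08
by default, ≈ the 3428/42 893 flag rate of the original deployment) get all
six true; other encounters draw each criterion independently with a fix-up
forcing at least one false. Events are then emitted to match: a true
organ-dysfunction intent forces one randomly chosen element into its
qualifying range, while a false one clamps *every* SOFA-governing value into
the non-qualifying region (platelets ≥ 150, GCS = 15, MAP re-scaled to
≥ 70 after integer rounding, P/F ≥ 400 via PaO₂ ≥ 85 at FiO₂ 0.21, no
vasopressors). Criterion-critical events are exempt from missingness.
Because the truth labels are intents, the test that re-runs the alert code
on the emitted events and demands exact agreement is a genuine cross-check
of both the generator's clamping and the alert's thresholds.

Specimens accrue as 1 + Poisson(1.8) draws per present tube type
(presence 0.90 for the three required blood tubes, 0.70 citrate, 0.60
urine), with truncated-normal remnant volumes whose defaults put ≈ 10% of
each required tube below its minimum — jointly about a quarter of
otherwise-eligible patients fail the volume rule. 8% of encounters have all
specimens collected after the 6-hour window. Arrival datetimes spread
uniformly over ≈ n/75 study days so the daily cap binds at a realistic rate.

What the generator does **not** emulate: disease trajectories, physiological
coupling between variables (an explicit latent factor structure is available
separately via `simulate_factor_cohort`), drug dosing, supplemental oxygen
(FiO₂ is charted as 0.21 throughout), or informative missingness. Passing
tests therefore demonstrate the correctness of the *pipeline logic* under
known truth, not clinical validity on real EHR streams.

## Enrollment, biorepository, cost

Exclusion reasons are mutually exclusive, first-match in the fixed order
window → volume → tube-absent (the original report gives overlapping
percentages without precedence; a cascade makes conservation exact, which
the funnel report enforces on every run). "Minimum number of required tube
types" is implemented as: at least one heparin, one EDTA and one
sodium-fluoride specimen in the window each meeting its volume minimum —
these are precisely the tubes the required-labs criterion guarantees —
and is configurable. Urine never affects enrollment. A volume rule fails as
`insufficient_volume` whenever some *present* required tube is underfilled,
even if another required tube is absent. Percentages ≥ 1% print to the
nearest integer, < 1% to one decimal (so 12 963 / 3 054 644 → 0.4%).

Biorepository timing uses minutes: retrieval within 2880 min of acquisition
and not before `clinical_testing_complete_minutes`; when no explicit
retrieval time is supplied, retrieval is assumed at testing completion.
The citrate volume minimum is unreported and defaults to the EDTA-like
450 µL. "≥ 2 aliquots" counts eligible specimens of a tube type, not
post-split fractions; a per-specimen `aliquot_count` (volume // 125 µL)
feeds only the total-inventory counter.

Currency is integer cents throughout; per-patient values round half-up.
The source report mixed truncation and rounding in its per-patient figures:
round-half-up reproduces $22.12, $1.77 and $238.48 exactly but gives $14.49
(not the printed $14.48) and $125.89 (not $125.88). Those two are
truncation artifacts and are intentionally not replicated. The prehospital
design's category split was never published, so its fixture is a single
laboratory-category line; the embedded design's laboratory category is split
into the $13 035.00 freezer and $9 682.50 supplies/staff so the category
total matches the published $22 717.50.

## Analytics

Log-fold changes use base 2 ("log-fold" alone is ambiguous; base 2 is the
biomarker-field convention and makes the observed ±4 display range
plausible for these analytes). Raw values are stored unclipped; the ±4
bound applies only to the display matrix. Column medians map to 0 exactly
because log₂ is monotone.

The factor screen eigendecomposes the Pearson correlation matrix computed
pairwise-complete (matching an analysis that filtered by missingness rather
than imputing), retains eigenvalues strictly greater than 1, and reports
unrotated loadings; rotation is out of scope because only the factor count
and qualitative loadings matter here. Constant columns raise rather than
silently dropping. Eigenvalue conservation (Σλ = p to 1e-8) is a tested
invariant. On the block-design generator (primary loadings 0.7, unique
variance 0.51, n = 549, p = 23), recovery of k ∈ {2,…,8} factors succeeds
in ≥ 95% of seeded replicates (tested at 42 replicates).

OPTICS is implemented exhaustively (full distance matrix, O(n²)) with the
canonical semantics: core distance = distance to the min_pts-th nearest
neighbour counting the point itself, undefined (+inf) beyond eps;
reachability(o←p) = max(core(p), d(p, o)); the scan always continues at the
unprocessed point of smallest reachability, ties to the smallest index, and
each sweep's first point keeps the +inf sentinel. Defaults min_pts = 5,
eps = ∞; coordinates are z-scored before the diagnostic in the pipeline
(the function itself never rescales, so distances mean what the caller
passed). Tests require exact profile agreement with scikit-learn's OPTICS
on seeded random instances with n ≤ 25; at degenerate floating-point ties
(reachability exactly equal to a core distance) visit order is inherently
implementation-ambiguous, which the fixed test seeds avoid.

The smoothness score is mean |successive difference| of the finite
reachability sequence divided by its IQR; 0 for constant profiles, +inf when
the IQR degenerates with non-zero jumps. The decision threshold (default
0.5, jagged ⇒ hierarchical) is an explicit heuristic — no numeric rule was
ever published — and on the reference geometries (three well-separated
Gaussians vs a uniform blob, n = 90, min_pts = 5) the score separates the
two by an order of magnitude (≈ 3.1 vs ≈ 0.29).

## Problem sizes and numerical conventions

The shipped tests run the funnel pipeline at 800–2500 encounters and one
end-to-end pass at 10 000 encounters (a few seconds each); Monte-Carlo
marginal checks use n = 5000–10 000 with 3-standard-error tolerances; the
factor screen runs at the nested-sample geometry 549 × 23. Integer minutes
everywhere; event streams are sorted (encounter, time, kind, code) with a
stable sort so output is byte-identical for a fixed config and seed.
Percentage rounding is floor(x + 0.5) (round-half-up), matching the
reported 99% (1021/1027) and 66% (674/1027).

## Known limitations

* The generator's truth labels coincide exactly with alert-satisfiability,
  so alert sensitivity/specificity against *latent disease* is 1 by
  construction; the labels are meant for pipeline verification, not for
  benchmarking screening accuracy against imperfect documentation.
* FiO₂ is never supplemental, so respiration scores are bounded by the
  PaO₂ range; cardiovascular scores are capped at 2.
* The real deployment's funnel counts came from live EHR data and are not
  reproducible from any seed; only their arithmetic (percentage
  conventions, conservation) is.
* The original excluded-count bookkeeping (1175 vs 2199 − 1027 = 1172) is
  internally inconsistent; this implementation enforces exact conservation
  and does not attempt to reproduce the discrepancy.
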