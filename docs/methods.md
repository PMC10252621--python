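# Methods

## The decision rule

The Kaiser score is a flowchart-based clinical decision rule for breast
lesions on contrast-enhanced imaging.  Five descriptors are read by the
radiologist:

| descriptor | categories |
|---|---|
| root sign (spiculation) | absent / present |
| delayed-phase kinetics | persistent / plateau / washout |
| margins | circumscribed / irregular |
| internal enhancement | homogeneous-centrifugal / inhomogeneous-centripetal |
| diffuse oedema | absent / present |

The flowchart routes every complete descriptor vector (2·3·2·2·2 = 48
combinations) to exactly one integer leaf in [1, 12]; a score strictly
greater than 4 (the "exceeds 4" rule) triggers a biopsy recommendation.

`kscem` treats the flowchart as *data*: a JSON document of nested
`{"node": {feature, branches}}` / `{"leaf": {score}}` objects, validated
on load (leaf bounds, exhaustive branch coverage, no feature retested on
a path, a unique leaf for every input).  The shipped `kaiser_mri.json`
was transcribed from the published flowchart figure by the package
authors; the flowchart's leaf values are published only as a figure, so
the transcription was cross-checked two ways: by a second independent
re-tracing, and by the summary-statistics consistency property that a
textbook-malignant profile must score far above a textbook-benign one
(the shipped tree gives 8 vs 1, consistent with reported group medians
of 9 vs 3).  On the spiculated branch the tree asks only about oedema
(scores 8 / 11); on the non-spiculated branch it asks kinetics, margins,
enhancement pattern and oedema in turn.  Because the transcription is a
data file, a corrected or alternative flowchart (e.g. a future CEM
variant with a microcalcification moderator) plugs in without code
changes, and none of the package's published-value checks depend on
individual leaf assignments — only on the score *distributions* of the
calibrated cohort.

The CEM variant (`kaiser_cem.json`, or `adapt_tree_for_cem`) is
identical in topology and leaf values; it differs only in the documented
reading of the oedema descriptor ("diffuse ipsilateral breast oedema"
only, since CEM cannot depict perifocal oedema).  Scoring behaviour on a
given descriptor vector is therefore provably identical, which the test
suite asserts over all 48 inputs.

The score→BI-RADS band mapping is configuration with a non-normative
default (1 → 2, 2–4 → 3, 5–7 → 4, 8–12 → 5); no published mapping table
exists, so the default makes no claim beyond "scores above the biopsy
threshold land in actionable categories".

## Enhancement kinetics on CEM

Curve type is classified from the change `d` in mean ROI density between
the ~2 min and ~8 min recombined images: `d > 10` units → persistent,
`d < −10` → washout, otherwise plateau.  The published rule assigns
"more than 10" to the outer classes and "less than 10" to plateau,
leaving a change of exactly 10 units unassigned; we close the middle
interval (|d| ≤ 10 → plateau) so the rule is total and deterministic,
and test that boundary explicitly.  The threshold is a parameter
(default 10) because the units are device-dependent recombined-image
densities with no physical definition.  The MRI curve vocabulary maps
one-to-one: type I → persistent, type II → plateau, type III → washout.

## Diagnostic evaluation

* **Positivity convention.** Test-positive ⇔ score ≥ cut-off.  This is
  the only convention under which the published 100%-NPV row (cut-off 3
  with 6 true negatives, specificity 28.57%) coexists with a benign
  median score of 3: with a strict (>) convention at least 11 benign
  lesions would test negative at that cut-off.
* **AUC.** Concordance probability with half credit for ties, computed
  through mid-ranks; algebraically identical to the average over all
  malignant×benign pairs and to the trapezoidal area under the empirical
  ROC staircase.  Both identities are property-tested.
* **Youden cut-off.** Exhaustive maximization of J = sensitivity +
  specificity − 1 over the distinct observed scores plus one value above
  the maximum; ties break toward the smallest cut-off (maximal
  sensitivity at equal J).
* **100%-NPV cut-off.** The largest cut-off at which every test-negative
  lesion is benign — equivalently the minimum malignant score.  If no
  benign lesion scores below it the point is degenerate (no true
  negatives); the cut-off is still returned with a warning.
* **DeLong test.** Paired-AUC comparison via per-observation structural
  components (mid-rank formulation), `z = ΔAUC / √(var_a + var_b −
  2 cov)`, two-sided normal p, no continuity correction.  Zero variance
  of the difference is flagged degenerate: p = 1 when the AUCs are equal,
  NaN otherwise.  The implementation is checked against a brute-force
  pair-enumeration of the structural components (agreement to machine
  precision) and against a delete-one jackknife of the AUC difference;
  the two estimators are asymptotically equivalent and differ by an
  O(1/N) factor at N ≤ 8, so the jackknife comparison uses a 35%
  relative band.
* **Summaries.** Median and IQR use linear interpolation between order
  statistics (the behaviour of `numpy.percentile`); a published benign
  IQR bound of 1.7 on 21 values is only producible by an interpolating
  estimator, which fixes this choice.
* **Undefined ratios** (zero denominators) are NaN plus an explicit flag
  set, never silently zero.
* **Reconstruction oracle.** With known class margins, an exhaustive
  search over all (TP, FN)×(TN, FP) splits returns every confusion
  matrix whose metrics — as percentages rounded half-up to the printed
  number of decimals — match all given constraints.  An empty result is
  reported as an inconsistency finding, not an exception.  Applied to
  the published ROC table this yields unique matrices for both Youden
  rows and the 100%-NPV row, and shows the printed accuracy cells
  (88.2% / 86.8%) to be arithmetically inconsistent with the uniquely
  determined matrices (which give 62/68 = 91.2% and 61/68 = 89.7%);
  accuracy is therefore excluded from the reproduction targets.

## The synthetic cohort

No per-lesion data are deposited for the study population this package
models (68 lesions: 47 malignant, 21 benign, each read on MRI and CEM),
so the generator works from per-(group, modality) score frequency
tables (`FixtureSpec`).  The shipped default was calibrated by integer
search so that the exact-count cohort *simultaneously* reproduces:

* malignant score summaries 9 (IQR 8–9) on both modalities and benign
  3 (IQR 2–3);
* Youden cut-off 6 and 100%-NPV cut-off 3 on both modalities;
* confusion at cut-off 6: MRI 42/1/5/20, CEM 41/1/6/20 (TP/FP/FN/TN),
  and at cut-off 3: 47/15/0/6;
* pair-counting AUCs of exactly 938.5/987 (MRI) and 928/987 (CEM),
  rounding to the printed 0.951 and 0.940.

`calibration_certificate()` recomputes this checklist at run time.  The
benign distribution is shared between modalities (the published CEM
benign IQR of 1.7–5 cannot be matched simultaneously with that
simplification and is left unconstrained; the MRI benign IQR is
matched).

Two generation modes are distinct operations by design: the exact-count
mode emits the calibrated multisets verbatim so evaluation results are
deterministic, while the sampling mode draws scores multinomially from
the normalized frequencies for robustness or power studies (a property
test checks frequency recovery at n = 10⁵ per group, a size chosen to
make three-standard-error bounds tight while keeping the suite fast).

Each generated record is internally consistent: the descriptor vector is
drawn uniformly from the flowchart paths reaching a leaf with the
required score (untested descriptors drawn uniformly from their
categories), and the CEM ROI pair is drawn so the kinetics classifier
recovers the record's delayed-phase descriptor.  ROI baselines are
uniform integers on [1800, 2400] — a plausible recombined-image density
scale bracketing published worked-example values of 2148–2180 — with
density changes of 11–60 units (outer classes) or within ±10 (plateau);
these ranges are configuration, not claims about device physics.  MRI
and CEM scores are paired rank-concordantly within each truth group, the
least-assumption choice given that no per-lesion cross-modality table is
published.  All randomness flows through one recorded seed
(`numpy.random.default_rng`), and the cohort CSV sidecar records the
seed and a SHA-256 hash of the spec.

### What the synthetic cohort does and does not show

The generator reproduces the *score distributions* and everything
derived from them; it does not emulate reader variability, imaging
physics, lesion morphology correlations between descriptors, or the
referral process.  Passing tests therefore demonstrate that the
pipeline's arithmetic and decision logic reproduce the published
operating characteristics — not that the flowchart would achieve them on
new patients.  Two published quantities are deliberately not
reproduction targets: the exact DeLong p of 0.749 (it depends on the
unavailable per-lesion pairing; under rank-concordant pairing the
fixture gives p ≈ 0.11, and only p > 0.05 — consistency with the
published non-significance — is asserted) and the BI-RADS medians (the
score→BI-RADS mapping is unpublished).

## Numerical choices

* Percent rounding in reports and the reconstruction oracle is decimal
  half-up, matching printed clinical tables; comparisons in the oracle
  are exact on `Decimal`s, with integer-count numerators so no rounding
  boundary is ambiguous.
* AUC equality checks use an absolute tolerance of 1e-12 (rank sums of
  half-integers are exact in double precision at these sizes).
* Youden maximization treats J improvements below 1e-12 as ties, far
  below the 1/(47·21) granularity of J on integer-count cohorts.
* Degenerate inputs raise (`ValueError`) where the request is
  unanswerable — empty classes, length mismatches, unknown labels or
  categories — and warn where an answer exists but is qualified (the
  degenerate 100%-NPV point).

## Known limitations

* The flowchart transcription fidelity is bounded by what the published
  figure shows; leaf-level ground truth is not otherwise published.
* The DeLong p on the synthetic cohort depends on the assumed
  cross-modality pairing and is reported only against the 0.05 level.
* The sampling mode draws modalities independently before rank-pairing
  within groups; it does not model per-lesion discordance rates.
* Single-reader descriptor vectors; inter-reader agreement is out of
  scope.
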