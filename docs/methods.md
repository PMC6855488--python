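# Methods

## Setting

`fibrolyse` implements the analysis used to compare fibrinolysis
assessment in dogs with intracavitary (abdominal and/or pleural)
effusion against matched effusion-free sick controls, by two independent
classification schemes: one built on rotational thromboelastometry
(ROTEM, EXTEM channel) plus plasma fibrinogen, the other on standard
plasma tests (semiquantitative FDPs, D-dimer, fibrinogen). The package
covers the full chain — trace parameterization, rule-based
classification, two-arm comparison statistics, cross-scheme agreement —
plus a synthetic trace/cohort generator so everything runs and is tested
without instrument data.

## Trace parameterization

A trace is a sampled clot-firmness curve (mm against seconds). Between
samples, amplitude is linearly interpolated, matching instrument exports
at ~1 s resolution; input files are never resampled. The extracted
parameters:

- **CT** — first up-crossing of the 2 mm clot threshold (interpolated).
  A trace that never reaches 2 mm raises a distinct "no clot" error
  rather than returning a number.
- **MCF** — maximum sampled amplitude over the run.
- **A5** — amplitude at CT + 5 min.
- **LI60** — `100 · A(CT + 60 min) / MCF`, clamped to [0, 100]. The
  denominator is the run-maximum MCF (standard ROTEM convention), which
  makes LI60 and ML commensurate and bounded.
- **ML** — `100 · (MCF − min A after the MCF time) / MCF` over the full
  run (ML/2h on the 2-hour protocol).
- **Breakdown time** — first down-crossing of the 2 mm threshold after
  MCF, i.e. total clot breakdown operationalized symmetrically with clot
  detection. Reported in minutes **from CT** (the same clock LI60 uses);
  clocking from the test start is selectable since the field literature
  does not fix the convention.

Default runtime is 7200 s (the 120-min protocol). A5/LI60 are reported
as absent, with explicit errors at the single-parameter level, when the
run is too short to read them.

One caveat on the bound `ML ≥ 100 − LI60`: it holds whenever formation
is essentially complete before the LI60 read-out (true for realistic
kinetics, and enforced as a tested property on simulated traces), but a
trace still rising at CT + 60 min can have LI60 < 100 with ML = 0
because LI60 is referenced to the later run-maximum. The bound is
therefore a property of realistic traces, not a hard invariant of the
parameter container.

## Classification rules

Reference intervals default to the originating laboratory's canine
values: LI60 86–98 %, A5 29–44 mm, ML 19–38 %, fibrinogen 152–284 mg/dL,
FDPs < 5 µg/mL, D-dimer 0.01–0.34 µg/mL, HCT 39.0–59.2 %. They load
from a YAML config for other laboratories.

**Viscoelastometric scheme.** LI60 > 98 → hypofibrinolysis; 86–98 →
basal; < 86 with fibrinogen > 100 mg/dL → increased fibrinolysis; < 86
with fibrinogen ≤ 100 mg/dL (boundary inclusive) → hyperfibrinolysis.
The 100 mg/dL cut-off ties the viscoelastometric evidence of lysis to a
concentration associated with spontaneous bleeding risk. Within
increased/hyper, total breakdown within 30 min is fulminant, in
(30, 60] min intermediate, later or never within the run late. The
30/60-min boundaries are read half-open on the fulminant side
(≤ 30 → fulminant, ≤ 60 → intermediate); both tie sides are
configurable because the verbal definitions do not fix them.

**Standard-test scheme.** FDPs is a 3-level ordinal (`<5`, `5-20`,
`>20` µg/mL); "elevated" means ≥ 5. D-dimer is elevated strictly above
0.34 µg/mL; sub-interval values count as normal (the scheme defines no
hypofibrinolysis, so hypo and basal are merged by construction).
Normal FDPs and D-dimer → hypo/basal. Any elevation → increased
(fibrinogen > 100) or hyperfibrinolysis (≤ 100), typed primary when
D-dimer is normal (so FDPs must be elevated: plasmin without
concomitant thrombin generation) and secondary when D-dimer is elevated,
whatever the FDPs level ("normal to increased FDPs" is read literally:
raised D-dimer with normal FDPs is secondary). Severity is the type
coarsened, so the two functions can never disagree.

Fibrinogen below the 60 mg/dL assay detection limit is encoded as
59 mg/dL, the laboratory's data-sheet convention, and the panel
container enforces that floor.

**Clinically relevant bleeding** requires both a recorded bleeding event
and anemia (HCT < 39.0 %); anemia alone never qualifies. Excluding
bleeders changes only membership of the comparison sets, never any
label.

## Statistics

- **Fisher–Freeman–Halton exact test** (authored here; scipy has no
  r×c exact test): full enumeration of tables with the observed margins,
  two-sided by the probability-ordering rule with a 1e-7 relative
  tolerance for probability ties. The package default is the **mid-p**
  variant (ties with the observed table's probability, including the
  observed table, contribute half weight): on the reference tables it is
  the variant that reproduces the published p-values (0.042, 0.017,
  0.044, 0.004, and the bleeding-excluded repeats), where the
  conventional rule gives 0.052/0.047 on two of them. The conventional
  rule stays selectable (`variant="prob"`). Enumeration is refused above
  n = 200; the reference tables (n ≤ 64) enumerate in milliseconds.
- **Chi-square** from the explicit Pearson formula, with the Yates
  continuity correction (|O−E| − 0.5, floored at 0) on 2×2 tables only;
  p from the χ² distribution.
- **Pooled-variance two-sample t** computed from summary statistics
  (mean, SD, n per arm), so published group summaries are sufficient
  input. Pooled, not Welch: it is the variant consistent with the
  published t values.
- **Mann-Whitney** via scipy: exact p for combined n ≤ 20 without ties,
  otherwise the tie-corrected normal approximation without continuity
  correction.
- **Cohen's kappa** (authored here, cross-checked against statsmodels in
  the tests): weighted κ = (p_o − p_e)/(1 − p_e) with identity, linear
  (1 − |i−j|/(k−1)) or quadratic weights; SE by the
  Fleiss–Cohen–Everitt large-sample formula; CI = κ ± 1.96·SE.
  **Default weighting is linear**: the severity scale is ordinal, and on
  the reference agreement table linear weighting yields the published
  κ = 0.06 with CI −0.14 to +0.26 (unweighted gives 0.04). Observed
  concordance is the raw diagonal percentage; conditional concordance
  for a category is diagonal / (row margin + column margin − diagonal).
- All comparisons two-sided at α = 0.05, no multiplicity correction
  (matching the reference analysis). Structural zero categories are kept
  in reported tables; they are dropped only on entry to the exact test
  (which cannot use empty margins), and a table that collapses below
  2×2 yields no comparison rather than an error.

## Synthetic data

**Trace model.** `A(t) = MCF·(1 − e^{−k(t−t0)+})·exp(−(λ(t−t0−d)+)^γ)`
— saturating-exponential formation (lag t0 ≈ 45 s, rate k ≈ 0.01/s,
plateau ≈ 60 mm for a healthy-dog EXTEM) times a Weibull lysis survival
(onset d after t0, rate λ, shape γ). γ = 1 is plain exponential decay;
γ < 1 gives decelerating lysis, which is what makes observed pairs like
LI60 = 61 % with ML = 47 % (most firmness lost before the 60-min
read-out, little after) reachable inside a 2-hour run — no
single-exponential survival can produce them. Noise is additive
Gaussian truncated at zero. Every parameter has a closed form, so
`params_for_li60` inverts the model exactly: the onset is placed where
formation is ≥ 99.9 % complete, the LI60/ML pair then fixes γ from the
ratio of log-survivals at the two read-out clocks and λ from either one.
Pairs with ML < 100 − LI60 are rejected as infeasible; ML exactly
100 − LI60 (a perfect post-60-min plateau) is approximated with 0.05
points of residual decay; ML = 100 has no finite-rate representation
and is simulated with explicit fulminant parameter sets instead.

**Cohort model.** Per arm: normal A5; log-normal fibrinogen and D-dimer
(right-skewed, log-SDs set from the published IQRs, floored at the
59 mg/dL detection encoding); categorical FDPs; LI60 = 100 − X with X a
mixture of a narrow uniform (little/no lysis) and an exponential left
tail; ML = (100 − LI60) plus an exponential second-hour increment;
breakdown time present only when ML ≥ 97 %. Default arm specs pin the
published locations: A5 34.88 ± 16.23 vs 53.41 ± 16.24 mm, fibrinogen
medians 177 vs 371 mg/dL, D-dimer medians 0.09 vs 0.16 µg/mL, FDPs
9:11:12 vs 16:8:8 over the three categories, bleeding 13/32 vs 4/32.
The LI60 mixture parameters (50 % within 5 points of 100 and tail scale
55 for the effusion arm; 85 % within 3 points and scale 20 for
controls) were chosen once from the published medians/quartiles
(95, 61–100 vs 99, 97–99). What the generator does **not** emulate:
disease-specific effect structure, correlations between analytes within
a subject, assay artefacts, or the matched-pairs design — so passing
tests show the pipeline's correctness and calibration on cohorts with
the right marginal structure, not clinical validity on real dogs.

**Reference fixture.** `fixture_cohort_from_tables()` is a
deterministic 64-subject panel set whose values, pushed through the real
classifiers, regenerate every published cross-tabulation exactly — the
per-arm severity grades, lysis patterns, standard-test types and FDPs
counts, the 3×3 agreement table, the bleeding 2×2, and all of these
restricted to the 47 subjects without relevant bleeding. The joint
allocation of subjects to cells is one consistent integer solution (the
published margins do not determine it uniquely; the two
fibrinogen-contradictory cells — standard-increased with
viscoelastometric-hyper and vice versa — are zero in the published
table, which is what makes a single consistent fibrinogen value per
subject possible). Continuous values are representative points inside
each category's region (LI60 99 / 92 / 80 / 40 / 3 for
hypo / basal / late / intermediate / fulminant; fibrinogen 177 / 80 on
the increased/hyper branches) and are synthetic stand-ins, not
measurements.

## Problem sizes and numerics

The test suite and the acceptance script run everything at the study's
own scale (n = 64; exact enumeration over tables with n ≤ 64) plus a
5000-per-arm simulated cohort for convergence checks and 100–200-draw
property sweeps; the whole suite completes in seconds on one CPU.
Probability ties in the exact test use a 1e-7 relative tolerance;
simulated traces default to 1 s sampling, and parameter-recovery
tolerances are one sample interval for CT and 0.5–1 percentage points
for LI60/ML.

## Known limitations

- The exact-test enumerator is exhaustive; r×c tables with large n or
  many categories need a Monte Carlo approach it deliberately refuses.
- The kappa CI is asymptotic (n = 64 is adequate but not luxurious); no
  bootstrap alternative is provided.
- The Weibull lysis survival has an infinite initial decay slope for
  γ < 1; at 1 s sampling this is invisible, but derivative-based
  analyses of simulated traces near onset should use γ = 1.
- Mann-Whitney U values from the reference study are not reproducible
  from published summaries (they need per-subject raw data) and are not
  targeted anywhere.
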