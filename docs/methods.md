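# Methods

## Scope

`ifnscore` implements the analysis chain *expression → IFN-score → response
labels → stratified specificity-constrained cut-off*, plus the group
statistics used to establish prednisone-related score suppression and a
generative cohort simulator. Out of scope by design: probe-level microarray
preprocessing, raw-Ct qPCR processing (ΔCt is consumed as given,
reference-normalised), DAS28 computation from joint counts, and any
longitudinal modelling of IRG expression during therapy.

## Expression handling

Input tables are delimited text (TSV default, CSV by extension), one header
row, first column gene symbol. Symbols are uppercased; duplicates after
uppercasing are an error. Three input scales map to the stored log2 scale:
`log2` (pass-through), `linear` (log2-transform; non-positive values are a
hard error unless the caller supplies an explicit additive offset — silent
flooring would bias scores downward invisibly), and `delta_ct` (x ↦ −x, since
one ΔCt unit is one doubling and larger ΔCt means less transcript).

**Median-centering.** To pool platforms with different location scales, each
gene row has its median (over that platform's samples, missing ignored;
even-count median = mean of the two middle order statistics, the
conventional definition) subtracted before merging. Centering is refused on
an already-centered matrix, and entirely-missing gene rows are dropped with
a warning. `merge_platforms` intersects gene sets (order of the first
input), concatenates sample blocks, and records per-sample platform
provenance; per-platform gene medians remain 0 after the merge. The exact
centering procedure used historically with these data is not fully
documented anywhere we can cite; per-gene within-platform centering is this
package's documented choice.

## Scoring

IFN-score = arithmetic mean of the panel's log2 values present and
non-missing for the sample. `min_gene_fraction` (default 0.75) excludes
samples with thin panel coverage while admitting the historically relevant
7-of-8 case (HERC5 absent from older arrays, fraction 0.875). Scores are
shift-equivariant and permutation-invariant by construction; a panel that is
a subset of another gives identical scores whether computed from the full or
the subset matrix. Dichotomisation (IFN-high/IFN-low) uses strict `score >
cutoff`, consistent with the prediction rule; a flag switches to `≥`.

## Clinical statistics

* **Response**: responder ⇔ ΔDAS28 > 1.2 strictly. DAS28 is reported to
  about one decimal, so differences within 1e-9 of the threshold count as
  equal — 5.0 − 3.8 is *not* a response despite binary-float excess.
* **Two-group comparison**: the normality gate is explicit where historical
  practice was a judgment call: Student's unpaired t-test only when both
  groups pass Shapiro–Wilk at α = 0.05 *and* each n ≥ 8; otherwise a
  two-sided Mann–Whitney rank-sum test. Exact enumeration is used when both
  n ≤ 10 and there are no ties; otherwise the tie-corrected normal
  approximation without continuity correction (scipy's exact path does not
  midrank-correct ties, and dropping the continuity correction keeps the
  symmetric null at p = 1 exactly).
* **Dose dependence**: Kruskal–Wallis (tie-corrected) across dose bins.
  Default bins: non-users {0}, (0, 5], (5, 10), [10, ∞) mg/day — the only
  externally anchored boundary is "10 mg/day or more", the rest are
  configurable.
* **Odds ratio**: crude cross-product with Woolf 95% CI
  (exp(log OR ± 1.96·√Σ1/cell)); any zero cell triggers the
  Haldane–Anscombe +0.5 correction on all cells, flagged in the result.

## Prediction

Positive state = non-responder; predicted positive when score > threshold
(strict; flag for ≥ — the boundary convention is not externally fixed, so it
is exposed rather than hidden). Candidate thresholds are midpoints between
consecutive distinct scores plus sentinels below the minimum and above the
maximum; this attains every achievable operating point and is reproducible,
unlike thresholds read manually off a curve. AUC is the trapezoidal area
over (FPR, TPR), which for this construction equals the concordance
probability (#concordant + ½ #tied)/(n₊·n₋) — asserted against exhaustive
pair counting in the tests.

Cut-off selection maximises sensitivity subject to specificity ≥ `s_min`
(default 1.0); ties break toward higher specificity, then the larger
threshold (most conservative non-response call). Feasibility is guaranteed
by the above-maximum sentinel (specificity 1, sensitivity 0).

`IfnResponseModel.fit()` runs ROC → cut-off → confusion per stratum
(default: prednisone use), reports the unstratified analysis alongside, and
pools confusion cells across evaluable strata (overall sensitivity
ΣTP/Σ(TP+FN), overall specificity ΣTN/Σ(TN+FP)). A stratum with only one
response class has no meaningful ROC; it is reported unevaluable and left
out of the pooled cells rather than silently merged. Reported percentages
round half away from zero (7/8 → 88%, 9/22 → 41%).

The published cut-offs 1.36 (all/PREDN+) and 0.48 (PREDN−) are data-derived
constants from the original, unpublished patient-level data; they ship as
documented constants in `ifnscore.examples`, never as defaults.

## Synthetic cohorts

The generator encodes the structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `p_ifn_high` | 0.5 | prevalence of the latent IFN-high class |
| `mu_low`, `mu_high` | 0.0, 1.5 | genuine-score class means (log2) |
| `sigma_score` | 0.4 | between-patient SD within class (log2) |
| `p_prednisone` | 0.675 | user fraction (27/40 in the rituximab cohort) |
| `dose_choices` | uniform {2.5, 5, 7.5, 10, 15, 20} | daily dose (mg) |
| `suppression` | saturating | δ(d) = delta_max·d/(d + d50); linear alternative |
| `delta_max`, `d50` | 1.2 log2, 5 mg/day | suppression magnitude/half-dose |
| `p_respond_given_high/low` | 0.2 / 0.8 | response probability by latent class |
| `n_genes`, `sigma_gene` | 8 (IRG8 symbols), 0.3 | panel size, within-patient gene noise |

Per patient: latent class → genuine score (Gaussian mixture — the ~50%
signature prevalence implies bimodality; the parametric form is this
package's choice) → prednisone/dose → observed score mean = genuine −
δ(dose) for users → per-gene log2 values = observed mean + gene offset +
N(0, σ_gene) → response ~ Bernoulli(p|class). Response depends on the
*latent* class, not the observed score: a suppressed IFN-high patient stays
a likely non-responder, the mechanism that creates false-negative
predictions among users. DAS28 pairs are cosmetic realisations consistent
with the drawn label (baseline ~ N(5.8, 1.1) truncated to [3.2, 10];
ΔDAS28 = 1.2 ± (10⁻³ + Exp(0.8)), clipped to keep month-6 inside [0, 10]
without crossing the 1.2 rule); they carry no information beyond the label.
All draws flow from one `numpy` Generator seeded by `cfg.seed`; identical
configs give byte-identical serialised cohorts.

No external estimate of the suppression magnitude in log2 units exists;
`delta_max`/`d50` are labelled non-reference values chosen to give
suppression of roughly one class-separation at high dose.

**What the simulator does not emulate:** covariate confounding (MTX,
disease activity), gene–gene correlation beyond the shared score factor,
platform-specific technical artefacts, longitudinal dynamics. Passing tests
therefore demonstrate the pipeline's correctness and the qualitative
suppression mechanism, not clinical performance on real cohorts.

### A known limitation of the generative design

The documented defaults do **not** reproduce the three-way stratified AUC
ordering AUC(PREDN−) > AUC(all) > AUC(PREDN+) in most replicates (measured:
~30% of 200 seeded replicates at n = 200, reported by
`scripts/acceptance.py` as `stratified_auc_ordering_fraction`). The reason
is structural: with response a Bernoulli flip of the latent class at
0.2/0.8, every stratum's AUC is capped at
P(non-responder is high, responder is low) + ½·P(same class) = 0.8; both
strata sit within ~0.005 of that cap because the dose-driven suppression
spread (SD ≈ 0.19 log2) is small against the 1.5 log2 class separation, and
the pooled analysis tends to be the *lowest* of the three (the ≈0.73 log2
between-stratum shift degrades cross-stratum score comparisons). Producing
the strong observed-data pattern (PREDN− ≫ all > PREDN+) would require a
response mechanism more tightly coupled to the genuine score in non-users;
the implemented mechanism is kept as documented, and the corresponding
acceptance test records the shortfall rather than masking it.

## Problem sizes

Default verification sizes, chosen as routine desk-scale simulation
settings: 500 random ≤12-sample instances for the ROC oracles, 200
replicates at n = 200 for the mechanism check, 100 replicates at n = 2000
for estimator bias, 1000 seeded cohorts at n = 200 for null calibration.

## Numerical notes

* Specificity is computed as TN/(TN+FP) directly (not 1 − FPR) so oracle
  comparisons are bit-exact.
* Cut-off feasibility tolerance: specificity ≥ s_min − 1e-12 guards against
  representation error in user-supplied constraints.
* Centering invariant checked at 1e-9; score subset consistency at 1e-12.
* Expression round-trips through text at `%.17g`, exact for doubles.
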