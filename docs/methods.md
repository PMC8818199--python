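# Methods

## Measurement model and normalization

Each urine sample is assayed in three qMSP multiplexes, each carrying
three methylation markers plus the reference gene *ACTB*:
A = {FAM19A4, PHACTR3, PRDM14}, B = {GHSR, SST, ZIC1},
C = {MAL, miR-129, miR-935}. The quantification cycle Ct is inversely
log-proportional to the amount of amplifiable (methylated, bisulphite-
converted) template. Methylation is expressed as the comparative-Ct
ratio

    ratio = 2^−(Ct_target − Ct_ACTB) × 100,

so ratio 100 means target and reference amplify identically and each
extra target cycle halves the ratio (an exactly tested invariant).

**QC rule.** A multiplex is valid iff its *ACTB* Ct is detected and
≤ 32; the boundary 32.0 is valid (the exclusion rule is strictly
"> 32"). All markers of a failed multiplex are invalid together —
validity partitions markers exactly by multiplex. The cohort QC summary
counts samples with ≥ 1 failed multiplex.

**Undetected wells.** A target well with no amplification but valid
*ACTB* is scored ratio 0: in methylation-specific PCR the absence of
amplification means no detectable methylated template, not missing
data. This is a convention of this package; instrument exports do not
distinguish the cases.

**Log scale.** Displayed methylation levels are log2(ratio + ε) with
ε = 10⁻⁴. ε only guards log2(0); every inferential step (rank tests,
ROC, threshold calls) uses the raw ratio or is invariant under the
strictly monotone transform, so ε cannot change any AUC, p-value or
panel call (tested).

## Per-marker inference

Case-vs-control comparisons use the two-sided Mann–Whitney U test
(exact enumeration when both groups ≤ 8 without ties, otherwise the
tie- and continuity-corrected normal approximation; with ~100 per group
the choice is immaterial). The nine marker-level p-values are
Bonferroni-adjusted: p_adj = min(1, 9·p). Heterogeneity of control
subtypes (haematuria / other benign urological conditions / healthy) is
tested per marker with the tie-corrected Kruskal–Wallis test.

The ROC curve is computed over candidate thresholds at the midpoints
between consecutive distinct scores (plus sentinels beyond the
extremes), with a positive call defined as score ≥ threshold; higher
methylation is always the case-like direction. The trapezoidal AUC over
this curve equals the tie-adjusted U/(n₁n₂) to 10⁻¹² (a tested
invariant with a brute-force pairwise oracle). AUCs carry the
conventional qualitative bands, assigned left-closed: [0.5, 0.6) very
poor, [0.6, 0.7) poor, [0.7, 0.8) fair, [0.8, 0.9) good, [0.9, 1.0]
excellent — so 0.90 is already "excellent"; the prose ranges these
bands come from overlap at the boundaries and a convention had to be
fixed.

**AUC confidence intervals** use DeLong's placement-based variance with
a normal-approximation interval truncated to [0, 1]; degenerate perfect
separation (zero variance) returns the point interval with a warning.
The implementation is cross-checked in the test suite against a frozen
reference computed with R's pROC on a fixed 12-control/10-case fixture
(agreement in AUC, SE and interval to ~10⁻⁹). Note the Wald-form
DeLong interval is mildly anti-conservative for AUCs near 1 at
moderate n — long-run coverage ≈ 93.5% (identical for pROC) at true
AUC ≈ 0.89 with ~100 per group — which the coverage test acknowledges
rather than hides.

## Panel classification

Per-marker cutpoints maximize Youden's J = sensitivity + specificity −
1 over the same midpoint candidate cuts. Ties in J are broken toward
the higher specificity, then the larger threshold: the clinical aim of
a urinary triage test is avoiding unnecessary cystoscopies, so among
equally informative cuts the more specific one is preferred. The
derived cut is verified against exhaustive search on random instances.

The panel (default *GHSR*/*MAL*) is "believe-the-positive": positive if
at least one valid marker is at or above its cut (the boundary counts
positive, consistent with hypermethylation indicating cancer). This OR
rule makes the panel provably at least as sensitive and at most as
specific as each member marker (tested exactly). A sample whose valid
markers are all negative while some panel marker is invalid is
*indeterminate* — the OR is not settled — and is excluded from
performance denominators with its count reported; a single valid
positive marker settles the OR regardless of invalid markers.

Sensitivity and specificity carry exact Clopper–Pearson intervals
(beta-quantile form, with the usual 0/1 boundary conventions); exact
intervals are conservative, and coverage ≥ nominal is verified by
simulation at n ∈ {23, 108}.

**Panel score.** For a panel AUC a continuous score is needed; the OR
rule alone yields only a binary call. The package uses the maximum
log2-margin over valid panel markers, score = max_m [log2(ratio_m + ε)
− log2(threshold_m + ε)], which is ≥ 0 exactly when the OR rule calls
positive, so the score's ROC passes through the panel's operating
point. This max-margin score is a declared convention of this package;
other continuous combinations (e.g. logistic) are possible.

## Validation

**LOOCV.** Each sample is classified and scored by a panel whose
thresholds were derived on all other samples; per-fold threshold
re-estimation is the construction under which cross-validation actually
differs from resubstitution. The out-of-fold call is invariant to the
held-out sample's own label (tested by flipping it), resubstitution is
optimistically biased relative to LOOCV on average over simulated
cohorts (directional test), and LOOCV on permuted labels yields
chance-level AUC.

**Subgroups.** Sensitivity of the pooled-threshold panel is reported
for the dichotomized case partitions G3 vs G1–G2, HG vs LG, stage ≥ T2
vs Ta/T1/Tis, primary vs recurrent, and male vs female, each contrast
tested with a Pearson chi-square on the positive/negative × stratum
table, 1 df, *without* continuity correction and unadjusted for
multiplicity (only the nine marker-level tests are Bonferroni-
corrected). The no-continuity-correction choice is anchored by a
printed worked example in the test suite: the 79/29 vs 63/37 gender
table gives p = 0.116 → 0.12 uncorrected, while the corrected value
(0.155) contradicts it. If all calls agree in both strata the
contingency table degenerates (a zero column); the contrast is then
reported as p = 1 (no association).

**Gender post hoc.** Because diagnostic performance differs by gender,
the cohort is also split by gender with thresholds, resubstitution
performance and LOOCV re-derived entirely within each stratum.

## Study design

The minimum per-group n for a maximum two-sided CI width w at
anticipated AUC A solves 2·z_{1−α/2}·SE_HM(A, n₁, n₂) ≤ w over
integers, where SE_HM is the Hanley–McNeil standard error (the
exponential-model Q₁ = A/(2−A), Q₂ = 2A²/(1+A) approximation). The
width is strictly decreasing in n, so the search brackets by doubling
and bisects; minimality (n passes, n−1 fails) is asserted. At A = 0.89,
w = 0.1, α = 0.05 and equal allocation the answer is 87 per group
(width 0.0997; 86 gives 0.1003). Enrolment targets inflate by
⌈n/(1−dropout)⌉: 87 at 20% dropout → 109 per group. Empirically,
DeLong CI widths of simulated Gaussian-score cohorts at the designed n
meet the target width on average (tested). Unequal allocation is
exposed as a cases:controls ratio, solving for the smaller group.

## Synthetic cohort generator

The generator emulates the structure of a prospectively collected
case/control urinary methylation study; its defaults are the study
conditions, not tuning knobs.

**Composition.** 108 cases / 100 controls. Covariates are filled by
exact quota (largest-remainder rounding of the published frequencies),
so the default cohort reproduces the baseline composition *exactly*:
cases 79 male / 29 female, WHO-1973 grades 17/39/52 (G1/G2/G3),
WHO-2004 45 LG / 63 HG, stages 59 Ta / 16 T1 / 10 Tis / 23 ≥T2, 76
primary / 32 recurrent; controls 63 male / 37 female, subtypes 34
haematuria / 43 other benign / 23 healthy. The two grading systems and
stage are assigned along one shared latent severity ordering per cohort
(so G3, HG and high stage co-occur, as they do histologically), while
gender and disease status are shuffled independently. Ages are Gaussian
(cases 70 ± 8, controls 67 ± 9 years, clipped), reflecting the study's
age-matched design; tumour count/size/CIS descriptors are quota-filled.

**Marker model.** Control log2-ratios are Normal(μ₀, σ²) per marker
with μ₀ = −6 (≈ 1.6% methylation signal relative to *ACTB*, a typical
urinary background) and σ = 2. Case log2-ratios shift by
δ_m·σ·B·g(covariates), where δ_m is the per-marker effect in SD units
(defaults 1.3–2.0, strongest for *GHSR* and *ZIC1*, chosen to land the
marker AUCs in the good-to-excellent range reported for such panels),
B ~ LogNormal(0, 0.5²) is a per-case tumour-burden factor shared across
markers (inducing the positive inter-marker correlation co-varying
markers show in tumours, with one parameter instead of a full
covariance matrix), and g multiplies the applicable factors:
high-grade ×1.5, stage ≥T2 ×1.3, recurrent ×0.6, female ×0.6. The
female dilution emulates the excess unmethylated DNA of gynaecological
origin in female urine; recurrent tumours carry lower burden than
primaries at diagnosis. The true inter-marker correlation structure of
real cohorts is unknown; the shared-burden model is an assumption and
its parameter is exposed.

With burden SD 0 and all multipliers 1, the model is the equal-variance
binormal model, so the per-marker AUC has the closed form Φ(δ/√2); the
calibration test checks the empirical AUC at δ = 2, n = 500/500 against
Φ(√2) ≈ 0.921 within 3 Monte-Carlo SEs.

**Assay back-transform.** Target Ct = ACTB Ct − log2(ratio/100) with
ACTB Ct ~ Normal(26, 1.5²) per (sample, multiplex), so comparative-Ct
normalization exactly inverts generation and the pipeline is
round-trip testable. No Ct ceiling/undetected truncation is applied by
default (it would break exact invertibility); undetected handling is
exercised through the reader instead. Sporadic QC failures replace a
multiplex's ACTB Ct by a Uniform(32.5, 38) draw with probability 0.03
per multiplex independently. (Note this is a per-multiplex rate; the
per-participant rate of losing ≥ 1 of 3 multiplexes is then ≈ 8.7%.
The 2.9%-of-participants QC worked example in the test suite is built
deterministically with exactly six failing participants out of 208.)

**What the generator does not emulate.** Amplification-efficiency
variation, plate/batch effects, technical replicates, realistic age–
outcome dependence, correlated missingness, and any real joint
distribution between covariates beyond the severity coupling above.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the *analysis* under the stated generative assumptions,
not the clinical performance of any marker panel on real urine.

## Numerical conventions

* Positive calls are score ≥ threshold everywhere; thresholds are
  midpoints, so results are insensitive to which side the boundary
  falls on except at exact ties.
* Youden tie-break: max J, then max specificity, then larger threshold.
* Display rounding is half-up (0.795 → 0.80, 2.884% → 2.9%), applied
  only to the `*_display` report fields; full-precision values are
  always retained in the JSON report, and CSVs are written with
  round-trippable float formatting.
* All simulation randomness flows from a single integer seed through
  numpy's PCG64 generator; identical seed + config ⇒ byte-identical
  outputs (tested).
* Problem sizes in the test suite (e.g. LOOCV at 40–208 samples,
  calibration at 500/500, coverage at 1000 replicates) are chosen so
  each statistical check has the resolution its tolerance needs while
  the whole suite stays interactive-fast.

## Known limitations

* The max-margin panel score and the ratio-0 convention for undetected
  wells are package conventions where instrument practice varies.
* DeLong intervals are slightly anti-conservative near AUC 1 (see
  above); exact or logit-transformed intervals could be substituted.
* The Hanley–McNeil variance is itself an approximation; designs very
  close to AUC 0.5 or 1 should be checked by simulation (the package
  provides the pieces to do so).
* Subgroup contrasts are unadjusted for multiplicity by design; with
  five partitions, isolated p ≈ 0.05 findings should be read
  accordingly.
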