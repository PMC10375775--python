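# Methods

This note documents the models and procedures implemented in `licograde`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic study generator does and does not emulate.

## The grading problem

Licorice root quality is traditionally graded from three provenance
factors — genuine production area, number of growth years, harvest
season — but those factors are not measurable on traded material. The
package's pipeline replaces them with 21 measurable quality indices per
batch and learns a grading rule on batches whose grade is known:

* 15 marker-compound contents (mg/g dry weight), quantified against OLS
  calibration curves;
* alcohol-soluble extract content (% dry weight), a pass-through from the
  pharmacopoeia extraction assay;
* root diameter (mm), the retained appearance trait;
* total flavonoid content (mg/g) from UV absorbance at 337 nm;
* a pharmacological-activity index: the summed contents of liquiritin
  apioside, liquiritigenin, glycyrrhizic acid and isoliquiritin apioside
  (mg/g), the four markers with documented anti-inflammatory activity;
* angle-cosine similarities of the 250-nm and 330-nm HPLC fingerprints to
  a consensus pattern (dimensionless, in [0, 1]).

Only pharmacopoeia-compliant batches (glycyrrhizic acid ≥ 2.0 % and
liquiritin ≥ 0.50 % of dry weight) enter the grading model.

## Fingerprint processing

Peak tables are aligned to a canonical common-peak pattern (13 peaks at
250 nm, 14 at 330 nm) by **relative retention time** with respect to the
wavelength's reference peak (licoricesaponin G2 at 250 nm, isoliquiritin
at 330 nm), greedy nearest-first within a tolerance of 0.02 relative-rt
units. Relative rt rather than absolute rt makes alignment robust to
run-to-run drift; with ≤ 14 well-spaced peaks, greedy matching coincides
with the optimal assignment (property-tested against an exhaustive
assignment oracle). Canonical peaks with no match contribute area 0 and a
missing-mask bit, keeping the fingerprint length fixed across batches.

The consensus reference pattern is the element-wise mean of aligned areas
over batches; similarity is the cosine of the angle between raw aligned
areas and the pattern. Raw rather than reference-relative areas are the
default (the choice is exposed as the caller may pass any vectors);
cosine similarity is scale-invariant, so overall concentration differences
between batches do not affect it. Similarities are reported to 4 decimals.

Method validation follows fingerprinting practice: per-common-peak RSD
(100·SD/mean) of relative retention time and relative area across
replicate injections, with shipped thresholds rt < 0.5 % and area < 3.0 %
for precision/stability and rt < 0.3 % and area < 2.9 % for repeatability
(the stricter of the two wavelengths' repeatability criteria; thresholds
are per-call parameters).

## Index screening

An index is retained when it differs significantly (default α = 0.05,
no multiple-testing correction, matching per-factor practice; a
Benjamini–Hochberg switch exists) across *every* configured provenance
factor: one-way ANOVA over production areas and growth years, pooled-
variance Student's t between seasons (Welch by flag). Retained indices
correlated above |r| = 0.8 are pruned to a designated primary — diameter
over weight, diameter being the traditionally preferred, easily measured
trait. Chemical indices must additionally reach VIP ≥ 1.0 in a PLS-DA
(NIPALS, autoscaled X, 2 components, dummy-coded genuine/non-genuine
response), computed as `VIP_j = sqrt(p · Σ_a w²_ja SSY_a / Σ_a SSY_a)`;
the Σ VIP² = p identity is asserted in tests. PLS-DA VIP stands in for
OPLS-DA VIP: the VIP threshold is the only OPLS-DA output the workflow
uses, the orthogonal rotation does not change predictive VIP materially,
and component count/scaling (2, autoscaling) are the conventional
defaults.

## Grading model

**Confidence boundary.** Second-class material is pre-screened by a
Mahalanobis ellipsoid fitted to the premium + first-class block of the
21-index table: sample mean, sample covariance (ridge-regularized by
λ = 10⁻⁸·tr(Σ)/p when near-singular — the pharmacological index is an
exact linear combination of four content columns, so the 21-feature
covariance is always rank-deficient by one), cutoff at the χ² quantile
q = 0.99 with df = 21. The ellipsoid is an assumption: the boundary
construction is not otherwise specified, and the choice is isolated
behind the `Boundary` interface.

**RBF-SVM.** Premium (+1) vs first-class (−1) with kernel
`exp(−γ‖x−z‖²)` on z-scored features (scaling fitted per training fold
during CV, on the full training block for the final model; unscaled mode
by flag). The dual program is solved by libsvm; the full dual vector α,
bias b and support set are exposed, and the KKT conditions
(0 ≤ αᵢ ≤ C, Σαᵢyᵢ = 0) are asserted post-hoc to 10⁻⁵·C regardless of
solver. Hyperparameters are chosen on a grid of C over e⁻⁵…e⁵ and γ over
10⁻⁵…10⁵, 21 log-steps each, by pooled stratified tenfold CV accuracy;
ties prefer smaller C, then smaller γ, making the search deterministic
given the fold seed.

**DJ contributions.** With α frozen, removing feature f from the kernel
changes the dual objective by
`DJ_f = |½ Σᵢⱼ αᵢαⱼyᵢyⱼ(Kᵢⱼ − K⁽⁻f⁾ᵢⱼ)|` — the SVM-RFE ranking criterion.
Computed efficiently as `K⁽⁻f⁾ = K ⊙ exp(γ δ²_f)` on the support set.
A zero-variance feature has DJ exactly 0; duplicated features receive
equal DJ. Contributions are DJ values normalized to sum to 100 %. The top
k = 9 features (ties broken by reporting order) are retained and the SVM
re-tuned on the subset with a second full grid search (one global
re-optimization, not per-fold).

A caveat worth recording: on *strongly separated* classes with a
moderate-to-large γ, frozen-dual DJ can invert — cross-class kernel
entries vanish, so only within-class noise differences register and
uninformative features can outrank informative ones. In this pipeline the
CV grid search selects small γ on the default synthetic study and the
ranking is reliable (property-tested over 50 seeds); users applying the
weighting at externally fixed large γ should treat the ranking with
caution.

**Platt calibration.** The sigmoid p(f) = 1/(1+exp(A·f+B)) is fitted to
*cross-validated* decision values of the retrained model (same folds as
the grid search) by regularized maximum likelihood with Platt's smoothed
targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2); Newton iterations with
backtracking run to gradient norm < 10⁻⁸. CV decision values avoid the
optimistic margins a separable training fit would feed the sigmoid. The
posterior is a monotone transform, so ranking metrics (AUC) are
preserved exactly.

**QCEI mapping.** Inside the boundary, p ≥ 0.5 ⇒ premium with score
86 + 28(p − 0.5) ∈ [86, 100]; p < 0.5 ⇒ first-class with score
70 + 30p ∈ [70, 85). The band edges (86 floor, 85 ceiling) are the fixed
anchors; the piecewise-linear interior is an assumption chosen for
monotonicity and continuity-per-band, as only the band ranges are pinned
down externally. Outside the boundary the batch is second-class and
scores 70·√(c/d²) < 70 where d² is the squared Mahalanobis distance and c
the cutoff — monotone decreasing in distance, approaching 70 at the
boundary; no external anchor exists for second-class scores, so they are
reported together with the distance and a "<70" display sentinel.

## Synthetic study generator

The generator emulates the study design end to end so that every stage
has realistic input: 282 batches (S1…S282) from three regions (two
genuine-area, one non-genuine; weights 0.40/0.40/0.20), growth years
uniform on 2–5, two harvest seasons. A latent quality score —
1.0·genuine + 1.0·year-quality (0 at 2 y, 0.5 at 3 y, 1 at 4–5 y) +
0.5·autumn + N(0, 0.6) — ranks batches; rank cutpoints produce exactly
93 non-compliant, 45 second-class, 92 first-class and 52 premium batches.
The score rule is an assumption (the factor-to-grade mapping is not
specified anywhere) and is fully configurable.

Grade-conditional index distributions: contents are lognormal (CV 20 %)
with mean shifted by Δ·CV·baseline per grade step, centred on
first-class; the default Δ is 1.5 on the nine informative indices
(diameter, total flavonoids, both similarities, liquiritin apioside,
liquiritin, glycyrrhizic acid, liquiritigenin, pharmacological index) and
0 elsewhere, so parameter-recovery tests have a known answer. Appearance
traits are normal (diameter mean 12 mm, CV 15 %); weight is generated
from diameter with target correlation r = 0.9, which the redundancy
screen must detect; length depends on growth years only. Fingerprint
similarity effects are realized through per-grade multiplicative peak-
area noise (log-SD 0.05/0.12/0.22/0.35 for premium/first/second/
non-compliant), shrunk toward the first-class level as the configured
similarity effect size drops, so a zero effect genuinely removes the
signal. Total flavonoids are emitted as 337-nm absorbances behind a true
calibration line (slope 0.053 AU·mL/µg, intercept 0.002, noise SD 0.002)
plus the liquiritin standard series (22.53 µg/mL stock, 0.2–5 mL into
10 mL), so the assay arithmetic is exercised, not bypassed.

Compliance is built into the latent classes: compliant grades draw
glycyrrhizic acid and liquiritin from distributions truncated above the
monograph minima, the non-compliant class from below the glycyrrhizic-
acid minimum (inverse-CDF truncated lognormal sampling). The filter
therefore passes exactly 189 of 282 at the default configuration —
non-compliance is a property of the latent class, not a random outcome —
which keeps every downstream sample size deterministic.

What the generator does **not** emulate: raw chromatogram traces (peak
tables only), instrument drift, batch-to-batch retention-order swaps,
content correlations beyond those induced by the shared grade, seasonal
interactions with specific compounds, and measurement-platform changes.
Passing tests therefore demonstrate that the pipeline recovers structure
it is designed to recover under its own stated noise model — not that it
would reach the same accuracy on field data, where grade separations are
smaller and index noise is correlated.

## Numerical choices

* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; fixed seed ⇒ bit-identical tables.
* Degenerate ANOVA input (all groups identical) reports F = 0, p = 1;
  zero within-group variance with distinct means reports F = ∞, p = 0.
* RSD of an exactly constant series returns exactly 0.
* Curve inversion outside the calibrated range flags the result instead
  of failing, so one outlier cannot abort a screening run.
* The QP tolerance is 10⁻⁶; KKT asserted to 10⁻⁵·C.
* Grid-search tie-breaking is smaller C then smaller γ (row-major first
  argmax over an ascending grid).
* Boundary covariance ridge λ = 10⁻⁸·tr(Σ)/p, applied only when the
  smallest eigenvalue falls below 10⁻¹⁰ of the largest.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at the
default study size (189 compliant batches, 144 in the premium/first
training block) with the documented 21-point grids; multi-seed properties
(score bands over 10 seeds, informative-index recovery over 50 seeds) use
6-point grids spanning the same ranges, since grid resolution is not the
property under test there and the selected optima sit well inside both
grids. Coverage and calibration simulations use n = 5000 (boundary) and
1200 null indices (screening type-I error).

## Known limitations

* The binary SVM grades only premium vs first-class; second-class
  assignment rests entirely on the confidence-boundary assumption, and at
  q = 0.99 with 1.5-SD grade shifts a substantial fraction of second-class
  batches falls inside the boundary and is scored as (low) first-class.
* DJ contributions inherit SVM-RFE's blind spots: mutually redundant
  informative features can share, and thereby dilute, their apparent
  contribution; the frozen-dual criterion degrades at large γ (above).
* The posterior-to-score map interior and the second-class decay are
  design choices anchored only at the band edges; scores are comparable
  within a trained model, not across models.
* PLS-DA VIP approximates OPLS-DA VIP; with a single predictive
  direction the difference is small, but exact equality is not claimed.
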