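# Methods

This note documents the statistical models, the synthetic-data
generators, the numerical choices, and the known limits of the
`persistomics` pipeline.

## Study design model

The design is a fully crossed treatments × timepoints × replicates
layout. The first treatment arm is the vehicle control; timepoint labels
beginning with `R` are flagged as post-washout (recovery). Every
contrast in the package is *treatment vs time-matched control within one
timepoint* — contrasts are never pooled across timepoints, because the
biology of a repeat-dose/washout experiment (daily medium renewal,
compound washout after day 5) makes the control series itself
time-dependent. The default layout is 3 arms × (T1, T3, T5, R3) × 3
biological replicates. Designs with fewer than two replicates per cell
are rejected: no within-cell variance would be estimable.

## Moderated t-test

For each feature, the two groups of a contrast give a pooled residual
variance s² on d = n₁ + n₂ − 2 df. Gene-wise variances are modelled as
draws from a scaled inverse-chi-square prior (d₀, s₀²). The
hyperparameters are estimated once per contrast by moment matching on
z = log s²: under the model, E[z] and Var[z] are analytic in
digamma/trigamma functions of d/2 and d₀/2, so d₀ solves
trigamma(d₀/2) = Var(z) − trigamma(d/2) via a Newton inversion of the
trigamma function, and s₀² follows from the mean. When the observed
spread of z does not exceed the pure-sampling component trigamma(d/2),
the excess is non-positive and d₀ = ∞ (complete shrinkage: every gene is
tested against s₀²). The posterior variance is
s̃² = (d₀s₀² + d·s²)/(d₀ + d) and t̃ = LFC/(s̃·√(1/n₁+1/n₂)) is referred
to a t distribution with d₀ + d df (normal when d₀ = ∞). Limiting cases
are exact: d₀ = 0 reproduces the classical pooled t to 1e−12; d₀ → ∞
uses s₀² alone. The LFC is always the difference of group means on the
log2 scale, independent of the moderation.

BH adjustment is delegated to `statsmodels.stats.multitest`
(`fdr_bh`); the test suite pins it against a hand-computed 4-value
example and an O(m²) literal implementation of the step-up definition.

### Significance presets

* mRNA counting: p < 0.001, no fold-change floor.
* miRNA differential calls: FDR < 0.05 (methods default); an FDR ≤ 0.1
  preset is provided for volcano-style displays. Both are exposed
  because impact *counting* of miRNAs conventionally uses raw p < 0.05
  while *calling* uses the FDR; the count and call surfaces use their
  respective defaults.
* Probe→gene reduction interprets "highest variation" as the sample
  variance across the condition's arrays (treatment + time-matched
  control); ties break to the lexicographically smallest probe id so the
  reduction is deterministic.

## Tiling-array region calling

Windows are every run of 7 consecutive probes within one promoter whose
genomic span (last end − first start + 1, coordinates 1-based inclusive)
is at most 750 bp; runs advance one probe at a time and never cross
promoter boundaries; promoters with fewer than 7 probes contribute no
windows. The two readings of "a 750 bp window of 7 probes" (fixed probe
count with a span cap, vs fixed genomic span) coincide on regular arrays
like the simulated ones; the span cap honors both numbers on irregular
layouts.

The per-window test is a one-way ANOVA on per-array window means —
arrays, not probes, are the replicates, because probe signals within a
750 bp window are strongly correlated and would otherwise inflate the
df. With two groups the F statistic equals the square of the pooled
two-sample t. Degenerate windows (zero within-group variance) get p = 1
when the group means agree and p = 0 (flagged) otherwise.

BH runs across all windows of one (layer, contrast) jointly; a gene is
called when any of its windows passes FDR < 0.01. The gene score is the
median over all probes in its significant windows of (per-probe median
treatment − median control), and the direction is the sign of that
score; a gene whose score ties at exactly 0 carries no direction and is
excluded from hyper/hypo counts. On tracks small enough to enumerate,
the caller agrees exactly with a brute-force oracle (direct window
enumeration, plain t-tests, textbook step-up BH).

Because windows within a promoter are correlated, the FDR calibration
property is evaluated at gene level: on pure-null tracks of 2000 genes
the called fraction stays at or below the nominal 0.01 within binomial
Monte-Carlo error.

## QC-RLSC metabolomics correction

Per metabolite, a robust LOESS curve (degree 1, span 0.75, three
robustifying iterations) is fitted to the QC peak areas against
injection index; the curve is linearly interpolated at every injection
and clamped to its end values outside the QC range (nearest-curve-value
extrapolation, flagged). The correction factor is curve/median(QC), so
the corrected data stay on the raw QC-median scale and a flat QC series
makes the correction the identity (verified to 1e−9). Metabolites with
fewer than five usable (finite, positive) QC measurements are left
uncorrected and flagged rather than corrected badly. With the minimum
five QCs the robust LOESS passes through the QC points nearly exactly,
so the post-correction QC CV is ≈ 0; sample-level biological and
analytical noise is unaffected. The span is configurable; 0.75 is the
package default since the method's source publication leaves it
tunable.

The posttest is a cell-means two-way ANOVA (treatment × time): the
pooled error mean square over all cells feeds treatment-vs-control
contrasts at each timepoint, adjusted within the family of m timepoint
comparisons by Sidak (1 − (1−p)^m) or Bonferroni (min(1, m·p));
Sidak ≤ Bonferroni always. Cells need ≥ 2 non-missing replicates;
missing peak areas are missing, never zero. Internal-standard columns
pass through untouched — normalization is by QC-RLSC only.

## Integration layer

* **Impact counts** partition each endpoint's significant features into
  up/down (expression) or hyper/hypo (tiling) per condition; up + down =
  total by construction.
* **Coupling** is Spearman ρ between the GE LFC and the gene-level
  region *score* (not just its sign — signs alone degenerate into ties)
  over genes with both a significant expression call and a region call
  at the condition; a switch widens the universe to all epigenetically
  called genes for sensitivity analysis. The p-value is the exact
  permutation probability for n ≤ 9 (full enumeration, vectorised) and
  the t-approximation above; stars at 0.05/0.01/0.001.
* **Persistence** is computed per direction: among R3 calls with
  direction d, the fraction whose gene already had direction d at T5.
  The per-direction denominators match the separate hyper/hypo
  percentages of recovery-phase reporting; the T5 count is carried
  alongside so the forward rate (persistent/T5) is also available.
* **Concordance** takes the persistent-HA genes whose R3 mRNA is
  significant (p < 0.001) with |LFC| ≥ 0.58 (≈1.5-fold) and labels each
  consistent (sign of expression change equals the mark's direction) or
  inconsistent; the two labels partition the set.
* **Pathway ranking** keeps pathway genes significantly modulated by the
  positive-control compound at any treatment timepoint (p < 0.001,
  configurable — the gating statistic is not uniquely determined and p
  matches the mRNA preset) and sorts the survivors by the test
  compound's average LFC over T1/T3/T5.

## Synthetic data and what it does (not) show

The generators emulate the study conditions so that downstream claims
are testable against planted truth:

* **Expression**: gene variances from scaled inverse-chi-square(d₀ = 4,
  s₀² = 0.03) — a prior-mean residual variance of 0.06 (per-sample sd
  ≈ 0.25 log2 units), typical of RMA-normalized arrays and chosen so a
  planted 2-fold change (LFC 1) at n = 3 is detectable with ≥ 80%
  sensitivity at FDR 0.05, the calibration the pipeline's power
  contract assumes. Baselines uniform on [6, 12] log2 units. A scalar
  effect size plants constant ±LFC; `uniform_magnitudes()` supplies a
  continuous magnitude distribution, which is required whenever rank
  coupling is analysed (a two-valued LFC marginal ties all within-sign
  ranks and caps the attainable Spearman ρ).
* **Tiling**: one promoter per gene, 20 probes at 100 bp spacing (50 bp
  probes, 1.95 kb span — comparable to deluxe promoter tiling density;
  the true array's layout is not described, so this is a stand-in, not
  a reconstruction). Planted regions cover the central 10 probes.
  Effects are coupled to expression truth through a Gaussian copula
  with Pearson r = 2·sin(πρ_s/6) so the *Spearman* target is exact in
  distribution; copula scores map to signed magnitudes through the
  strictly increasing function sign(z)·(0.6 + 1.4·(2Φ(|z|)−1)) —
  order-preserving (Spearman-invariant) with magnitudes in
  [0.6, 2.0]× effect size, bounded away from zero for detectability and
  spread widely enough that score measurement noise cannot scramble the
  within-sign ranking. Exactly ⌊persistence_fraction · n_regions⌋ genes
  keep the same-direction region at the recovery timepoints; the rest
  lose it.
* **Metabolomics**: the run opens with a QC injection, inserts one QC
  after every (qc_every − 1) study samples and closes with a QC
  (n_QC = ⌈n_samples/(qc_every−1)⌉ + 1); a linear multiplicative drift
  ending at 1 + amplitude applies identically to QCs and samples;
  noise is log-normal (CV 0.08 by default). A fraction of metabolites
  carries a planted LFC in all test-treatment cells.

All generators are bit-deterministic given a seed, and every planted
effect is recorded in the truth object before noise is added. Passing
tests on these data show that the estimators recover what was planted
under Gaussian/log-normal noise and a correctly specified design; they
do not speak to probe sequence bias, dye effects, MeDIP enrichment
chemistry, batch structure, outlier samples, or annotation error in
real arrays.

## Numerical choices and degenerate inputs

Problem sizes in the routine test/acceptance runs are scaled for a
single CPU: 2000 genes for calibration and coupling recovery, 5000 for
hyperparameter recovery, 120–300 genes for full-pipeline checks; these
choices are the package's own and keep every run in seconds to minutes.
Other choices: quantile normalization resolves within-column ties by
average ranks (equivalently, the mean over the spanned ranks) and is
idempotent; trigamma inversion runs Newton to 1e−10 relative tolerance
with closed-form guards at both extremes; Spearman permutation p-values
enumerate all n! rank permutations up to n = 9; the LOESS correction
curve is clamped outside the QC range; zero-variance ANOVA windows and
zero region scores are handled by explicit conventions (above) rather
than NaNs. File formats: GFF3 probe coordinates are 1-based inclusive,
BED promoter maps 0-based half-open, converted on read; all internal
arithmetic is 1-based inclusive, and strand is ignored (promoter
identity comes from the map).

## Limitations

The pipeline consumes *normalized* matrices and probe-level signal
tables; RMA summarization of CEL files, NimbleScan feature extraction,
and GC-MS peak deconvolution are upstream of its scope. The windowed
ANOVA implements the published parameters literally (7 probes / 750 bp /
FDR 0.01); the proprietary scanner software's exact internals
(permutation components, scaling) are not public and are not emulated.
One promoter interval per gene is assumed; alternative promoters of the
same gene are not merged or distinguished.
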