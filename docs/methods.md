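# Methods

This note documents the models, defaults, and design choices behind
metaboflow, and what the synthetic-cohort generator does and does not
emulate.

## Synthetic cohort model

The generator produces a subject roster and three platform feature tables
(LC-MS polar, LC-MS lipid, GC-MS) from one seeded RNG. On the log2 scale a
cell is

    baseline_f + Δ_f·[case] + O_{b,f} + s_b·t + ε,

with feature baseline baseline_f ~ N(17, 1.5²) (log2 arbitrary intensity
units), group effect Δ_f = `effect_log2fc` on the `n_informative` informative
features for samples in `case_groups`, batch offset O_{b,f} ~
N(0, `inter_batch_sd`²) independently per batch and feature, within-batch
drift slope s_b ~ N(0, `drift_slope_sd`²) multiplying the injection position
t, and residual ε ~ N(0, `noise_sd`²). Intensities are 2^(log2 value), i.e.
log-normal, matching the multiplicative behaviour of MS peak intensities.

Injection types: QC_NIST shares one fixed metabolome (baseline + a fixed
feature-wise offset), so its replicate variation isolates the technical
terms; QC_bio is the linear-scale mean of a random 50% subject subset;
QC_mix carries only the spiked standards, with intensity proportional to the
gradient concentration; QC_blank sits one log2 unit below the platform LOD.
Missingness is `missing_base_rate` plus a logistic term
(1 + exp(−(log2 LOD − log2 I)))⁻¹, so cells fade out preferentially below the
LOD — producing the abundance/intensity regimes the imputation rules
distinguish.

Key defaults (all config fields, chosen as plausible magnitudes for a
multi-month plasma study; the batch-effect sizes are generator settings, not
estimates of any particular instrument): batch size 40; QC triplet every 10
biological injections; gradient 40…7 µg/mL; `inter_batch_sd` 0.5 log2 units
(≈ 40% CV); `drift_slope_sd` 0.005 log2/injection; `noise_sd` 0.2 log2
(≈ 15% CV); `missing_base_rate` 0.02; LOD 10⁴ (LC) / 10³ (GC) intensity
units; group fractions approximating a cancer-enriched case-control cohort.
Cross-platform duplicate annotations (default 8) are injected deliberately so
deduplication always has work to do.

What the generator does **not** emulate: chromatographic peak shapes, adducts
and isotopes, in-source fragmentation, RT nonlinearity, correlated metabolite
panels, covariate-driven biology (age/sex/hospital effects on the
metabolome), and heavy-tailed or structured missingness beyond the logistic
model. Passing tests therefore demonstrate correctness of the pipeline's
logic and its behaviour under the stated effect model — not performance on
real instrument data.

## Screening

All exclusion predicates are evaluated and every firing reason is returned;
tabulation uses the first reason in a fixed canonical order. The processing
cutoff is strictly > 240 min and the volume cutoff strictly < 60 µL
(boundaries pass). Comorbidity rules (diabetes, hypertension, cardiovascular
disease) apply only to healthy-group volunteers, reflecting the two-column
structure of typical inclusion/exclusion tables. Repeat enrollment keeps the
first record. Whether "severe metabolic disease" subsumes diabetes for
non-healthy groups is left to the caller: the flags are independent.

## Scheduling

Strata are the cross of hospital, group, sex, and age stratum (<55, 55–65,
≥65 years). Members of each stratum are shuffled and dealt through a global
cyclic counter over batches, which guarantees per-stratum per-batch counts
within ±1 and batch totals within the configured size; within-batch order is
then shuffled. The QC cadence formalizes "about every 10" as exactly every
`qc_period` (default 10) with the fixed triplet order QC_mix → QC_bio →
QC_NIST, and the calibration gradient runs once at the head of each batch.
Both choices are configurable.

## QC metrics

CVs use the sample (n−1) standard deviation. Intra-batch CV pools replicate
injections at the periodic stability concentration (the most frequent
concentration among a standard's observations); extra-batch CV pools batch
mean intensities; calibration is fit per batch by OLS over the gradient and
summarized as the mean r². A standard with no observations is reported as
missing and fails its report. Default pass bounds: |RT_dev| ≤ 0.3 min,
|Mass_err| < 10 ppm (polar) / 5 ppm (lipid), extra-batch Int_CV < 30%,
r² ≥ 0.90. The first three follow the ranges a stable large-batch acquisition
is expected to hold; the r² bound reflects what a 6-point fit under ~15%
multiplicative intensity noise can achieve. All are descriptive defaults and
config-overridable, not hard requirements of the method. GC-MS runs
nominal-mass, so GC reports omit mass error.

## Curation

"Coverage" and "abundance" are the same quantity — the fraction of biological
injections with a detected value — computed before imputation. The coverage
filter drops only unannotated features by default (a `drop_low_coverage_
annotated` switch extends it to annotated ones). Imputation noise is uniform
on ±5% (the distribution is a package choice). A feature whose biological
values are all missing cannot supply a median and falls through to the
LOD/zero branch (logged). Because a fully imputed matrix no longer reveals
detection patterns, `impute` records pre-imputation coverage and mean
intensity in the feature metadata and `deduplicate` uses those stored values.
When no explicit LOD is configured the pipeline uses the 1st percentile of
observed intensities per platform.

Deduplication tie-breaks (rule 4) are ordered annotation score → abundance →
mean intensity; peak shape is unavailable in a feature table and is excluded.
An optional significance rule (smaller p, then larger |log2FC|) applies
between the RT-window rule and the tie-breaks when a per-platform contrast is
supplied.

## Batch correction

Architecture: encoder d → 64 → 32 → 8 (leaky-ReLU, slope 0.1), decoder
(8 + n_batches + 1) → 32 → 64 → d, discriminators 8 → 64 → {n_batches, 1}.
The decoder is *conditioned* on the batch one-hot and normalized injection
order, so technical structure is modelled explicitly rather than forced
through the latent code; corrected data are decoded at a batch-neutral
reference (uniform batch weights, mid-batch order). This conditioning is
essential: a plain bottleneck autoencoder must either reconstruct the batch
offsets (removing nothing) or suppress them by shrinking everything,
attenuating biological fold changes along the way.

The encoder's adversarial terms are bounded confusion objectives — cross-
entropy of the batch classifier against the uniform distribution and the
squared order prediction — rather than negated discriminator losses, which
are unbounded and destabilize training. Gradients are normalized per sample
(reconstruction summed over features), putting the adversarial weights
λ_batch = 5 and λ_order = 1 on a comparable scale; a small latent L2 (10⁻³)
and a global gradient-norm clip (5) keep the optimization bounded. Training
is full-batch Adam (lr 3·10⁻³ for both players, 2 discriminator steps per
autoencoder step, 200 reconstruction-only warm-up epochs, ≤ 1000 epochs).
Only metabolome-carrying injections (biological, QC_bio, QC_NIST) enter the
scaler and the training set — solvent blanks and standards mixtures sit
several log2 units below the biology and would otherwise dominate the
per-feature variance. Intensities are floored at 1 before the log2 transform
so zero-imputed cells stay finite, and decoded log2 values are clamped to
[0, 40] before exponentiation.

Early stopping monitors the median QC_NIST CV of the corrected output every
10 epochs and halts after 15 evaluations without improvement, keeping the
final parameters (restoring a "best-CV" snapshot is degenerate: the CV
criterion alone rewards shrinking all output toward feature means).
Correction is applied identically to every injection. The correction is
approximately, not exactly, idempotent — a second application moves the
output by much less than the first but not by zero, since the encoder sees a
slightly different (already corrected) distribution.

Per-platform correction is the default; the merged table can be corrected
instead by passing it as a single table. An acquisition-gap covariate (e.g. a
two-phase study interruption) can be emulated by encoding the phase into the
batch labels.

## Analysis

The volcano contrast uses a two-sided Welch t-test on log2 intensities — a
deliberate choice over the pooled-variance test since group variances are not
assumed equal — with no multiple-testing correction by default (the printed
thresholds |log2FC| > 0.25, p < 0.05 are marginal); Benjamini–Hochberg is a
flag. Classifier evaluation repeats a stratified 75/25 split `n_repeats`
times; hyperparameters are searched by successive halving (factor 3,
resource = training subsample size, smallest rung 2 × classes × folds capped
at the training size) scored by stratified k-fold CV macro F1 with k =
min(10, smallest training class); classes below 8 members are rejected
up front. Grids are small documented defaults (see
`analysis.DEFAULT_GRIDS`). XGBoost uses the exact tree method: histogram
binning places tie-breaking split thresholds at the edge of a class gap
rather than its midpoint and can flip margin points. Both per-class and
macro-averaged F1 are reported.

## Determinism and problem sizes

Every stochastic stage takes a seed; the pipeline derives per-stage seeds
from one root seed, and rerunning a pipeline with the same configuration
reproduces all tabular artifacts byte-identically. The bundled scenarios
(cohorts of 120–500 subjects, 100–300 features per platform) are sized so
that the full test suite and the acceptance script run in minutes on a single
CPU; all generator parameters scale to larger studies without code changes.

## Known limitations

The autoencoder assumes batch effects are stable within a batch up to a
linear-in-order drift; abrupt mid-batch shifts are not modelled. Corrected
intensities are reconstructions — features poorly captured by the latent code
plus batch inputs are smoothed toward their conditional means, which distorts
fold-change estimates (the recovery scenario shows ≈ 10–20% relative
deviation on a 1-log2FC effect, a slight overestimate at the default
settings). Deduplication requires class/carbon annotations to
apply its first two rules and silently skips them otherwise (logged). The
screening module validates fields but does not parse medical records; the QC
module reads feature-level observations, not raw chromatograms.
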