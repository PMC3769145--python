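# Methods

This note records the models, estimators, parameter choices and limitations
behind `methylnorm`, in enough detail to judge what the test suite does and
does not demonstrate.

## Signal model

Each CpG probe yields a methylated and an unmethylated fluorescence intensity
(M, U ≥ 0); the methylation fraction is summarized as
beta = M/(M + U + alpha) with alpha = 100 stabilizing low-intensity ratios,
and the logit-like M-value is log2((M + alpha)/(U + alpha)). Type I probes
(two beads, one colour) and Type II probes (one bead, two colours) have
systematically different background levels; because background adds to both M
and U, a higher Type II background compresses Type II betas toward 0.5. The
package's preprocessing philosophy is to correct technical structure on the
intensity scale — where nuisance effects are close to additive or
multiplicative — and only then form beta, rather than manipulating beta's
awkward bounded bimodal distribution directly. Background is *equalized*
between chemistries, never subtracted: background estimates are themselves
noisy, and removing them would add variance without improving group
comparisons.

## Quantile normalization

The QN engine maps every column (sample) onto the vector of row means of the
column-sorted matrix. Ties within a column receive the mean of the reference
values at the tied ranks. Consequences worth knowing:

- After QN, all columns share identical sorted values **exactly** when the
  input is tie-free. With ties (e.g. intensities clipped at zero) the
  tie-averaging rule preserves within-column rank order but the sorted
  multisets can differ between columns at the tied values. The test suite
  checks exact distribution equality on tie-free data and tie handling
  separately.
- Grouped normalization runs QN independently within row groups (probe
  types); the joined mode concatenates the M and U columns before QN so the
  two channels are forced onto one distribution, removing dye bias. A group
  with a single row is passed through with a warning.
- QN's known hazard: in sparse regions of the distribution the inverse-CDF
  is steep, so rank noise becomes value noise. The mid-beta region (the
  scientifically interesting one) is exactly such a region, which is why QN
  of beta (`betaqn`) tends to underperform QN of intensities.

## Background offset estimation

For each sample and channel the estimator locates the low-intensity density
peak of each probe type and reports offset = peak(Type II) − peak(Type I);
equalization adds this signed offset to the Type I intensities of that sample
and channel, clipping negatives at zero.

Peak location: a Gaussian-kernel density (Silverman's rule bandwidth) is
computed by linear binning on a 512-point grid spanning [0, max intensity] —
the same fast approximation R's `density()` uses — from the intensities below
the channel's median, i.e. the low-intensity mass where the background peak
lives. Three numerical safeguards matter:

1. the smoothing width is floored at two grid steps, otherwise the "mode"
   chases histogram noise when Silverman's bandwidth falls near the grid
   resolution;
2. the mode is refined by quadratic interpolation of the three grid points
   around the argmax, removing grid quantization (~half a grid step);
3. a second pass re-estimates the density from the values below
   (peak + 0.25 × median): how much mid-distribution plateau mass happens to
   fall below the median varies between samples and would otherwise sway the
   bandwidth and hence the located mode. Anchoring the window on the peak
   makes the estimate stable under shifts of the whole distribution — the
   property that guarantees offsets re-estimated after equalization are near
   zero.

If no intensity lies below the median (degenerate input), the estimator falls
back to the global mode with a logged warning.

Offsets are estimated per channel by default (the two channels' background
bumps sit at different positions once dye bias acts on the unmethylated
channel); `pool_channels=True` averages them into one offset per sample.
Position smoothing (`smooth_by_position`, used by `daten2`) replaces
per-sample offsets with fitted values of an ordinary least-squares model
offset ~ chip row, per channel; chip column can be added as a covariate.

## Quality metrics

- **DMRSE** = sd(all iDMR betas, pooled over probes and samples, sample
  variance) / sqrt(n samples). The pooled form is the default; per-probe
  ("row") and per-sample ("col") variants are available behind a mode flag.
  Note the 1/sqrt(n) scaling makes it comparable across cohort sizes.
- **GCOSE**: per SNP control probe, one-dimensional k-means with k = 3,
  initial centers (0.2, 0.5, 0.8), Lloyd iteration to convergence (tolerance
  1e-8, max 100 iterations), clusters labelled BB/AB/AA by ascending final
  center. Within-cluster sums of squares and sizes are summed across probes
  per group; MS_g = ΣSS_g/Σn_g; each MS_g is divided by sqrt(total samples)
  and the three are averaged. The fixed initialization makes the procedure
  fully deterministic (the `seed` argument exists for interface uniformity
  only). A probe with fewer than three distinct values is clustered with
  reduced k and contributes only to the genotype groups it forms (matched to
  group slots by nearest canonical center, conflicts resolved by optimal
  assignment); an empty cluster contributes nothing.
- **Seabird** = 1 − AUC, with AUC computed by the rank-sum (Mann–Whitney)
  formulation on score = −p (ties share average ranks), positives =
  X-chromosome probes. p-values come from per-probe two-sided Welch t-tests
  of female vs male betas; probes with zero variance in both groups score
  p = 1 when means are equal. Y-chromosome probes count as negatives by
  default (`include_y=False` drops them). Bonferroni-corrected significance
  counting is provided as a reporting utility only; Seabird itself ranks raw
  p-values.

All three metrics are invariant under probe and sample reordering, and all
are computed separately for Type I and Type II probe subsets (Seabird's ROC
restricted to probes of the assay type being scored).

## Ranking (steps A–F)

Per dataset and probe type: compute the metrics (A), collapse the three
genotype-group scores to one GCOSE by averaging (B), rank methods within each
metric ascending (C), average the three metric ranks per method (D); then
average those mean ranks across datasets per type (E) and rank the averages
(F), ties receiving mean ranks throughout (hence fractional ranks like 1.5).
The reported table holds the Type I rank, Type II rank, and their mean.
Step F ranks the step-E mean-of-mean-ranks — the ranking is therefore
invariant to any strictly increasing transform applied uniformly to one
metric. Datasets are weighted equally regardless of sample size. A metric
missing for *every* cell (e.g. Seabird on a single-sex cohort) is dropped
with a logged note; a metric missing for only some cells is an error rather
than a silent imputation.

## The synthetic-array generator

`SimulationConfig` defaults define the study conditions used throughout the
tests and the acceptance script: 20 samples, 20,000 autosomal + 237 iDMR +
65 SNP + 500 X-chromosome probes (X probes are 2.3% of the total, the same
proportion as the 11,232 X features on the real 485k-probe array), 72% Type
II. Intensity units mimic scanner counts: mean total signal 4,000, Type I
background 300, Type II background 800, Type II dye-bias multiplier 1.3 on
the unmethylated channel.

True methylation: autosomal probes draw from a three-component mixture —
40% unmethylated (Beta(2,40)), 40% methylated (Beta(40,2)), 20% intermediate
(Beta(5,5)); the sizeable intermediate fraction matches real tissue data and
keeps the mid-beta density realistic (QN behaviour there depends on it).
iDMR probes sit at theta = 0.5; SNP probes draw Hardy–Weinberg genotypes at
per-probe allele frequencies (default U(0.2, 0.8)) giving theta ∈ {0, ½, 1};
X probes are hypermethylated in females (0.5 + U(0, 0.3)) and low in males
(U(0.05, 0.25)), except a 20% XCI-escape fraction with no sex difference —
so even a perfect method cannot reach Seabird = 0, mirroring real arrays.
Per-cell biological/technical scatter applies a Beta distribution around
theta with concentration 150 (sd ≈ 0.04 at theta = 0.5).

Per-sample technical structure — the variation between-array normalization
exists to remove — comprises: lognormal intensity scaling (sd 0.15),
background-level jitter shared by both probe types and channels (sd 150),
lognormal dye-bias variation around the Type II multiplier (sd 0.15), and
incomplete bisulfite conversion (a half-normal fraction f, scale 0.02, of
unmethylated cytosines reading methylated: theta → theta + f(1−theta),
applied to methylation probes but not to SNP genotyping probes). The nuisance
magnitudes are realistic for scanner data and were fixed at levels where the
simulated method ordering is stable across replicate seeds, which is what the
default scale is for. An optional chip-row gradient tilts the *Type II*
background (units per row), so the Type II − Type I offset varies linearly
with row at exactly the configured slope — making the gradient recoverable
from smoothed offsets by construction. Intensities are
M = theta·T + b + noise, U = (1−theta)·T·d + b + noise (additive Gaussian
noise sd 100, clipped at zero), with T the per-cell total intensity.

What the generator does **not** emulate: probe-sequence effects (GC content,
degenerate bases), spatial within-chip correlation beyond the row gradient,
batch structure across chips, cell-composition heterogeneity, detection
failures, or missing values. Passing tests therefore demonstrate internal
consistency and correct behaviour under the modelled nuisances — not
performance on any particular real cohort.

## Numerical and interface choices

- alpha is applied after normalization (beta is formed from normalized
  intensities); alpha = 0 with M = U = 0 raises rather than imputing.
- Negative intensities after equalization are clipped to zero (the beta
  domain requires M, U ≥ 0).
- Missing intensities are rejected at parse time, never imputed: the QN
  engine's contract assumes complete matrices.
- Chromosome labels are stored without a "chr" prefix; X/Y comparison is
  case-insensitive.
- The Type I Red/Grn sub-channel is carried in the manifest but not used to
  stratify QN further (stratification is by assay type and M/U only).
- `MethylationNormalizer` follows the scikit-learn transformer contract
  (get_params/set_params, fitted `spec_`/`offsets_` attributes). Quantile
  normalization has no out-of-sample reference distribution — each dataset is
  normalized against itself — so `transform` is per-dataset and `fit`
  resolves and validates the configuration; `offsets_` holds the diagnostics
  of the most recent transform.
- Determinism: the simulator derives independent sub-streams from one seed;
  `gcose` is deterministic by construction; the `evaluate` pipeline writes
  byte-identical outputs for a fixed seed.

## Test-condition choices

- Exact distribution-equality checks run on tie-free simulated data
  (additive noise off, so no zero-clipping ties).
- Gradient-recovery checks use a 48-sample fixture at 50 units/row and
  regress the *methylated*-channel smoothed offsets on chip row: that channel
  carries no dye bias, so its offsets isolate the injected gradient; 48
  samples keep the slope standard error a factor ~3 below the 10% tolerance.
- The method-ordering study uses 10 replicate datasets at default scale
  (~21,300 probes × 20 samples) and the method set {raw, betaqn, danen,
  dasen}; it runs in well under a minute on one CPU.

## Known limitations

- The background peak estimator assumes a unimodal low-intensity bump well
  separated from the signal mass; arrays whose background and signal merge
  (very low-quality samples) would need the logged fallback path and manual
  review.
- The `daten1`/`daten2` distinction (per-sample vs position-smoothed offsets)
  is the package's interpretation of an otherwise identical design point; it
  is isolated behind the method registry.
- Ranking requires every method × dataset × type cell; it does not handle
  partially missing designs beyond dropping a wholly absent metric.
- Sample-failure screening (atypical intensity distributions, poor
  inter-sample correlation) is out of scope; inputs are assumed to be
  passing samples.
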