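# Methods

## The problem

Normalization of targeted expression assays (qPCR, ddPCR) divides a
target's measured level in each sample by a normalization factor built
from reference genes whose expression is insensitive to the condition
under study. In a time course that globally reorganizes the
transcriptome — the motivating system is dark-induced senescence of
barley leaves — candidate references must first be mined from genome-wide
data and then validated. `refnorm` implements that workflow plus the
synthetic data needed to test it.

## Models and procedures

### Synthetic time course (`refnorm.simulate`)

The generator emulates a 6 × 3 design: time points (days) 0, 3, 5, 7,
10, 12 with 3 biological replicates, one array/RNA sample per cell.

* **True abundance.** Each gene is `stable` (constant), `up` or `down`.
  Responder trajectories are linear in log2 between the day-0 level and
  the day-12 endpoint (the simplest monotone shape); endpoint
  magnitudes are drawn uniformly from `up_fold_range_log2` /
  `down_fold_range_log2` (default 1.5–4 log2 units, i.e. ~3–16-fold).
  Base levels are log2-uniform over ≈ 90–2000 copies/µl so that ddPCR
  occupancies λ = c·v stay in the quantifiable range.
* **Sample scale factors.** One log-normal factor per biological
  sample, `exp(N(0, sample_scale_sd))`, shared by every gene measured
  in that sample. This models RNA-quality/reverse-transcription/input
  variability and is what produces congruent raw profiles across
  unrelated genes. Default sd 0.3 (natural log, ≈ 31% CV): the source
  study does not report the magnitude it observed, and 0.3 reproduces
  raw replicate CVs of roughly 0.2–0.7, the range its CV table shows.
* **Expression matrix.** log2 intensity = log2(abundance) +
  log2(scale) + N(0, `biological_noise_sd`); default gene-level noise
  0.1 log2 units.
* **Cq tables.** Cq = intercept − log_E(abundance × scale) +
  N(0, `cq_noise_sd`) per technical replicate (default 3 replicates,
  noise 0.15 cycles, intercept 35, efficiency E = 2). Technical
  replicates share the sample's scale factor; only the technical noise
  differs.
* **Droplet wells.** The accepted droplet count n is uniform over
  14,000–17,000; positives are k ~ Binomial(n, 1 − exp(−c·s·v)) with
  v = 0.85 nL. This is the exact marginal law of Poisson molecule
  placement, without simulating individual molecules. The panel builder
  additionally applies the gene-level log-normal noise to the
  concentration, so normalized data retain a realistic residual floor.
  NTC wells are simulated at `ntc_background` (default 0) copies/µl.

The default ddPCR panel has five stable references (three high, two
2–3× lower, mirroring the validated candidate set) and two 8-fold
markers (`marker_up`, SAG12-like; `marker_down`, RbcS-like).

What the generator does **not** emulate: PCR chemistry and efficiency
drift, droplet "rain" (intermediate fluorescence), probe annotation
noise, partial RNA degradation correlated with phenotype, or array
spatial artifacts. Passing tests therefore demonstrate the statistical
machinery under the assumed noise model, not robustness to those
real-data pathologies.

### Stable-gene screen (`refnorm.screen`)

Per-day log2 fold changes are day-mean differences versus the baseline
day (first day listed in the design; labels are opaque). Differential
expression requires both |log2FC| ≥ log2(2) at some day and BH-adjusted
p < 0.0005 from a per-gene one-way ANOVA F across days (externally
computed p-values are accepted; moderated/empirical-Bayes F statistics
are deliberately out of scope). "Progressive" responders additionally
change ≥ 2-fold between the early (day 3) and late (day 10) stage.

The candidate screen keeps genes with

1. |2^log2FC − 1| < 0.20 at every non-baseline day — the 20% bound is
   applied on the linear scale, which makes it asymmetric in log space,
   exactly as a percent change is;
2. A_mean (per-gene mean intensity) inside the "typical expression"
   window, by default the min–max of the DE genes' A_mean (the literal
   reading of "within the range"), optionally percentile bounds
   (linear-interpolation percentiles);
3. CV_A = sd/mean of the per-array values, n−1 denominator, computed on
   the stored (log2) scale, < 0.01.

Candidates are reported sorted by ascending CV_A. The cascade is
monotone in both thresholds (property-tested).

### geNorm statistics (`refnorm.genorm`)

Input quantities must be strictly positive. From Cq, technical
replicates are averaged on the Cq scale, then
q(g, s) = E^(minCq_g − meanCq(g, s)), so each gene's best-expressed
sample has q = 1 (default E = 2; per-gene override). All standard
deviations use the n−1 denominator, logs are base 2.

Stepwise exclusion removes, at each round, the gene with the largest M
recomputed on the remaining set; exact ties remove the gene later in
input order (deterministic). The final two genes cannot be separated by
the pairwise statistic and share rank 1. V_{n/n+1} is the sd over
samples of log2(NF_n/NF_{n+1}), NF_n being the geometric mean of the n
top-ranked genes' quantities.

By construction M and V are invariant under per-sample and per-gene
rescaling; the test suite asserts this numerically and checks M against
an independent brute-force double loop at 1e-12.

### Poisson droplet quantification (`refnorm.ddpcr`)

λ = −ln(1 − k/n); concentration = λ/v with v in µl (droplet volume is
instrument-specific and not always published; the 0.85 nL default is
the common QX200 figure and the copies/µl scale is proportional to it).
The 95% CI uses the delta-method standard error σ_λ = √(k/(n(n−k)));
a parametric bootstrap validates it in the tests (vendor software may
differ in the third digit). Edge cases: k = 0 is a valid zero estimate
with a one-sided rule-of-three upper bound −ln(1 − 3/n)/v; k = n is a
saturation error, not infinity. Background correction subtracts the
mean NTC concentration per target and floors at zero; targets with no
NTC well are left uncorrected with a warning. copies/ng = conc ×
reaction volume / cDNA input, only when the input mass is given.

### Normalization evaluation (`refnorm.normalize`)

NF(s) is the geometric mean of the chosen references' levels in sample
s; normalized values are dimensionless ratios (no rescaling back to
copies/µl — every downstream summary here is scale-free, so the
arbitrary constant is omitted). CV is the n−1 sd over the arithmetic
mean across the biological replicates of one day;
CV_reduce = 100·(CV_raw − CV_norm)/CV_raw and may be negative when
normalization adds noise (typical when raw CV is already small).
Baseline-scaled profiles divide each replicate's trajectory by its own
day-0 value (default, per-replicate mode) or day means by the day-0
mean (mean mode). Because CV is scale-invariant, CV_reduce is identical
in copies/µl and copies/ng units at constant input mass.

The bundled worked table (`refnorm.datasets`) carries published CVs
printed to two decimals; percentages recomputed from the printed pairs
agree with the printed percentages only to within the propagated
half-ULP of that rounding (≈ ±0.8 points where raw CV ≥ 0.65, wider
where raw CV ≈ 0.16), which the tests encode explicitly.

## Problem sizes and numerical choices

* Monte-Carlo checks use 5,000–10,000 wells of 15,000 droplets
  (estimator bias < 1%, CI coverage 93.5–96.5%) and 100 random matrices
  for the oracle equivalence; the end-to-end normalization study uses
  20 seeds of the default 6 × 3 panel. These sizes give sub-percent
  Monte-Carlo error on every asserted quantity.
* The screen-recovery scenario uses 2,000 genes with 100 injected
  ≥4-fold responders and low residual noise (gene noise 0.02 log2,
  sample scale sd 0.02), i.e. a well-normalized array study — the
  regime in which an exact-recovery claim is meaningful.
* All randomness flows through `numpy.random.default_rng`; pipeline
  stages draw from one generator in a fixed order, so a seed fixes
  every output byte.
* Floating-point ties in stepwise exclusion are resolved by input
  order; sorting of candidates uses a stable sort.

## Design choices and limitations

* The sklearn-estimator surface mirrors the natural shape of each step
  (screen = feature selection on arrays × genes; stability = selector;
  normalization = transformer). Per-well droplet arithmetic and the
  generator remain plain functions.
* Whether real geNorm runs are fed raw Cq or transformed quantities
  varies in practice; the transform above is the documented
  requirement, and the `stability` CLI accepts either input type.
* Real microarray intensity pipelines (two-channel merging, probe
  annotation) and fluorescence thresholding of droplets are upstream of
  this package: it starts from a normalized matrix and from
  positive/negative counts respectively.
* CV_A's scale (log versus linearized intensities) is not standardized
  in the field; it is computed on the stored scale and the threshold is
  configurable.
* The published gene counts and M values of any particular real study
  depend on its raw data and are not reproduced here; the package's
  claims are about the statistical machinery, validated on labelled
  synthetic data and hand-checkable worked examples.
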