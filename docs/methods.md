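# Methods

## The probe-level model

A probeset's evidence for differential expression between two arrays is the
sum of its probes' background-corrected intensity differences, each weighted
by a heteroscedastic error estimate:

    GCSs_k = Σ_{i=1..N} (l_iB − l_iA) / (ε_i √N)
    ε_i    = sqrt( γ² (l_iA² + l_iB²) + SDT_A² + SDT_B² )

The error model has two regimes. Near the noise floor the additive term
dominates: SDT = 4·rawQ·SF, where rawQ is the sample standard deviation
(n−1 denominator) of the lowest ⌈2%⌉ of all probe intensities on the array
and SF is the factor that scales the median grouping-level intensity to a
target (default 500 — the MAS5 convention, making SDT the familiar "4
standard deviations above noise" threshold on the scaled scale). For bright
probes the proportional term dominates and the score of a fixed fold change
saturates at a γ-limited ceiling (≈ √N·Δ/(γ‖l‖)), which is what makes the
statistic sensitive to *relative* rather than absolute change; γ = 0.1
throughout. Note the proportional term uses the **sum** of the two squared
intensities: this is the only symmetric, always-real form of the error term
and matches the original S-score error model that this method extends.

### Processing order

1. SF from the **raw** intensities of the grouping-level PM probes
   (plain median; symmetric trimming cannot move a median, so the "trimmed
   median" of array software is a no-op here).
2. rawQ from the **raw** intensities of all probes (PM, MM, BG); SDT =
   4·rawQ·SF puts it on the scaled scale.
3. All intensities multiplied by SF; GC background medians computed on the
   scaled values; subtraction last. Corrected intensities may be negative —
   the score is difference-based and clipping would bias it.

### Background correction

On whole-transcriptome designs each PM probe's non-specific binding is
estimated as the median scaled intensity of the antigenomic (no genomic
target) probes with the same G+C count (stored as an integer 0–25 for the
25-mer probes). GC bins without background probes borrow the nearest
populated bin, ties toward the lower GC count; antigenomic panels span GC
3–25, so the fallback is rarely exercised. On 3′ IVT designs the paired MM
probe is subtracted instead. When every MM intensity equals the background
median of its PM's GC bin the two corrections are algebraically identical —
the test suite constructs exactly this fixture.

### Normalization

Raw scores are standardized using the scores between the 1st and 99th
percentiles (linear interpolation, inclusive bounds): subtract the trimmed
mean, divide by the trimmed sample SD rescaled by the Gaussian truncation
constant c = SD(N(0,1) | middle 98%) ≈ 0.93460. Without that rescaling a
Gaussian null would come out with overall SD ≈ 1/0.9346 ≈ 1.07 rather than
the advertised 1; with it, the null output is standard normal while genuine
outliers (which the trim excludes from the *estimate* but not from the
*transform*) keep |score| ≫ 3. The normalization presumes differential
expression is sparse; with a large changed fraction the middle-98% spread
absorbs part of the signal and scores compress toward zero. A zero trimmed
SD (e.g. scoring an array against itself) raises a degenerate-distribution
error; the CLI downgrades this to a warning and emits raw scores.

## Replicated workflow

Scores are oriented control→treatment (control is array A), so positive
values mean up-regulation. For T treatments × C controls, all T·C pairs are
scored; each treatment's C scores are averaged (keeping T semi-independent
values per probeset rather than inflating n to T·C), and the mean of those
T averages is AvgSs, the effect-size filter (|AvgSs| > 1.8 ≈ the point
where a standard-normal score becomes individually notable).

The T replicate averages feed a one-class SAM test of mean ≠ 0:

- d_i = x̄_i / (se_i + s0), se_i the row standard error;
- s0 chosen from the {0,5,…,100}-percentile grid of se, minimizing the
  coefficient of variation of the median absolute deviations of d across
  100 se-quantile bins;
- null distribution from sign-flipping the T columns — exhaustive over all
  2^T assignments while 2^T ≤ 4096, otherwise a seeded sample of distinct
  sign vectors;
- q_i = π0 · median_b #{|d_b| ≥ |d_i|} / #{|d_obs| ≥ |d_i|}, monotonized
  (running minimum from the least-significant end, the usual q-value
  convention) and clipped to [0,1], with π0 = min(1, 2 · fraction of
  observed d inside the pooled permuted-d IQR).

With a fixed seed the whole pipeline is bit-reproducible.

### A calibration caveat that users should know

The replicate-average columns are **not** independent: two pair scores that
share an array are correlated 0.5 (the shared array contributes half of the
difference variance), so with pair scores normalized to SD 1 the T columns
have correlation 0.25 and the observed column-mean variance (1/3 for T=C=3)
exceeds what balanced sign flips can reproduce (0.185). The sign-flip null
therefore understates null |d|, and one-class SAM on shared-control
replicate averages is intrinsically anti-conservative: in simulations with
1% truly changed probesets at |log2FC| = 1 the combined q ≤ 0.05 and
|AvgSs| > 1.8 rule recovers ≈ 95% of true changes but the realized
false-discovery proportion is ≈ 0.25–0.30, not the nominal 0.05. This is a
property of the design (it would affect any implementation of this
workflow, including the original R-based one), not of the simulator: the
0.5 correlation holds for any exchangeable noise model. On independent
rows the same SAM implementation is well calibrated (realized FDP ≈ 0.05
at q ≤ 0.05 in the test suite). Practical mitigation is a stricter cutoff
— q ≤ 0.0125–0.015 is the conventional choice for this workflow — or
treating q as a ranking rather than a literal FDR.

## The synthetic-data generator

Simulated arrays reproduce the features the method relies on:

- per-probeset abundance θ_k ~ lognormal(log 300, 1) — a broad expression
  range with the array median landing near the few-hundred-unit scale of
  real scanners;
- a fixed per-probe affinity multiplier, lognormal with log-SD 0.25,
  **identical across arrays**: probe-level differencing cancels it, which
  is precisely the mechanism the statistic exploits and must be present in
  any faithful simulator;
- non-specific background rising linearly with GC count, bg(gc) = 40 +
  4·gc (≈52 at GC 3 to ≈140 at GC 25) — the minimal structure honouring
  the GC-dependence of non-specific binding; curvature is a config knob;
- multiplicative lognormal measurement noise with mean 1 and CV 0.1 on
  every probe (background and MM probes see background × noise only);
- a chosen fraction of probesets carries a signed log2 fold change in the
  treatment arm; 3 treatment and 3 control arrays by default, matching the
  replicate numbers typical of the studies this method targets.

Not modelled: spatial artifacts, scanner saturation, cross-hybridization,
probe-sequence effects beyond GC content, and biological replicate
variability (arrays differ only by measurement noise). Passing tests
therefore demonstrate the algorithm's internal correctness and null
calibration, not robustness to those real-data phenomena.

Default problem sizes in the tests and the acceptance script (5,000-probeset
chips for pipeline calibration, 20,000 for the null-distribution summary,
10 simulation seeds for recovery rates) are chosen so Monte-Carlo error is
small relative to the tolerances being asserted; the null-distribution
summary uses the larger chip because the standard error of the mean at
5,000 probesets (~0.014) would be a sizeable fraction of its ±0.02 band.

## Numerical and design choices

- Percentiles/quantiles: linear interpolation between order statistics,
  inclusive endpoints, everywhere.
- Chip definitions are an open three-table TSV schema rather than vendor or
  Bioconductor formats: the algorithm needs only probe → GC → probeset
  structure, and flat tables keep it inspectable and platform-independent.
  A PM probe may belong to one TC set and one PSR-or-JUC set (gene-level
  and exon-level groupings reuse probes); uniqueness is enforced per level.
- Intensity input: two-column TSV or plain-text CEL v3 with cell (X,Y) →
  probe index Y·Cols + X; the MEAN column is the intensity, STDV/NPIXELS
  ignored. No saturation masking is applied. Binary Calvin CEL is out of
  scope by design (vendor container plumbing, conversion tools exist) and
  is rejected with an explanatory error.
- rawQ is global ("across the array"), not zone-based; SF's median is over
  grouping-level PM probes only.
- normalize_scores requires ≥ 10 finite scores — below that a trimmed
  spread estimate is meaningless.
- Exhaustive sign-flip enumeration bounded at 2^T ≤ 4096 keeps the exact
  null affordable through T = 12; beyond that, seeded sampling without
  replacement.

## Known limitations

- The anti-conservative FDR under shared-control averaging described above.
- Exon-level (PSR/JUC) scoring is structurally identical to gene-level
  scoring with a different grouping; junction-specific phenomena
  (cross-junction hybridization) are not modelled.
- The normalization constant assumes Gaussian-like score cores; for very
  heavy-tailed raw score distributions the null SD can exceed 1 by a few
  percent (the simulations in the test suite measure ≈ 1.03).
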