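# Methods

## Problem and pipeline

ALK-rearranged non-small-cell lung cancers respond to ALK kinase
inhibitors, so patients must be triaged by a companion diagnostic.
`alkscreen` implements, as a reusable and fully testable pipeline, the
computational path from microarray marker discovery to a three-level qPCR
rearrangement caller, together with simulators for the input data and for
the confirmatory assays (break-apart FISH, IHC) so that every stage runs
and is verifiable without external downloads.

The stages, in execution order:

1. **synthetic cohort** (`alkscreen.synthetic`) — probe-level expression,
   qPCR Ct tables and ground truth for a cohort with ALK-positive,
   EGFR-mutant, KRAS-mutant, triple-negative and adjacent-normal subgroups;
2. **marker screen** (`alkscreen.screen`) — quantile normalization,
   median-polish summarization, SAM permutation statistics, fold change,
   signal correlation, probe-to-transcript matching;
3. **qPCR caller** (`alkscreen.caller`) — marker ΔCt, 5′/3′ imbalance ΔCt,
   combined score with learned cutoffs, fusion-subtype panel
   interpretation, integrated status call;
4. **reference truth** (`alkscreen.truth`) — FISH/IHC simulation and
   PCR-vs-FISH concordance;
5. **io / cli** (`alkscreen.io`, `alkscreen.cli`) — file formats and the
   `alkscreen` subcommand interface.

## Marker screen

**Quantile normalization.** Each array column is mapped onto the mean
empirical distribution: sorted values of every column equal the
across-column mean of sorted values. Ties within a column receive the mean
of the reference values at their tied ranks. The transform is idempotent
(to 1e-12) on tie-free input; tie-averaging perturbs the reference on a
second pass, so exact idempotence is a property of distinct values.

**Summarization.** Per probe set, Tukey median polish decomposes the probe
× sample sub-matrix into overall + probe (row) + sample (column) effects +
residuals, sweeping row then column medians until the largest effect change
in a sweep is below `tol` (default 1e-10) or `max_iter` (100) is reached.
Reported expression is overall + column effect, the RMA convention. The
sweep order (rows, overall from columns, columns, overall from rows)
matches the classical algorithm, so results agree with an independent
iterative-median implementation to 1e-8 on small random matrices.

The convolution background-correction step of full RMA is not implemented:
it requires raw scanner-scale intensities, while quantile normalization and
median polish are the computationally load-bearing parts for log-scale
input. This is a deliberate simplification of scope, not of the two
implemented steps.

**SAM.** For two classes, the moderated statistic is
`d_i = (x̄_pos − x̄_neg) / (s_i + s0)` with `s_i` the pooled two-sample
standard-error term and `s0` chosen on the percentile grid (0, 5, …, 100)
of `s` to minimize the coefficient of variation of median |d| across
windows of genes ordered by `s` (10 windows, fewer when the matrix is
tiny). q-values come from class-label permutations: all distinct label
splits when there are no more than `n_perm` of them, otherwise `n_perm`
splits sampled without replacement from the given seed. For each gene, the
estimated false-positive count is the median over permutations of the
number of permuted |d| at or above the observed |d|; dividing by the
observed count at that threshold, clipping to [0, 1] and enforcing
monotonicity along the |d| ranking gives the q-value. Ties in |d| are
broken by lexicographic probe-set id so ranks are deterministic. No π₀
estimate is applied; the q-values are therefore conservative, which the
null-calibration test confirms (observed null fraction at q ≤ 0.05 is well
below 0.05).

**Fold change** is `2^(Δ of mean log2 expression)` — the standard
convention for RMA-scale output — and is location-invariant on the log
scale.

**Probe matching** is an ungapped Hamming scan of the probe (and by
default its reverse complement) along each transcript, 0-based half-open
coordinates, `N` matching nothing (an N/N alignment still counts as a
mismatch), default at most 1 mismatch. Short oligo probes make gapped
alignment unnecessary.

## qPCR caller

Conventions (cycle-threshold scale; lower Ct = more template):

- `ΔCt_marker = Ct(marker) − (Ct(HPRT1) + Ct(ESD)) / 2`. The two reference
  genes are averaged on the Ct scale; under equal amplification
  efficiencies this equals the geometric-mean normalization of abundances.
- `ΔCt_imbalance = Ct(ALK 3′) − Ct(ALK 5′)`: negative when the retained 3′
  kinase-domain side is overexpressed. Reference genes cancel by
  construction, and any per-sample additive Ct shift (global efficiency or
  input-amount shift) leaves both ΔCt values unchanged.
- combined score = the sum of the two; it is the primary classifier
  because the two evidence levels are driven by the same underlying event
  and their noise is largely independent.

Censored (no-amplification) Cts are replaced by the max-cycle sentinel
(default 40 cycles, the number of cycles run) with an explicit flag —
absence of amplification is informative for negatives and is never
silently imputed. A censored reference gene is a QC failure: the sample is
reported indeterminate.

**Cutoffs** are learned from labeled samples per evidence level: the
midpoint between the maximum positive-class and minimum negative-class
score when classes separate perfectly, otherwise the Youden-J maximizing
threshold (ties toward higher specificity; the median score when the score
carries no information). Lower score ⇒ positive throughout.

**Subtype panel.** A primer pair is detected iff its amplicon Ct ≤
`ct_detect` (default 35 cycles) and its melt temperature is within `tm_tol`
(default 0.5 °C) of the pair's expected Tm — conventional qPCR practice.
Among multiple detections the lowest Ct wins (tie: lexicographic variant
id) with a multi-detection flag; a winning pair covering several variants
returns the covering set with an ambiguity flag.

**Integration.** Evidence flags (marker, imbalance, combined, subtype) fire
independently against their cutoffs. Status is positive when the combined
score is below its cutoff or a subtype amplicon was detected; a detected
subtype in a score-negative sample yields a positive call annotated as
discordant. The `combined` flag exists so that a positive status always
carries at least one piece of evidence even when neither component crosses
its own cutoff.

## Reference-truth simulation

**FISH.** Scored cells showing a rearranged pattern are
`Binomial(n_cells, f)` with `f` the tumor fraction for true positives and a
configurable false-signal rate (default 0) otherwise. The call is positive
iff the count strictly exceeds 15% of 50 scored cells, i.e. at least 8
cells (7/50 = 14% is negative; the boundary is pinned by test). The exact
positive-call probability is the binomial tail `P(K > 0.15·n)`; at
f = 0.03 it is 1.14 × 10⁻⁴ — a specimen with ~3% rearrangement-bearing
cells essentially always reads FISH-negative. The two clinically described
positive signal patterns (break-apart, isolated red) are collapsed into a
single positive-cell event since the decision rule depends only on the
combined count.

**IHC.** The 0–3 score is drawn from a configurable categorical
distribution conditional on true status (default: degenerate, 3 for
positives and 0 for negatives); when rearranged cells do not exceed 10% of
the specimen the score is capped at 1. The call is positive at 2+/3+.

**Concordance** is a 2×2 table with PCR as index and FISH as reference;
indeterminate PCR calls are excluded and listed separately.

## Synthetic-data generator

The generator's defaults are the study conditions the rest of the package
is tested under.

- **Cohort.** Default 16 ALK-positive / 40 negative (18 EGFR, 8 KRAS, 10
  triple-negative, 4 normal) for fast tests; `SimConfig.full_cohort()`
  switches to the full-size composition (11 / 127 / 20 / 68 / 20 = 246
  arrays) that the screening fold changes refer to.
- **Probe intensities** are log2-additive Gaussian: probe-set baseline +
  fixed probe affinity offset (SD 0.7, giving median polish nontrivial row
  effects) + group effect + noise (SD 0.5 log2 units). Background probe-set
  baselines are uniform over log2 4–13, the dynamic range of summarized
  arrays; the two designated probe sets (marker and ALK-3′ analogues) sit
  at background (log2 = 5) in negatives — the marker is a non-coding RNA
  with below-background signal outside the ALK subgroup — and are elevated
  by log2(37.4) ≈ 5.22 and log2(29.8) ≈ 4.90 in ALK-positive samples. The
  wide baseline range keeps the elevated values at interior quantiles of
  the array distribution, where quantile normalization preserves effect
  sizes as it does on full 54k-probe arrays; concentrating all baselines
  near one value would push the marker probes into the extreme ranks of
  these small simulated arrays and compress the recovered fold change, a
  small-array artifact with no real-data counterpart.
- **Ct model.** `Ct = intercept − log(a) / log(E) + N(0, σ)` with relative
  abundance `a`, efficiency `E` (default 2, the assumption underlying ΔCt
  arithmetic), intercept 28 cycles at unit abundance and σ = 0.3 cycles.
  Cts above 40 cycles (and targets with zero abundance) are censored.
  Abundances: marker 1.0 vs 0.005 (200-fold contrast, matching the
  >100-fold expression difference between positive and negative cells),
  ALK 3′ 3.2 vs 0.05 (~6-cycle imbalance at full tumor fraction), ALK 5′
  and reference genes constant. Variant amplicons amplify only in samples
  whose variant the pair covers, at 0.5 × tumor fraction; their melt
  temperatures are jittered 0.1 °C around the pair's expected Tm.
- **Tumor fraction** is uniform on (0.3, 0.9) for positives and acts
  linearly on fusion-derived abundance — the simplest mechanism that
  reproduces, at f ≈ 0.03, the PCR-positive/FISH-negative presentation: at
  3% tumor cells the variant amplicon still crosses threshold near cycle 34
  (no competing background signal) while the combined score sits in the
  negative range and FISH is negative with near-certainty.
- **Panel.** `build_default_panel()` is a synthetic stand-in: 17 primer
  pairs covering 27 hybrid variants across EML4, KIF5B, STRN, KLC1, TFG,
  CUX1, TPR and HIP1, with invented variant names and melt temperatures;
  real panels are user-supplied TSVs. The default variant catalogue drawn
  from in simulation contains three EML4-ALK variants and one KIF5B-ALK,
  echoing the variant spectrum seen clinically.
- **Noise distributions** for Ct and tumor fraction are stated assumptions
  (Gaussian, uniform); no published distributional detail exists for them.
- **Randomness.** One seed; each operation (truth assignment, probe
  matrix, Ct table) draws from a deterministically derived sub-stream, so
  fixed seed ⇒ bit-identical outputs and partial reruns are reproducible.

What the generator does **not** emulate: raw scanner images or CEL-format
intensities (so the RMA convolution background step is untestable here by
design), probe-sequence-level fusion breakpoints, batch effects,
RNA-quality gradients, inter-observer IHC variability beyond the score
table, and correlated noise across assays. Passing tests therefore
demonstrate correctness of the computations and the internal consistency
of the three-level logic under the stated generative model — not clinical
performance on real specimens.

## Numerical choices

- Median polish: convergence tol 1e-10 on the max effect change, 100
  sweeps maximum; 1-probe sets reduce to the probe row exactly.
- Quantile normalization: stable mergesort ranking; tie blocks averaged.
- SAM: s0 grid of 21 percentiles; strictly-better comparison (1e-15
  slack) keeps the smallest candidate under exact CV ties, and an all-zero
  d vector yields CV 0 so the null case picks the first candidate.
- Cutoffs: candidate thresholds are midpoints of consecutive unique
  scores plus sentinels beyond both extremes.
- Degenerate inputs raise typed errors (`ValidationError`, `ConfigError`,
  `QCError`, `ParseError`) rather than producing silent NaNs; censored
  values are explicit flags end to end.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200 probe sets
× 4 probes, 56-sample default cohort (246 for the full-size preset), SAM
with up to 1000 permutations (100–200 in repeated-seed loops), 20–50 seeds
for recovery/calibration/discordance checks, 10⁵ replicates for the FISH
Monte-Carlo comparison. These sizes make every property measurable in
seconds while leaving all effect sizes at their study values.

## Known limitations

- The fold-change convention (2^Δ of log2 means) is fixed here; analyses
  computing fold change on linear-scale means will differ.
- The algebraic definition of the imbalance ΔCt (3′ minus 5′, references
  cancelling) is one reasonable reading of a quantity usually presented
  only graphically; the sign convention is documented and tested, not
  assayed against an external standard.
- Clinical cutoffs are learned from labeled data per cohort; no universal
  cutoff is claimed, and cutoff transfer across cohorts is out of scope.
- The subtype panel is synthetic; real primer pairs, their cross-reactivity
  and their melt behavior must be characterized by the user.
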