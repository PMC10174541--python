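# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `sterilopt`.

## Data model

The experiment is a factorial screen: six disinfectants, each tested at
4–5 concentration levels × 3 immersion times, with untreated controls
repeated in every disinfectant's table (90 printed rows in total; the
repeated controls are kept per table so each disinfectant's subset is
self-contained). Each row carries mean ± standard error of two responses
on the percent scale: contamination rate and seed germination.

Treatments are encoded as 7-entry feature vectors — one concentration
slot per disinfectant plus immersion time — with at most one nonzero
concentration slot per row (the design never mixes disinfectants;
controls have all slots zero). Features are min–max scaled to [0, 1] on
the training subset (constant columns map to 0); responses stay on the
raw percent scale, which is the only scaling consistent with reporting
RMSE in percentage points. Train/test splits are random at the row
level, stratified by disinfectant table so no disinfectant can vanish
from either subset at this small n; the train size is
⌊fraction · n⌋ exactly.

## Synthetic replicates

Only treatment means and SEs were published. The generator treats the
printed SE as the standard error of a mean over k = 8 sub-set
datapoints, so each treatment is expanded into k replicates drawn from
Normal(mean, SE·√k) truncated to [0, 100]. Truncation (rather than
clipping) avoids point masses at the range ends that would bias
treatment means. With SE = 0 the replicates are exactly the mean. All
draws are reproducible from a single seed.

What the generator does *not* emulate:

* **Seed-level granularity.** Real responses are proportions out of 12
  seeds; replicates here are continuous percentages.
* **Replicate spread beyond mean ± SE.** The printed SEs are small
  (≤ 1.7 points), so the synthetic replicates cluster tightly around
  their treatment means, and every treatment's feature vector occurs
  identically in train and test. Consequently a memory-based model can
  nearly interpolate the surface: the GRNN/RBF test R² on this synthetic
  data is ≈ 0.99, well above the ≈ 0.84–0.89 reported for the original
  (unpublished) replicate-level data, whose within-treatment spread was
  evidently much larger. Passing model-quality tests on the synthetic
  data therefore demonstrates correctness of the pipeline, not the
  generalization error one would see on raw experimental replicates.

Benchmark surfaces (`sharp-peak`, `broad-peak`) provide fully synthetic
bi-objective ground truths — a Gaussian germination peak at a known
interior input and a logistic contamination decay that is already near
its minimum at the peak — sampled on a (concentration, time) grid with
optional Gaussian noise. Because the truth is analytic, the true optimum
is known exactly and the surrogate + optimizer stack can be tested for
parameter recovery.

## Surrogate models

One model is fitted per response; all operate on scaled features.

**MLP.** 7→128→64→1 with tanh hidden activations and a linear output,
minimizing mean squared error by Levenberg–Marquardt. The update solves
(JᵀJ + λI)δ = Jᵀr in its dual form δ = Jᵀ(JJᵀ + λI)⁻¹r, so the factorized
system is n×n rather than p×p — with ~17k parameters and ≤ 720 rows this
is both exact and fast. The Jacobian is computed analytically. λ shrinks
(÷3) on accepted steps and grows (×2.5) on rejected ones; 16 consecutive
rejections are treated as divergence and the best parameters so far are
returned with a warning. A 10% inner validation split drives early
stopping (patience 8, default cap 60 iterations) to tame the deliberate
over-parameterization; the output bias is initialized at the target mean.

**RBF.** Centers by seeded k-means (nominally 120; when the data contain
fewer distinct rows — the replicated tables have only ~90 — every
distinct row becomes a center). Shared width σ = d_max/√(2p) with
d_max the maximum inter-center distance, floored at 10⁻⁶ so collapsed
centers cannot produce a zero width. Output weights by linear least
squares; a rank-deficient basis (common here: with near-indicator bases
the bias column is almost the column sum) falls back to a λ = 10⁻⁸ ridge
solve with a warning.

**GRNN.** Stores all training patterns; prediction is the kernel-weighted
mean Sd/Ss with Gaussian kernel exp(−‖x−xᵢ‖²/2σ²). σ is selected by
leave-one-out RMSE over a log-spaced grid (10⁻²…10¹ on the scaled-input
metric, 25 points); selection at a grid boundary warns. Kernel weights
are computed after subtracting the per-query minimum squared distance —
the shared factor cancels in Sd/Ss, and as σ→0 the prediction tends
exactly to the nearest stored target (ties averaged) instead of
underflowing to 0/0. Predictions are convex combinations of stored
targets, hence always within [min y, max y].

The published equations for the RBF and GRNN kernels have garbled
exponents; the standard Gaussian forms above are used.

## Evaluation conventions

R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² with the denominator taken about the *observed*
mean; RMSE in percentage points; MBE = mean(ŷ − y), so negative MBE means
under-prediction. The best model flag is the highest test R² averaged
over the two responses. Models carry a fingerprint of their training
data so a comparison across mismatched splits is rejected.

## Sensitivity analysis

"Removing" an input means retraining without that column on the same
split and seed, not zeroing it at prediction time. VSE_j is the reduced
model's test RMSE; VSR_j = VSE_j / RMSE_full; ranks descend by VSR with
ties broken by feature order. Caveat specific to this encoding: deleting
a concentration column makes that disinfectant's rows feature-identical
to untreated controls, so concentration VSRs bundle the (large)
treated-vs-control contrast with the concentration effect proper. On the
replicated tables this places the concentration inputs above immersion
time for contamination; the original analysis reported immersion time as
rank 1, which this removal mechanism does not reproduce (the mechanism
used there is unstated).

## NSGA-II

Standard elitist NSGA-II with: binary tournament on (rank, crowding);
two-point crossover at rate 0.70 over the full 7-gene chromosome (the
cut segment may span inactive genes, which are re-masked to their fixed
value afterwards, so the stated operator is preserved while the scenario
constraint holds); per-gene Gaussian mutation with probability 0.01 and
sd = 10% of the gene range, then clipping to bounds; (μ+λ) environmental
selection by rank then crowding. Population 85 and 800 generations follow
the original run; odd populations are allowed (the last crossover pair
contributes one child).

One deliberate deviation from the textbook algorithm: before the (μ+λ)
truncation, exact duplicate decision vectors (e.g. un-mutated clones)
are collapsed, keeping the first occurrence. Duplicate-blind crowding
assigns both copies of the extremes infinite distance, letting clones
crowd out distinct front members; with deduplication, evolution with
crossover and mutation disabled is a true fixed point and the best
front distance to the utopia point is non-increasing across
generations.

Maximization is handled by negating germination internally; reported
objectives are on the natural scale. Scenario boxes come from each
disinfectant's tested ranges (concentration ∈ [0, max level], time ∈
[min, max tested]); the utopia references m and n are the minimum
observed contamination and maximum observed germination of that
disinfectant's own table (the scoping of "observed data" is
configurable via the `Scenario` fields). The ideal point is the front
member minimizing √((C−m)² + (G−n)²), ties broken by lower
contamination.

## Pipeline and reproducibility

A single global seed fans out to per-stage seeds through a fixed
`SeedSequence` derivation, so any stage can be rerun independently.
Every run writes its resolved configuration, a manifest (seed, config
hash, stage seeds) and deterministic CSV/JSON artifacts; rerunning the
same configuration reproduces them byte for byte. The run report lays
reproduced metric/optimization/sensitivity tables beside the previously
reported values with explicit deltas.

Problem sizes used by the replication entry points: 90 treatments × 8
replicates = 720 rows; 10 seeds for the model-comparison replication;
5 seeds per optimization scenario with the full GA settings
(85 × 800). These sizes make a full replication run complete in about a
minute while keeping the multi-seed averages stable.

## Known limitations

* The published "76 treatments … 8 sub-sets … 608 datapoints" arithmetic
  cannot be mapped onto the 90 printed rows; the canonical dataset here
  is the 90 rows, and whether the SE is over 8 sub-sets or 12 seeds is
  an assumption (√8 chosen).
* Synthetic replicates understate real replicate spread (see above), so
  absolute test-error levels are optimistic relative to raw data.
* The GRNN near-interpolates the replicated tables, so its optimized
  response surface is plateau-like between tested treatments; optimizer
  output concentrates at or near tested levels rather than smoothly
  interpolated intermediate optima.
* No constraint handling beyond box bounds; two objectives only.
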