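# Methods

This note documents the statistical model and the implementation decisions
behind `rhythmboot`: what is computed, under which assumptions, with which
defaults, and what the synthetic validation does and does not establish.

## Data model

Input is a dense three-way array of background-corrected probe-level
intensities X[g, p, t] for genes g = 1…G, probes p = 1…P (P constant
across genes) and arrays t = 1…T, with one array per time point of an
equally spaced time course. All computation happens on the log2 scale; the
loader applies log2 to natural-scale input and rejects non-positive
values. Time labels are validated for strict ordering only — downstream
the array index is a categorical label, so equal spacing is assumed but
never used arithmetically. The container accepts T ≥ 2 (the minimum for
the two-way fit); rhythm detection itself requires T ≥ 4 and is guarded
separately. CEL/CDF parsing and background correction are out of scope:
the input is assumed corrected.

For RNA-seq counts, a variance-stabilizing transform maps the data onto an
approximately homoscedastic scale first: 2√x for Poisson noise,
asinh(√(x/k)) for negative-binomial noise with size parameter k (variance
= μ + μ²/k). The square-root family is used for Poisson because it is the
transform whose asymptotic variance is constant (~1) in the mean.

## Two-way fit (median polish)

Per gene, the P×T log2 matrix is decomposed additively as
`overall + probe_effect[p] + array_effect[t] + residual[p, t]` by Tukey's
median polish: rows (probes) are swept first, then columns (arrays), with
the medians of the accumulated effect vectors folded into the overall term
after each pair of sweeps so both effect vectors stay median-centered.
Even-length medians use the midpoint convention. Iteration stops when the
sum of absolute residuals decreases by less than `tol × (initial sum)`
(default `tol = 1e-4`) or after `max_iter = 10` full sweeps — standard
median-polish defaults, both configurable. The decomposition identity is
exact by construction at every iterate. On exactly additive matrices the
algorithm terminates within two sweeps with zero residuals, and the
median-centered parameterization makes the recovered effects unique.

The residual mean square σ̂² = SSR/((P−1)(T−1)) uses the two-way ANOVA
residual degrees of freedom; it requires P ≥ 2. A robust scale estimate
was deliberately not substituted — the plain MSE is the quantity the
bootstrap model calls for.

Summarization follows the RMA convention: expression at time t is
`overall + array_effect[t]`. With P = 1 this returns the single probe's
series unchanged.

## Parametric bootstrap

Replicate b regenerates every gene's probe-level matrix as fitted signal
plus iid Gaussian noise N(0, σ̂²_g), with α̂, β̂, σ̂² estimated from the
**unnormalized** corrected intensities. Because replicates are centered at
the observed fitted signal, the bootstrap mean converges to the original
expression (verified to 4σ̂/√B per cell in the tests) — no information is
lost in the mean, which is also why the machinery doubles as a realistic
simulator.

Seeding discipline: replicate b, gene g draws from an independent RNG
substream keyed by `(seed, b, g)` (`numpy` `SeedSequence` spawn keys), so
ensembles are reproducible regardless of iteration order or parallel
scheduling, and — importantly — the *same* replicates are reused across
all normalization methods scored with the same seed. Cross-method
differences in the resulting measures therefore reflect normalization, not
Monte-Carlo noise. Default B = 100 (B = 50 in the desk-scale validation
runs, which keeps a full two-method comparison near ten seconds).

## Detectors and measures

`cosinor_f` fits y_t = m + A·cos(2πt/period) + B·sin(2πt/period) by least
squares and tests the harmonic terms with an F(2, T−3) statistic;
zero-variance series get p = 1 by convention, and p-values are floored at
1e-300. `rank_template` computes Kendall's τ against cosine templates at
`n_phases = 8` equispaced phase shifts and Bonferroni-combines the
two-sided per-phase p-values; it depends only on ranks and is therefore
invariant to any strictly monotone per-gene transform (and conservative by
construction). Neither detector estimates the period: the test period is a
parameter, defaulting to T/2 because the reference designs observe two
full cycles. External detectors plug in as per-gene raw p-value vectors.

BH adjustment is recomputed across genes *within each bootstrap
replicate* — each replicate is a complete dataset passing through the full
pipeline. M = 1 − adjusted p. The robust measure implements
Ê − RMSÊ with RMSÊ = sqrt(Σ_b (θ̂^(b) − θ̂)²/(B−1)) centered at the
original-data estimate θ̂ and divisor B−1, a deliberate hybrid: it charges
both bootstrap variance and the displacement of the bootstrap distribution
from θ̂. Consequences implemented as stated: M_Robust ≤ Ê always, and
M_Robust may be negative (no clipping). In the degenerate case σ̂² ≡ 0 all
replicates equal the fitted signal and the penalty collapses to zero
(exactly, up to floating-point roundoff, under the identity normalization;
non-identity normalizations map the residual-free replicate and the
original data slightly differently, leaving a penalty at numerical-noise
level rather than zero).

## Normalization

All methods operate on the (G·P)×T matrix whose columns are arrays, before
summarization, and preserve shape and row identity. Registered methods:

- **quantile** — each column's sorted values are replaced by the
  across-column mean of order statistics; ties receive the mean of the
  reference values their positions span. Post-condition (asserted
  exactly): all columns share the same sorted vector.
- **constant** — per-array scaling on the natural scale to a baseline
  array's mean intensity (baseline: column 1 by default, or the global
  mean); equivalent to a per-column log2 shift.
- **cyclic_loess** — for each array pair, a lowess curve (span 0.4) of
  M = col_i − col_j on A = (col_i + col_j)/2 is fit and half the fitted M
  transferred between the columns. Adjustments from all pairs in a cycle
  are accumulated and applied together, *scaled by 1/(T−1)*: each column
  collects T−1 pairwise corrections, and the unscaled synchronous update
  would overshoot by a factor ~T/2 and diverge for larger T. The scaled
  update equals the plain pairwise update at T = 2 and is contractive for
  all T; cycles repeat until the largest adjustment is below 0.01 log2
  units or `max_cycles = 3`.
- **invariant_set** — per non-baseline column, probes whose rank differs
  from their baseline rank by less than `rank_tol = 0.01` of the current
  set size are kept, iterated until stable (fallback to constant scaling
  below 10 probes). The monotone map onto the baseline is quantile
  matching over the invariant set: linear interpolation between the set's
  sorted column values and sorted baseline values. An isotonic regression
  of baseline on column values was evaluated and rejected: with noise on
  both axes it suffers regression dilution (fitted slope < 1), leaving a
  systematic ~0.06 log2 distortion even on technically unbiased data,
  whereas quantile matching is an exact identity when the two arrays agree
  in distribution and still inverts shifts and monotone warps exactly in
  the noise-free case.

Contrast, Qspline and VSN are not implemented; the registry accepts
third-party methods with the same matrix-in/matrix-out contract.

## Evaluation

A gene is called rhythmic when its measure reaches the threshold 0.99
(inclusive; the 1% significance level on the adjusted-p scale). Pairwise
agreement between normalization methods is quantified by Spearman and
Pearson correlation of the score vectors and by the percentage of
concordant calls, by default restricted to the union-rhythmic subset:
genes called rhythmic by the standard measure under at least one method (a
config flag switches to all genes). Zero-variance score vectors yield an
undefined correlation, reported as missing with a warning rather than
coerced. The robustness report lists, per method pair and metric, the
standard value, the robust value and their delta; heatmap rendering is
cosmetic and optional, the TSV is the interface of record.

## Synthetic data generator

The generator emulates a two-period circadian probe-level design:
per gene, baseline ~ U(6, 12) log2 (a typical background-corrected
intensity range), probe affinities ~ N(0, 1.0²) median-centered, noise sd
~ U(0.2, 0.6) log2, and for rhythmic genes a cosine temporal signal with
amplitude ~ U(0.5, 2.0) log2 and uniform phase (an `asymmetric` waveform —
cosine cubed, recentered — provides sharp-peaked variants). Defaults:
G = 300, P = 8, T = 48, period 24 in index units, 30% rhythmic, seed 17 —
sized so a full two-normalization comparison with B = 50 runs in about ten
seconds on one CPU. Because the signal sits in the array effects and the
noise is additive Gaussian on log2, the generated data satisfy the
bootstrap model by construction, and noise-free configurations are
recovered exactly by the two-way fit (the round-trip fixture exploits
this).

Technical bias is injected per array, on top of the clean data and without
touching ground-truth labels: `offset` (constant log2 shift ~ N(0, m²)),
`scale` (natural-scale factor, i.e. a random log2 rescaling) or
`nonlinear` (a random increasing cubic warp of the normalized intensity
axis with peak displacement ~ m log2 units, guaranteed monotone). The
robustness experiments use the nonlinear model with m = 0.5 — a visible
but realistic distortion that quantile and constant normalization handle
differently, reproducing the cross-normalization discordance the robust
measure is designed to repair.

What the synthetic validation does **not** show: the generator's genes are
independent, noise is homoscedastic Gaussian within gene, and distortions
are smooth and array-wide. Real probe-level data have correlated probes,
saturation, heavy tails and spatial artifacts; passing these tests
demonstrates correctness of the machinery and the qualitative robustness
mechanism, not performance guarantees on any particular real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as the
package's own validation design: oracle comparisons on 200 random 5×8
matrices; bootstrap centering on 50 genes × 8 probes × 48 arrays with
B = 500; detector calibration on 2,000 flat genes; null-case normalization
checks on 2,000 genes (150 for the pairwise-loess method, which is
O(T²·N·cycles)); the robustness comparison at G = 300, P = 8, T = 48,
B = 50 over three generator seeds; planted-truth recovery on 400 genes at
amplitude/noise = 4. Tolerances: reconstruction and centering invariants
at 1e-9; "exact" post-conditions (quantile sorted-values, BH vs the
brute-force rule) at machine precision; stochastic calibration bands as
stated per test. Degenerate inputs are handled by convention rather than
error where a convention is standard (zero-variance series → p = 1,
all-tied ranks → p = 1); everything else (ragged datasets, non-finite
values, out-of-range p-values, insufficient degrees of freedom) raises a
typed error.

## Known limitations

- Detector internals of published tools (JTK_CYCLE, RAIN, ORIOS) are not
  reproduced; only the measure machinery around any plugged-in detector.
- The bootstrap assumes within-gene homoscedastic Gaussian residuals; a
  heavy-tailed or heteroscedastic noise model would need a different
  resampling scheme.
- Cyclic loess is quadratic in the number of arrays and is the slow path
  for long series; quantile normalization is the practical default at
  T = 48.
- With few genes, BH adjustment and the union-rhythmic restriction make
  the measures heavily tied near 1, which deflates rank correlations —
  comparisons are more informative at G in the hundreds or more.
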