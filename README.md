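# rhythmboot

Bootstrap-robust rhythmicity detection for long-series time-course
expression data.

## The problem

In oscillatory systems — the circadian clock, the cell cycle, metabolic
cycles — a core analysis step is deciding which genes are *rhythmic*:
whether a gene's expression oscillates with the system's period across a
time course in which each hybridization array (or sequencing library) is
one time point. Probe-level intensities must be normalized before that
decision, and there are many reasonable normalization methods (quantile,
constant scaling, cyclic loess, invariant set, ...). Uncomfortably, the
rhythmicity call for a given gene can flip depending on which method was
used: rhythmicity can be an artifact of preprocessing. This package
implements a measure designed to be robust to that choice, for anyone
analyzing long time-course transcriptomic experiments (microarray probe
level, or variance-stabilized counts).

## The method

For a normalization method *n* and a rhythmicity detector *a* producing
Benjamini–Hochberg adjusted p-values across genes *g = 1…G*, the standard
per-gene measure is

    M^g(n, a) = 1 − adjusted p-value^g(n, a),

with values near 1 flagging likely rhythmic genes (the conventional call is
M ≥ 0.99, i.e. a 1% significance level). M is what depends strongly on *n*.

The robust variant works at probe level. Each gene's background-corrected,
**unnormalized** log2 intensity matrix X (probes p × arrays t) is
decomposed by Tukey's median polish into probe effects α̂_p, array effects
β̂_t and residuals, with residual mean square σ̂² = SSR/((P−1)(T−1)). A
parametric bootstrap then regenerates probe-level datasets

    log2 X*(b)[p, t] = α̂_p + β̂_t + ε,   ε ~ N(0, σ̂²) iid,  b = 1…B,

i.e. fresh Gaussian noise around the fitted signal, so the bootstrap mean
retains the original expression. Every replicate is pushed through the
*identical* pipeline — normalization → median-polish summarization →
detector → BH → M — giving bootstrap measures θ̂^(b). With θ̂ the
original-data measure, the robust measure per gene is

    Ê     = (1/B) Σ_b θ̂^(b)
    RMSÊ  = sqrt( Σ_b (θ̂^(b) − θ̂)² / (B − 1) )
    M_Robust = Ê − RMSÊ.

RMSÊ is a bias-plus-variance penalty (deviations are centered at the
original estimate, not the bootstrap mean); genes whose measure is unstable
under resampling are pulled down, which is precisely what stabilizes calls
across normalization methods. M_Robust can be negative for highly unstable
detectors and is deliberately not clipped.

The same bootstrap doubles as a simulator of realistic rhythmic
time-course data from a reference dataset, and the synthetic-data module
generates fully ground-truthed datasets (rhythmic/flat genes, probe
affinities, Gaussian noise, injectable array-level technical bias) for
validation without any downloads.

## Worked example

`examples/03_normalization_robustness.py` injects a nonlinear per-array
distortion into a 300-gene synthetic time course (8 probes, 48 hourly
arrays spanning two 24 h periods), scores all genes under quantile and
constant normalization with B = 50 shared bootstrap replicates, and
compares the two pipelines:

```
             pair      metric  standard_value  robust_value  delta
constant|quantile    spearman           0.878         0.910  0.032
constant|quantile     pearson           0.322         0.780  0.457
constant|quantile concordance          76.378       100.000 23.622
```

Read: on the genes called rhythmic under at least one method, the standard
measures under the two normalizations correlate at Pearson 0.32 and agree
on only 76% of rhythmic/non-rhythmic calls — the normalization artifact.
The robust measures correlate at 0.78 and agree on 100% of calls. The
other examples demonstrate the median-polish decomposition, the per-gene
score tables, and count-data variance stabilization.

A thin CLI wraps the same library calls:

```
rhythmboot simulate --config cfg.yml --out sim/
rhythmboot score --input sim/probes.tsv --log-scale \
    --normalizations quantile,constant --detector cosinor_f \
    --period 24 --B 100 --seed 17 --out scores/
rhythmboot evaluate --scores scores/ --threshold 0.99 --out report/
```

Detectors are pluggable: two reference detectors ship with the package
(`cosinor_f`, a harmonic-regression F-test, and `rank_template`, a
Kendall-correlation template test), and external per-gene p-value vectors
(e.g. from JTK_CYCLE, RAIN or ORIOS) can be supplied as a TSV. The
normalization registry likewise accepts user methods with a
matrix-in/matrix-out contract.

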