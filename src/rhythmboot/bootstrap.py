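"""Parametric bootstrap of probe-level time-course data.

Replicate b regenerates each gene's log2 intensities as

    log2(X*[g, p, t]) = overall_g + probe_effect_g[p] + array_effect_g[t] + e,
    e ~ N(0, sigma2_g) iid,

i.e. Gaussian noise around the median-polish fitted signal, with the noise
variance estimated from the original two-way residuals.  Because the
replicates are centered at the observed fitted signal, their average
converges to the original expression — no information is lost in the mean.

Also provides variance-stabilizing transforms that map RNA-seq count
matrices onto an approximately homoscedastic scale so the same Gaussian
machinery applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import StateError, ValidationError
from .io import ProbeLevelDataset
from .median_polish import GeneFitCollection


@dataclass
class BootstrapConfig:
    """Number of replicates and the root seed driving them."""

    B: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")


def _gene_rng(seed: int, replicate_index: int, gene_index: int) -> np.random.Generator:
    # independent substream per (seed, replicate, gene): results do not
    # depend on iteration order or parallel scheduling
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate_index, gene_index))
    return np.random.default_rng(ss)


def generate_replicate(
    fits: GeneFitCollection, replicate_index: int, seed: int
) -> ProbeLevelDataset:
    """One parametric-bootstrap dataset from fitted per-gene signals.

    Deterministic given ``(seed, replicate_index)``.  Every fit must carry
    ``sigma2`` (set by ``compute_mse`` / ``fit_all_genes``).
    """
    G = len(fits)
    if G == 0:
        raise ValidationError("empty fit collection")
    for fit, gid in zip(fits.fits, fits.gene_ids):
        if fit.sigma2 is None:
            raise StateError(f"gene {gid!r}: sigma2 not computed; run compute_mse first")
    P = fits.fits[0].probe_effects.size
    T = fits.fits[0].array_effects.size
    out = np.empty((G, P, T))
    for g, fit in enumerate(fits.fits):
        rng = _gene_rng(seed, replicate_index, g)
        noise = rng.normal(0.0, np.sqrt(fit.sigma2), size=(P, T))
        out[g] = fit.fitted_signal + noise
    return ProbeLevelDataset(out, list(fits.gene_ids), fits.time_points.copy(), True)


def generate_ensemble(
    fits: GeneFitCollection, config: BootstrapConfig
) -> Iterator[ProbeLevelDataset]:
    """Lazily yield replicates b = 1..B; memory stays O(one replicate)."""
    for b in range(1, config.B + 1):
        yield generate_replicate(fits, b, config.seed)


def variance_stabilize_counts(
    counts: np.ndarray, model: str = "poisson", dispersion: float | None = None
) -> np.ndarray:
    """Variance-stabilizing transform for count matrices.

    ``poisson`` applies ``2*sqrt(x)``, the classical square-root-family
    stabilizer whose variance is ~1 for all means.  ``negative_binomial``
    applies ``asinh(sqrt(x / dispersion))``, which stabilizes a
    gamma-Poisson mixture; ``dispersion`` is the gamma shape (size)
    parameter, i.e. variance = mean + mean^2 / dispersion, and is required
    for this model.  The output is a log-like homoscedastic scale suitable as
    input to the two-way fit.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts must be nonnegative")
    if model == "poisson":
        if dispersion is not None:
            raise ValidationError("dispersion only applies to negative_binomial")
        return 2.0 * np.sqrt(counts)
    if model == "negative_binomial":
        if dispersion is None or dispersion <= 0:
            raise ValidationError("negative_binomial requires a positive dispersion")
        return np.arcsinh(np.sqrt(counts / dispersion))
    raise ValidationError(f"unknown count model {model!r}")
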