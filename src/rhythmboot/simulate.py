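"""Synthetic probe-level time-course data with known ground truth.

The generator emulates a long-series circadian microarray experiment: G
probe sets (genes), each measured by P probes over T equally spaced arrays
spanning two full periods.  On the log2 scale a gene's intensity is

    log2 X[g, p, t] = probe_effect[g, p] + baseline_g + s_g(t) + noise,

with multiplicative probe affinities (additive on log2), an oscillatory
temporal signal s_g(t) = A_g * cos(2 pi (t - phi_g) / period) for rhythmic
genes (zero for flat genes), and iid Gaussian noise.  This is exactly the
additive probe + array structure the two-way median-polish fit assumes, so
noise-free data are recovered exactly by the fit.

Array-level technical distortions (constant offsets, natural-scale
scalings, or smooth monotone nonlinear warps of the intensity axis) can be
injected on top; they change the data, never the ground-truth labels, and
are the variation normalization methods are supposed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ProbeLevelDataset
from .median_polish import GeneFitCollection, TwoWayFit

_BIAS_MODELS = {"none", "offset", "scale", "nonlinear"}
_WAVEFORMS = {"cosine", "asymmetric"}


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic generator.

    Defaults describe a two-period circadian design small enough for a
    laptop: 300 genes x 8 probes x 48 hourly arrays with a 24-index period,
    30% rhythmic genes with log2 amplitudes 0.5-2.0, probe affinities of
    SD 1.0 log2 units and per-gene noise SD 0.2-0.6 log2 units.
    """

    G: int = 300
    P: int = 8
    T: int = 48
    fraction_rhythmic: float = 0.3
    period: float | None = None  # defaults to T / 2 (two observed periods)
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    baseline_range: tuple[float, float] = (6.0, 12.0)
    probe_effect_sd: float = 1.0
    noise_sd_range: tuple[float, float] = (0.2, 0.6)
    bias_model: str = "none"
    bias_magnitude: float = 0.0
    waveform: str = "cosine"
    seed: int = 17

    def __post_init__(self) -> None:
        if self.G < 1 or self.P < 1 or self.T < 2:
            raise ValidationError("need G >= 1, P >= 1, T >= 2")
        if not 0 <= self.fraction_rhythmic <= 1:
            raise ValidationError("fraction_rhythmic must be in [0, 1]")
        for name in ("amplitude_range", "baseline_range", "noise_sd_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must be well ordered")
        if self.noise_sd_range[0] < 0 or self.probe_effect_sd < 0:
            raise ValidationError("noise and probe-effect SDs must be nonnegative")
        if self.bias_model not in _BIAS_MODELS:
            raise ValidationError(f"bias_model must be one of {sorted(_BIAS_MODELS)}")
        if self.bias_magnitude < 0:
            raise ValidationError("bias_magnitude must be nonnegative")
        if self.waveform not in _WAVEFORMS:
            raise ValidationError(f"waveform must be one of {sorted(_WAVEFORMS)}")

    @property
    def effective_period(self) -> float:
        return self.T / 2 if self.period is None else self.period


@dataclass
class GroundTruth:
    """Planted per-gene truth, aligned with the dataset's gene_ids."""

    is_rhythmic: np.ndarray
    true_amplitude: np.ndarray
    true_phase: np.ndarray
    true_noise_sd: np.ndarray
    gene_ids: list[str] = field(default_factory=list)


def _waveform(config: SyntheticConfig, amplitude: float, phase: float) -> np.ndarray:
    t = np.arange(config.T)
    c = np.cos(2.0 * np.pi * (t - phase) / config.effective_period)
    if config.waveform == "cosine":
        return amplitude * c
    # sharp-peaked variant: odd power keeps the sign and period, then recenter
    w = c**3
    return amplitude * (w - w.mean())


def generate_dataset(config: SyntheticConfig) -> tuple[ProbeLevelDataset, GroundTruth]:
    """Draw one synthetic dataset plus its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    G, P, T = config.G, config.P, config.T
    gene_ids = [f"gene_{g:04d}" for g in range(G)]

    n_rhythmic = int(round(G * config.fraction_rhythmic))
    is_rhythmic = np.zeros(G, dtype=bool)
    is_rhythmic[rng.permutation(G)[:n_rhythmic]] = True

    amplitude = np.where(
        is_rhythmic, rng.uniform(*config.amplitude_range, size=G), 0.0
    )
    phase = rng.uniform(0.0, config.effective_period, size=G)
    noise_sd = rng.uniform(*config.noise_sd_range, size=G)
    baseline = rng.uniform(*config.baseline_range, size=G)

    log2x = np.empty((G, P, T))
    for g in range(G):
        pe = rng.normal(0.0, config.probe_effect_sd, size=P)
        pe -= np.median(pe)
        s = _waveform(config, amplitude[g], phase[g]) if is_rhythmic[g] else 0.0
        signal = baseline[g] + s  # the array effect / temporal profile
        log2x[g] = pe[:, None] + signal + rng.normal(0.0, noise_sd[g], size=(P, T))

    dataset = ProbeLevelDataset(log2x, gene_ids, np.arange(T, dtype=float), True)
    truth = GroundTruth(is_rhythmic, amplitude, phase, noise_sd, gene_ids)
    if config.bias_model != "none" and config.bias_magnitude > 0:
        dataset = inject_array_bias(
            dataset, config.bias_model, config.bias_magnitude, config.seed + 1
        )
    return dataset, truth


def inject_array_bias(
    dataset: ProbeLevelDataset, bias_model: str, bias_magnitude: float, seed: int
) -> ProbeLevelDataset:
    """Add per-array technical distortion to a log2 dataset.

    ``offset``     per-array constant log2 shift ~ N(0, magnitude^2).
    ``scale``      per-array multiplicative factor on the natural scale,
                   factor = 2**N(0, magnitude^2) (a random log2 rescaling).
    ``nonlinear``  per-array smooth monotone warp of the intensity axis: a
                   random increasing cubic of the normalized intensity,
                   with maximum displacement ~ magnitude log2 units.

    Ground truth is untouched: bias alters the data, not the labels.
    """
    if bias_model not in _BIAS_MODELS:
        raise ValidationError(f"unknown bias model {bias_model!r}")
    if not dataset.is_log_scale:
        raise ValidationError("bias injection expects a log2-scale dataset")
    if bias_model == "none" or bias_magnitude == 0:
        return dataset.with_intensities(dataset.intensities.copy())

    rng = np.random.default_rng(seed)
    x = dataset.intensities.copy()
    T = dataset.n_times
    if bias_model == "offset":
        shifts = rng.normal(0.0, bias_magnitude, size=T)
        x += shifts[None, None, :]
    elif bias_model == "scale":
        log2_factors = rng.normal(0.0, bias_magnitude, size=T)
        x += log2_factors[None, None, :]
    else:  # nonlinear
        lo = float(x.min())
        hi = float(x.max())
        span = max(hi - lo, 1e-12)
        for t in range(T):
            u = (x[:, :, t] - lo) / span
            # increasing cubic warp u + c*u*(1-u)*(u-r): |c| < 1 keeps the
            # derivative positive on [0, 1]
            r = rng.uniform(0.2, 0.8)
            c = rng.uniform(-0.99, 0.99)
            disp = c * u * (1.0 - u) * (u - r)
            # scale so the largest displacement is ~ bias_magnitude log2 units
            peak = np.abs(disp).max()
            if peak > 0:
                disp *= min(1.0, bias_magnitude / (span * peak)) * span
            x[:, :, t] = lo + span * u + disp
    return dataset.with_intensities(x)


def median_polish_roundtrip_fixture(
    config: SyntheticConfig,
) -> tuple[ProbeLevelDataset, GeneFitCollection]:
    """Noise-free dataset paired with the exact two-way fits it must yield.

    Requires ``noise_sd_range == (0, 0)`` and no bias: with zero noise the
    generated data are exactly additive, so the fitted overall, probe and
    array effects are known in closed form (median-centered convention) and
    every residual and sigma2 is zero.
    """
    if config.noise_sd_range != (0.0, 0.0) and config.noise_sd_range != (0, 0):
        raise ValidationError("fixture requires noise_sd_range == (0, 0)")
    if config.bias_model != "none":
        raise ValidationError("fixture requires bias_model == 'none'")

    rng = np.random.default_rng(config.seed)
    G, P, T = config.G, config.P, config.T
    gene_ids = [f"gene_{g:04d}" for g in range(G)]

    n_rhythmic = int(round(G * config.fraction_rhythmic))
    is_rhythmic = np.zeros(G, dtype=bool)
    is_rhythmic[rng.permutation(G)[:n_rhythmic]] = True
    amplitude = np.where(is_rhythmic, rng.uniform(*config.amplitude_range, size=G), 0.0)
    phase = rng.uniform(0.0, config.effective_period, size=G)
    rng.uniform(*config.noise_sd_range, size=G)  # keep the draw order of generate_dataset
    baseline = rng.uniform(*config.baseline_range, size=G)

    log2x = np.empty((G, P, T))
    fits = []
    for g in range(G):
        pe = rng.normal(0.0, config.probe_effect_sd, size=P)
        pe -= np.median(pe)
        rng.normal(0.0, 0.0, size=(P, T))  # keep rng stream aligned with generate_dataset
        s = _waveform(config, amplitude[g], phase[g]) if is_rhythmic[g] else np.zeros(T)
        beta = baseline[g] + s
        log2x[g] = pe[:, None] + beta[None, :]
        beta_centered = beta - np.median(beta)
        fits.append(
            TwoWayFit(
                overall=float(baseline[g] + np.median(beta - baseline[g])),
                probe_effects=pe.copy(),
                array_effects=beta_centered,
                residuals=np.zeros((P, T)),
                sigma2=0.0,
                converged=True,
                n_iterations=0,
            )
        )
    dataset = ProbeLevelDataset(log2x, gene_ids, np.arange(T, dtype=float), True)
    return dataset, GeneFitCollection(fits, gene_ids, dataset.time_points.copy())


def noise_free(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of a config with noise and bias switched off (fixture-ready)."""
    return replace(config, noise_sd_range=(0.0, 0.0), bias_model="none", bias_magnitude=0.0)


def write_truth(truth: GroundTruth, path) -> None:
    """Persist ground truth as TSV (gene_id, is_rhythmic, amplitude, phase, noise_sd)."""
    pd.DataFrame(
        {
            "gene_id": truth.gene_ids,
            "is_rhythmic": truth.is_rhythmic.astype(int),
            "amplitude": truth.true_amplitude,
            "phase": truth.true_phase,
            "noise_sd": truth.true_noise_sd,
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        df["is_rhythmic"].to_numpy(dtype=bool),
        df["amplitude"].to_numpy(dtype=float),
        df["phase"].to_numpy(dtype=float),
        df["noise_sd"].to_numpy(dtype=float),
        df["gene_id"].astype(str).tolist(),
    )
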