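"""The standard and bootstrap-robust rhythmicity measures.

For a normalization method n and detector a, the standard per-gene measure
is

    M^g(n, a) = 1 - adjusted p-value^g(n, a),

with Benjamini-Hochberg adjustment across genes: values near 1 flag likely
rhythmic genes.  M depends strongly on n in long-series data, so a gene's
rhythmicity can be an artifact of preprocessing.  The robust variant runs
the identical (n, a) pipeline over B parametric-bootstrap replicates of the
*unnormalized* corrected intensities and penalizes sampling variability:

    E_hat^g    = mean_b  theta^(b)g            (bootstrap mean of M)
    RMSE_hat^g = sqrt( sum_b (theta^(b)g - theta_hat^g)^2 / (B - 1) )
    M_robust^g = E_hat^g - RMSE_hat^g

where theta_hat^g is the original-data measure.  Note the deviations are
centered at the original estimate, not the bootstrap mean, so RMSE_hat is a
bias-plus-variance penalty; M_robust can go negative when a detector's
p-values are highly unstable, and it is deliberately not clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, generate_replicate
from .detectors import DetectorMethod, DetectorResult, run_detector
from .errors import AlignmentError, DegreesOfFreedomError, ValidationError
from .io import ProbeLevelDataset
from .median_polish import GeneFitCollection, fit_all_genes, summarize_expression
from .normalization import NormalizationMethod, normalize


@dataclass
class RhythmicityScores:
    """Per-gene standard measure M for one (normalization, detector) pair."""

    M: np.ndarray
    gene_ids: list[str]
    normalization: str
    detector: str

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if np.any(self.M < 0) or np.any(self.M > 1):
            raise ValidationError("M must lie in [0, 1]")
        if len(self.gene_ids) != self.M.size:
            raise AlignmentError("gene_ids and M differ in length")


@dataclass
class RobustScores:
    """Bootstrap mean, RMSE penalty and robust measure for one (n, a) pair."""

    E_hat: np.ndarray
    RMSE_hat: np.ndarray
    M_robust: np.ndarray
    B: int
    gene_ids: list[str]
    normalization: str
    detector: str


def standard_measure(
    result: DetectorResult, normalization_name: str
) -> RhythmicityScores:
    """M = 1 - BH-adjusted p-value, per gene."""
    return RhythmicityScores(
        1.0 - result.adjusted_pvalues,
        list(result.gene_ids),
        normalization_name,
        result.method.name,
    )


def robust_measure(
    theta_hat: RhythmicityScores,
    bootstrap_scores: Iterable[RhythmicityScores],
) -> RobustScores:
    """Combine the original measure with B bootstrap measures.

    ``RMSE_hat`` uses divisor B-1 with deviations centered at the
    original-data estimate ``theta_hat`` (not the bootstrap mean).
    """
    boot = list(bootstrap_scores)
    B = len(boot)
    if B < 2:
        raise DegreesOfFreedomError("robust measure needs B >= 2 bootstrap scores")
    for s in boot:
        if s.gene_ids != theta_hat.gene_ids:
            raise AlignmentError("bootstrap scores must share theta_hat's gene set")
        if (s.normalization, s.detector) != (
            theta_hat.normalization,
            theta_hat.detector,
        ):
            raise AlignmentError(
                "all scores must come from the same (normalization, detector) pair"
            )
    thetas = np.stack([s.M for s in boot])  # B x G
    E_hat = thetas.mean(axis=0)
    RMSE_hat = np.sqrt(np.sum((thetas - theta_hat.M[None, :]) ** 2, axis=0) / (B - 1))
    return RobustScores(
        E_hat=E_hat,
        RMSE_hat=RMSE_hat,
        M_robust=E_hat - RMSE_hat,
        B=B,
        gene_ids=list(theta_hat.gene_ids),
        normalization=theta_hat.normalization,
        detector=theta_hat.detector,
    )


def _single_run(
    dataset: ProbeLevelDataset, n: NormalizationMethod, a: DetectorMethod
) -> RhythmicityScores:
    expr = summarize_expression(normalize(dataset, n))
    return standard_measure(run_detector(expr, a), n.name)


def score_pipeline(
    corrected: ProbeLevelDataset,
    n: NormalizationMethod | str,
    a: DetectorMethod,
    config: BootstrapConfig,
    fits: GeneFitCollection | None = None,
) -> tuple[RhythmicityScores, RobustScores]:
    """Full pipeline: M from the data, M_robust from B bootstrap replicates.

    Probe and array effects (and sigma2) are estimated from the corrected,
    *unnormalized* intensities; each replicate then passes through the
    identical normalize -> summarize -> detect -> M pipeline, with BH
    adjustment recomputed within every replicate.  Replicates depend only on
    ``config.seed`` and the replicate index, so different normalization
    methods scored with the same seed see the same bootstrap datasets.
    """
    if isinstance(n, str):
        n = NormalizationMethod(n)
    if fits is None:
        fits = fit_all_genes(corrected)
    theta_hat = _single_run(corrected, n, a)
    boot = [
        _single_run(generate_replicate(fits, b, config.seed), n, a)
        for b in range(1, config.B + 1)
    ]
    return theta_hat, robust_measure(theta_hat, boot)


def compare_normalizations(
    corrected: ProbeLevelDataset,
    methods: Sequence[NormalizationMethod | str],
    a: DetectorMethod,
    config: BootstrapConfig,
) -> dict[str, tuple[RhythmicityScores, RobustScores]]:
    """Score several normalization methods against shared bootstrap replicates.

    Each replicate is generated once and pushed through every method's
    pipeline, so cross-method differences in the resulting measures reflect
    normalization, not Monte-Carlo noise.
    """
    methods = [NormalizationMethod(m) if isinstance(m, str) else m for m in methods]
    if not methods:
        raise ValidationError("need at least one normalization method")
    fits = fit_all_genes(corrected)
    theta = {m.name: _single_run(corrected, m, a) for m in methods}
    boot: dict[str, list[RhythmicityScores]] = {m.name: [] for m in methods}
    for b in range(1, config.B + 1):
        replicate = generate_replicate(fits, b, config.seed)
        for m in methods:
            boot[m.name].append(_single_run(replicate, m, a))
    return {
        m.name: (theta[m.name], robust_measure(theta[m.name], boot[m.name]))
        for m in methods
    }


def write_scores(
    theta_hat: RhythmicityScores, robust: RobustScores, directory
) -> Path:
    """Write one "<normalization>__<detector>.scores.tsv" per (n, a) pair."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{theta_hat.normalization}__{theta_hat.detector}.scores.tsv"
    pd.DataFrame(
        {
            "gene_id": theta_hat.gene_ids,
            "M": theta_hat.M,
            "E_hat": robust.E_hat,
            "RMSE_hat": robust.RMSE_hat,
            "M_robust": robust.M_robust,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_scores(path) -> pd.DataFrame:
    """Read a scores TSV back into a DataFrame indexed by gene_id."""
    df = pd.read_csv(path, sep="\t")
    expected = {"gene_id", "M", "E_hat", "RMSE_hat", "M_robust"}
    if not expected.issubset(df.columns):
        raise ValidationError(f"scores file missing columns {expected - set(df.columns)}")
    return df.set_index("gene_id")
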