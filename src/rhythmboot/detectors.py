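"""Per-gene rhythmicity tests on summarized expression.

A detector maps a gene x time expression matrix to one raw p-value per gene
for the null hypothesis "flat over time" against a periodic alternative at
a known test period.  Two bespoke detectors are provided and the registry
accepts external per-gene p-value vectors, so published tools (JTK_CYCLE,
RAIN, ORIOS, ...) can be plugged in without re-implementation:

``cosinor_f``
    Least-squares fit of a single sinusoid at the test period; the F test
    of the harmonic terms against the intercept-only model.
``rank_template``
    Kendall rank correlation against cosine templates over a grid of phase
    shifts, Bonferroni-combined; depends only on ranks, hence invariant to
    any strictly monotone per-gene transform.
``external``
    A user-supplied raw p-value vector (array or TSV with columns
    gene_id, raw_pvalue).

Raw p-values are turned into Benjamini-Hochberg adjusted p-values across
all genes, which downstream modules convert into rhythmicity measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, RegistryError, ValidationError
from .io import ExpressionMatrix

_DETECTOR_NAMES = {"cosinor_f", "rank_template", "external"}

# p-values of exactly 0 are floored here before any downstream use
_P_FLOOR = 1e-300


@dataclass
class DetectorMethod:
    """A registered detector with its test period (in time-index units)."""

    name: str
    period: float | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _DETECTOR_NAMES:
            raise RegistryError(
                f"unknown detector {self.name!r}; registered: {sorted(_DETECTOR_NAMES)}"
            )


@dataclass
class DetectorResult:
    """Raw and BH-adjusted p-values for one detector run."""

    raw_pvalues: np.ndarray
    adjusted_pvalues: np.ndarray
    gene_ids: list[str]
    method: DetectorMethod

    def __post_init__(self) -> None:
        self.raw_pvalues = np.asarray(self.raw_pvalues, dtype=float)
        self.adjusted_pvalues = np.asarray(self.adjusted_pvalues, dtype=float)
        if len(self.gene_ids) != self.raw_pvalues.size:
            raise AlignmentError("gene_ids and p-values differ in length")


def detect_cosinor(expr: ExpressionMatrix, period: float) -> np.ndarray:
    """Cosinor F-test raw p-values, one per gene.

    Per gene the model ``y_t = m + A cos(2 pi t / period) + B sin(2 pi t /
    period)`` is fit by least squares over time indices t = 0..T-1 and
    compared with the intercept-only model via the F statistic with
    (2, T-3) degrees of freedom.  Zero-variance series get p = 1 by
    convention.  The test depends on the series only through R^2, so it is
    invariant to per-gene affine transforms with positive slope.
    """
    T = expr.n_times
    if T < 4:
        raise ValidationError("cosinor needs T >= 4")
    if not 2 < period <= T:
        raise ValidationError(f"period must be in (2, T]; got {period}")
    t = np.arange(T)
    omega = 2.0 * np.pi * t / period
    X = np.column_stack([np.ones(T), np.cos(omega), np.sin(omega)])
    Y = expr.values  # G x T
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = X @ coef  # T x G
    sse = np.sum((Y.T - fitted) ** 2, axis=0)
    sst = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    pvals = np.ones(expr.n_genes)
    ok = sst > 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((sst - sse) / 2.0) / (sse / (T - 3))
    # perfect fits (sse ~ 0) have F -> inf and survive sf() as p = 0
    F = np.where(sse <= 1e-30 * np.maximum(sst, 1.0), np.inf, F)
    pvals[ok] = stats.f.sf(F[ok], 2, T - 3)
    return np.clip(pvals, _P_FLOOR, 1.0)


def detect_rank_template(
    expr: ExpressionMatrix, period: float, n_phases: int = 8
) -> np.ndarray:
    """Rank-template raw p-values, one per gene.

    Per gene, Kendall's tau is computed between the series and cosine
    reference curves at ``n_phases`` equispaced phase shifts; the per-phase
    two-sided p-values (exact/normal null of the rank statistic) are
    Bonferroni-combined as ``min(p) * n_phases``, capped at 1.  All-tied
    series get p = 1.
    """
    T = expr.n_times
    if T < 8:
        raise ValidationError("rank template needs T >= 8")
    if n_phases < 2:
        raise ValidationError("n_phases must be >= 2")
    t = np.arange(T)
    phases = period * np.arange(n_phases) / n_phases
    templates = [np.cos(2.0 * np.pi * (t - ph) / period) for ph in phases]
    pvals = np.ones(expr.n_genes)
    for g in range(expr.n_genes):
        y = expr.values[g]
        if np.ptp(y) == 0:
            continue
        best = 1.0
        for template in templates:
            res = stats.kendalltau(y, template)
            if np.isfinite(res.pvalue):
                best = min(best, float(res.pvalue))
        pvals[g] = min(best * n_phases, 1.0)
    return np.clip(pvals, _P_FLOOR, 1.0)


def adjust_bh(raw_pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order.

    Sorted p-values are scaled by m/k, made monotone by cumulative minima
    from the largest, and capped at 1; the adjusted value is never below
    the raw one.
    """
    p = np.asarray(raw_pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("expected a nonempty 1-d p-value vector")
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_external_pvalues(path, gene_ids: list[str]) -> np.ndarray:
    """Load a per-gene raw p-value TSV (columns gene_id, raw_pvalue).

    The file's gene set must match ``gene_ids`` exactly; values are
    returned in ``gene_ids`` order.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["gene_id", "raw_pvalue"]:
        raise ValidationError("expected columns gene_id, raw_pvalue")
    series = df.set_index(df["gene_id"].astype(str))["raw_pvalue"]
    if set(series.index) != set(gene_ids) or len(series) != len(gene_ids):
        raise AlignmentError("external p-value genes do not match the expression matrix")
    return series.loc[gene_ids].to_numpy(dtype=float)


def run_detector(expr: ExpressionMatrix, method: DetectorMethod) -> DetectorResult:
    """Run a registered detector and BH-adjust across all genes."""
    period = method.period if method.period is not None else expr.n_times / 2
    if method.name == "cosinor_f":
        raw = detect_cosinor(expr, period)
    elif method.name == "rank_template":
        n_phases = int(method.parameters.get("n_phases", 8))
        raw = detect_rank_template(expr, period, n_phases)
    elif method.name == "external":
        if "pvalues" in method.parameters:
            raw = np.asarray(method.parameters["pvalues"], dtype=float)
            if raw.size != expr.n_genes:
                raise AlignmentError("external p-value vector length mismatch")
        elif "path" in method.parameters:
            raw = read_external_pvalues(method.parameters["path"], expr.gene_ids)
        else:
            raise ValidationError(
                "external detector needs parameters['pvalues'] or ['path']"
            )
        raw = np.clip(raw, _P_FLOOR, 1.0)
    else:  # pragma: no cover - guarded by DetectorMethod
        raise RegistryError(method.name)
    return DetectorResult(raw, adjust_bh(raw), list(expr.gene_ids), method)
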