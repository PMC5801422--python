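"""Per-gene two-way median-polish decomposition of log2 probe intensities.

Each gene's ``P x T`` log2 intensity matrix is decomposed into

    y[p, t] = overall + probe_effect[p] + array_effect[t] + residual[p, t]

by Tukey's median polish: alternate sweeps remove row (probe) medians and
column (array) medians until the total absolute residual stops shrinking.
Medians rather than means make the fit robust to outlying cells.  The same
fit provides RMA-style summarization (expression at time t is
``overall + array_effect[t]``) and, via the residual mean square, the noise
variance used by the parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegreesOfFreedomError, ValidationError
from .io import ExpressionMatrix, ProbeLevelDataset


@dataclass
class TwoWayFit:
    """Additive two-way decomposition of one gene's log2 intensity matrix.

    ``probe_effects`` and ``array_effects`` are median-centered; the centering
    constants are folded into ``overall``, so the reconstruction

        overall + probe_effects[p] + array_effects[t] + residuals[p, t]

    reproduces the input exactly.  ``sigma2`` (the residual mean square) is
    ``None`` until :func:`compute_mse` is called.
    """

    overall: float
    probe_effects: np.ndarray
    array_effects: np.ndarray
    residuals: np.ndarray
    sigma2: float | None = None
    converged: bool = False
    n_iterations: int = 0

    @property
    def fitted_signal(self) -> np.ndarray:
        """The ``P x T`` noise-free signal overall + probe + array effects."""
        return (
            self.overall
            + self.probe_effects[:, None]
            + self.array_effects[None, :]
        )

    def reconstruct(self) -> np.ndarray:
        return self.fitted_signal + self.residuals


@dataclass
class GeneFitCollection:
    """One :class:`TwoWayFit` per gene, aligned with ``gene_ids``."""

    fits: list[TwoWayFit]
    gene_ids: list[str]
    time_points: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.fits) != len(self.gene_ids):
            raise ValidationError("fits and gene_ids must have equal length")
        if self.time_points is None:
            T = self.fits[0].array_effects.size if self.fits else 0
            self.time_points = np.arange(T, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)

    def __len__(self) -> int:
        return len(self.fits)

    def __iter__(self):
        return iter(self.fits)


def fit_median_polish(
    log2_matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-4
) -> TwoWayFit:
    """Fit a robust additive two-way model to a ``P x T`` matrix.

    Sweeps rows (probes) first, then columns (arrays).  After each pair of
    sweeps the median of the accumulated effects is folded into the overall
    term so both effect vectors stay median-centered.  Iteration stops when
    the sum of absolute residuals decreases by less than
    ``tol * (initial sum + eps)`` or after ``max_iter`` full sweeps.

    Ties in even-length medians resolve to the midpoint of the two central
    values (numpy's default).
    """
    x = np.asarray(log2_matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("input must be a 2-d matrix")
    if not np.all(np.isfinite(x)):
        raise ValidationError("input matrix must be finite")
    P, T = x.shape
    if P < 1 or T < 2:
        raise ValidationError(f"need P >= 1 and T >= 2; got {P} x {T}")

    resid = x.copy()
    overall = 0.0
    row = np.zeros(P)
    col = np.zeros(T)

    init_sum = float(np.abs(resid).sum())
    prev = init_sum
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rdelta = np.median(resid, axis=1)
        resid -= rdelta[:, None]
        row += rdelta
        cmed = float(np.median(col))
        col -= cmed
        overall += cmed

        cdelta = np.median(resid, axis=0)
        resid -= cdelta[None, :]
        col += cdelta
        rmed = float(np.median(row))
        row -= rmed
        overall += rmed

        cur = float(np.abs(resid).sum())
        if prev - cur < tol * (init_sum + 1e-12):
            converged = True
            break
        prev = cur

    # final centering so both effect vectors have median exactly ~0
    rmed = float(np.median(row))
    row -= rmed
    overall += rmed
    cmed = float(np.median(col))
    col -= cmed
    overall += cmed

    return TwoWayFit(
        overall=overall,
        probe_effects=row,
        array_effects=col,
        residuals=resid,
        converged=converged,
        n_iterations=n_iter,
    )


def compute_mse(fit: TwoWayFit) -> float:
    """Residual mean square of a two-way fit, SSR / ((P-1)(T-1)).

    This is the noise variance estimate the parametric bootstrap draws
    from; it is stored on the fit as ``sigma2``.
    """
    P, T = fit.residuals.shape
    if P < 2 or T < 2:
        raise DegreesOfFreedomError(
            f"MSE needs P >= 2 and T >= 2 (residual df (P-1)(T-1)); got {P} x {T}"
        )
    sigma2 = float(np.sum(fit.residuals**2) / ((P - 1) * (T - 1)))
    fit.sigma2 = sigma2
    return sigma2


def fit_all_genes(
    dataset: ProbeLevelDataset,
    max_iter: int = 10,
    tol: float = 1e-4,
    with_mse: bool = True,
) -> GeneFitCollection:
    """Independent median-polish fit for every gene of a log2 dataset.

    ``with_mse`` additionally computes sigma2 per gene (requires P >= 2),
    which the bootstrap engine needs.  Errors are re-raised with the
    offending gene id attached.
    """
    if not dataset.is_log_scale:
        raise ValidationError("fit_all_genes expects a log2-scale dataset")
    fits: list[TwoWayFit] = []
    for g, gid in enumerate(dataset.gene_ids):
        try:
            fit = fit_median_polish(dataset.intensities[g], max_iter, tol)
            if with_mse:
                compute_mse(fit)
        except (ValidationError, DegreesOfFreedomError) as exc:
            raise type(exc)(f"gene {gid!r}: {exc}") from exc
        fits.append(fit)
    return GeneFitCollection(fits, list(dataset.gene_ids), dataset.time_points.copy())


def summarize_expression(
    normalized: ProbeLevelDataset, max_iter: int = 10, tol: float = 1e-4
) -> ExpressionMatrix:
    """Collapse probes to one expression value per gene per array.

    RMA-style summarization: a median polish is fit per gene and the
    expression at time t is ``overall + array_effects[t]``, discarding probe
    effects and residuals.  With a single probe per gene this returns that
    probe's log2 series unchanged.
    """
    fits = fit_all_genes(normalized, max_iter, tol, with_mse=False)
    values = np.stack([f.overall + f.array_effects for f in fits.fits])
    return ExpressionMatrix(values, list(normalized.gene_ids), normalized.time_points.copy())
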