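"""Between-array normalization of probe-level log2 intensities.

Arrays (time points) differ for technical reasons — labeling efficiency,
hybridization conditions, scanner drift — and normalization removes that
variation so that downstream rhythmicity calls reflect biology.  Four
classical methods are implemented behind a registry with a common
matrix-in/matrix-out contract, so third-party methods can be plugged in:

=================  ===========================================================
``none``           identity (the "unnormalized" baseline)
``quantile``       force all arrays to share the mean empirical distribution
``constant``       per-array global scaling to a baseline array's mean
``cyclic_loess``   pairwise MA-plot loess smoothing, iterated over all pairs
``invariant_set``  rank-invariant probe set + monotone mapping onto a baseline
=================  ===========================================================

All methods operate on the ``(G*P) x T`` matrix whose columns are arrays,
preserve shape and row identity, and are (near-)identities when the arrays
already agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import RegistryError, ValidationError
from .io import ProbeLevelDataset


@dataclass
class NormalizationMethod:
    """A registered normalization method plus its parameter overrides."""

    name: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise RegistryError(
                f"unknown normalization {self.name!r}; "
                f"registered: {sorted(_REGISTRY)}"
            )


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Map every column onto the across-column mean of order statistics.

    After normalization all columns have identical sorted values.  Ties
    within a column receive the mean of the reference values their sorted
    positions span, so the map is well defined and monotone per column.
    """
    x = _check_matrix(matrix, min_cols=2)
    N, T = x.shape
    sorted_cols = np.sort(x, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(x)
    for j in range(T):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # group tied runs; each run gets the mean reference value it spans
        boundaries = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        sums = np.add.reduceat(reference, boundaries)
        counts = np.diff(np.r_[boundaries, N])
        group_means = sums / counts
        vals_sorted = np.repeat(group_means, counts)
        out[order, j] = vals_sorted
    return out


def constant_normalize(matrix: np.ndarray, baseline=0) -> np.ndarray:
    """Global per-array scaling on the natural intensity scale.

    Each column is multiplied (on the natural scale) by
    ``baseline mean / column mean`` so all arrays share the baseline's mean
    intensity; input and output are log2.  ``baseline`` is a column index or
    ``"global"`` for the grand mean across arrays.
    """
    x = _check_matrix(matrix, min_cols=2)
    natural = np.exp2(x)
    col_means = natural.mean(axis=0)
    if np.any(col_means <= 0):
        raise ValidationError("zero natural-scale column mean")
    if baseline == "global":
        target = float(col_means.mean())
    else:
        target = float(col_means[int(baseline)])
    return x + np.log2(target / col_means)[None, :]


def cyclic_loess_normalize(
    matrix: np.ndarray,
    span: float = 0.4,
    max_cycles: int = 3,
    tol: float = 0.01,
) -> np.ndarray:
    """Pairwise MA-plot loess normalization, cycled over all array pairs.

    For each pair (i, j) a loess curve of M = col_i - col_j on
    A = (col_i + col_j)/2 is fit; half the fitted M is subtracted from
    col_i and added to col_j.  Adjustments from all pairs in a cycle are
    accumulated and applied together (synchronous update), which makes the
    result independent of pair ordering; cycles repeat until the largest
    absolute adjustment drops below ``tol`` (log2 units) or ``max_cycles``
    is reached.
    """
    if not 0 < span <= 1:
        raise ValidationError("span must be in (0, 1]")
    x = _check_matrix(matrix, min_cols=2).copy()
    N, T = x.shape
    for _ in range(max_cycles):
        adjust = np.zeros_like(x)
        for i in range(T - 1):
            for j in range(i + 1, T):
                a = 0.5 * (x[:, i] + x[:, j])
                m = x[:, i] - x[:, j]
                if np.ptp(a) < 1e-12:
                    warnings.warn(
                        f"cyclic loess: degenerate A range for arrays ({i}, {j}); "
                        "pair skipped"
                    )
                    continue
                fitted = lowess(m, a, frac=span, return_sorted=False)
                adjust[:, i] -= fitted / 2
                adjust[:, j] += fitted / 2
        # each column accumulates T-1 pairwise corrections; dividing by T-1
        # keeps the synchronous update contractive for any T (and equals the
        # plain pairwise update when T = 2)
        adjust /= T - 1
        x += adjust
        if np.max(np.abs(adjust)) < tol:
            break
    return x


def invariant_set_normalize(
    matrix: np.ndarray, baseline: int = 0, rank_tol: float = 0.01
) -> np.ndarray:
    """Rank-invariant-set normalization onto a baseline array.

    For each non-baseline column, probes whose rank (within the current
    candidate set) differs from their baseline rank by less than
    ``rank_tol`` of the set size are kept; the selection is iterated until
    it stabilizes.  The whole column is then mapped onto the baseline scale
    through the monotone quantile-matching curve of the invariant set
    (linear interpolation between the set's sorted column values and sorted
    baseline values).  Matching sorted values rather than regressing one
    noisy axis on the other keeps the map an identity when the two arrays
    already agree in distribution.  Columns whose invariant set shrinks
    below 10 probes fall back to constant scaling with a warning.
    """
    x = _check_matrix(matrix, min_cols=2)
    N, T = x.shape
    base = x[:, int(baseline)]
    out = x.copy()
    for j in range(T):
        if j == int(baseline):
            continue
        col = x[:, j]
        idx = np.arange(N)
        for _ in range(50):
            rb = rankdata(base[idx])
            rc = rankdata(col[idx])
            keep = np.abs(rb - rc) / idx.size < rank_tol
            new_idx = idx[keep]
            if new_idx.size == idx.size or new_idx.size < 10:
                idx = new_idx
                break
            idx = new_idx
        if idx.size < 10:
            warnings.warn(
                f"invariant set for array {j} collapsed to {idx.size} probes; "
                "falling back to constant scaling"
            )
            nat = np.exp2(col)
            out[:, j] = col + np.log2(np.exp2(base).mean() / nat.mean())
            continue
        xs = np.sort(col[idx])
        ys = np.sort(base[idx])
        # collapse tied x so np.interp sees strictly increasing knots
        xs, first = np.unique(xs, return_index=True)
        ys = np.array(
            [seg.mean() for seg in np.split(ys, first[1:])]
        )
        if xs.size < 2:
            warnings.warn(
                f"invariant set for array {j} is degenerate; "
                "falling back to constant scaling"
            )
            nat = np.exp2(col)
            out[:, j] = col + np.log2(np.exp2(base).mean() / nat.mean())
            continue
        out[:, j] = np.interp(col, xs, ys)
    return out


_REGISTRY: dict[str, Callable[..., np.ndarray]] = {
    "none": lambda m: np.asarray(m, dtype=float).copy(),
    "quantile": quantile_normalize,
    "constant": constant_normalize,
    "cyclic_loess": cyclic_loess_normalize,
    "invariant_set": invariant_set_normalize,
}


def register_method(name: str, func: Callable[..., np.ndarray]) -> None:
    """Register a third-party normalization (matrix-in/matrix-out, log2)."""
    _REGISTRY[name] = func


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def normalize(
    dataset: ProbeLevelDataset, method: NormalizationMethod | str
) -> ProbeLevelDataset:
    """Apply a registered method to a log2 probe-level dataset.

    The dataset is flattened to the ``(G*P) x T`` matrix whose columns are
    arrays, normalized, and reshaped; all gene/probe/time metadata is
    preserved.
    """
    if isinstance(method, str):
        method = NormalizationMethod(method)
    if not dataset.is_log_scale:
        raise ValidationError("normalize expects a log2-scale dataset")
    func = _REGISTRY[method.name]
    normalized = func(dataset.as_matrix(), **method.parameters)
    return dataset.with_intensities(normalized)


def _check_matrix(matrix: np.ndarray, min_cols: int = 2) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("expected a 2-d matrix (rows=probes, cols=arrays)")
    if x.shape[1] < min_cols:
        raise ValidationError(f"need at least {min_cols} arrays")
    if not np.all(np.isfinite(x)):
        raise ValidationError("matrix must be finite")
    return x
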