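"""Rhythmicity calling and cross-normalization agreement analysis.

A gene is declared rhythmic when its measure reaches a threshold (default
0.99, i.e. a 1% significance level on the adjusted p-value scale).  To
quantify how much the choice of normalization method matters, score vectors
obtained under different methods are compared pairwise via Spearman and
Pearson correlation and via the percentage of concordant rhythmic /
non-rhythmic calls, usually restricted to genes called rhythmic under at
least one method.  The robustness report places the standard measure M and
the bootstrap measure M_robust side by side so the stabilizing effect of
the bootstrap is visible as positive deltas.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ValidationError


@dataclass
class CallMatrix:
    """Boolean rhythmicity calls, genes x (normalization, detector) columns."""

    calls: pd.DataFrame
    threshold: float


def call_rhythmic(scores: np.ndarray, threshold: float = 0.99) -> np.ndarray:
    """Boolean calls: score >= threshold (inclusive)."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    return scores >= threshold


def build_call_matrix(
    score_vectors: dict[str, np.ndarray], threshold: float = 0.99
) -> CallMatrix:
    """Stack per-method call vectors into a genes x methods boolean table."""
    cols = {name: call_rhythmic(v, threshold) for name, v in score_vectors.items()}
    return CallMatrix(pd.DataFrame(cols), threshold)


def concordance_percent(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Percentage of genes with identical rhythmic/non-rhythmic calls."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape:
        raise AlignmentError("call vectors differ in length")
    return 100.0 * float(np.mean(a == b))


def correlation_matrix(
    score_vectors: dict[str, np.ndarray], kind: str = "spearman"
) -> pd.DataFrame:
    """Pairwise Spearman or Pearson correlations between score vectors.

    Zero-variance vectors make the coefficient undefined; those entries are
    reported as NaN with a warning rather than coerced to a number.
    """
    if kind not in ("spearman", "pearson"):
        raise ValidationError("kind must be 'spearman' or 'pearson'")
    names = list(score_vectors)
    if len(names) < 2:
        raise ValidationError("need at least two score vectors")
    lengths = {len(v) for v in score_vectors.values()}
    if len(lengths) != 1:
        raise AlignmentError("score vectors differ in length")
    if lengths.pop() < 3:
        raise ValidationError("need at least 3 genes")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        x = np.asarray(score_vectors[names[i]], dtype=float)
        y = np.asarray(score_vectors[names[j]], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"zero-variance scores for ({names[i]}, {names[j]}); "
                "correlation undefined"
            )
            r = np.nan
        elif kind == "spearman":
            r = stats.spearmanr(x, y).statistic
        else:
            r = stats.pearsonr(x, y).statistic
        out.iloc[i, j] = out.iloc[j, i] = r
    return out


def select_union_rhythmic(
    score_vectors: dict[str, np.ndarray], threshold: float = 0.99
) -> np.ndarray:
    """Boolean mask of genes called rhythmic under at least one method."""
    mask = None
    for v in score_vectors.values():
        calls = call_rhythmic(v, threshold)
        mask = calls if mask is None else (mask | calls)
    if mask is None:
        raise ValidationError("need at least one score vector")
    return mask


def robustness_report(
    standard: dict[str, np.ndarray],
    robust: dict[str, np.ndarray],
    threshold: float = 0.99,
    restrict_to_union: bool = True,
) -> pd.DataFrame:
    """Side-by-side agreement metrics for M vs M_robust, per method pair.

    For every unordered pair of normalization methods the report lists
    Spearman and Pearson correlation and call concordance, computed from the
    standard scores and from the robust scores, plus the robust-minus-
    standard delta.  By default all metrics are computed on the subset of
    genes rhythmic (by the standard measure) under at least one method;
    ``restrict_to_union=False`` uses all genes.
    """
    if set(standard) != set(robust):
        raise AlignmentError("standard and robust maps must share methods")
    names = sorted(standard)
    if len(names) < 2:
        raise ValidationError("need at least two normalization methods")
    if restrict_to_union:
        mask = select_union_rhythmic(standard, threshold)
        if mask.sum() < 3:
            warnings.warn(
                "fewer than 3 union-rhythmic genes; falling back to all genes"
            )
            mask = np.ones_like(mask, dtype=bool)
    else:
        mask = np.ones(len(next(iter(standard.values()))), dtype=bool)

    std = {k: np.asarray(v, dtype=float)[mask] for k, v in standard.items()}
    rob = {k: np.asarray(v, dtype=float)[mask] for k, v in robust.items()}

    rows = []
    for a, b in itertools.combinations(names, 2):
        pair = f"{a}|{b}"
        for metric in ("spearman", "pearson", "concordance"):
            if metric == "concordance":
                sv = concordance_percent(
                    call_rhythmic(std[a], threshold), call_rhythmic(std[b], threshold)
                )
                rv = concordance_percent(
                    _call_unclipped(rob[a], threshold), _call_unclipped(rob[b], threshold)
                )
            else:
                sv = _pair_corr(std[a], std[b], metric)
                rv = _pair_corr(rob[a], rob[b], metric)
            rows.append(
                {
                    "pair": pair,
                    "metric": metric,
                    "standard_value": sv,
                    "robust_value": rv,
                    "delta": rv - sv,
                }
            )
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)


def plot_report_heatmaps(
    standard: dict[str, np.ndarray],
    robust: dict[str, np.ndarray],
    out_prefix,
    kind: str = "spearman",
) -> list[str]:
    """Optional side-by-side correlation heatmaps (standard vs robust).

    Purely cosmetic; the TSV report is the interface of record.  Returns
    the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (label, vectors) in zip(axes, [("standard", standard), ("robust", robust)]):
        corr = correlation_matrix(vectors, kind)
        im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(corr)), corr.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(corr)), corr.index)
        ax.set_title(f"{kind} ({label})")
        for (i, j), v in np.ndenumerate(corr.values):
            ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=axes.tolist(), shrink=0.8)
    path = f"{out_prefix}_{kind}.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(path)
    return paths


def _pair_corr(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance scores; correlation undefined")
        return np.nan
    if kind == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def _call_unclipped(scores: np.ndarray, threshold: float) -> np.ndarray:
    # robust scores may be negative; thresholding still applies as-is
    return np.asarray(scores, dtype=float) >= threshold
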