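"""Data containers and TSV readers/writers for probe-level and gene-level data.

The central container is :class:`ProbeLevelDataset`, a dense three-way array
of background-corrected intensities indexed by (gene, probe, time).  One
hybridization array corresponds to one time point, so the third axis is both
the time axis and the array axis.  All computation downstream of loading
happens on the log2 scale; the loader applies ``log2`` when the input file
holds natural-scale intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RaggedDatasetError, ValidationError

PROBE_TABLE_COLUMNS = ("gene_id", "probe_id", "time_index", "intensity")


@dataclass
class ProbeLevelDataset:
    """Dense probe-level intensity array indexed by (gene, probe, time).

    Parameters
    ----------
    intensities
        Array of shape ``(G, P, T)``.  Log2 scale when ``is_log_scale`` is
        true, strictly positive natural scale otherwise.
    gene_ids
        ``G`` unique gene (probe-set) identifiers.
    time_points
        ``T`` strictly increasing time labels; only the ordering is used
        downstream, where each time point is treated as a categorical array
        label.
    is_log_scale
        Whether ``intensities`` are already log2-transformed.
    """

    intensities: np.ndarray
    gene_ids: list[str]
    time_points: np.ndarray
    is_log_scale: bool = True

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.time_points = np.asarray(self.time_points, dtype=float)
        if self.intensities.ndim != 3:
            raise ValidationError(
                f"intensities must be 3-d (gene, probe, time); got shape "
                f"{self.intensities.shape}"
            )
        G, P, T = self.intensities.shape
        if len(self.gene_ids) != G:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {G} genes")
        if len(set(self.gene_ids)) != G:
            raise ValidationError("gene ids must be unique")
        if P < 1:
            raise ValidationError("need at least one probe per gene")
        if T < 2:
            raise ValidationError("need at least two time points")
        if len(self.time_points) != T:
            raise ValidationError(
                f"{len(self.time_points)} time labels for {T} time points"
            )
        if np.any(np.diff(self.time_points) <= 0):
            raise ValidationError("time labels must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")
        if not self.is_log_scale and np.any(self.intensities <= 0):
            raise ValidationError(
                "natural-scale intensities must be strictly positive"
            )

    @property
    def n_genes(self) -> int:
        return self.intensities.shape[0]

    @property
    def probes_per_gene(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_times(self) -> int:
        return self.intensities.shape[2]

    def to_log2(self) -> "ProbeLevelDataset":
        """Return a log2-scale view of the dataset (no-op if already log2)."""
        if self.is_log_scale:
            return self
        return ProbeLevelDataset(
            np.log2(self.intensities), self.gene_ids, self.time_points, True
        )

    def as_matrix(self) -> np.ndarray:
        """Flatten to a ``(G*P) x T`` matrix with probes nested within genes."""
        G, P, T = self.intensities.shape
        return self.intensities.reshape(G * P, T)

    def with_intensities(self, values: np.ndarray) -> "ProbeLevelDataset":
        """Copy of the dataset with intensities replaced (same metadata)."""
        values = np.asarray(values, dtype=float)
        if values.shape == (self.n_genes * self.probes_per_gene, self.n_times):
            values = values.reshape(self.intensities.shape)
        return ProbeLevelDataset(
            values, list(self.gene_ids), self.time_points.copy(), self.is_log_scale
        )


@dataclass
class ExpressionMatrix:
    """Gene x time expression values on the log2 scale (post-summarization)."""

    values: np.ndarray
    gene_ids: list[str]
    time_points: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-d matrix")
        G, T = self.values.shape
        if len(self.gene_ids) != G:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {G} rows")
        if self.time_points is None:
            self.time_points = np.arange(T, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        if len(self.time_points) != T:
            raise ValidationError(
                f"{len(self.time_points)} time labels for {T} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


def read_probe_table(path, log_scale_flag: bool = False) -> ProbeLevelDataset:
    """Load a long-format probe table into a dense :class:`ProbeLevelDataset`.

    The file is tab-separated with header
    ``gene_id\\tprobe_id\\ttime_index\\tintensity``.  Every (gene, probe, time)
    combination must appear exactly once; duplicates or missing cells raise.
    When ``log_scale_flag`` is false the intensities must be strictly
    positive and are log2-transformed on load, so the returned dataset is
    always on the log2 scale.

    Gene order follows first appearance in the file; probe order follows
    first appearance within each gene; time points are sorted numerically.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if tuple(df.columns) != PROBE_TABLE_COLUMNS:
        raise ValidationError(
            f"expected columns {list(PROBE_TABLE_COLUMNS)}, got {list(df.columns)}"
        )
    if df["intensity"].isna().any():
        raise ValidationError("missing intensity values")
    if df.duplicated(subset=["gene_id", "probe_id", "time_index"]).any():
        raise ValidationError("duplicate (gene_id, probe_id, time_index) rows")
    if not log_scale_flag and (df["intensity"] <= 0).any():
        raise ValidationError(
            "non-positive intensity in a natural-scale table; "
            "pass log_scale_flag=True for log-scale data"
        )

    gene_ids = list(dict.fromkeys(df["gene_id"].astype(str)))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    time_points = np.sort(df["time_index"].unique().astype(float))
    time_pos = {t: i for i, t in enumerate(time_points)}

    # probe index = first-appearance order within each gene
    probe_pos: dict[str, dict[str, int]] = {g: {} for g in gene_ids}
    for g, p in zip(df["gene_id"].astype(str), df["probe_id"].astype(str)):
        d = probe_pos[g]
        if p not in d:
            d[p] = len(d)
    P = len(probe_pos[gene_ids[0]])
    for g, d in probe_pos.items():
        if len(d) != P:
            raise RaggedDatasetError(
                f"gene {g!r} has {len(d)} probes, expected {P}"
            )

    G, T = len(gene_ids), len(time_points)
    expected = G * P * T
    if len(df) != expected:
        raise RaggedDatasetError(
            f"ragged dataset: {len(df)} rows, expected {expected} "
            f"(G={G}, P={P}, T={T})"
        )

    arr = np.full((G, P, T), np.nan)
    gi = df["gene_id"].astype(str).map(gene_pos).to_numpy()
    pi = np.array(
        [probe_pos[g][p] for g, p in zip(df["gene_id"].astype(str), df["probe_id"].astype(str))]
    )
    ti = df["time_index"].astype(float).map(time_pos).to_numpy()
    arr[gi, pi, ti] = df["intensity"].to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise RaggedDatasetError("ragged dataset: missing (gene, probe, time) cell")

    ds = ProbeLevelDataset(arr, gene_ids, time_points, is_log_scale=log_scale_flag)
    return ds.to_log2()


def write_probe_table(dataset: ProbeLevelDataset, path) -> None:
    """Write a dataset as a long-format probe table (inverse of the reader).

    Probe ids are written as 0..P-1; intensities are written as stored
    (log2 values for a log-scale dataset) with full float precision, so
    ``read_probe_table(path, log_scale_flag=dataset.is_log_scale)`` round-trips
    exactly.
    """
    G, P, T = dataset.intensities.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PROBE_TABLE_COLUMNS) + "\n")
        for g in range(G):
            for p in range(P):
                for t in range(T):
                    fh.write(
                        f"{dataset.gene_ids[g]}\t{p}\t"
                        f"{_fmt(dataset.time_points[t])}\t"
                        f"{float(dataset.intensities[g, p, t])!r}\n"
                    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a gene x time expression matrix as TSV.

    Header is ``gene_id`` followed by one column per time point, in
    ``time_points`` order; values carry full float precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        header = "gene_id\t" + "\t".join(_fmt(t) for t in matrix.time_points)
        fh.write(header + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV written by :func:`write_expression_matrix`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise ValidationError("first column must be gene_id")
    gene_ids = df["gene_id"].astype(str).tolist()
    times = np.array([float(c) for c in df.columns[1:]])
    return ExpressionMatrix(df.iloc[:, 1:].to_numpy(dtype=float), gene_ids, times)


def _fmt(t: float) -> str:
    # integral time labels print without a trailing .0
    return str(int(t)) if float(t).is_integer() else repr(float(t))
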