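"""TSS-proximal windowed quantification of stranded nascent-RNA coverage.

Genes are quantified over the whole gene body when shorter than a cap
(default 30 kb) and over the cap-length interval downstream of the TSS
otherwise, yielding an RPKM matrix over labeling windows that reflects
productive initiation rather than full-gene output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._tsv import read_tsv, write_tsv

DEFAULT_CAP = 30_000
DEFAULT_EXPRESSED_THRESHOLD = 0.5
MIN_QUANT_INTERVAL = 300

STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# Gene annotation (BED6)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body in 0-based half-open genomic coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def read_genes(path) -> list[GeneAnnotation]:
    """Parse a BED6 file into gene annotations.

    Raises ``ValueError`` naming the offending line number on malformed
    input; the strand column is required.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            if strand not in STRANDS:
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(GeneAnnotation(name, chrom, start, end, strand))
    return genes


def write_genes(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Stranded binned coverage
# ---------------------------------------------------------------------------


def read_bedgraph(path):
    """Yield (chrom, start, end, value) records; track/comment lines ignored."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            try:
                yield fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed record") from exc


def _format_value(v: float) -> str:
    if abs(v - round(v)) < 1e-9:
        return str(int(round(v)))
    return f"{v:.10g}"


def write_bedgraph(arrays: dict[str, np.ndarray], bin_size: int, path) -> None:
    """Write per-chromosome binned count arrays as bedGraph (zero bins skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            arr = arrays[chrom]
            for j in np.flatnonzero(arr != 0):
                j = int(j)
                fh.write(
                    f"{chrom}\t{j * bin_size}\t{(j + 1) * bin_size}\t{_format_value(float(arr[j]))}\n"
                )


class StrandedCoverageSet:
    """Binned read counts per labeling window per strand, plus library sizes.

    A bedGraph record's value is interpreted as the read count within that
    interval; records are accumulated onto a uniform genome-wide bin grid,
    splitting counts by overlap fraction when a record straddles bin edges.
    """

    def __init__(self, bin_size: int, windows: Sequence[str]):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.windows = list(windows)
        self._arrays: dict[tuple[str, str], dict[str, np.ndarray]] = {
            (w, s): {} for w in self.windows for s in STRANDS
        }
        self.library_size: dict[str, float] = {}

    # -- construction -------------------------------------------------------

    def add_record(self, window: str, strand: str, chrom: str, start: int, end: int, value: float) -> None:
        if end <= start:
            raise ValueError("bedGraph interval must have end > start")
        chroms = self._arrays[(window, strand)]
        b = self.bin_size
        j0, j1 = start // b, (end - 1) // b
        arr = chroms.get(chrom)
        if arr is None or len(arr) <= j1:
            new = np.zeros(max(j1 + 1, 256 if arr is None else 2 * len(arr)), dtype=float)
            if arr is not None:
                new[: len(arr)] = arr
            chroms[chrom] = arr = new
        if j0 == j1:
            arr[j0] += value
            return
        density = value / (end - start)
        for j in range(j0, j1 + 1):
            lo = max(start, j * b)
            hi = min(end, (j + 1) * b)
            arr[j] += density * (hi - lo)

    def add_bedgraph(self, window: str, strand: str, path) -> None:
        for chrom, start, end, value in read_bedgraph(path):
            self.add_record(window, strand, chrom, start, end, value)

    def set_array(self, window: str, strand: str, chrom: str, arr: np.ndarray) -> None:
        self._arrays[(window, strand)][chrom] = np.asarray(arr, dtype=float)

    def finalize_library_sizes(self, overrides: dict[str, float] | None = None) -> None:
        """Library size = total reads in the window's coverage unless overridden."""
        overrides = overrides or {}
        for w in self.windows:
            if w in overrides and overrides[w] is not None and not (
                isinstance(overrides[w], float) and math.isnan(overrides[w])
            ):
                self.library_size[w] = float(overrides[w])
            else:
                total = 0.0
                for s in STRANDS:
                    for arr in self._arrays[(w, s)].values():
                        total += float(arr.sum())
                self.library_size[w] = total

    # -- access -------------------------------------------------------------

    def get_array(self, window: str, strand: str, chrom: str) -> np.ndarray | None:
        return self._arrays[(window, strand)].get(chrom)

    def interval_sum(self, window: str, strand: str, chrom: str, start: int, end: int) -> float:
        """Reads in [start, end), partial bins weighted by overlap fraction."""
        arr = self.get_array(window, strand, chrom)
        if arr is None:
            warnings.warn(f"chromosome {chrom!r} absent from coverage window {window!r}")
            return 0.0
        return _interval_sum(arr, self.bin_size, start, end)

    def gene_profile(self, window: str, gene: GeneAnnotation, bin_size: int | None = None) -> np.ndarray:
        """Strand-oriented binned counts from the TSS along the gene body."""
        b = bin_size or self.bin_size
        n = math.ceil(gene.length / b)
        arr = self.get_array(window, gene.strand, gene.chrom)
        if arr is None:
            return np.zeros(n)
        edges_local = np.minimum(np.arange(n + 1) * b, gene.length)
        if gene.strand == "+":
            edges = gene.tss + edges_local
        else:
            edges = gene.tss - edges_local
        cum = _cumulative(arr, self.bin_size)
        vals = np.interp(edges.astype(float), cum[0], cum[1])
        out = np.abs(np.diff(vals))
        return out

    @classmethod
    def from_sample_sheet(cls, path, bin_size: int) -> "StrandedCoverageSet":
        """Load coverage from a sample sheet TSV.

        Columns: window, plus, minus, library_size (blank = derive from data).
        Row order defines window order; the first row is the baseline window.
        """
        import os

        sheet = read_tsv(path)
        required = {"window", "plus", "minus"}
        if not required.issubset(sheet.columns):
            raise ValueError(f"sample sheet {path} must have columns {sorted(required)}")
        cov = cls(bin_size, [str(w) for w in sheet["window"]])
        base = os.path.dirname(os.path.abspath(path))
        overrides: dict[str, float] = {}
        for _, row in sheet.iterrows():
            w = str(row["window"])
            for strand, col in (("+", "plus"), ("-", "minus")):
                p = str(row[col])
                if not os.path.isabs(p):
                    p = os.path.join(base, p)
                cov.add_bedgraph(w, strand, p)
            if "library_size" in sheet.columns and pd.notna(row["library_size"]):
                overrides[w] = float(row["library_size"])
        cov.finalize_library_sizes(overrides)
        return cov


def _cumulative(arr: np.ndarray, bin_size: int):
    edges = np.arange(len(arr) + 1, dtype=float) * bin_size
    cum = np.concatenate([[0.0], np.cumsum(arr)])
    return edges, cum


def _interval_sum(arr: np.ndarray, bin_size: int, start: int, end: int) -> float:
    if end <= start:
        return 0.0
    edges, cum = _cumulative(arr, bin_size)
    a, b = np.interp([float(start), float(end)], edges, cum)
    return float(b - a)


def count_reads(coverage: StrandedCoverageSet, window: str, gene: GeneAnnotation,
                interval: tuple[int, int]) -> float:
    """Strand-matched read count over a genomic interval (fractional bins)."""
    return coverage.interval_sum(window, gene.strand, gene.chrom, interval[0], interval[1])


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------


def quant_window(gene: GeneAnnotation, cap: int = DEFAULT_CAP) -> tuple[int, int]:
    """Quantification interval: whole gene if shorter than ``cap``, else the
    cap-length interval downstream of the TSS (genes exactly at the cap are
    capped)."""
    if gene.length < cap:
        return gene.start, gene.end
    if gene.strand == "+":
        return gene.start, gene.start + cap
    return gene.end - cap, gene.end


def rpkm(reads: float, interval_length: int, library_size: float) -> float:
    """Reads per kilobase of interval per million mapped reads."""
    if interval_length <= 0:
        raise ValueError("interval_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return reads / (interval_length / 1e3) / (library_size / 1e6)


@dataclass
class ExpressionMatrix:
    """Gene x labeling-window RPKM values plus per-gene quantification metadata."""

    values: pd.DataFrame            # index gene_id, columns = window names
    meta: pd.DataFrame              # index gene_id: chrom, strand, length, qstart, qend, overlap
    baseline: str = field(default="starved")

    @property
    def windows(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stimulated(self) -> list[str]:
        return [w for w in self.windows if w != self.baseline]

    def to_tsv(self, path) -> None:
        df = self.meta.join(self.values).reset_index().rename(columns={"index": "gene_id"})
        write_tsv(df, path)

    @classmethod
    def from_tsv(cls, path, baseline: str = "starved") -> "ExpressionMatrix":
        df = read_tsv(path).set_index("gene_id")
        meta_cols = [c for c in ("chrom", "strand", "length", "qstart", "qend", "overlap") if c in df.columns]
        windows = [c for c in df.columns if c not in meta_cols]
        return cls(df[windows].astype(float), df[meta_cols], baseline=baseline)


def _flag_overlaps(genes: Sequence[GeneAnnotation], intervals: dict[str, tuple[int, int]]) -> dict[str, bool]:
    """Flag genes whose quantification windows overlap a same-strand neighbour."""
    flags = {g.gene_id: False for g in genes}
    by_key: dict[tuple[str, str], list[GeneAnnotation]] = {}
    for g in genes:
        if g.gene_id in intervals:
            by_key.setdefault((g.chrom, g.strand), []).append(g)
    for group in by_key.values():
        group.sort(key=lambda g: intervals[g.gene_id])
        for prev, cur in zip(group, group[1:]):
            if intervals[cur.gene_id][0] < intervals[prev.gene_id][1]:
                flags[prev.gene_id] = flags[cur.gene_id] = True
                warnings.warn(
                    f"quantification windows of {prev.gene_id} and {cur.gene_id} "
                    f"overlap on {cur.chrom}{cur.strand}"
                )
    return flags


def build_expression_matrix(genes: Sequence[GeneAnnotation], coverage: StrandedCoverageSet,
                            cap: int = DEFAULT_CAP, baseline: str = "starved",
                            min_interval: int = MIN_QUANT_INTERVAL) -> ExpressionMatrix:
    """Quantify every gene in every labeling window.

    Genes whose quantification interval is shorter than ``min_interval``
    are skipped with a warning.
    """
    intervals: dict[str, tuple[int, int]] = {}
    kept: list[GeneAnnotation] = []
    for g in genes:
        iv = quant_window(g, cap)
        if iv[1] - iv[0] < min_interval:
            warnings.warn(
                f"gene {g.gene_id}: quantification interval shorter than "
                f"{min_interval} bp, skipped"
            )
            continue
        intervals[g.gene_id] = iv
        kept.append(g)

    flags = _flag_overlaps(kept, intervals)
    rows = {}
    for g in kept:
        iv = intervals[g.gene_id]
        length = iv[1] - iv[0]
        rows[g.gene_id] = [
            rpkm(count_reads(coverage, w, g, iv), length, coverage.library_size[w])
            for w in coverage.windows
        ]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=coverage.windows)
    values.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "chrom": [g.chrom for g in kept],
            "strand": [g.strand for g in kept],
            "length": [g.length for g in kept],
            "qstart": [intervals[g.gene_id][0] for g in kept],
            "qend": [intervals[g.gene_id][1] for g in kept],
            "overlap": [flags[g.gene_id] for g in kept],
        },
        index=[g.gene_id for g in kept],
    )
    meta.index.name = "gene_id"
    if baseline not in coverage.windows:
        raise ValueError(f"baseline window {baseline!r} not among windows {coverage.windows}")
    return ExpressionMatrix(values, meta, baseline=baseline)


def expressed_filter(matrix: ExpressionMatrix,
                     threshold: float = DEFAULT_EXPRESSED_THRESHOLD) -> set[str]:
    """Genes with RPKM strictly above ``threshold`` in at least one window
    (baseline included)."""
    mask = (matrix.values > threshold).any(axis=1)
    return set(matrix.values.index[mask])
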