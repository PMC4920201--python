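"""Kinetic simulator of pulse-labeled nascent transcription.

The model: point polymerases initiate at a piecewise-constant,
time-dependent rate, move deterministically through a position-dependent
piecewise-constant elongation-rate field, and a genomic position is
labeled in a window iff a polymerase transcribes it while label is
present. Expected per-bin coverage therefore has the closed form

    E[c(x)] = integral of I(t0) dt0 over { t0 : ws <= t0 + tau(x) <= we }

with tau(x) the deterministic travel time from the TSS to x. Poisson
read sampling on top of the expectation yields stranded bedGraph tracks
with a known truth manifest for every downstream stage.
"""

from __future__ import annotations

import math
import os
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._tsv import write_tsv
from .quant import GeneAnnotation, quant_window, write_bedgraph, write_genes

PATTERNS = (
    "constant",
    "sustained_up",
    "sustained_down",
    "transient_up",
    "transient_down",
    "delayed_up",
    "delayed_down",
    "reversal",
)


# ---------------------------------------------------------------------------
# Elongation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElongationProfile:
    """Position-dependent elongation rates: ordered (length_bp, rate_kb_per_min)
    segments covering the gene body from the TSS."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("ElongationProfile needs at least one segment")
        for length, rate in self.segments:
            if length <= 0:
                raise ValueError("segment lengths must be positive")
            if rate <= 0:
                raise ValueError("elongation rates must be positive")

    @classmethod
    def constant(cls, rate_kb_min: float, length_bp: float) -> "ElongationProfile":
        return cls(((float(length_bp), float(rate_kb_min)),))

    @property
    def total_length(self) -> float:
        return float(sum(seg[0] for seg in self.segments))

    def _knots(self):
        lengths = np.array([s[0] for s in self.segments], dtype=float)
        rates_bp = np.array([s[1] for s in self.segments], dtype=float) * 1e3  # bp/min
        x = np.concatenate([[0.0], np.cumsum(lengths)])
        t = np.concatenate([[0.0], np.cumsum(lengths / rates_bp)])
        return x, t

    def travel_time(self, x):
        """Minutes for a polymerase to travel from the TSS to position x (bp)."""
        x_arr = np.asarray(x, dtype=float)
        xk, tk = self._knots()
        if np.any(x_arr < 0) or np.any(x_arr > xk[-1] + 1e-9):
            raise ValueError("position outside elongation profile")
        out = np.interp(x_arr, xk, tk)
        return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out

    def front_position(self, t, cap: float | None = None):
        """Position (bp) reached after t minutes; capped at profile end
        (or at ``cap`` when given)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be non-negative")
        xk, tk = self._knots()
        out = np.interp(t_arr, tk, xk)
        if cap is not None:
            out = np.minimum(out, cap)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def travel_time(profile: ElongationProfile, x):
    return profile.travel_time(x)


def front_position(profile: ElongationProfile, t, cap: float | None = None):
    return profile.front_position(t, cap=cap)


# ---------------------------------------------------------------------------
# Initiation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InitiationProfile:
    """Piecewise-constant initiation rate I(t), in initiations/min.

    The baseline rate holds for every t before the first change time
    (including all t < 0, the starved steady state); after change time k
    the rate is ``baseline_rate * fold_factors[k]``.
    """

    baseline_rate: float
    change_times: tuple[float, ...] = ()
    fold_factors: tuple[float, ...] = ()
    pattern: str = "constant"
    epoch_rates: tuple[float, ...] | None = None  # absolute rates, override folds

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.epoch_rates is None:
            if len(self.change_times) != len(self.fold_factors):
                raise ValueError("change_times and fold_factors must have equal length")
        elif len(self.change_times) != len(self.epoch_rates):
            raise ValueError("change_times and epoch_rates must have equal length")
        if any(f < 0 for f in self.fold_factors):
            raise ValueError("epoch rates must be >= 0")
        if self.epoch_rates is not None and any(r < 0 for r in self.epoch_rates):
            raise ValueError("epoch rates must be >= 0")
        if any(b >= a for a, b in zip(self.change_times[1:], self.change_times)):
            raise ValueError("change_times must be strictly increasing")
        if self.pattern == "constant" and self.change_times:
            raise ValueError("constant pattern admits no epochs")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")

    @property
    def _levels(self) -> np.ndarray:
        if self.epoch_rates is not None:
            post = np.asarray(self.epoch_rates, dtype=float)
        else:
            post = self.baseline_rate * np.asarray(self.fold_factors, dtype=float)
        return np.concatenate([[self.baseline_rate], post])

    # -- factories ----------------------------------------------------------

    @classmethod
    def constant(cls, baseline_rate: float) -> "InitiationProfile":
        return cls(baseline_rate)

    @classmethod
    def from_rates(cls, baseline_rate: float, change_times, rates,
                   pattern: str = "sustained_up") -> "InitiationProfile":
        """Profile given absolute initiation rates per epoch (allows induction
        from a fully silent baseline)."""
        return cls(baseline_rate, tuple(change_times), (), pattern,
                   epoch_rates=tuple(rates))

    @classmethod
    def from_pattern(cls, pattern: str, baseline_rate: float, fold: float = 3.0,
                     onset: float = 0.0, duration: float = 30.0,
                     reversal_order: str = "down_up",
                     reversal_lag: float = 60.0) -> "InitiationProfile":
        """Build the step-change initiation profile for a named temporal pattern."""
        if fold <= 1:
            raise ValueError("fold must be > 1")
        if pattern == "constant":
            return cls(baseline_rate)
        if pattern == "sustained_up":
            return cls(baseline_rate, (onset,), (fold,), pattern)
        if pattern == "sustained_down":
            return cls(baseline_rate, (onset,), (1.0 / fold,), pattern)
        if pattern == "transient_up":
            return cls(baseline_rate, (onset, onset + duration), (fold, 1.0), pattern)
        if pattern == "transient_down":
            return cls(baseline_rate, (onset, onset + duration), (1.0 / fold, 1.0), pattern)
        if pattern == "delayed_up":
            return cls(baseline_rate, (onset,), (fold,), pattern)
        if pattern == "delayed_down":
            return cls(baseline_rate, (onset,), (1.0 / fold,), pattern)
        if pattern == "reversal":
            if reversal_order == "down_up":
                factors = (1.0 / fold, fold)
            elif reversal_order == "up_down":
                factors = (fold, 1.0 / fold)
            else:
                raise ValueError("reversal_order must be 'down_up' or 'up_down'")
            return cls(baseline_rate, (onset, onset + reversal_lag), factors, pattern)
        raise ValueError(f"unknown pattern {pattern!r}")

    # -- evaluation ---------------------------------------------------------

    def rate_at(self, t):
        """I(t); vectorized."""
        t_arr = np.asarray(t, dtype=float)
        if not self.change_times:
            out = np.full_like(t_arr, self.baseline_rate, dtype=float)
        else:
            idx = np.searchsorted(np.asarray(self.change_times), t_arr, side="right")
            out = self._levels[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def integrate(self, a, b):
        """Integral of I over [a, b] (vectorized over paired arrays)."""
        a_arr = np.asarray(a, dtype=float)
        b_arr = np.asarray(b, dtype=float)
        levels = self._levels
        times = np.asarray(self.change_times, dtype=float)
        # cumulative integral from the first change time (0 if no epochs)
        ref = times[0] if times.size else 0.0

        def cum(t):
            t = np.asarray(t, dtype=float)
            if not times.size:
                return levels[0] * t
            total = levels[0] * (np.minimum(t, ref) - ref)
            edges = np.concatenate([times, [np.inf]])
            for k in range(times.size):
                lo, hi = edges[k], edges[k + 1]
                seg = np.clip(t, lo, hi) - lo
                total = total + levels[k + 1] * np.where(t > lo, np.minimum(seg, hi - lo), 0.0)
            return total

        out = cum(b_arr) - cum(a_arr)
        out = np.where(b_arr <= a_arr, 0.0, out)
        if np.isscalar(a) and np.isscalar(b):
            return float(out)
        return out

    @property
    def onset_time(self) -> float | None:
        """Time of the first rate change, or None for a constant profile."""
        return self.change_times[0] if self.change_times else None


# ---------------------------------------------------------------------------
# Labeling scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelingScheme:
    """Ordered, equal-duration, non-overlapping labeling windows.

    The first window must end at or before t=0: it is the starved
    baseline, labeled at steady state before stimulation.
    """

    windows: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.windows) < 2:
            raise ValueError("need a baseline window plus at least one stimulated window")
        durations = {round(e - s, 9) for _, s, e in self.windows}
        if len(durations) != 1 or min(durations) <= 0:
            raise ValueError("windows must have equal positive duration")
        for (_, _, e0), (_, s1, _) in zip(self.windows, self.windows[1:]):
            if s1 < e0:
                raise ValueError("windows must be non-overlapping and ordered")
        if self.windows[0][2] > 0:
            raise ValueError("the first window must end at or before t=0 (baseline)")

    @classmethod
    def default(cls) -> "LabelingScheme":
        return cls((
            ("starved", -30.0, 0.0),
            ("0-30", 0.0, 30.0),
            ("30-60", 30.0, 60.0),
            ("60-90", 60.0, 90.0),
            ("90-120", 90.0, 120.0),
        ))

    @property
    def duration(self) -> float:
        _, s, e = self.windows[0]
        return e - s

    @property
    def names(self) -> list[str]:
        return [w[0] for w in self.windows]

    @property
    def baseline(self) -> str:
        return self.windows[0][0]

    @property
    def stimulated(self) -> list[tuple[str, float, float]]:
        return list(self.windows[1:])

    def window(self, name: str) -> tuple[float, float]:
        for n, s, e in self.windows:
            if n == name:
                return s, e
        raise KeyError(name)

    def onset_window(self, t: float) -> int | None:
        """1-based stimulated-window index containing time t (start-inclusive)."""
        for k, (_, s, e) in enumerate(self.stimulated, start=1):
            if s <= t < e:
                return k
        return None


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneKinetics:
    gene: GeneAnnotation
    initiation: InitiationProfile
    elongation: ElongationProfile

    def __post_init__(self) -> None:
        if self.elongation.total_length < self.gene.length:
            raise ValueError(
                f"gene {self.gene.gene_id}: elongation profile shorter than gene"
            )


@dataclass(frozen=True)
class SimScenario:
    genes: tuple[GeneKinetics, ...]
    bin_size: int = 1000
    read_depth: float = 1.0
    seed: int = 0
    noise: str = "poisson"
    scheme: LabelingScheme = field(default_factory=LabelingScheme.default)

    def __post_init__(self) -> None:
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for gk in self.genes:
            g = gk.gene
            if g.start % self.bin_size or g.end % self.bin_size:
                raise ValueError(
                    f"gene {g.gene_id}: coordinates must align to the {self.bin_size}-bp bin grid"
                )

    def with_seed(self, seed: int) -> "SimScenario":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def _bin_centers(length: float, bin_size: int) -> np.ndarray:
    n = math.ceil(length / bin_size)
    edges = np.minimum(np.arange(n + 1, dtype=float) * bin_size, length)
    return (edges[:-1] + edges[1:]) / 2.0


def expected_coverage(gene: GeneAnnotation, init: InitiationProfile,
                      elong: ElongationProfile, window: tuple[float, float],
                      bin_size: int) -> np.ndarray:
    """Expected labeled-polymerase passages per bin (TSS-oriented).

    Bin value at center x equals the initiation mass of polymerases that
    transcribe x while label is present: integral of I(t0) over
    ws - tau(x) <= t0 <= we - tau(x).
    """
    ws, we = window
    if we <= ws:
        raise ValueError("window duration must be positive")
    centers = _bin_centers(gene.length, bin_size)
    tau = elong.travel_time(centers)
    return np.asarray(init.integrate(ws - tau, we - tau), dtype=float)


def sample_reads(expected: np.ndarray, read_depth: float, seed, noise: str = "poisson") -> np.ndarray:
    """Per-bin integer read counts with mean ``read_depth * expected``.

    ``noise='none'`` returns the rounded expectation; ``seed`` may be an
    integer, a sequence of integers, or a Generator.
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected values must be >= 0")
    if read_depth < 0:
        raise ValueError("read_depth must be >= 0")
    mean = read_depth * expected
    if noise == "none":
        return np.rint(mean).astype(np.int64)
    if noise != "poisson":
        raise ValueError("noise must be 'poisson' or 'none'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(mean).astype(np.int64)


def _gene_stream_key(gene_id: str) -> int:
    # stable across runs and cohort composition, unlike hash()
    return zlib.crc32(gene_id.encode("utf-8"))


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------


def truth_for_gene(gk: GeneKinetics, scheme: LabelingScheme) -> dict:
    """Ground-truth response labels, wave-front positions, and displacements."""
    init, elong, gene = gk.initiation, gk.elongation, gk.gene
    pattern = init.pattern
    onset_t = init.onset_time
    row: dict = {"gene_id": gene.gene_id, "sim_pattern": pattern}

    if pattern == "constant":
        direction, call_pattern, onset_window = "none", "none", None
    else:
        onset_window = scheme.onset_window(onset_t) if onset_t is not None else None
        if pattern == "reversal":
            direction = call_pattern = "reversal"
        elif pattern.endswith("_up"):
            direction = "induced"
            base = "transient" if pattern.startswith("transient") else "sustained"
            call_pattern = "delayed" if (onset_window or 1) > 1 else base
        else:
            direction = "repressed"
            base = "transient" if pattern.startswith("transient") else "sustained"
            call_pattern = "delayed" if (onset_window or 1) > 1 else base
    row["direction"] = direction
    row["pattern"] = call_pattern
    row["onset_window"] = onset_window if onset_window is not None else ""

    fronts: dict[str, float] = {}
    for name, _s, e in scheme.stimulated:
        if onset_t is None or e <= onset_t:
            fronts[name] = float("nan")
        else:
            fronts[name] = float(elong.front_position(e - onset_t, cap=gene.length))
        row[f"front_{name}"] = fronts[name]
    stim = scheme.stimulated
    for (prev, _, _), (cur, _, _) in zip(stim, stim[1:]):
        fp, fc = fronts[prev], fronts[cur]
        disp = (fc - fp) / 1e3 if not (math.isnan(fp) or math.isnan(fc)) else float("nan")
        row[f"disp_{cur}_kb"] = disp
        row[f"rate_{cur}"] = disp / scheme.duration if not math.isnan(disp) else float("nan")
    return row


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimOutput:
    out_dir: str
    genes_bed: str
    sample_sheet: str
    truth_manifest: str
    bedgraphs: dict[tuple[str, str], str]
    library_sizes: dict[str, float]


def simulate_cohort(scenario: SimScenario, out_dir) -> SimOutput:
    """Simulate the cohort and write bedGraphs, BED6 genes, a sample sheet,
    and the truth manifest. Byte-identical for identical scenarios/seeds."""
    os.makedirs(out_dir, exist_ok=True)
    scheme = scenario.scheme
    b = scenario.bin_size

    # accumulate per (window, strand, chrom)
    tracks: dict[tuple[str, str], dict[str, np.ndarray]] = {
        (name, strand): {} for name in scheme.names for strand in ("+", "-")
    }
    chrom_bins: dict[str, int] = {}
    for gk in scenario.genes:
        g = gk.gene
        chrom_bins[g.chrom] = max(chrom_bins.get(g.chrom, 0), g.end // b)

    for widx, (name, ws, we) in enumerate(scheme.windows):
        for gk in scenario.genes:
            g = gk.gene
            expected = expected_coverage(g, gk.initiation, gk.elongation, (ws, we), b)
            if scenario.noise == "none":
                counts = scenario.read_depth * expected
            else:
                rng = np.random.default_rng(
                    [scenario.seed, _gene_stream_key(g.gene_id), widx]
                )
                counts = sample_reads(expected, scenario.read_depth, rng, "poisson").astype(float)
            chroms = tracks[(name, g.strand)]
            arr = chroms.get(g.chrom)
            if arr is None:
                arr = chroms[g.chrom] = np.zeros(chrom_bins[g.chrom], dtype=float)
            j0 = g.start // b
            if g.strand == "+":
                arr[j0 : j0 + len(counts)] += counts
            else:
                arr[j0 : j0 + len(counts)] += counts[::-1]

    bedgraphs: dict[tuple[str, str], str] = {}
    library: dict[str, float] = {}
    for name in scheme.names:
        total = 0.0
        for strand, label in (("+", "plus"), ("-", "minus")):
            path = os.path.join(out_dir, f"{name}.{label}.bedGraph")
            write_bedgraph(tracks[(name, strand)], b, path)
            bedgraphs[(name, strand)] = path
            total += sum(float(a.sum()) for a in tracks[(name, strand)].values())
        library[name] = total

    genes_bed = os.path.join(out_dir, "genes.bed")
    write_genes([gk.gene for gk in scenario.genes], genes_bed)

    overlap_flags = _quant_overlap_flags(scenario)

    import pandas as pd

    sheet = pd.DataFrame(
        {
            "window": scheme.names,
            "plus": [f"{n}.plus.bedGraph" for n in scheme.names],
            "minus": [f"{n}.minus.bedGraph" for n in scheme.names],
            "library_size": [library[n] for n in scheme.names],
        }
    )
    sample_sheet = os.path.join(out_dir, "samples.tsv")
    write_tsv(sheet, sample_sheet)

    rows = []
    for gk in scenario.genes:
        row = truth_for_gene(gk, scheme)
        row["overlap"] = overlap_flags[gk.gene.gene_id]
        rows.append(row)
    manifest = pd.DataFrame(rows)
    truth_path = os.path.join(out_dir, "truth.tsv")
    write_tsv(manifest, truth_path)

    return SimOutput(str(out_dir), genes_bed, sample_sheet, truth_path, bedgraphs, library)


def _quant_overlap_flags(scenario: SimScenario) -> dict[str, bool]:
    flags = {gk.gene.gene_id: False for gk in scenario.genes}
    by_key: dict[tuple[str, str], list] = {}
    for gk in scenario.genes:
        g = gk.gene
        by_key.setdefault((g.chrom, g.strand), []).append((quant_window(g), g.gene_id))
    for group in by_key.values():
        group.sort()
        for (iv0, id0), (iv1, id1) in zip(group, group[1:]):
            if iv1[0] < iv0[1]:
                flags[id0] = flags[id1] = True
                warnings.warn(
                    f"same-strand quantification windows of {id0} and {id1} overlap"
                )
    return flags
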