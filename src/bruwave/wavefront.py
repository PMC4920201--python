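"""Transcription wave-front detection and elongation-rate estimation.

For long responder genes the per-window coverage shows a moving edge:
an advancing wedge after induction, a retreating 5' clearing after
repression. The detector locates the edge by thresholding a smoothed
profile (threshold = beta x plateau) and then refines the boundary by a
linear fit of the raw edge, extrapolated to the background level
(advancing) or to the plateau (retreating). Displacements between
consecutive windows divided by the labeling duration give per-interval
elongation rates; cohort statistics use a paired Wilcoxon signed-rank
test between intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._tsv import write_tsv
from .classify import ResponseCall
from .quant import GeneAnnotation, StrandedCoverageSet

DEFAULT_MIN_LENGTH = 200_000


@dataclass(frozen=True)
class FrontParams:
    smooth_w: int = 5          # moving-average width, bins
    beta: float = 0.25         # threshold as fraction of plateau
    noise_floor: float = 0.0   # absolute floor (e.g. intergenic background)
    gap_tol: int = 2           # below-threshold bins tolerated inside a run
    min_run: int = 5           # minimum above-threshold bins for a detection
    refine: bool = True        # sub-threshold edge refinement by linear fit
    round_to: int | None = None  # optionally round positions (e.g. 10 kb)

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.smooth_w < 1 or self.min_run < 1 or self.gap_tol < 0:
            raise ValueError("bad detector parameters")


@dataclass(frozen=True)
class FrontCall:
    position: float | None     # bp downstream of TSS; None if undetectable
    flag: str                  # ok | saturated | not_started | undetectable
    cleared_start: float | None = None  # retreating only: 5' end of the rising edge

    @property
    def usable(self) -> bool:
        return self.flag == "ok" and self.position is not None


def _smooth(v: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return v.astype(float)
    kernel = np.ones(w)
    norm = np.convolve(np.ones_like(v, dtype=float), kernel, mode="same")
    return np.convolve(v.astype(float), kernel, mode="same") / norm


def _round(pos: float, params: FrontParams) -> float:
    if params.round_to:
        return round(pos / params.round_to) * params.round_to
    return pos


def _anchored_run(above: np.ndarray, gap_tol: int, start: int = 0) -> tuple[int, int]:
    """(last above index, n above bins) of the run anchored at ``start``;
    (-1, 0) if the anchor region is below threshold."""
    last, count, gaps = -1, 0, 0
    for i in range(start, len(above)):
        if above[i]:
            last, gaps = i, 0
            count += 1
        else:
            gaps += 1
            if gaps > gap_tol:
                break
    return last, count


def _fit_edge(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    if len(x) < 3:
        return None
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        return None
    return float(slope), float(intercept)


def _covered_region(s: np.ndarray, params: FrontParams) -> np.ndarray:
    """Indices considered part of the transcribed wave region.

    A fractional cut on the profile maximum keeps a residual (e.g. low
    starved-baseline) signal downstream of the wave from being mistaken for
    wave coverage, which would corrupt the plateau estimate.
    """
    cut = max(params.noise_floor, 0.2 * float(s.max()))
    return np.flatnonzero(s > cut)


def detect_front_advancing(values: Sequence[float], bin_size: int,
                           params: FrontParams = FrontParams()) -> FrontCall:
    """Leading edge of an advancing transcription wave, bp downstream of TSS."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0 or not np.any(v > params.noise_floor):
        return FrontCall(None, "undetectable")
    s = _smooth(v, params.smooth_w)
    covered = _covered_region(s, params)
    extent = int(covered[-1]) if covered.size else n - 1
    q = max(1, (extent + 1) // 4)
    plateau = float(np.median(s[:q]))
    thr = max(params.noise_floor, params.beta * plateau)

    last, count = _anchored_run(s > thr, params.gap_tol)
    if last < 0 or count < params.min_run:
        return FrontCall(None, "undetectable")
    run_end_bp = (last + 1) * bin_size
    if last >= n - 1 - params.gap_tol:
        return FrontCall(float(n * bin_size), "saturated")

    # background level beyond the wave
    tail = s[min(n, last + 2 * params.smooth_w):]
    floor = float(np.median(tail)) if tail.size >= params.min_run else params.noise_floor
    pos = run_end_bp
    if params.refine:
        refined = _refine_falling_edge(v, s, bin_size, last, plateau, floor, thr, params)
        if refined is not None:
            pos = refined
    return FrontCall(_round(float(np.clip(pos, 0.0, n * bin_size)), params), "ok")


def _edge_fit_position(v, s, bin_size, j, target_level, band_lo, band_hi,
                       inner_lo, inner_hi, smooth_w, slope_sign):
    """Boundary position from a linear fit of the edge, extrapolated to
    ``target_level``.

    Prefers the smoothed profile restricted to the edge interior (where a
    moving average of a ramp stays exactly linear); falls back to a raw-value
    fit across the full band for edges narrower than the smoothing kernel.
    """
    inner = (s[j] >= inner_lo) & (s[j] <= inner_hi)
    if inner.sum() >= 3 and np.ptp(j[inner]) >= 2 * smooth_w:
        x = (j[inner] + 0.5) * bin_size
        fit = _fit_edge(x, s[j[inner]])
    else:
        fit = None
    if fit is None or fit[0] * slope_sign <= 0:
        band = (v[j] >= band_lo) & (v[j] <= band_hi)
        x = (j[band] + 0.5) * bin_size
        fit = _fit_edge(x, v[j[band]])
    if fit is None or fit[0] * slope_sign <= 0:
        return None
    slope, intercept = fit
    return (target_level - intercept) / slope, abs(slope)


def _clipped_ramp_corner(v, s, bin_size, lo, hi, floor, amp, b0, m0, falling):
    """Weighted least-squares fit of a clipped linear ramp; returns the corner
    where the edge meets the floor (falling) or the plateau (rising).

    The ramp model uses the (precise) floor and plateau level estimates and
    optimizes only the corner position and edge slope, with approximate
    Poisson weights, which avoids the variance blow-up of extrapolating a
    band-limited line fit out to the corner.
    """
    from scipy.optimize import minimize

    x = (np.arange(lo, hi) + 0.5) * bin_size
    y = v[lo:hi]
    var = np.maximum(s[lo:hi], 0.5)
    if len(x) < 5 or m0 <= 0:
        return None

    def sse(p):
        b, m = p
        if m <= 0:
            return 1e300
        if falling:
            f = floor + np.clip(m * (b - x), 0.0, amp)
        else:
            f = floor + np.clip(amp - m * (b - x), 0.0, amp)
        return float(np.sum((y - f) ** 2 / var))

    res = minimize(sse, [b0, m0], method="Nelder-Mead",
                   options={"xatol": 1.0, "fatol": 1e-10, "maxiter": 400})
    b, m = float(res.x[0]), float(res.x[1])
    if not np.isfinite(b) or m <= 0 or b < (lo - 1) * bin_size or b > (hi + 1) * bin_size:
        return None
    return b, m


def _refine_falling_edge(v, s, bin_size, last, plateau, floor, thr, params):
    amp = plateau - floor
    if amp <= 0:
        return None
    hi_level = floor + 0.75 * amp
    lo_level = floor + 0.05 * amp
    hi_idx = np.flatnonzero(s[: last + 2 * params.smooth_w] >= hi_level)
    e_hi = int(hi_idx[-1]) if hi_idx.size else 0
    below = np.flatnonzero(s[e_hi:] <= lo_level)
    e_lo = e_hi + int(below[0]) if below.size else len(v) - 1
    j = np.arange(e_hi, e_lo + 1)
    fitted = _edge_fit_position(
        v, s, bin_size, j, target_level=floor,
        band_lo=floor + 0.05 * amp, band_hi=floor + 0.90 * amp,
        inner_lo=floor + 0.15 * amp, inner_hi=floor + 0.85 * amp,
        smooth_w=params.smooth_w, slope_sign=-1.0)
    if fitted is not None:
        pos, slope = fitted
        if pos >= (e_hi + 0.5) * bin_size:
            lo = max(0, e_hi - 2 * params.smooth_w)
            hi = min(len(v), int(np.ceil(pos / bin_size)) + max(10, 2 * params.smooth_w))
            refined = _clipped_ramp_corner(v, s, bin_size, lo, hi, floor, amp,
                                           b0=pos, m0=slope, falling=True)
            return refined[0] if refined is not None else pos
    # fall back to the last raw above-threshold bin (sharp step)
    raw_above = np.flatnonzero(v[: e_lo + 1] > thr)
    if raw_above.size:
        return float((raw_above[-1] + 1) * bin_size)
    return None


def detect_front_retreating(values: Sequence[float], bin_size: int,
                            params: FrontParams = FrontParams()) -> FrontCall:
    """Boundary between the 5' cleared region and the 3' still-occupied
    region of a retreating transcription wave."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0 or not np.any(v > params.noise_floor):
        return FrontCall(None, "undetectable")
    s = _smooth(v, params.smooth_w)
    covered = _covered_region(s, params)
    if covered.size == 0:
        return FrontCall(None, "undetectable")
    extent = int(covered[-1])
    q = max(1, (extent + 1) // 4)
    plateau = float(np.median(s[extent + 1 - q: extent + 1]))

    # two passes: re-estimate the plateau from the top segment of the run,
    # which excludes the rising edge when it reaches into the last quartile
    first = 0
    for _ in range(2):
        thr = max(params.noise_floor, params.beta * plateau)
        rev = (s[: extent + 1] > thr)[::-1]
        last_rev, count = _anchored_run(rev, params.gap_tol)
        if last_rev < 0 or count < params.min_run:
            return FrontCall(None, "undetectable")
        first = extent - last_rev
        q2 = max(params.min_run, (extent - first + 1) // 4)
        plateau = float(np.median(s[max(first, extent + 1 - q2): extent + 1]))
    if first <= params.gap_tol:
        return FrontCall(0.0, "not_started")
    run_start_bp = first * bin_size

    head = s[: max(0, first - 2 * params.smooth_w)]
    floor = float(np.median(head)) if head.size >= params.min_run else params.noise_floor
    pos, cleared = run_start_bp, None
    if params.refine:
        refined = _refine_rising_edge(v, s, bin_size, first, plateau, floor, thr, params)
        if refined is not None:
            pos, cleared = refined
            cleared = _round(float(np.clip(cleared, 0.0, n * bin_size)), params)
    return FrontCall(_round(float(np.clip(pos, 0.0, n * bin_size)), params), "ok",
                     cleared_start=cleared)


def _refine_rising_edge(v, s, bin_size, first, plateau, floor, thr, params):
    amp = plateau - floor
    if amp <= 0:
        return None
    hi_level = floor + 0.75 * amp
    lo_level = floor + 0.05 * amp
    start = max(0, first - 2 * params.smooth_w)
    hi_idx = np.flatnonzero(s[start:] >= hi_level)
    e_hi = start + int(hi_idx[0]) if hi_idx.size else len(v) - 1
    below = np.flatnonzero(s[:e_hi] <= lo_level)
    e_lo = int(below[-1]) if below.size else 0
    j = np.arange(e_lo, e_hi + 1)
    fitted = _edge_fit_position(
        v, s, bin_size, j, target_level=plateau,
        band_lo=floor + 0.10 * amp, band_hi=floor + 0.95 * amp,
        inner_lo=floor + 0.15 * amp, inner_hi=floor + 0.85 * amp,
        smooth_w=params.smooth_w, slope_sign=1.0)
    if fitted is not None:
        pos, slope = fitted
        if pos >= e_lo * bin_size:
            lo = max(0, e_lo - max(10, 2 * params.smooth_w))
            hi = min(len(v), int(np.ceil(pos / bin_size)) + max(10, 2 * params.smooth_w))
            refined = _clipped_ramp_corner(v, s, bin_size, lo, hi, floor, amp,
                                           b0=pos, m0=slope, falling=False)
            if refined is not None:
                b, m = refined
                return b, b - amp / m
            return pos, pos - amp / slope
    raw_above = np.flatnonzero(v[e_lo:] > thr)
    if raw_above.size:
        pos = float((e_lo + raw_above[0]) * bin_size)
        return pos, pos
    return None


# ---------------------------------------------------------------------------
# Eligibility, displacements, cohort statistics
# ---------------------------------------------------------------------------


def eligible_genes(calls: Iterable[ResponseCall], genes: Mapping[str, GeneAnnotation] | Sequence[GeneAnnotation],
                   min_length: int = DEFAULT_MIN_LENGTH) -> dict[str, set[str]]:
    """Responder genes strictly longer than ``min_length``, split into the
    advancing (induced) and retreating (repressed) analysis sets."""
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    out: dict[str, set[str]] = {"advancing": set(), "retreating": set()}
    for c in calls:
        g = genes.get(c.gene_id)
        if g is None or g.length <= min_length:
            continue
        if c.direction == "induced":
            out["advancing"].add(c.gene_id)
        elif c.direction == "repressed":
            out["retreating"].add(c.gene_id)
    return out


def combine_retreating_fronts(fronts: Mapping[str, FrontCall],
                              window_names: Sequence[str]) -> dict[str, FrontCall]:
    """Refine retreating fronts using the next window's cleared-region start.

    The 5' end of window k+1's rising edge marks the same wave boundary as
    window k's plateau corner but sits in the low-noise cleared region, so it
    is preferred when available; the last window keeps its own estimate.
    """
    out: dict[str, FrontCall] = {}
    for i, name in enumerate(window_names):
        cur = fronts.get(name, FrontCall(None, "undetectable"))
        nxt = fronts.get(window_names[i + 1]) if i + 1 < len(window_names) else None
        if nxt is not None and nxt.usable and nxt.cleared_start is not None:
            out[name] = FrontCall(nxt.cleared_start, "ok")
        else:
            out[name] = cur
    return out


@dataclass(frozen=True)
class ElongationEstimate:
    gene_id: str
    interval: str              # name of the later window, e.g. "30-60"
    displacement_kb: float
    rate_kb_min: float
    flag: str = "ok"           # ok | negative


def displacements(gene_id: str, fronts: Mapping[str, FrontCall],
                  window_names: Sequence[str], labeling_min: float = 30.0,
                  include_first: bool = False) -> list[ElongationEstimate]:
    """Per-interval displacements from consecutive detected fronts.

    ``window_names`` are the stimulated windows in order; interval k is
    named after window k and spans window k-1 -> k. With
    ``include_first`` the 0 -> window-1 displacement is also reported.
    """
    out: list[ElongationEstimate] = []
    prev: tuple[str, float] | None = ("origin", 0.0) if include_first else None
    for name in window_names:
        call = fronts.get(name)
        if call is None or not call.usable:
            prev = None
            continue
        if prev is not None:
            disp = (call.position - prev[1]) / 1e3
            flag = "ok" if disp >= 0 else "negative"
            out.append(ElongationEstimate(gene_id, name, disp, disp / labeling_min, flag))
        prev = (name, call.position)
    return out


def cohort_stats(estimates: Sequence[ElongationEstimate], test: str = "wilcoxon"
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-interval cohort statistics and paired between-interval comparisons.

    Negative-displacement estimates are excluded. Comparisons cover
    consecutive interval pairs plus first-vs-last, paired by gene over the
    genes present in both; exact Wilcoxon for n <= 25 where possible.
    """
    ok = [e for e in estimates if e.flag == "ok"]
    intervals = sorted({e.interval for e in ok}, key=_interval_sort_key)
    per: dict[str, dict[str, float]] = {
        e.interval: {} for e in ok
    }
    for e in ok:
        per[e.interval][e.gene_id] = e.rate_kb_min

    rows = []
    for iv in intervals:
        rates = np.array(list(per[iv].values()))
        rows.append({
            "interval": iv,
            "n": len(rates),
            "mean_rate_kb_min": float(rates.mean()),
            "sd_rate_kb_min": float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
            "median_rate_kb_min": float(np.median(rates)),
            "median_displacement_kb": float(np.median(rates) * 30.0),
        })
    stats_df = pd.DataFrame(rows, columns=[
        "interval", "n", "mean_rate_kb_min", "sd_rate_kb_min",
        "median_rate_kb_min", "median_displacement_kb"])

    pairs = list(zip(intervals, intervals[1:]))
    if len(intervals) > 2:
        pairs.append((intervals[0], intervals[-1]))
    comp_rows = []
    for a, b in pairs:
        shared = sorted(set(per[a]) & set(per[b]))
        if len(shared) < 2:
            warnings.warn(f"comparison {a} vs {b}: fewer than 2 paired genes, omitted")
            continue
        xa = np.array([per[a][g] for g in shared])
        xb = np.array([per[b][g] for g in shared])
        stat, p = paired_test(xa, xb, test)
        comp_rows.append({"interval_a": a, "interval_b": b, "n_pairs": len(shared),
                          "statistic": stat, "p_value": p,
                          "mean_difference": float((xb - xa).mean())})
    comp_df = pd.DataFrame(comp_rows, columns=[
        "interval_a", "interval_b", "n_pairs", "statistic", "p_value", "mean_difference"])
    return stats_df, comp_df


def paired_test(x: np.ndarray, y: np.ndarray, test: str = "wilcoxon") -> tuple[float, float]:
    """Two-sided paired test on per-gene rates; (statistic, p-value)."""
    diffs = y - x
    if np.allclose(diffs, 0):
        return 0.0, 1.0
    if test == "ttest":
        res = stats.ttest_rel(y, x)
        return float(res.statistic), float(res.pvalue)
    if test != "wilcoxon":
        raise ValueError("test must be 'wilcoxon' or 'ttest'")
    nz = diffs[diffs != 0]
    method = "exact" if len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz) else "auto"
    res = stats.wilcoxon(y, x, alternative="two-sided", method=method, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def _interval_sort_key(name: str):
    try:
        return (0, float(str(name).split("-")[0]))
    except ValueError:
        return (1, str(name))


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------


@dataclass
class WavefrontResult:
    fronts: pd.DataFrame
    estimates: pd.DataFrame
    stats: dict[str, pd.DataFrame]
    comparisons: dict[str, pd.DataFrame]


def run_wavefront(genes: Sequence[GeneAnnotation], coverage: StrandedCoverageSet,
                  calls: Sequence[ResponseCall], params: FrontParams = FrontParams(),
                  min_length: int = DEFAULT_MIN_LENGTH, labeling_min: float = 30.0,
                  include_first: bool = False, test: str = "wilcoxon",
                  top_n: int | None = None) -> WavefrontResult:
    """Detect fronts for all eligible genes and compute cohort statistics."""
    gene_map = {g.gene_id: g for g in genes}
    eligible = eligible_genes(calls, gene_map, min_length)
    stim_windows = [w for w in coverage.windows if w != coverage.windows[0]]

    front_rows = []
    estimates: dict[str, list[ElongationEstimate]] = {"advancing": [], "retreating": []}
    for mode, detect in (("advancing", detect_front_advancing),
                         ("retreating", detect_front_retreating)):
        ids = sorted(eligible[mode])
        if top_n is not None:
            ids = ids[:top_n]
        for gid in ids:
            g = gene_map[gid]
            fronts: dict[str, FrontCall] = {}
            for w in stim_windows:
                profile = coverage.gene_profile(w, g)
                fronts[w] = detect(profile, coverage.bin_size, params)
                front_rows.append({
                    "gene_id": gid, "mode": mode, "window": w,
                    "position_bp": "" if fronts[w].position is None else fronts[w].position,
                    "flag": fronts[w].flag,
                })
            if mode == "retreating":
                fronts = combine_retreating_fronts(fronts, stim_windows)
            estimates[mode].extend(
                displacements(gid, fronts, stim_windows, labeling_min, include_first))

    est_rows = [
        {"gene_id": e.gene_id, "mode": mode, "interval": e.interval,
         "displacement_kb": e.displacement_kb, "rate_kb_min": e.rate_kb_min, "flag": e.flag}
        for mode in ("advancing", "retreating") for e in estimates[mode]
    ]
    stats_d, comps_d = {}, {}
    for mode in ("advancing", "retreating"):
        stats_d[mode], comps_d[mode] = cohort_stats(estimates[mode], test=test)
    return WavefrontResult(
        pd.DataFrame(front_rows, columns=["gene_id", "mode", "window", "position_bp", "flag"]),
        pd.DataFrame(est_rows, columns=["gene_id", "mode", "interval",
                                        "displacement_kb", "rate_kb_min", "flag"]),
        stats_d, comps_d)


def write_wavefront(result: WavefrontResult, out_dir) -> None:
    import os

    write_tsv(result.fronts, os.path.join(out_dir, "fronts.tsv"))
    write_tsv(result.estimates, os.path.join(out_dir, "estimates.tsv"))
    for mode in ("advancing", "retreating"):
        write_tsv(result.stats[mode], os.path.join(out_dir, f"cohort_stats_{mode}.tsv"))
        write_tsv(result.comparisons[mode], os.path.join(out_dir, f"cohort_comparisons_{mode}.tsv"))
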