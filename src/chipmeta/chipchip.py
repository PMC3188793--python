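"""Cross-platform tiling-array meta-analysis.

The array branch takes per-platform standardized window-score tracks, puts
them on a common genomic grid by gap-limited linear interpolation, converts
each to Z-scores against a robustly estimated null, combines them with
Stouffer's method, calls peaks on the composite and estimates an empirical
FDR by sign flipping.

The composite at a grid point with m contributing datasets is

    S = sum_i w_i Z_i / sqrt(sum_i w_i^2)

over the non-missing subset, which is standard normal under the null for any
subset size; with unit weights and full coverage it reduces to the classical
(sum Z_i)/sqrt(k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .track_io import Peak, ScoreTrack

__all__ = [
    "GridTrack",
    "NullModel",
    "CompositeTrack",
    "ChipChipConfig",
    "interpolate_to_grid",
    "estimate_null",
    "to_zscores",
    "combine_stouffer",
    "call_peaks_composite",
    "efdr_signflip",
    "chipchip_pipeline",
]

# normal-consistency factor for the median absolute deviation
_MAD_SCALE = 1.4826


@dataclass
class GridTrack:
    """Scores resampled onto a regular grid anchored at coordinate 0.

    ``data`` maps chromosome -> (grid_start, step, values); grid positions are
    grid_start + i*step and missing points are NaN.
    """

    dataset_id: str
    data: dict[str, tuple[int, int, np.ndarray]]

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)


@dataclass
class NullModel:
    """Null mean and spread of window scores, estimated from the non-enriched
    bulk (robust to the enriched right tail)."""

    mu0: float
    sigma0: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu0) and math.isfinite(self.sigma0)):
            raise ValueError("null parameters must be finite")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")


@dataclass
class CompositeTrack:
    """Stouffer composite over a set of Z-score grids.

    ``data`` maps chromosome -> (grid_start, step, composite S, k_used) where
    k_used counts the datasets contributing at each point.
    """

    data: dict[str, tuple[int, int, np.ndarray, np.ndarray]]
    weights: dict[str, float] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)


@dataclass
class ChipChipConfig:
    target_step: int = 7
    pvalue_cutoff: float = 1e-4
    merge_gap: int | None = None       # default: 2 * target_step
    min_peak_len: int | None = None    # default: 4 * target_step
    min_datasets: int = 1
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.target_step <= 0:
            raise ValueError("target_step must be > 0")
        if not (0.0 < self.pvalue_cutoff < 1.0):
            raise ValueError("pvalue_cutoff must be in (0, 1)")
        if self.merge_gap is None:
            self.merge_gap = 2 * self.target_step
        if self.min_peak_len is None:
            self.min_peak_len = 4 * self.target_step
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.weights is not None and any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be > 0")

    @property
    def z0(self) -> float:
        """One-sided standard-normal quantile for the P-value cutoff."""
        return float(stats.norm.isf(self.pvalue_cutoff))


# ---------------------------------------------------------------------------
# Interpolation to a common grid
# ---------------------------------------------------------------------------


def interpolate_to_grid(track: ScoreTrack, target_step: int) -> GridTrack:
    """Resample probe scores onto a grid of multiples of ``target_step``.

    A grid point strictly between adjacent probes is filled by linear
    interpolation only when the probes lie within ``track.max_interp_dist`` of
    each other; grid points coinciding with a probe take the probe score
    exactly, and nothing is extrapolated beyond the outermost probes.
    """
    if target_step <= 0:
        raise ValueError("target_step must be > 0")
    if track.n_probes == 0:
        raise ValueError("empty score track")
    out: dict[str, tuple[int, int, np.ndarray]] = {}
    for chrom in track.chroms:
        pos, score = track.data[chrom]
        if pos.size == 0:
            out[chrom] = (0, target_step, np.empty(0))
            continue
        first = int(math.ceil(pos[0] / target_step))
        last = int(math.floor(pos[-1] / target_step))
        if last < first:
            out[chrom] = (0, target_step, np.empty(0))
            continue
        grid = np.arange(first, last + 1, dtype=np.int64) * target_step
        values = np.full(grid.size, np.nan)

        # right neighbour index of each grid point among probes
        j = np.searchsorted(pos, grid, side="left")
        exact = (j < pos.size) & (pos[np.minimum(j, pos.size - 1)] == grid)
        values[exact] = score[np.minimum(j, pos.size - 1)][exact]

        between = ~exact & (j > 0) & (j < pos.size)
        if np.any(between):
            jl = j[between] - 1
            jr = j[between]
            gap = pos[jr] - pos[jl]
            ok = gap <= track.max_interp_dist
            idx = np.flatnonzero(between)[ok]
            jl, jr = jl[ok], jr[ok]
            frac = (grid[idx] - pos[jl]) / (pos[jr] - pos[jl])
            values[idx] = score[jl] + frac * (score[jr] - score[jl])
        out[chrom] = (int(grid[0]) if grid.size else 0, target_step, values)
    return GridTrack(dataset_id=track.dataset_id, data=out)


# ---------------------------------------------------------------------------
# Null model and Z-scores
# ---------------------------------------------------------------------------


def estimate_null(values: np.ndarray) -> NullModel:
    """Estimate the null mean/SD of window scores from the non-enriched bulk.

    mu0 is the sample median; sigma0 is the median absolute deviation of the
    values at or below the median (the left half, reflected), scaled by 1.4826
    for consistency with a normal SD.  Using only the left side keeps the
    estimate untouched by the enriched heavy right tail.
    """
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < 100:
        raise ValueError(f"need >= 100 finite values to estimate the null, got {values.size}")
    mu0 = float(np.median(values))
    left_dev = mu0 - values[values <= mu0]
    sigma0 = _MAD_SCALE * float(np.median(left_dev))
    if sigma0 <= 0:
        raise ValueError("degenerate score distribution: zero spread below the median")
    return NullModel(mu0=mu0, sigma0=sigma0)


def to_zscores(grid: GridTrack, null: NullModel) -> GridTrack:
    """Standardize grid values: Z = (score - mu0) / sigma0; NaN stays NaN."""
    out = {
        chrom: (start, step, (vals - null.mu0) / null.sigma0)
        for chrom, (start, step, vals) in grid.data.items()
    }
    return GridTrack(dataset_id=grid.dataset_id, data=out)


# ---------------------------------------------------------------------------
# Stouffer combination
# ---------------------------------------------------------------------------


def combine_stouffer(z_grids: list[GridTrack], config: ChipChipConfig) -> CompositeTrack:
    """Combine Z-score grids into the weighted Stouffer composite.

    Points with fewer than ``config.min_datasets`` contributing datasets are
    left missing; at covered points the null-preserving weighted form keeps S
    standard normal under the null for any non-missing subset.
    """
    if not z_grids:
        raise ValueError("need at least one Z grid")
    weights = config.weights or {}
    chroms = sorted({c for g in z_grids for c in g.data})
    out: dict[str, tuple[int, int, np.ndarray, np.ndarray]] = {}
    steps = {step for g in z_grids for (_, step, _) in g.data.values()}
    if len(steps) > 1:
        raise ValueError(f"grids have mismatched steps: {sorted(steps)}")
    step = steps.pop() if steps else config.target_step

    for chrom in chroms:
        spans = []
        for g in z_grids:
            if chrom in g.data and g.data[chrom][2].size:
                start, _, vals = g.data[chrom]
                spans.append((start, start + (vals.size - 1) * step))
        if not spans:
            continue
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        n = (hi - lo) // step + 1
        wsum = np.zeros(n)
        w2sum = np.zeros(n)
        k_used = np.zeros(n, dtype=np.int64)
        for g in z_grids:
            if chrom not in g.data or not g.data[chrom][2].size:
                continue
            start, _, vals = g.data[chrom]
            w = float(weights.get(g.dataset_id, 1.0))
            off = (start - lo) // step
            seg = slice(off, off + vals.size)
            present = np.isfinite(vals)
            wsum[seg][present] += w * vals[present]
            w2sum[seg][present] += w * w
            k_used[seg][present] += 1
        composite = np.full(n, np.nan)
        ok = k_used >= max(1, config.min_datasets)
        composite[ok] = wsum[ok] / np.sqrt(w2sum[ok])
        k_out = np.where(ok, k_used, 0)
        out[chrom] = (lo, step, composite, k_out)
    return CompositeTrack(data=out, weights={g.dataset_id: float(weights.get(g.dataset_id, 1.0)) for g in z_grids})


# ---------------------------------------------------------------------------
# Peak calling on the composite
# ---------------------------------------------------------------------------


def _runs_above(values: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Maximal index runs with values > cutoff (NaN breaks a run)."""
    above = np.zeros(values.size, dtype=bool)
    finite = np.isfinite(values)
    above[finite] = values[finite] > cutoff
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    return list(zip(starts.tolist(), ends.tolist()))


def call_peaks_composite(comp: CompositeTrack, config: ChipChipConfig) -> list[Peak]:
    """Call peaks as maximal grid runs with composite S above the Z cutoff.

    Runs separated by at most ``merge_gap`` bp are merged, runs shorter than
    ``min_peak_len`` bp are discarded, the summit is the leftmost grid point
    of maximal S, and the P-value is the one-sided standard-normal tail of
    the maximum.
    """
    return _call_peaks(comp, config, sign=+1)


def _call_peaks(comp: CompositeTrack, config: ChipChipConfig, sign: int) -> list[Peak]:
    z0 = config.z0
    peaks: list[Peak] = []
    for chrom in comp.chroms:
        start0, step, composite, k_used = comp.data[chrom]
        values = sign * composite
        runs = _runs_above(values, z0)
        if not runs:
            continue
        # merge runs whose genomic gap is <= merge_gap
        merged = [list(runs[0])]
        for a, b in runs[1:]:
            # gap between end of previous occupied span and start of next, in bp
            gap = (a - merged[-1][1]) * step
            if gap <= config.merge_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            length = (b - a) * step
            if length < config.min_peak_len:
                continue
            seg = values[a:b]
            local = np.where(np.isfinite(seg), seg, -np.inf)
            imax = int(np.argmax(local))  # argmax is leftmost on ties
            smax = float(local[imax])
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start0 + a * step,
                    end=start0 + (b - 1) * step + step,
                    summit=start0 + (a + imax) * step,
                    score=sign * smax,
                    pvalue=float(stats.norm.sf(smax)),
                    n_datasets=int(k_used[a + imax]),
                )
            )
    return peaks


def efdr_signflip(comp: CompositeTrack, config: ChipChipConfig) -> float | None:
    """Empirical FDR by sign flipping.

    Counts peaks above +Z0 (P) and, with identical merge/length rules on the
    negated composite, peaks below -Z0 (N); returns min(1, N/P).  When no
    positive peaks exist the ratio is undefined and None is returned, which
    is distinct from an eFDR of 0.
    """
    n_pos = len(_call_peaks(comp, config, sign=+1))
    n_neg = len(_call_peaks(comp, config, sign=-1))
    if n_pos == 0:
        return None
    return min(1.0, n_neg / n_pos)


# ---------------------------------------------------------------------------
# End-to-end branch
# ---------------------------------------------------------------------------


def chipchip_pipeline(
    tracks: list[ScoreTrack], config: ChipChipConfig
) -> tuple[list[Peak], float | None, CompositeTrack]:
    """Interpolate, Z-normalize, combine, call peaks and estimate the eFDR.

    Returns (peaks sorted by ascending P-value, eFDR, composite track).  The
    eFDR is written onto every returned peak.
    """
    z_grids = []
    for track in tracks:
        grid = interpolate_to_grid(track, config.target_step)
        values = np.concatenate([v for (_, _, v) in grid.data.values()]) if grid.data else np.empty(0)
        null = estimate_null(values)
        z_grids.append(to_zscores(grid, null))
    comp = combine_stouffer(z_grids, config)
    peaks = call_peaks_composite(comp, config)
    efdr = efdr_signflip(comp, config)
    if efdr is not None:
        for p in peaks:
            p.efdr = efdr
    peaks.sort(key=lambda p: (p.pvalue, p.chrom, p.start))
    return peaks, efdr, comp
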