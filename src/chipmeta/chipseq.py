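"""Cross-laboratory ChIP-seq meta-analysis.

Sequencing tags mark fragment ends: around a true binding site Watson-strand
tags pile up upstream and Crick-strand tags downstream, separated by the
library's characteristic fragment size d.  The branch estimates d separately
for every library from that bimodal pattern, shifts each library's tags 3' by
d/2 so pileups center on the protein-DNA contact point, pools the shifted
tags across libraries, and scans the pool with a Poisson model whose rate
parameter is taken as the maximum of a genome-wide background rate and local
rates from 1 kb / 5 kb / 10 kb windows (absorbing chromatin, copy-number and
sequencing biases).  The empirical FDR comes from swapping ChIP and control.

A merge-first comparator (pool raw tags, fit one fragment-size model for the
mixture) is provided; it degrades when libraries differ in fragment size,
whereas the per-library model does not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .track_io import Peak, TagSet

__all__ = [
    "ShiftModel",
    "LambdaSet",
    "ChipSeqConfig",
    "PooledLibrary",
    "ModelBuildError",
    "dedup_tags",
    "estimate_fragment_size",
    "shift_tags",
    "pool_libraries",
    "poisson_sf",
    "local_lambda",
    "call_peaks_seq",
    "efdr_swap",
    "merged_baseline",
    "chipseq_pipeline",
]

logger = logging.getLogger("chipmeta")


class ModelBuildError(RuntimeError):
    """Fragment-size model building failed (too few candidates or no
    bimodal structure); override with a default d to proceed."""


@dataclass
class ShiftModel:
    """Estimated characteristic fragment size of one ChIP-DNA library."""

    d: int
    n_model_peaks: int
    watson_profile: np.ndarray
    crick_profile: np.ndarray


@dataclass
class LambdaSet:
    """Poisson rates (expected tags per scan window) at one locus."""

    lambda_bg: float
    lambda_1k: float | None = None
    lambda_5k: float | None = None
    lambda_10k: float | None = None

    @property
    def lambda_local(self) -> float:
        members = [self.lambda_bg] + [
            v for v in (self.lambda_1k, self.lambda_5k, self.lambda_10k) if v is not None
        ]
        return max(members)


@dataclass
class ChipSeqConfig:
    genome_size: float = 2.7e9
    bandwidth: int = 300          # model-building scan half-window
    mfold_lo: float = 10.0
    mfold_hi: float = 30.0
    max_model_peaks: int = 1000
    min_model_peaks: int = 100
    min_d: int = 50
    default_d: int = 100          # fallback fragment size / no-shift scan window
    scan_window: int | None = None  # defaults to max per-library d
    pvalue_cutoff: float = 1e-5
    seed_pvalue: float = 1e-3     # loose cutoff for candidate windows vs lambda_bg
    max_dup_per_pos: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.mfold_lo < self.mfold_hi):
            raise ValueError("need 0 < mfold_lo < mfold_hi")
        if self.bandwidth <= 0 or self.genome_size <= 0:
            raise ValueError("bandwidth and genome_size must be > 0")


@dataclass
class PooledLibrary:
    """Model-shifted tags pooled across libraries."""

    tags: TagSet
    source_ids: list[str]
    per_source_d: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tag preprocessing
# ---------------------------------------------------------------------------


def dedup_tags(tags: TagSet, max_dup_per_pos: int = 1) -> TagSet:
    """Keep at most ``max_dup_per_pos`` tags per (chrom, position, strand)."""
    if max_dup_per_pos < 1:
        raise ValueError("max_dup_per_pos must be >= 1")
    data = {}
    for chrom, (plus, minus) in tags.data.items():
        kept = []
        for arr in (plus, minus):
            uniq, counts = np.unique(arr, return_counts=True)
            kept.append(np.repeat(uniq, np.minimum(counts, max_dup_per_pos)))
        data[chrom] = tuple(kept)
    return TagSet(dataset_id=tags.dataset_id, data=data)


def shift_tags(tags: TagSet, d: int) -> TagSet:
    """Shift tags 3' by floor(d/2): + strand moves right, - strand moves left
    (floored at 0).  d = 0 is the identity."""
    if d < 0:
        raise ValueError("d must be >= 0")
    half = d // 2
    data = {
        chrom: (plus + half, np.maximum(minus - half, 0))
        for chrom, (plus, minus) in tags.data.items()
    }
    return TagSet(dataset_id=tags.dataset_id, data=data)


def pool_libraries(shifted: list[TagSet], per_source_d: dict[str, int] | None = None) -> PooledLibrary:
    """Concatenate already-shifted libraries into one sorted pool."""
    ids = [t.dataset_id for t in shifted]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate dataset ids in pool: {ids}")
    chroms = sorted({c for t in shifted for c in t.data})
    data = {}
    for chrom in chroms:
        plus = np.concatenate([t.data[chrom][0] for t in shifted if chrom in t.data])
        minus = np.concatenate([t.data[chrom][1] for t in shifted if chrom in t.data])
        data[chrom] = (np.sort(plus), np.sort(minus))
    return PooledLibrary(
        tags=TagSet(dataset_id="pooled(" + "+".join(ids) + ")", data=data),
        source_ids=ids,
        per_source_d=dict(per_source_d or {}),
    )


# ---------------------------------------------------------------------------
# Fragment-size model
# ---------------------------------------------------------------------------


def _window_counts(positions: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    return np.searchsorted(positions, starts + width) - np.searchsorted(positions, starts)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def estimate_fragment_size(chip: TagSet, config: ChipSeqConfig) -> ShiftModel:
    """Estimate fragment size d from the Watson/Crick bimodal pattern.

    Windows of 2*bandwidth with tag counts between mfold_lo and mfold_hi
    times the background expectation become model candidates (greedily
    non-overlapping, best-count first, capped at ``max_model_peaks``).  Each
    candidate is centered on the midpoint of its Watson and Crick modes; the
    strand-specific tag densities are averaged across candidates and d is the
    distance between the averaged Crick and Watson modes.
    """
    bw = config.bandwidth
    width = 2 * bw
    lam_bg = chip.n_tags * width / config.genome_size
    lo, hi = config.mfold_lo * lam_bg, config.mfold_hi * lam_bg

    candidates: list[tuple[int, str, int]] = []  # (count, chrom, start)
    for chrom in chip.chroms:
        pos = chip.positions(chrom)
        if pos.size == 0:
            continue
        starts = np.arange(0, pos[-1] + 1, bw, dtype=np.int64)
        counts = _window_counts(pos, starts, width)
        sel = (counts >= lo) & (counts <= hi)
        candidates.extend(
            (int(c), chrom, int(s)) for c, s in zip(counts[sel], starts[sel])
        )
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen: list[tuple[str, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for count, chrom, start in candidates:
        spans = occupied.setdefault(chrom, [])
        if any(start < e and start + width > s for s, e in spans):
            continue
        spans.append((start, start + width))
        chosen.append((chrom, start))
        if len(chosen) >= config.max_model_peaks:
            break
    if len(chosen) < config.min_model_peaks:
        raise ModelBuildError(
            f"only {len(chosen)} model candidates (need {config.min_model_peaks}); "
            "supply a default fragment size to proceed without model building"
        )

    prof_len = 2 * width + 1  # relative positions -width..width around the midpoint
    watson = np.zeros(prof_len)
    crick = np.zeros(prof_len)
    used = 0
    for chrom, start in chosen:
        plus, minus = chip.data[chrom]
        wp = plus[(plus >= start) & (plus < start + width)]
        cp = minus[(minus >= start) & (minus < start + width)]
        if wp.size == 0 or cp.size == 0:
            continue
        # center on the midpoint of the strand means (stabler than raw
        # histogram modes), then collect profile tags from the whole library
        # so wide fragments aren't clipped at the candidate-window edge
        mid = int(round((wp.mean() + cp.mean()) / 2))
        for arr, prof in ((plus, watson), (minus, crick)):
            near = arr[(arr >= mid - width) & (arr <= mid + width)]
            np.add.at(prof, near - mid + width, 1.0)
        used += 1
    if used == 0 or crick.sum() == 0 or watson.sum() == 0:
        raise ModelBuildError("no candidate with tags on both strands; cannot model d")
    watson /= used
    crick /= used
    # d = lag maximizing the alignment of the smoothed strand profiles
    # (equals the mode-to-mode distance for symmetric peaks, but integrates
    # the whole profile shape instead of two noisy argmaxes)
    sm_w = _smooth(watson, 21)
    sm_c = _smooth(crick, 21)
    corr = np.correlate(sm_c - sm_c.mean(), sm_w - sm_w.mean(), mode="full")
    d = int(corr.argmax()) - (sm_w.size - 1)
    if d < config.min_d:
        logger.warning(
            "modeled d=%d below min_d=%d; falling back to default d=%d",
            d, config.min_d, config.default_d,
        )
        d = config.default_d
    return ShiftModel(d=d, n_model_peaks=used, watson_profile=watson, crick_profile=crick)


# ---------------------------------------------------------------------------
# Poisson scoring
# ---------------------------------------------------------------------------


def poisson_sf(count: int, lam: float) -> float:
    """P(X >= count) for X ~ Poisson(lam), via the regularized lower
    incomplete gamma function (stable in log space internally)."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if count == 0:
        return 1.0
    return float(special.gammainc(count, lam))


def local_lambda(
    control: TagSet | None,
    chip: TagSet,
    region_center: int,
    chrom: str,
    config: ChipSeqConfig,
    scan_window: int,
    depth_ratio: float = 1.0,
) -> LambdaSet:
    """Dynamic Poisson rate at one locus, in expected tags per scan window.

    Local rates come from 1 kb / 5 kb / 10 kb windows centered on the region,
    estimated from the control when available (scaled to ChIP depth by
    ``depth_ratio``); without a control the 1 kb member is dropped and the
    5 kb / 10 kb members come from the ChIP library itself.  The rate used
    for scoring is the maximum of the members and the genome-wide background.
    """
    lam_bg = chip.n_tags * scan_window / config.genome_size
    source = control if control is not None else chip
    ratio = depth_ratio if control is not None else 1.0
    pos = source.positions(chrom)

    def rate(w: int) -> float:
        lo, hi = region_center - w // 2, region_center + w // 2
        cnt = int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))
        return cnt * ratio * scan_window / w

    kwargs = {"lambda_5k": rate(5000), "lambda_10k": rate(10000)}
    if control is not None:
        kwargs["lambda_1k"] = rate(1000)
    return LambdaSet(lambda_bg=lam_bg, **kwargs)


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------


def call_peaks_seq(
    chip: PooledLibrary, control: PooledLibrary | None, config: ChipSeqConfig
) -> list[Peak]:
    """Sliding-window scan of the pooled shifted tags with dynamic-Poisson
    rescoring.

    Windows of ``scan_window`` bp at half-window steps whose counts beat a
    loose Poisson seed threshold against the genome-wide background are
    merged into candidate regions; each region is rescored with the local
    dynamic rate, and regions passing ``pvalue_cutoff`` become peaks.  The
    summit is the leftmost maximum of the smoothed shifted-tag pileup.
    Control counts are scaled to the ChIP depth before comparison.
    """
    w0 = config.scan_window or (
        max(chip.per_source_d.values()) if chip.per_source_d else config.default_d
    )
    if w0 <= 0:
        w0 = config.default_d
    step = max(1, w0 // 2)
    chip_tags = chip.tags
    ctrl_tags = control.tags if control is not None else None
    total_chip = chip_tags.n_tags
    if total_chip == 0:
        return []
    ratio = 1.0
    if ctrl_tags is not None and ctrl_tags.n_tags > 0:
        ratio = total_chip / ctrl_tags.n_tags
        if ctrl_tags.n_tags < total_chip:
            logger.warning(
                "control depth (%d) below ChIP depth (%d); scaling control counts by %.3f",
                ctrl_tags.n_tags, total_chip, ratio,
            )
    lam_bg = total_chip * w0 / config.genome_size

    peaks: list[Peak] = []
    for chrom in chip_tags.chroms:
        pos = chip_tags.positions(chrom)
        if pos.size == 0:
            continue
        starts = np.arange(0, pos[-1] + 1, step, dtype=np.int64)
        counts = _window_counts(pos, starts, w0)
        nz = counts > 0
        pvals = np.ones(starts.size)
        pvals[nz] = special.gammainc(counts[nz], lam_bg)
        sel = np.flatnonzero(pvals <= config.seed_pvalue)
        if sel.size == 0:
            continue
        # merge overlapping/adjacent selected windows into regions
        regions: list[tuple[int, int]] = []
        reg_start = int(starts[sel[0]])
        reg_end = reg_start + w0
        for i in sel[1:]:
            s = int(starts[i])
            if s <= reg_end:
                reg_end = s + w0
            else:
                regions.append((reg_start, reg_end))
                reg_start, reg_end = s, s + w0
        regions.append((reg_start, reg_end))

        for rs, re in regions:
            in_reg = pos[(pos >= rs) & (pos < re)]
            cnt = int(in_reg.size)
            if cnt == 0:
                continue
            length = re - rs
            scaled = int(round(cnt * w0 / length))
            center = (rs + re) // 2
            lamset = local_lambda(
                ctrl_tags, chip_tags, center, chrom, config, w0, depth_ratio=ratio
            )
            p = poisson_sf(scaled, lamset.lambda_local)
            if p > config.pvalue_cutoff:
                continue
            pileup = np.bincount(in_reg - rs, minlength=length)
            # odd-width triangular kernel: no half-bin offset, and a tight
            # tag spike maps to a unique central maximum instead of a plateau
            kern = max(1, w0 // 2) | 1
            tri = np.bartlett(kern + 2)[1:-1]
            smoothed = np.convolve(pileup.astype(float), tri / tri.sum(), mode="same")
            summit = rs + int(smoothed.argmax())
            score = -10.0 * math.log10(max(p, 1e-300))
            peaks.append(
                Peak(chrom=chrom, start=rs, end=re, summit=summit,
                     score=score, pvalue=p, n_datasets=len(chip.source_ids))
            )
    peaks.sort(key=lambda pk: (pk.pvalue, pk.chrom, pk.start))
    return peaks


def efdr_swap(
    chip: PooledLibrary, control: PooledLibrary, config: ChipSeqConfig
) -> float | None:
    """Empirical FDR by sample swap: peaks called from control-vs-ChIP over
    peaks called from ChIP-vs-control with identical parameters, capped at 1.
    None (not-defined) when no ChIP peaks are found."""
    n_pos = len(call_peaks_seq(chip, control, config))
    if n_pos == 0:
        return None
    swapped_chip = PooledLibrary(
        tags=control.tags, source_ids=control.source_ids, per_source_d=chip.per_source_d
    )
    swapped_ctrl = PooledLibrary(
        tags=chip.tags, source_ids=chip.source_ids, per_source_d=chip.per_source_d
    )
    n_neg = len(call_peaks_seq(swapped_chip, swapped_ctrl, config))
    return min(1.0, n_neg / n_pos)


# ---------------------------------------------------------------------------
# End-to-end pipelines
# ---------------------------------------------------------------------------


def _prepare_controls(
    control_libraries: list[TagSet], d_values: list[int], config: ChipSeqConfig
) -> PooledLibrary | None:
    if not control_libraries:
        return None
    # a control has no bimodal signal to model: shift it with the paired
    # ChIP library's d (mean d when the libraries don't pair up one-to-one)
    if len(control_libraries) == len(d_values):
        ds = d_values
    else:
        mean_d = int(round(np.mean(d_values))) if d_values else config.default_d
        ds = [mean_d] * len(control_libraries)
    shifted = [
        shift_tags(dedup_tags(c, config.max_dup_per_pos), d)
        for c, d in zip(control_libraries, ds)
    ]
    return pool_libraries(shifted, dict(zip([c.dataset_id for c in shifted], ds)))


def chipseq_pipeline(
    chip_libraries: list[TagSet],
    control_libraries: list[TagSet] | None,
    config: ChipSeqConfig,
    shift_override: int | None = None,
) -> tuple[list[Peak], float | None, dict[str, int]]:
    """Per-library model building, d/2 shifting, pooling and peak calling.

    ``shift_override`` forces a fixed d for every library (0 disables
    shifting entirely, with the scan window falling back to ``default_d``).
    Returns (peaks by ascending P-value, eFDR or None, per-library d).
    """
    control_libraries = control_libraries or []
    per_d: dict[str, int] = {}
    shifted = []
    for lib in chip_libraries:
        lib = dedup_tags(lib, config.max_dup_per_pos)
        if shift_override is not None:
            d = shift_override
        else:
            try:
                d = estimate_fragment_size(lib, config).d
            except ModelBuildError as exc:
                logger.warning("%s: %s; using default d=%d", lib.dataset_id, exc, config.default_d)
                d = config.default_d
        per_d[lib.dataset_id] = d
        shifted.append(shift_tags(lib, d))
    pooled_chip = pool_libraries(shifted, per_d)
    pooled_ctrl = _prepare_controls(control_libraries, list(per_d.values()), config)

    peaks = call_peaks_seq(pooled_chip, pooled_ctrl, config)
    efdr = None
    if pooled_ctrl is not None:
        efdr = efdr_swap(pooled_chip, pooled_ctrl, config)
        if efdr is not None:
            for p in peaks:
                p.efdr = efdr
    return peaks, efdr, per_d


def merged_baseline(
    raw_libraries: list[TagSet],
    control_libraries: list[TagSet] | None,
    config: ChipSeqConfig,
) -> list[Peak]:
    """Merge-first comparator: pool the raw (unshifted) tags from all
    libraries, fit ONE fragment-size model to the mixture, shift everything by
    that single d/2, then call peaks.  With a single library this coincides
    with the per-library pipeline."""
    deduped = [dedup_tags(t, config.max_dup_per_pos) for t in raw_libraries]
    merged = pool_libraries(deduped).tags
    merged.dataset_id = "merged"
    model = estimate_fragment_size(merged, config)
    shifted = shift_tags(merged, model.d)
    pooled_chip = PooledLibrary(
        tags=shifted, source_ids=[t.dataset_id for t in raw_libraries],
        per_source_d={"merged": model.d},
    )
    pooled_ctrl = _prepare_controls(control_libraries or [], [model.d], config)
    return call_peaks_seq(pooled_chip, pooled_ctrl, config)
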