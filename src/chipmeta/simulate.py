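"""Synthetic benchmark generators.

Three designs with the statistical structure the meta-analysis assumes:

* a spike-in tiling-array benchmark — ~100 known enriched regions of mean
  length ~497 bp observed by several platforms with different tiling
  resolutions, interpolation distances and noise levels (null probe noise is
  Student-t so the robust null estimator faces a heavy right tail);
* ChIP-seq tag libraries with the bimodal Watson/Crick pattern around known
  binding sites and a configurable fragment size d, plus a matched
  background-only control;
* the Δd two-library construction — split one library into random halves and
  move one half's tags toward 5' so its effective fragment size grows by Δd,
  emulating joint analysis of libraries prepared with different protocols.

All generators are pure functions of (design, seed) and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import TruthSet
from .track_io import ScoreTrack, TagSet

__all__ = [
    "PlatformSpec",
    "SpikeInDesign",
    "SeqLibraryDesign",
    "make_spikein_tracks",
    "make_seq_library",
    "make_delta_d_pair",
]


@dataclass
class PlatformSpec:
    """One tiling-array platform in a spike-in design."""

    resolution: int
    max_interp_dist: int
    noise_df: float = 5.0      # Student-t degrees of freedom of null probe noise
    probe_dropout: float = 0.02

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.max_interp_dist < self.resolution:
            raise ValueError("max_interp_dist must be >= resolution")
        if not (0.0 <= self.probe_dropout < 1.0):
            raise ValueError("probe_dropout must be in [0, 1)")


def _default_platforms() -> list[PlatformSpec]:
    # three platforms with very different tiling densities, echoing the
    # one-color high-density / two-color medium / two-color sparse trio
    return [
        PlatformSpec(resolution=7, max_interp_dist=10),
        PlatformSpec(resolution=35, max_interp_dist=50),
        PlatformSpec(resolution=100, max_interp_dist=100),
    ]


@dataclass
class SpikeInDesign:
    """Spike-in benchmark: known enriched regions in genomic background."""

    n_regions: int = 100
    mean_len: int = 497
    genome_len: int = 2_000_000
    platforms: list[PlatformSpec] = field(default_factory=_default_platforms)
    fold_range: tuple[float, float] = (2.0, 6.0)  # per-region score shift, null-SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")


@dataclass
class SeqLibraryDesign:
    """Bimodal ChIP-seq library around known sites plus matched control."""

    n_sites: int = 2000
    tags_per_site: float = 20.0
    d: int = 100
    genome_len: int = 20_000_000
    bg_rate: float = 0.002  # background tags per bp (both strands together)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if self.d / 4 < 1:
            raise ValueError("d too small: positional spread d/4 degenerates below 1 bp")
        if self.bg_rate < 0:
            raise ValueError("bg_rate must be >= 0")


def _place_nonoverlapping(
    rng: np.random.Generator, lengths: np.ndarray, genome_len: int, margin: int = 0
) -> np.ndarray:
    """Uniformly random non-overlapping starts for intervals of given lengths.

    Classic gap construction: draw sorted offsets in the free space left after
    removing the interval lengths, then re-inflate."""
    padded = lengths + margin
    free = genome_len - int(padded.sum())
    if free <= 0:
        raise ValueError(
            f"cannot place {lengths.size} regions (total {padded.sum()} bp) "
            f"in a {genome_len} bp genome; increase genome_len"
        )
    offsets = np.sort(rng.integers(0, free, size=lengths.size))
    starts = offsets + np.concatenate([[0], np.cumsum(padded[:-1])])
    return starts


# ---------------------------------------------------------------------------
# Spike-in tiling-array tracks
# ---------------------------------------------------------------------------


def make_spikein_tracks(
    design: SpikeInDesign, chrom: str = "chr1"
) -> tuple[list[ScoreTrack], TruthSet]:
    """Generate one score track per platform plus the ground-truth regions.

    Region lengths are Normal(mean_len, mean_len/5) floored at 100 bp and
    placed uniformly without overlap.  Per platform, probes tile the genome
    at its resolution with Student-t null scores; probes inside a truth
    region are shifted upward by that region's fold (drawn once per region
    from ``fold_range``), and a ``probe_dropout`` fraction of probes is
    removed at random.
    """
    rng = np.random.default_rng(design.seed)
    lengths = np.maximum(
        100, np.round(rng.normal(design.mean_len, design.mean_len / 5, design.n_regions))
    ).astype(np.int64)
    starts = _place_nonoverlapping(rng, lengths, design.genome_len, margin=design.mean_len)
    truth = TruthSet(
        intervals=[(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]
    )
    folds = rng.uniform(*design.fold_range, size=design.n_regions)

    tracks = []
    for i, plat in enumerate(design.platforms):
        positions = np.arange(plat.resolution, design.genome_len, plat.resolution, dtype=np.int64)
        scores = rng.standard_t(plat.noise_df, size=positions.size)
        for (c, s, e), fold in zip(truth.intervals, folds):
            inside = (positions > s) & (positions <= e)
            scores[inside] += fold
        if plat.probe_dropout > 0:
            keep = rng.random(positions.size) >= plat.probe_dropout
            positions, scores = positions[keep], scores[keep]
        tracks.append(
            ScoreTrack(
                dataset_id=f"platform_{i}_res{plat.resolution}",
                platform=f"res{plat.resolution}",
                data={chrom: (positions, scores)},
                resolution=plat.resolution,
                max_interp_dist=plat.max_interp_dist,
            )
        )
    return tracks, truth


# ---------------------------------------------------------------------------
# ChIP-seq libraries
# ---------------------------------------------------------------------------


def make_seq_library(
    design: SeqLibraryDesign, chrom: str = "chr1", dataset_id: str = "synthetic_chip"
) -> tuple[TagSet, TagSet, np.ndarray]:
    """Generate (chip, control, truth_sites) for one synthetic library.

    Around each site s, Watson 5' ends fall at s - d/2 + Normal(0, d/4) and
    Crick 5' ends at s + d/2 + Normal(0, d/4), with Poisson(tags_per_site/2)
    tags per strand.  Uniform background tags are added on both strands at
    ``bg_rate`` per bp; the control is background-only at the ChIP depth.
    """
    rng = np.random.default_rng(design.seed)
    margin = 4 * design.d
    lengths = np.full(design.n_sites, 1, dtype=np.int64)
    sites = _place_nonoverlapping(rng, lengths, design.genome_len - 2 * margin, margin=margin) + margin
    sites = np.sort(sites)

    sd = design.d / 4
    half = design.d / 2
    plus_parts, minus_parts = [], []
    n_per = rng.poisson(design.tags_per_site / 2, size=(design.n_sites, 2))
    for s, (nw, nc) in zip(sites, n_per):
        if nw:
            plus_parts.append(np.round(s - half + rng.normal(0, sd, nw)))
        if nc:
            minus_parts.append(np.round(s + half + rng.normal(0, sd, nc)))

    n_bg = rng.poisson(design.bg_rate * design.genome_len)
    bg_pos = rng.integers(0, design.genome_len, size=n_bg)
    bg_strand = rng.random(n_bg) < 0.5
    plus_parts.append(bg_pos[bg_strand])
    minus_parts.append(bg_pos[~bg_strand])

    plus = np.clip(np.concatenate(plus_parts), 0, design.genome_len - 1).astype(np.int64)
    minus = np.clip(np.concatenate(minus_parts), 0, design.genome_len - 1).astype(np.int64)
    chip = TagSet(dataset_id=dataset_id, data={chrom: (plus, minus)})

    n_ctrl = plus.size + minus.size
    ctrl_pos = rng.integers(0, design.genome_len, size=n_ctrl)
    ctrl_strand = rng.random(n_ctrl) < 0.5
    control = TagSet(
        dataset_id=dataset_id + "_control",
        data={chrom: (ctrl_pos[ctrl_strand].astype(np.int64), ctrl_pos[~ctrl_strand].astype(np.int64))},
    )
    return chip, control, sites


def make_delta_d_pair(
    base: TagSet, delta_d: int, seed: int
) -> tuple[TagSet, TagSet]:
    """Split ``base`` into random halves; move the variant half's tags toward
    5' by delta_d/2 so its effective fragment size exceeds the common half's
    by ``delta_d`` (each strand's mode moves delta_d/2 further from the site).

    Tag counts are conserved: |common| + |variant| = |base|.
    """
    if delta_d < 0:
        raise ValueError("delta_d must be >= 0")
    rng = np.random.default_rng(seed)
    shift = delta_d // 2
    common_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    variant_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (plus, minus) in base.data.items():
        n = plus.size + minus.size
        pick = np.zeros(n, dtype=bool)
        pick[rng.permutation(n)[: n // 2]] = True
        pick_plus, pick_minus = pick[: plus.size], pick[plus.size:]
        common_data[chrom] = (plus[~pick_plus], minus[~pick_minus])
        # 5' direction: decreasing coordinate on +, increasing on -
        variant_data[chrom] = (
            np.maximum(plus[pick_plus] - shift, 0),
            minus[pick_minus] + shift,
        )
    common = TagSet(dataset_id=base.dataset_id + "_common", data=common_data)
    variant = TagSet(dataset_id=base.dataset_id + "_variant", data=variant_data)
    return common, variant
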