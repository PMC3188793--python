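"""Readers, writers and coordinate conventions for score tracks, tag files,
peak tables, FASTA sequences and position weight matrices.

Coordinate conventions
----------------------
* BED inputs/outputs are 0-based half-open, per the UCSC standard.
* Wiggle (fixedStep/variableStep) positions are 1-based points.
* In memory, tag coordinates and peak intervals are 0-based; :class:`ScoreTrack`
  probe centers are 1-based points.  Conversion happens only at parse/serialize
  boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "ScoreTrack",
    "TagSet",
    "Peak",
    "Pwm",
    "TrackIOError",
    "read_score_track",
    "write_score_track",
    "read_tag_bed",
    "write_tag_bed",
    "read_peaks",
    "write_peaks",
    "read_fasta",
    "read_pwm",
]

PEAK_TABLE_HEADER = "#chrom\tstart\tend\tname\tscore\tsummit\tpvalue\tefdr\tn_datasets"


class TrackIOError(ValueError):
    """Raised for malformed or inconsistent on-disk inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ScoreTrack:
    """Probe-level standardized window scores for one tiling-array dataset.

    ``data`` maps chromosome -> (positions, scores) where positions are
    1-based probe-center coordinates, strictly increasing, and scores are the
    platform's standardized window statistics (e.g. MAT/MA2C scores, or the
    ChIP-minus-input score difference).
    """

    dataset_id: str
    platform: str
    data: dict[str, tuple[np.ndarray, np.ndarray]]
    resolution: int
    max_interp_dist: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.max_interp_dist < self.resolution:
            raise ValueError("max_interp_dist must be >= resolution")
        for chrom, (pos, sc) in self.data.items():
            pos = np.asarray(pos, dtype=np.int64)
            sc = np.asarray(sc, dtype=np.float64)
            if pos.shape != sc.shape:
                raise ValueError(f"{chrom}: positions/scores length mismatch")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: probe positions not strictly increasing")
            if sc.size and not np.all(np.isfinite(sc)):
                raise ValueError(f"{chrom}: non-finite scores")
            self.data[chrom] = (pos, sc)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p, _ in self.data.values())


@dataclass
class TagSet:
    """Strand-aware 5'-end tag coordinates for one sequencing library.

    ``data`` maps chromosome -> (plus, minus): two sorted int64 arrays of
    0-based 5'-end positions, one per strand.  Only the 5' end is kept; read
    lengths are discarded at parse time, so libraries with different read
    lengths mix freely.
    """

    dataset_id: str
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for chrom, (plus, minus) in self.data.items():
            plus = np.sort(np.asarray(plus, dtype=np.int64))
            minus = np.sort(np.asarray(minus, dtype=np.int64))
            for arr in (plus, minus):
                if arr.size and arr[0] < 0:
                    raise ValueError(f"{chrom}: negative tag coordinate")
            norm[chrom] = (plus, minus)
        self.data = norm

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    @property
    def n_tags(self) -> int:
        return sum(p.size + m.size for p, m in self.data.values())

    def positions(self, chrom: str) -> np.ndarray:
        """All tag positions on ``chrom`` regardless of strand, sorted."""
        plus, minus = self.data.get(chrom, (np.empty(0, np.int64),) * 2)
        return np.sort(np.concatenate([plus, minus]))

    def records(self) -> Iterable[tuple[str, int, str]]:
        """Yield (chrom, pos5, strand) sorted by (chrom, pos5, strand)."""
        for chrom in self.chroms:
            plus, minus = self.data[chrom]
            merged = sorted(
                [(int(p), "+") for p in plus] + [(int(m), "-") for m in minus]
            )
            yield from ((chrom, pos, strand) for pos, strand in merged)


@dataclass
class Peak:
    """A called enriched region.

    ``score`` is the composite Z for the array branch and -10*log10(P) for the
    sequencing branch.  ``efdr`` is NaN when not yet annotated or not defined.
    """

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    pvalue: float
    efdr: float = math.nan
    n_datasets: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak start must be < end")
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak")
        if not math.isnan(self.efdr):
            self.efdr = min(1.0, max(0.0, self.efdr))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Pwm:
    """Position weight matrix over {A, C, G, T}."""

    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be width x 4")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# Score tracks (wiggle / bedGraph)
# ---------------------------------------------------------------------------


def _collapse_duplicates(pos: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # duplicate probe positions are averaged: deterministic, order-independent
    order = np.argsort(pos, kind="stable")
    pos, score = pos[order], score[order]
    uniq, inverse, counts = np.unique(pos, return_inverse=True, return_counts=True)
    sums = np.zeros(uniq.size)
    np.add.at(sums, inverse, score)
    return uniq, sums / counts


def read_score_track(
    path: str, platform: str, resolution: int, max_interp_dist: int,
    dataset_id: str | None = None,
) -> ScoreTrack:
    """Read a wiggle (fixedStep/variableStep) or bedGraph score track.

    bedGraph intervals are reduced to their midpoint (floored), standing in
    for the probe center.  Duplicate positions are collapsed by mean.
    """
    raw: dict[str, tuple[list[int], list[float]]] = {}
    mode = None  # None (bedGraph unless declared), or (kind, chrom, ...)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            try:
                if fields[0] == "fixedStep":
                    kv = dict(f.split("=", 1) for f in fields[1:])
                    mode = ["fixed", kv["chrom"], int(kv["start"]), int(kv["step"])]
                    continue
                if fields[0] == "variableStep":
                    kv = dict(f.split("=", 1) for f in fields[1:])
                    mode = ["variable", kv["chrom"]]
                    continue
                if mode is None:
                    # bedGraph: chrom start end value (0-based half-open)
                    chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    pos = (start + end) // 2  # interval midpoint, floored
                    raw.setdefault(chrom, ([], []))[0].append(pos)
                    raw[chrom][1].append(value)
                elif mode[0] == "fixed":
                    _, chrom, start, step = mode
                    raw.setdefault(chrom, ([], []))[0].append(start)
                    raw[chrom][1].append(float(fields[0]))
                    mode[2] = start + step
                else:  # variableStep
                    chrom = mode[1]
                    raw.setdefault(chrom, ([], []))[0].append(int(fields[0]))
                    raw[chrom][1].append(float(fields[1]))
            except (KeyError, IndexError, ValueError) as exc:
                raise TrackIOError(f"{path}:{lineno}: malformed line: {line!r}") from exc
    if not raw:
        raise TrackIOError(f"{path}: empty score track")
    data = {}
    for chrom, (pos, score) in raw.items():
        data[chrom] = _collapse_duplicates(
            np.asarray(pos, dtype=np.int64), np.asarray(score, dtype=np.float64)
        )
    return ScoreTrack(
        dataset_id=dataset_id or path,
        platform=platform,
        data=data,
        resolution=resolution,
        max_interp_dist=max_interp_dist,
    )


def write_score_track(track: ScoreTrack, path: str) -> None:
    """Write a ScoreTrack as variableStep wiggle (1-based positions)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            pos, score = track.data[chrom]
            fh.write(f"variableStep chrom={chrom}\n")
            for p, s in zip(pos, score):
                fh.write(f"{p}\t{s:.6g}\n")


# ---------------------------------------------------------------------------
# Tag files (BED6)
# ---------------------------------------------------------------------------


def read_tag_bed(path: str, dataset_id: str | None = None) -> TagSet:
    """Read mapped tags from 6-column BED; keep only the 5'-end position.

    pos5 = start for + strand tags, end - 1 for - strand tags.
    """
    plus: dict[str, list[int]] = {}
    minus: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise TrackIOError(f"{path}:{lineno}: BED6 required (strand column missing)")
            chrom, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
            if start < 0 or end < 0:
                raise TrackIOError(f"{path}:{lineno}: negative coordinate")
            if strand == "+":
                plus.setdefault(chrom, []).append(start)
            elif strand == "-":
                minus.setdefault(chrom, []).append(end - 1)
            else:
                raise TrackIOError(f"{path}:{lineno}: bad strand {strand!r}")
    data = {
        chrom: (
            np.asarray(plus.get(chrom, []), dtype=np.int64),
            np.asarray(minus.get(chrom, []), dtype=np.int64),
        )
        for chrom in set(plus) | set(minus)
    }
    return TagSet(dataset_id=dataset_id or path, data=data)


def write_tag_bed(tags: TagSet, path: str, read_length: int = 36) -> None:
    """Serialize a TagSet to BED6 with a nominal read length."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    with open(path, "w") as fh:
        i = 0
        for chrom, pos, strand in tags.records():
            if strand == "+":
                start, end = pos, pos + read_length
            else:
                start, end = max(0, pos - read_length + 1), pos + 1
            fh.write(f"{chrom}\t{start}\t{end}\ttag_{i}\t0\t{strand}\n")
            i += 1


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------


def write_peaks(peaks: list[Peak], path: str, dialect: str = "tabular") -> None:
    """Write peaks as BED (coordinates + score + summit) or as a full
    tab-separated table.  Peak names are ``chipmeta_peak_<k>`` in rank order.
    """
    if dialect not in ("bed", "tabular"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "tabular":
            fh.write(PEAK_TABLE_HEADER + "\n")
        for k, p in enumerate(peaks, start=1):
            name = f"chipmeta_peak_{k}"
            if dialect == "bed":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:.6g}\t.\t{p.summit}\t{p.summit + 1}\n"
                )
            else:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:.6g}\t{p.summit}"
                    f"\t{p.pvalue:.6g}\t{p.efdr:.6g}\t{p.n_datasets}\n"
                )


def read_peaks(path: str, dialect: str = "tabular") -> list[Peak]:
    """Re-read a peak table written by :func:`write_peaks`.

    The BED dialect carries only coordinates, score and summit; pvalue, efdr
    and n_datasets come back as their defaults.
    """
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "bed":
                peaks.append(
                    Peak(chrom=f[0], start=int(f[1]), end=int(f[2]),
                         summit=int(f[6]), score=float(f[4]), pvalue=1.0)
                )
            else:
                peaks.append(
                    Peak(chrom=f[0], start=int(f[1]), end=int(f[2]),
                         summit=int(f[5]), score=float(f[4]),
                         pvalue=float(f[6]), efdr=float(f[7]), n_datasets=int(f[8]))
                )
    return peaks


# ---------------------------------------------------------------------------
# FASTA and PWM
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    """Read FASTA into {identifier: uppercased sequence}; N is allowed."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise TrackIOError(f"{path}: empty sequence for {name!r}")
        if name in seqs:
            raise TrackIOError(f"{path}: duplicate identifier {name!r}")
        seqs[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                if name is None:
                    raise TrackIOError(f"{path}: sequence before first header")
                chunks.append(line)
    _flush()
    if not seqs:
        raise TrackIOError(f"{path}: no FASTA records")
    return seqs


def read_pwm(path: str, pseudocount: float = 0.0) -> Pwm:
    """Read a JASPAR-style matrix: 4 whitespace-separated rows (A/C/G/T order),
    counts or probabilities; columns are motif positions."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            # tolerate "A [ 1 2 3 ]" style
            cleaned = line.replace("[", " ").replace("]", " ")
            vals = [v for v in cleaned.split() if not v.isalpha()]
            rows.append([float(v) for v in vals])
    if len(rows) != 4:
        raise TrackIOError(f"{path}: expected 4 matrix rows (A/C/G/T), got {len(rows)}")
    mat = np.asarray(rows, dtype=np.float64).T  # width x 4
    mat = mat + pseudocount
    mat = mat / mat.sum(axis=1, keepdims=True)
    return Pwm(probs=mat, pseudocount=pseudocount)
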