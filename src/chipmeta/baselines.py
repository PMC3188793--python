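"""Comparison baselines and evaluation machinery.

Naive multi-dataset combination by majority voting (a base is enriched when
more than half of the per-dataset peak calls cover it) or region intersection
(all calls cover it), plus ROC evaluation against a known truth set and
ranked summit-accuracy curves for synthetic benchmarks.

Voting and intersection operate on base-pair coverage rather than whole-peak
identity, which avoids arbitrary overlap-fraction thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track_io import Peak

__all__ = [
    "TruthSet",
    "majority_vote",
    "intersect_regions",
    "roc_curve",
    "binary_auc",
    "summit_accuracy",
]

Interval = tuple[str, int, int]


@dataclass
class TruthSet:
    """Known enriched regions (non-overlapping after normalization)."""

    intervals: list[Interval]
    fold: list[float] | None = None

    def __post_init__(self) -> None:
        merged = _merge_coverage([self.intervals])
        if sum(e - s for _, s, e in merged) != sum(e - s for _, s, e in self.intervals):
            self.intervals = merged
            self.fold = None
        for _, s, e in self.intervals:
            if s >= e:
                raise ValueError("truth interval start must be < end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        for c, s, e in self.intervals:
            if c == chrom and start < e and end > s:
                return True
        return False


def _coverage_events(
    peak_lists: list[list[Peak]] | list[list[Interval]],
) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome (position, +1/-1) coverage change events."""
    events: dict[str, list[tuple[int, int]]] = {}
    for lst in peak_lists:
        for p in lst:
            if isinstance(p, Peak):
                chrom, start, end = p.chrom, p.start, p.end
            else:
                chrom, start, end = p
            events.setdefault(chrom, []).append((start, +1))
            events[chrom].append((end, -1))
    return events


def _regions_at_depth(peak_lists, min_depth: int) -> list[Interval]:
    """Maximal regions where the per-list coverage depth is >= min_depth.

    Each list contributes depth at most 1 per base (within-list overlaps are
    flattened first)."""
    flattened = [_merge_coverage([lst]) for lst in peak_lists]
    events = _coverage_events(flattened)
    out: list[Interval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        start = None
        prev_pos = None
        merged: list[tuple[int, int]] = []
        for pos, delta in evs:
            if prev_pos is not None and pos > prev_pos:
                if depth >= min_depth:
                    if start is None:
                        start = prev_pos
                else:
                    if start is not None:
                        merged.append((start, prev_pos))
                        start = None
            depth += delta
            prev_pos = pos
        if start is not None and prev_pos is not None and prev_pos > start:
            merged.append((start, prev_pos))
        # join touching segments
        joined: list[list[int]] = []
        for s, e in merged:
            if joined and s <= joined[-1][1]:
                joined[-1][1] = max(joined[-1][1], e)
            else:
                joined.append([s, e])
        out.extend((chrom, s, e) for s, e in joined)
    return out


def _merge_coverage(peak_lists) -> list[Interval]:
    intervals: list[Interval] = []
    for lst in peak_lists:
        for p in lst:
            if isinstance(p, Peak):
                intervals.append((p.chrom, p.start, p.end))
            else:
                intervals.append(tuple(p))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    out: list[Interval] = []
    for c in sorted(by_chrom):
        spans = sorted(by_chrom[c])
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend((c, s, e) for s, e in merged)
    return out


def majority_vote(peak_lists: list[list[Peak]]) -> list[Interval]:
    """Regions covered by peaks in strictly more than half of the lists."""
    if len(peak_lists) < 2:
        raise ValueError("majority voting needs at least 2 peak lists")
    k = len(peak_lists)
    min_depth = k // 2 + 1  # strictly more than half
    return _regions_at_depth(peak_lists, min_depth)


def intersect_regions(peak_lists: list[list[Peak]]) -> list[Interval]:
    """Regions covered by peaks in every list."""
    if len(peak_lists) < 2:
        raise ValueError("intersection needs at least 2 peak lists")
    return _regions_at_depth(peak_lists, len(peak_lists))


# ---------------------------------------------------------------------------
# ROC and summit accuracy
# ---------------------------------------------------------------------------


def windowed_candidates(
    grid_data: dict, window: int
) -> list[tuple[str, int, int, float]]:
    """Tile grid tracks into fixed windows ranked by their best score.

    ``grid_data`` maps chromosome -> (grid_start, step, values, ...) as in
    GridTrack/CompositeTrack data; every ``window``-bp tile gets the maximum
    finite value inside it (missing-only tiles score -inf).  Returns
    (chrom, start, end, score) sorted best-first — the candidate universe for
    window-level ROC evaluation.
    """
    out = []
    for chrom, entry in grid_data.items():
        start0, step, values = entry[0], entry[1], np.asarray(entry[2])
        if values.size == 0:
            continue
        end_bp = start0 + (values.size - 1) * step + step
        for ws in range(start0 - start0 % window, end_bp, window):
            i0 = max(0, -(-(ws - start0) // step))        # ceil
            i1 = min(values.size, (ws + window - 1 - start0) // step + 1)
            if i1 <= i0:
                continue
            seg = values[i0:i1]
            finite = seg[np.isfinite(seg)]
            score = float(finite.max()) if finite.size else -np.inf
            out.append((chrom, ws, ws + window, score))
    out.sort(key=lambda t: -t[3])
    return out


def _truth_lookup(truth: TruthSet) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in truth.intervals:
        by_chrom.setdefault(c, []).append((s, e))
    return {c: np.asarray(sorted(v)) for c, v in by_chrom.items()}


def _overlaps_any(lookup: dict[str, np.ndarray], chrom: str, start: int, end: int) -> int:
    """Index of the first overlapped truth interval, or -1."""
    arr = lookup.get(chrom)
    if arr is None or arr.size == 0:
        return -1
    i = int(np.searchsorted(arr[:, 0], end)) - 1
    while i >= 0 and arr[i, 1] > start:
        if arr[i, 0] < end:
            return i
        i -= 1
    return -1


def roc_curve(
    ranked: list, truth: TruthSet, universe: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC of a significance-ranked candidate list against known regions.

    ``ranked`` is a list of Peak objects or (chrom, start, end[, score])
    tuples, best first.  A candidate is a true positive when it overlaps a
    truth interval by at least 1 bp; sweeping down the ranking, tpr is the
    fraction of truth intervals recovered and fpr the fraction of the
    non-truth universe selected.  ``universe`` optionally sets the total
    candidate count (extra candidates count as never selected); the default
    universe is the ranked list itself.  Returns (fpr, tpr, trapezoid AUC).
    """
    if not truth.intervals:
        raise ValueError("truth set is empty")
    lookup = _truth_lookup(truth)
    n_truth = len(truth.intervals)
    truth_seen: set[tuple[str, int]] = set()
    tpr_steps = []
    fp = 0
    fps = []
    for i, cand in enumerate(ranked):
        if isinstance(cand, Peak):
            chrom, start, end = cand.chrom, cand.start, cand.end
        else:
            chrom, start, end = cand[0], cand[1], cand[2]
        j = _overlaps_any(lookup, chrom, start, end)
        if j >= 0:
            truth_seen.add((chrom, j))
        else:
            fp += 1
        tpr_steps.append(len(truth_seen) / n_truth)
        fps.append(fp)
    total = universe if universe is not None else len(ranked)
    n_neg = max(1, total - n_truth)
    fpr = np.concatenate([[0.0], np.asarray(fps) / n_neg, [1.0]])
    tpr = np.concatenate([[0.0], np.asarray(tpr_steps), [tpr_steps[-1] if tpr_steps else 0.0]])
    fpr = np.clip(fpr, 0.0, 1.0)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def binary_auc(regions: list[Interval], truth: TruthSet, universe: list[Interval]) -> float:
    """AUC of an unranked region set: the area under the two-segment ROC
    through its single operating point over the given candidate universe."""
    if not truth.intervals:
        raise ValueError("truth set is empty")
    lookup = _truth_lookup(truth)
    reg_lookup = _truth_lookup(TruthSet(intervals=list(regions))) if regions else {}
    n_truth_hit = 0
    tp = fp = pos = neg = 0
    for chrom, s, e in universe:
        is_truth = _overlaps_any(lookup, chrom, s, e) >= 0
        selected = bool(reg_lookup) and _overlaps_any(reg_lookup, chrom, s, e) >= 0
        pos += is_truth
        neg += not is_truth
        tp += is_truth and selected
        fp += (not is_truth) and selected
    tpr = tp / max(1, pos)
    fpr = fp / max(1, neg)
    # trapezoid through (0,0) -> (fpr, tpr) -> (1,1)
    return 0.5 * (tpr * fpr) + 0.5 * (tpr + 1.0) * (1.0 - fpr)


def summit_accuracy(
    ranked: list[Peak], truth_sites: dict[str, np.ndarray] | list, tol: int
) -> np.ndarray:
    """Fraction of top-N peaks whose summit lies within ``tol`` bp of a truth
    site, for every nested prefix N = 1..len(ranked).

    ``truth_sites`` is {chrom: sorted positions} or, for single-chromosome
    data, a plain sequence of positions (assigned to every peak's chrom).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if not isinstance(truth_sites, dict):
        arr = np.sort(np.asarray(truth_sites, dtype=np.int64))
        sites = {p.chrom: arr for p in ranked} or {"": arr}
    else:
        sites = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in truth_sites.items()}
    hits = np.zeros(len(ranked), dtype=float)
    for i, p in enumerate(ranked):
        arr = sites.get(p.chrom)
        if arr is None or arr.size == 0:
            continue
        j = int(np.searchsorted(arr, p.summit))
        best = min(
            abs(int(arr[k]) - p.summit) for k in (j - 1, j) if 0 <= k < arr.size
        )
        hits[i] = best <= tol
    if hits.size == 0:
        return hits
    return np.cumsum(hits) / np.arange(1, hits.size + 1)
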