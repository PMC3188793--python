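"""PWM scanning against a k-th order Markov background and the
motif-fraction-vs-top-N evaluation of ranked peak lists.

A window w of PWM width is scored as the log2 likelihood ratio

    score(w) = sum_i log2 PWM_i(w_i) - log2 P_bg(w)

where P_bg is the Markov-chain likelihood of the window (initial k-mer
distribution times the conditional transitions).  Both strands are scanned:
the reverse complement of each window is scored the same way.  Windows
containing N are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .track_io import Peak, Pwm

__all__ = [
    "MarkovBackground",
    "train_background",
    "scan_pwm",
    "null_score_threshold",
    "motif_fraction_curve",
    "revcomp",
]

logger = logging.getLogger("chipmeta")

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and anything else to -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_IDX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


@dataclass
class MarkovBackground:
    """Markov chain over {A,C,G,T}: conditional P(base | previous ``order``
    bases) as a 4^order x 4 table plus an initial distribution over
    ``order``-mers."""

    order: int
    conditional: np.ndarray   # (4^order, 4), rows sum to 1
    initial: np.ndarray       # (4^order,), sums to 1

    def __post_init__(self) -> None:
        n_ctx = 4 ** self.order
        if self.conditional.shape != (n_ctx, 4):
            raise ValueError("conditional table has wrong shape")
        if not np.allclose(self.conditional.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if np.any(self.conditional <= 0) or np.any(self.initial <= 0):
            raise ValueError("probabilities must be > 0 (use a pseudocount)")

    def log2_likelihood(self, codes: np.ndarray) -> float:
        """log2 probability of an encoded window (no ambiguous bases)."""
        k = self.order
        if codes.size < k:
            raise ValueError(f"window shorter than Markov order {k}")
        ctx = 0
        for c in codes[:k]:
            ctx = ctx * 4 + int(c)
        ll = float(np.log2(self.initial[ctx]))
        mask = 4 ** (k - 1)
        for c in codes[k:]:
            ll += float(np.log2(self.conditional[ctx, int(c)]))
            ctx = (ctx % mask) * 4 + int(c)  # drop the oldest base
        return ll

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        """Sample an encoded sequence of the given length from the chain."""
        k = self.order
        out = np.empty(length, dtype=np.int64)
        ctx = int(rng.choice(4 ** k, p=self.initial))
        # unpack initial context
        for i in range(min(k, length) - 1, -1, -1):
            out[i] = ctx % 4
            ctx //= 4
        ctx = 0
        for i in range(min(k, length)):
            ctx = ctx * 4 + int(out[i])
        mask = 4 ** (k - 1)
        for i in range(k, length):
            b = int(rng.choice(4, p=self.conditional[ctx]))
            out[i] = b
            ctx = (ctx % mask) * 4 + b
        return out


def train_background(
    seqs: list[str] | dict[str, str], order: int = 3, pseudocount: float = 0.5
) -> MarkovBackground:
    """Estimate the Markov background from (order+1)-mer counts.

    Windows containing ambiguous bases are skipped; ``pseudocount`` is added
    to every cell so all transitions stay strictly positive."""
    if isinstance(seqs, dict):
        seqs = list(seqs.values())
    if not seqs or not any(seqs):
        raise ValueError("empty training corpus")
    n_ctx = 4 ** order
    counts = np.full((n_ctx, 4), pseudocount, dtype=np.float64)
    init = np.full(n_ctx, pseudocount, dtype=np.float64)
    total_len = sum(len(s) for s in seqs)
    if total_len <= 4 ** (order + 1):
        logger.warning(
            "background corpus (%d bp) is short for order %d (4^%d = %d contexts)",
            total_len, order, order + 1, 4 ** (order + 1),
        )
    mask = 4 ** (order - 1)
    for seq in seqs:
        codes = _encode(seq.upper())
        ctx = -1
        valid = 0  # run length of unambiguous bases ending at i-1
        for c in codes:
            c = int(c)
            if c < 0:
                valid, ctx = 0, -1
                continue
            if valid >= order:
                counts[ctx, c] += 1
                init[ctx] += 1
                ctx = (ctx % mask) * 4 + c
            else:
                ctx = (0 if ctx < 0 else ctx) * 4 + c
            valid += 1
    conditional = counts / counts.sum(axis=1, keepdims=True)
    initial = init / init.sum()
    return MarkovBackground(order=order, conditional=conditional, initial=initial)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _pwm_log2(pwm: Pwm) -> np.ndarray:
    probs = pwm.probs + (pwm.pseudocount if np.any(pwm.probs == 0) else 0.0)
    probs = probs / probs.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        return np.log2(probs)


def _window_scores(codes: np.ndarray, logp: np.ndarray, bg: MarkovBackground) -> np.ndarray:
    """Log-ratio score of every window start (NaN where the window has an
    ambiguous base)."""
    width = logp.shape[0]
    n = codes.size - width + 1
    scores = np.full(max(n, 0), np.nan)
    for i in range(max(n, 0)):
        win = codes[i : i + width]
        if np.any(win < 0):
            continue
        pwm_ll = float(logp[np.arange(width), win].sum())
        scores[i] = pwm_ll - bg.log2_likelihood(win)
    return scores


def scan_pwm(
    seq: str, pwm: Pwm, bg: MarkovBackground, threshold: float
) -> list[tuple[int, str, float]]:
    """Scan both strands of ``seq``; return (offset, strand, score) hits with
    log2-ratio score >= threshold.  Offsets are 0-based window starts on the
    forward sequence; windows containing N are skipped."""
    if len(seq) < pwm.width:
        return []
    seq = seq.upper()
    logp = _pwm_log2(pwm)
    fwd = _window_scores(_encode(seq), logp, bg)
    rc = _window_scores(_encode(revcomp(seq)), logp, bg)
    hits = []
    n = len(seq) - pwm.width + 1
    for i in range(n):
        if np.isfinite(fwd[i]) and fwd[i] >= threshold:
            hits.append((i, "+", float(fwd[i])))
        j = n - 1 - i  # window i on the forward strand, read on the reverse
        if np.isfinite(rc[j]) and rc[j] >= threshold:
            hits.append((i, "-", float(rc[j])))
    return hits


def null_score_threshold(
    pwm: Pwm,
    bg: MarkovBackground,
    exceedance: float = 1e-4,
    n_samples: int = 100_000,
    seed: int = 0,
) -> float:
    """Score threshold whose per-window null exceedance probability is
    ``exceedance``, estimated by sampling windows from the background model."""
    if not (0 < exceedance < 1):
        raise ValueError("exceedance must be in (0, 1)")
    rng = np.random.default_rng(seed)
    logp = _pwm_log2(pwm)
    width = pwm.width
    # one long chain sample, scored window by window
    codes = bg.sample(n_samples + width - 1, rng)
    scores = _window_scores(codes, logp, bg)
    scores = scores[np.isfinite(scores)]
    return float(np.quantile(scores, 1.0 - exceedance))


def motif_fraction_curve(
    ranked: list[Peak],
    seqs: list[str],
    pwm: Pwm,
    bg: MarkovBackground,
    threshold: float,
) -> np.ndarray:
    """Fraction of top-N peaks whose summit-centered window contains at least
    one motif hit, for nested prefixes N = 1..len(ranked).

    ``seqs[i]`` is the sequence around ``ranked[i]``'s summit (summit +/-
    flank).  Sequences shorter than the PWM count as motif-negative."""
    if len(ranked) != len(seqs):
        raise ValueError("one sequence per ranked peak required")
    hits = np.zeros(len(ranked), dtype=float)
    for i, seq in enumerate(seqs):
        if len(seq) < pwm.width:
            logger.warning("peak %d: window shorter than PWM; counted motif-negative", i)
            continue
        hits[i] = bool(scan_pwm(seq, pwm, bg, threshold))
    if hits.size == 0:
        return hits
    return np.cumsum(hits) / np.arange(1, hits.size + 1)
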