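"""Tandem repeat detection and control-region domain partitioning.

The detector is a seed-and-extend scanner, not a reimplementation of the
Tandem Repeats Finder alignment model.  For each candidate period ``p`` it
matches the sequence against itself at lag ``p``; a run of ``p`` consecutive
matches (one exact copy pair) seeds a candidate which is extended in both
directions under an X-drop rule on a match/mismatch score (+2/-7, TRF-like
weights).  Candidates must clear a minimum score, identity and copy number;
overlapping candidates are resolved by keeping the highest
``length x identity`` score (ties prefer the shorter period, which
suppresses period multiples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .composition import CompositionProfile, composition_profile
from .errors import ValidationError

_MATCH = 2
_MISMATCH = -7


@dataclass
class TandemRepeat:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    period: int
    copy_number: float  # array length / period; display rounds to 1 dp
    consensus: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def copy_number_display(self) -> float:
        return round(self.copy_number, 1)


def _consensus_and_identity(array: str, period: int) -> tuple[str, float]:
    cols: list[dict] = [dict() for _ in range(period)]
    for i, base in enumerate(array):
        col = cols[i % period]
        col[base] = col.get(base, 0) + 1
    consensus = "".join(max(sorted(col), key=col.get) if col else "N"
                        for col in cols)
    matches = sum(1 for i, base in enumerate(array)
                  if base == consensus[i % period])
    return consensus, matches / len(array)


def _divisors(period: int, floor: int) -> list[int]:
    return [q for q in range(floor, period) if period % q == 0]


def _extend(m: np.ndarray, lo: int, hi: int) -> tuple[int, int]:
    """X-drop extension of the all-match seed [lo, hi) over match array m.

    The drop threshold is deliberately small so edges stay tight (chance
    matches beyond a boundary barely extend an array); runs broken by
    mutation clusters are rejoined afterwards by span bridging.
    """
    xdrop = 10
    # right
    score = best = 0
    j = best_j = hi
    while j < len(m):
        score += _MATCH if m[j] else _MISMATCH
        if score > best:
            best, best_j = score, j + 1
        if score < best - xdrop:
            break
        j += 1
    hi = best_j
    # left
    score = best = 0
    j = lo - 1
    best_j = lo
    while j >= 0:
        score += _MATCH if m[j] else _MISMATCH
        if score > best:
            best, best_j = score, j
        if score < best - xdrop:
            break
        j -= 1
    return best_j, hi


def _kadane(seq: str, wlo: int, whi: int, consensus: str, anchor: int,
            period: int):
    """Best-scoring subarray of [wlo, whi) against a phased consensus."""
    best = best_lo = best_hi = None
    running = 0
    run_lo = wlo
    for i in range(wlo, whi):
        pts = (_MATCH if seq[i] == consensus[(i - anchor) % period]
               else _MISMATCH)
        if running <= 0:
            running = pts
            run_lo = i
        else:
            running += pts
        if best is None or running > best:
            best, best_lo, best_hi = running, run_lo, i + 1
    return best, best_lo, best_hi


def _refine_bounds(seq: str, core_lo: int, core_hi: int,
                   wlo: int, whi: int, period: int):
    """Anchor array boundaries to the consensus via a max-subarray pass.

    The consensus is estimated from the core span only (the margin window
    may be mostly background for short arrays), then each base of the
    padded window scores +2 when it matches the consensus at its phase and
    -7 otherwise; the best-scoring subarray becomes the array.  This trims
    chance periodic continuation at the edges, reclaims terminal copies
    clipped by the seed extension, and keeps mutation clusters flanked by
    strong periodic signal.  A second pass re-estimates the consensus on
    the refined array.
    """
    if core_hi - core_lo < period:
        return None
    consensus, _ = _consensus_and_identity(seq[core_lo:core_hi], period)
    best, lo, hi = _kadane(seq, wlo, whi, consensus, core_lo, period)
    if best is None or best <= 0 or hi - lo < period:
        return None
    consensus, identity = _consensus_and_identity(seq[lo:hi], period)
    score, lo2, hi2 = _kadane(seq, lo, hi, consensus, lo, period)
    if score is None or score <= 0 or hi2 - lo2 < period:
        return None
    if (lo2, hi2) != (lo, hi):
        lo, hi = lo2, hi2
        consensus, identity = _consensus_and_identity(seq[lo:hi], period)
        score = sum(_MATCH if seq[lo + i] == consensus[i % period]
                    else _MISMATCH for i in range(hi - lo))
    return lo, hi, score, consensus, identity


def find_tandem_repeats(sequence: str,
                        min_period: int = 2,
                        max_period: int = 12,
                        min_identity: float = 0.85,
                        min_copies: float = 2.0,
                        min_score: int = 30) -> list[TandemRepeat]:
    """Detect tandem repeat arrays with period in [min_period, max_period].

    ``min_score`` is the significance floor on ``2*matches - 7*mismatches``
    over the self-match profile of the array; it is what keeps short chance
    arrays in random sequence from being reported.  Pass ``min_score=0`` to
    recover every exact micro-array down to ``min_copies``.
    """
    if min_period < 1 or max_period < min_period:
        raise ValidationError("need 1 <= min_period <= max_period")
    if not 0.0 < min_identity <= 1.0:
        raise ValidationError("min_identity must be in (0, 1]")
    if min_copies < 1.0:
        raise ValidationError("min_copies must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_period:
        raise ValidationError("sequence shorter than two minimum periods")

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    candidates: list[TandemRepeat] = []
    for period in range(min_period, min(max_period, n // 2) + 1):
        m = arr[:-period] == arr[period:]
        if len(m) < period:
            continue
        run = np.convolve(m.astype(np.int32), np.ones(period, dtype=np.int32),
                          mode="valid")
        seeds = np.flatnonzero(run == period)
        spans: list[list[int]] = []  # [lo, hi) in self-match space
        consumed_until = -1
        for seed in seeds:
            if seed <= consumed_until:
                continue
            lo, hi = _extend(m, int(seed), int(seed) + period)
            consumed_until = hi
            # bridge fragments split by a mutation cluster; spans live in
            # self-match space, where an array covers its span plus one
            # period, so adjacency allows for that tail
            if spans and lo - spans[-1][1] <= 3 * period + 16:
                spans[-1][1] = max(spans[-1][1], hi)
            else:
                spans.append([lo, hi])
        for lo, hi in spans:
            array = seq[lo:hi + period]
            consensus, identity = _consensus_and_identity(array, period)
            # a lag-2p array over a true p-periodic signal fits marginally
            # better; reduce to the smallest divisor period that explains
            # the array nearly as well
            best_period = period
            for q in _divisors(period, min_period):
                _, id_q = _consensus_and_identity(array, q)
                if id_q >= identity - 0.02:
                    best_period = q
                    break
            # refine over a margin so terminal copies clipped by the
            # extension (edge mutations) can be reclaimed
            margin = 2 * best_period + 8
            refined = _refine_bounds(seq, lo, hi + period,
                                     max(0, lo - margin),
                                     min(n, hi + period + margin), best_period)
            if refined is None:
                continue
            array_lo, array_hi, score, consensus, identity = refined
            array = seq[array_lo:array_hi]
            copies = len(array) / best_period
            if score < min_score or copies < min_copies or identity < min_identity:
                continue
            candidates.append(TandemRepeat(
                start=array_lo + 1, end=array_hi, period=best_period,
                copy_number=copies, consensus=consensus, identity=identity))

    # resolve overlaps: best (length x identity) wins, shorter period on ties
    candidates.sort(key=lambda r: (-r.length * r.identity, r.period, r.start))
    kept: list[TandemRepeat] = []
    for cand in candidates:
        clash = False
        for existing in kept:
            ov = (min(cand.end, existing.end) -
                  max(cand.start, existing.start) + 1)
            if ov > 0.5 * cand.length:
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda r: r.start)
    return kept


@dataclass
class CRDomain:
    label: str
    start: int
    end: int
    profile: CompositionProfile

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CRDomainMap:
    segments: list[CRDomain]


def cr_domains(cr_sequence: str,
               anchors: Optional[list[tuple[str, int, int]]] = None) -> CRDomainMap:
    """Partition a control region into labeled domains.

    ``anchors`` is a sorted list of (label, start, end) in 1-based CR-local
    coordinates (e.g. ETAS1/ETAS2/CSB1-3); when empty, the whole CR becomes
    one segment.  Each segment carries a composition profile.
    """
    if not cr_sequence:
        raise ValidationError("empty control-region sequence")
    n = len(cr_sequence)
    if not anchors:
        return CRDomainMap(segments=[CRDomain(
            "CR", 1, n, composition_profile(cr_sequence, "CR"))])
    prev_end = 0
    segments = []
    for label, start, end in anchors:
        if start <= prev_end:
            raise ValidationError(
                f"anchor {label} at {start}-{end} overlaps the previous segment")
        if start < 1 or end < start or end > n:
            raise ValidationError(f"anchor {label} out of CR bounds 1-{n}")
        segments.append(CRDomain(
            label, start, end,
            composition_profile(cr_sequence[start - 1:end], label)))
        prev_end = end
    return CRDomainMap(segments=segments)
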