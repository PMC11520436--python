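"""Smith-Waterman-Gotoh extension and scoring.

Candidates from seeding are turned into full local alignments with affine
gap penalties (open + per-base extend).  Final scores are quality-aware:
a mismatch against a low-confidence base is forgiven in proportion to the
base's error probability, mirroring the intent of base-quality
recalibration without an empirical covariate table.

The DP kernel is written once in plain Python/numpy and compiled with
numba when available; the algorithm is identical either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

try:  # optional acceleration
    from numba import njit as _njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in normal installs
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not a or not callable(a[0]) else a[0]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap local alignment parameters.

    A gap of length k costs ``gap_open + k * gap_extend``.  The default
    (1, 4, 6, 1) mirrors the de-facto short-read standard.
    """

    match_bonus: int = 1
    mismatch_penalty: int = 4
    gap_open_penalty: int = 6
    gap_extend_penalty: int = 1
    quality_aware: bool = True

    def __post_init__(self) -> None:
        if self.match_bonus <= 0:
            raise ValueError("match bonus must be positive")
        if min(self.mismatch_penalty, self.gap_open_penalty,
               self.gap_extend_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if self.gap_open_penalty < self.gap_extend_penalty:
            raise ValueError("gap open must be >= gap extend")


@dataclass
class AlignmentResult:
    """One candidate's local alignment, read-relative.

    ``ref_start`` is 0-based within the coordinate system of the
    reference window handed to :func:`swg_align`; callers shift it to
    global coordinates.  The CIGAR consumes exactly the read length
    (soft-clips for unaligned ends).
    """

    ref_start: int
    cigar: str
    raw_score: int
    nm: int
    strand: str = "+"
    final_score: float = 0.0
    second_best_score: float = float("-inf")
    # read indices (0-based) of mismatching aligned columns, for quality
    # weighting and NM accounting
    mismatch_read_idx: tuple[int, ...] = ()


_ENC = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_ENC[ord("N")] = 4


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _swg_kernel(ref, read, match, mismatch, gap_open, gap_extend):
    """Gotoh local DP.  Returns (best, i, j, ptrH, ptrE, ptrF).

    ptrH: 0 stop, 1 diagonal, 2 from E (gap in reference row = insertion
    to the read axis), 3 from F (deletion).  ptrE/ptrF: 1 if the gap was
    just opened from H, 0 if extended.
    """
    n = ref.shape[0]
    m = read.shape[0]
    NEG = -10 ** 6
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            if ref[i - 1] == read[j - 1] and ref[i - 1] != 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] - mismatch
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


if _HAVE_NUMBA:
    _swg_kernel = _njit(cache=True)(_swg_kernel)


def _cigar_str(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{length}{op}" for op, length in ops)


def swg_align(ref_window: str, read_bases: str,
              scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimal local affine-gap alignment of ``read_bases`` against
    ``ref_window``; unaligned read ends become soft-clips."""
    scheme = scheme or ScoringScheme()
    if not ref_window or not read_bases:
        raise ValueError("both sequences must be non-empty")
    ref = _encode(ref_window)
    read = _encode(read_bases)
    best, bi, bj, ptrH, ptrE, ptrF = _swg_kernel(
        ref, read, scheme.match_bonus, scheme.mismatch_penalty,
        scheme.gap_open_penalty, scheme.gap_extend_penalty)

    # traceback
    ops: list[tuple[str, int]] = []   # reversed
    mismatches: list[int] = []
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                if ops and ops[-1][0] == "M":
                    ops[-1] = ("M", ops[-1][1] + 1)
                else:
                    ops.append(("M", 1))
                if ref[i - 1] != read[j - 1] or ref[i - 1] == 4:
                    mismatches.append(j - 1)
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":   # gap consuming read (insertion)
            if ops and ops[-1][0] == "I":
                ops[-1] = ("I", ops[-1][1] + 1)
            else:
                ops.append(("I", 1))
            opened = ptrE[i, j]
            j -= 1
            if opened:
                state = "H"
        else:                # F: gap consuming reference (deletion)
            if ops and ops[-1][0] == "D":
                ops[-1] = ("D", ops[-1][1] + 1)
            else:
                ops.append(("D", 1))
            opened = ptrF[i, j]
            i -= 1
            if opened:
                state = "H"

    ops.reverse()
    lead_clip = j
    tail_clip = len(read_bases) - bj
    full_ops: list[tuple[str, int]] = []
    if lead_clip:
        full_ops.append(("S", lead_clip))
    full_ops.extend(ops)
    if tail_clip:
        full_ops.append(("S", tail_clip))

    nm = len(mismatches) + sum(n for op, n in ops if op in "ID")
    return AlignmentResult(
        ref_start=i,
        cigar=_cigar_str(full_ops),
        raw_score=int(best),
        nm=nm,
        mismatch_read_idx=tuple(sorted(mismatches)),
    )


def quality_adjusted_score(result: AlignmentResult,
                           quals: Sequence[int],
                           scheme: Optional[ScoringScheme] = None) -> float:
    """Scale each mismatch penalty by (1 - 10^(-Q/10)) of the base's
    quality: a mismatch at an error-prone base is barely penalized, so
    the adjusted score is >= the raw score and equal when there are no
    mismatches."""
    scheme = scheme or ScoringScheme()
    refund = 0.0
    for j in result.mismatch_read_idx:
        e = 10.0 ** (-quals[j] / 10.0)
        refund += scheme.mismatch_penalty * e
    return result.raw_score + refund


_MAPQ_UNIT = math.log(10.0)


def choose_best(results: Sequence[AlignmentResult]
                ) -> tuple[AlignmentResult, int]:
    """Pick the primary alignment and assign a mapping quality.

    Ties on final score go to the forward strand, then the smallest
    reference start.  MAPQ is 60 for a unique candidate, 0 on an exact
    score tie, otherwise min(60, round(6 * score gap / ln 10)).
    """
    if not results:
        raise ValueError("choose_best needs at least one result")
    order = sorted(results,
                   key=lambda r: (-r.final_score, r.strand != "+", r.ref_start))
    primary = order[0]
    if len(order) == 1:
        return primary, 60
    second = order[1].final_score
    primary.second_best_score = second
    gap = primary.final_score - second
    if gap <= 0:
        return primary, 0
    return primary, min(60, int(round(6.0 * gap / _MAPQ_UNIT)))


def perfect_match_result(m: int, scheme: ScoringScheme,
                         strand: str = "+") -> AlignmentResult:
    """Shortcut for a verified exact full-length match (the common case
    the adaptive search is built around): mM, no mismatches, score m."""
    return AlignmentResult(ref_start=0, cigar=f"{m}M",
                           raw_score=m * scheme.match_bonus, nm=0,
                           strand=strand)
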