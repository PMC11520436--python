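"""Candidate-location search for a read.

Two strategies are provided:

* fixed-stride hash seeding (the BLAST-style baseline): keys are taken
  every ``s`` bases, each key's bucket positions are offset-corrected to
  point at the read's first base, and locations supported by many keys
  win;
* adaptive-stride hybrid search: the index's ``longest_match`` is called
  at offset 0, the offset then advances by half the match length just
  found, and after the scan only matches longer than half the running
  maximum are retained.  This keeps the per-read cost O(m) while
  guaranteeing that at least the latter half of the true longest match —
  length (p+2)/2 — is seen.

A chimeric mode with a fixed small shift exists for split reads, where
the longest exact match is not a reliable guide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .hybrid_index import HashTable, HybridIndex, encode_key

FORWARD = "+"
REVERSE = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedHit:
    """A candidate placement: the read's offset where the match starts,
    the corrected reference start of the *whole* read, and the match
    length p."""

    read_offset: int
    ref_start: int      # corrected: hit position - read_offset
    p: int
    strand: str = FORWARD


@dataclass
class CandidateSet:
    hits: list[SeedHit] = field(default_factory=list)
    p_max: int = 0
    mode: str = "adaptive"
    descents: int = 0    # longest_match calls (cost-contract counter)

    def finalize(self, keep_floor: Optional[float] = None) -> "CandidateSet":
        """Retain hits with p above the floor (default: half of p_max,
        strict) and deduplicate by (strand, ref_start), keeping max p."""
        floor = self.p_max / 2 if keep_floor is None else keep_floor
        best: dict[tuple[str, int], SeedHit] = {}
        for hit in self.hits:
            if hit.p <= floor:
                continue
            key = (hit.strand, hit.ref_start)
            prev = best.get(key)
            if prev is None or hit.p > prev.p:
                best[key] = hit
        self.hits = sorted(best.values(),
                           key=lambda h: (-h.p, h.ref_start, h.strand))
        return self


# ---------------------------------------------------------------------------
# fixed-stride (hash-only) seeding
# ---------------------------------------------------------------------------

def fixed_stride_starts(m: int, l: int, s: int) -> list[int]:
    """Key start offsets {0, s, 2s, ...} <= m-l, with the tail offset m-l
    always included so the read's last l bases are covered."""
    if s < 1:
        raise ValueError("stride must be >= 1")
    if m < l:
        return []
    offsets = list(range(0, m - l + 1, s))
    if offsets[-1] != m - l:
        offsets.append(m - l)
    return offsets


def hash_candidates(table: HashTable, read_bases: str,
                    offsets: Sequence[int],
                    bucket_cap: Optional[int] = 500) -> dict[int, set[int]]:
    """Per-offset corrected location sets: bucket positions minus the
    offset, negatives discarded.  Buckets larger than ``bucket_cap``
    (repeat guard) contribute nothing."""
    result: dict[int, set[int]] = {}
    for offset in offsets:
        key = encode_key(read_bases[offset:offset + table.l])
        if key is None:
            result[offset] = set()
            continue
        positions = table.buckets.get(key, [])
        if bucket_cap is not None and len(positions) > bucket_cap:
            result[offset] = set()
            continue
        result[offset] = {p - offset for p in positions if p - offset >= 0}
    return result


def consensus_locations(per_offset: dict[int, set[int]]
                        ) -> list[tuple[int, int, bool]]:
    """Rank corrected starts by vote count then position.

    Returns (location, votes, perfect) triples; ``perfect`` flags full
    support — every offset that formed a key voted for the location.
    """
    votes: dict[int, int] = {}
    for locations in per_offset.values():
        for loc in locations:
            votes[loc] = votes.get(loc, 0) + 1
    n_offsets = len(per_offset)
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(loc, v, v == n_offsets and n_offsets > 0) for loc, v in ranked]


# ---------------------------------------------------------------------------
# adaptive-stride hybrid search
# ---------------------------------------------------------------------------

def adaptive_seed(index: HybridIndex, read_bases: str,
                  strand: str = FORWARD,
                  shift_divisor: int = 2,
                  retention_divisor: int = 2) -> CandidateSet:
    """Scan the read with ``longest_match``, shifting by p/shift_divisor.

    After the scan, hits with p <= p_max/retention_divisor are dropped.
    Offsets whose key window is absent or contains N advance by one base.
    Corrected starts that fall before the reference origin are discarded.
    """
    m = len(read_bases)
    l = index.l
    cand = CandidateSet(mode="adaptive")
    offset = 0
    while offset <= m - l:
        p, positions = index.longest_match(read_bases, offset)
        cand.descents += 1
        if p >= l:
            cand.p_max = max(cand.p_max, p)
            for pos in positions:
                corrected = pos - offset
                if corrected >= 0:
                    cand.hits.append(SeedHit(offset, corrected, p, strand))
            offset += max(1, p // shift_divisor)
        else:
            offset += 1
    return cand.finalize(keep_floor=cand.p_max / retention_divisor)


def chimeric_seed(index: HybridIndex, read_bases: str, small_shift: int = 1,
                  p_floor: Optional[int] = None,
                  strand: str = FORWARD) -> CandidateSet:
    """Fixed small-shift scan retaining all hits with p >= p_floor
    (default l): finds every short-match location of a split read."""
    if small_shift < 1:
        raise ValueError("small_shift must be >= 1")
    m = len(read_bases)
    l = index.l
    floor = l if p_floor is None else p_floor
    cand = CandidateSet(mode="chimeric")
    offset = 0
    while offset <= m - l:
        p, positions = index.longest_match(read_bases, offset)
        cand.descents += 1
        if p >= l:
            cand.p_max = max(cand.p_max, p)
            for pos in positions:
                corrected = pos - offset
                if corrected >= 0:
                    cand.hits.append(SeedHit(offset, corrected, p, strand))
        offset += small_shift
    return cand.finalize(keep_floor=floor - 1)


def seed_both_strands(index: HybridIndex, read_bases: str,
                      mode: str = "low") -> tuple[CandidateSet, CandidateSet]:
    """Seed the read and its reverse complement.

    ``mode`` maps to search exhaustiveness: "low" shifts by p/2 and keeps
    hits above half the maximum; "high" shifts by p/4 and keeps hits
    above a third of the maximum.
    """
    if mode == "high":
        shift_div, keep_div = 4, 3
    else:
        shift_div, keep_div = 2, 2
    fwd = adaptive_seed(index, read_bases, FORWARD, shift_div, keep_div)
    rev = adaptive_seed(index, reverse_complement(read_bases), REVERSE,
                        shift_div, keep_div)
    return fwd, rev
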