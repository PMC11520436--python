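"""Deterministic synthetic data: references, implanted diploid variants,
and sampled reads with sequencing errors plus a machine-readable truth.

One integer seed drives everything; each stage (reference, variants,
reads) derives its own child stream from it, so enlarging one stage does
not perturb the others.  Qualities follow a uniform-Q model: every base
gets Q = -10 log10(error_rate), capped at 40 for error-free runs.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import Read, ReferenceSequence
from .seeding import reverse_complement

_BASES = np.array(list("ACGT"))


def _stage_seed(seed: int, stage: int) -> int:
    """Stable per-stage child seed (< 2^31)."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0]
               & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def make_reference(length: int, seed: int, name: str = "chr1",
                   repeat_spec: Optional[tuple[int, int]] = None
                   ) -> ReferenceSequence:
    """Pseudo-random ACGT contig; ``repeat_spec = (unit_length, copies)``
    optionally overwrites a stretch with a tandem repeat to exercise the
    high-frequency-key pathology."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = _BASES[rng.integers(0, 4, size=length)]
    if repeat_spec is not None:
        unit_len, copies = repeat_spec
        total = unit_len * copies
        if total > length:
            raise ValueError("repeat tract longer than the reference")
        unit = _BASES[rng.integers(0, 4, size=unit_len)]
        start = int(rng.integers(0, length - total + 1))
        bases[start:start + total] = np.tile(unit, copies)
    return ReferenceSequence(name, "".join(bases))


# ---------------------------------------------------------------------------
# variant implanting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueVariant:
    """Implanted variant in VCF-style anchored representation
    (0-based anchor position)."""

    id: str
    pos: int
    ref: str
    alt: str
    genotype: str    # "het" | "hom"

    @property
    def kind(self) -> str:
        return "snp" if len(self.ref) == len(self.alt) == 1 else "indel"


@dataclass
class Haplotype:
    """One haplotype sequence plus a piecewise-linear map back to
    reference coordinates."""

    bases: str
    hap_anchors: tuple[int, ...]    # breakpoints in haplotype coords
    ref_anchors: tuple[int, ...]    # corresponding reference coords

    def to_ref(self, hap_pos: int) -> int:
        i = bisect_right(self.hap_anchors, hap_pos) - 1
        return self.ref_anchors[i] + (hap_pos - self.hap_anchors[i])


def implant_variants(ref: ReferenceSequence, n_snp: int, n_indel: int,
                     seed: int, min_gap: int = 10,
                     max_indel: int = 5, edge_margin: int = 200
                     ) -> tuple[list[Haplotype], list[TrueVariant]]:
    """Place SNPs and 1..max_indel bp indels at well-separated positions,
    assign het/hom genotypes 50/50, and build the two haplotypes.

    ``edge_margin`` keeps variants away from the contig ends, where
    uniform read sampling cannot reach working coverage (the same reason
    benchmark truth sets exclude reference edges)."""
    rng = np.random.default_rng(seed)
    n_total = n_snp + n_indel
    span = max_indel + min_gap + 2
    margin = min(edge_margin, max(1, ref.n // 10))
    if n_total * span >= ref.n - 2 * margin:
        raise ValueError(f"cannot place {n_total} variants with gap "
                         f"{min_gap} in {ref.n} bases")
    # draw distinct anchor positions with min_gap separation
    positions: list[int] = []
    taken = np.zeros(ref.n, dtype=bool)
    attempts = 0
    while len(positions) < n_total:
        pos = int(rng.integers(margin, ref.n - span - margin))
        attempts += 1
        if attempts > 100 * n_total + 1000:
            raise ValueError("variant density infeasible")
        lo, hi = max(0, pos - span), min(ref.n, pos + span)
        if taken[lo:hi].any():
            continue
        taken[pos] = True
        positions.append(pos)
    positions.sort()
    is_snp = np.zeros(n_total, dtype=bool)
    is_snp[rng.permutation(n_total)[:n_snp]] = True

    variants: list[TrueVariant] = []
    for i, pos in enumerate(positions):
        genotype = "hom" if rng.random() < 0.5 else "het"
        if is_snp[i]:
            ref_base = ref.bases[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            variants.append(TrueVariant(f"v{i}", pos, ref_base, alt, genotype))
        else:
            k = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:   # insertion after pos
                ins = "".join(_BASES[rng.integers(0, 4, size=k)])
                variants.append(TrueVariant(
                    f"v{i}", pos, ref.bases[pos], ref.bases[pos] + ins,
                    genotype))
            else:                    # deletion of k bases after pos
                variants.append(TrueVariant(
                    f"v{i}", pos, ref.bases[pos:pos + k + 1], ref.bases[pos],
                    genotype))

    het_side = {v.id: int(rng.integers(0, 2)) for v in variants}
    haplotypes = []
    for side in (0, 1):
        chosen = [v for v in variants
                  if v.genotype == "hom" or het_side[v.id] == side]
        haplotypes.append(_apply_variants(ref, chosen))
    return haplotypes, variants


def _apply_variants(ref: ReferenceSequence,
                    variants: Sequence[TrueVariant]) -> Haplotype:
    parts: list[str] = []
    hap_anchors = [0]
    ref_anchors = [0]
    cursor = 0
    hap_len = 0
    for v in sorted(variants, key=lambda x: x.pos):
        parts.append(ref.bases[cursor:v.pos])
        hap_len += v.pos - cursor
        parts.append(v.alt)
        hap_len += len(v.alt)
        cursor = v.pos + len(v.ref)
        hap_anchors.append(hap_len)
        ref_anchors.append(cursor)
    parts.append(ref.bases[cursor:])
    return Haplotype("".join(parts), tuple(hap_anchors), tuple(ref_anchors))


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    """Ground truth for simulated reads.

    ``reads`` maps read id -> (contig, true 0-based reference start of
    the read's leftmost aligned base, strand, haplotype index).
    """

    reads: dict[str, tuple[str, int, str, int]] = field(default_factory=dict)
    variants: list[TrueVariant] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "wt") as out:
            out.write("#read_id\tcontig\tstart\tstrand\thaplotype\n")
            for rid, (contig, start, strand, hap) in sorted(self.reads.items()):
                out.write(f"{rid}\t{contig}\t{start}\t{strand}\t{hap}\n")
            out.write("#variant_id\tpos\tref\talt\tgenotype\n")
            for v in self.variants:
                out.write(f"{v.id}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.genotype}\n")


def _error_quality(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return min(40, int(round(-10.0 * math.log10(error_rate))))


def sample_reads(haplotypes: Sequence[Haplotype], contig_name: str,
                 depth: float, read_len: int, error_rate: float,
                 paired: bool, seed: int,
                 insert_mean: int = 350, insert_sd: int = 20,
                 duplicate_copies: int = 0,
                 duplicate_fraction: float = 0.0
                 ) -> tuple[list[Read], ReadTruth]:
    """Sample uniform-coverage reads from the diploid haplotypes.

    Strands are 50/50; paired mode emits inward-facing pairs at the
    stated insert size.  Per-base substitution errors occur at
    ``error_rate`` with every quality set to Q = -10 log10(error_rate).
    ``duplicate_fraction`` optionally re-emits that fraction of
    reads/pairs as ``duplicate_copies`` exact PCR copies.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    genome_len = sum(len(h.bases) for h in haplotypes) // len(haplotypes)
    if read_len > min(len(h.bases) for h in haplotypes):
        raise ValueError("read length exceeds haplotype length")
    n_reads = max(1, int(round(depth * genome_len / read_len)))
    if paired:
        n_fragments = (n_reads + 1) // 2
    else:
        n_fragments = n_reads
    q = _error_quality(error_rate)
    reads: list[Read] = []
    truth = ReadTruth()

    def finish(bases: str) -> tuple[str, tuple[int, ...]]:
        arr = np.array(list(bases))
        if error_rate > 0:
            hit = rng.random(len(arr)) < error_rate
            if hit.any():
                idx = np.nonzero(hit)[0]
                shift = rng.integers(1, 4, size=idx.size)
                codes = np.array([_code_of(b) for b in arr[idx]])
                arr[idx] = _BASES[(codes + shift) % 4]
        return "".join(arr), (q,) * len(arr)

    serial = 0
    for _ in range(n_fragments):
        hap_idx = int(rng.integers(0, len(haplotypes)))
        hap = haplotypes[hap_idx]
        hap_len = len(hap.bases)
        if paired:
            insert = int(round(rng.normal(insert_mean, insert_sd)))
            insert = max(2 * read_len, min(insert, hap_len))
            frag_start = int(rng.integers(0, hap_len - insert + 1))
            flip = bool(rng.random() < 0.5)   # which mate is the forward one
            seq1 = hap.bases[frag_start:frag_start + read_len]
            seq2 = hap.bases[frag_start + insert - read_len:
                             frag_start + insert]
            rid = f"r{serial}"
            serial += 1
            b1, q1 = finish(seq1)
            b2, q2 = finish(reverse_complement(seq2))
            first = Read(rid, b1, q1, "first")
            second = Read(rid, b2, q2, "second")
            if flip:
                # swap roles: first mate on reverse strand
                b1r, q1r = finish(reverse_complement(seq1))
                b2f, q2f = finish(seq2)
                first = Read(rid, b2f, q2f, "first")
                second = Read(rid, b1r, q1r, "second")
                truth.reads[rid + "/1"] = (contig_name,
                                           hap.to_ref(frag_start + insert
                                                      - read_len), "+", hap_idx)
                truth.reads[rid + "/2"] = (contig_name, hap.to_ref(frag_start),
                                           "-", hap_idx)
            else:
                truth.reads[rid + "/1"] = (contig_name, hap.to_ref(frag_start),
                                           "+", hap_idx)
                truth.reads[rid + "/2"] = (contig_name,
                                           hap.to_ref(frag_start + insert
                                                      - read_len), "-", hap_idx)
            reads.extend([first, second])
        else:
            start = int(rng.integers(0, hap_len - read_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = hap.bases[start:start + read_len]
            if strand == "-":
                seq = reverse_complement(seq)
            rid = f"r{serial}"
            serial += 1
            b, qs = finish(seq)
            reads.append(Read(rid, b, qs, "none"))
            truth.reads[rid] = (contig_name, hap.to_ref(start), strand, hap_idx)

    if duplicate_fraction > 0 and duplicate_copies > 0:
        span = 2 if paired else 1
        n_orig = len(reads) // span
        n_dup = int(round(duplicate_fraction * n_orig))
        chosen = rng.choice(n_orig, size=n_dup, replace=False)
        extra: list[Read] = []
        for orig in sorted(int(c) for c in chosen):
            group = reads[orig * span:(orig + 1) * span]
            for copy in range(duplicate_copies):
                for rd in group:
                    extra.append(Read(f"{rd.id}dup{copy}", rd.bases,
                                      rd.quals, rd.mate))
        reads.extend(extra)
    return reads, truth


def _code_of(base: str) -> int:
    return "ACGT".index(base) if base in "ACGT" else 0


def split_chunks(reads: Sequence[Read], q: int,
                 paired: bool) -> list[list[Read]]:
    """Split the read stream into q chunk files' worth, keeping mates of
    a pair in the same chunk."""
    span = 2 if paired else 1
    units = [reads[i:i + span] for i in range(0, len(reads), span)]
    chunks: list[list[Read]] = [[] for _ in range(q)]
    per = math.ceil(len(units) / q) if units else 0
    for i, unit in enumerate(units):
        chunks[min(i // per, q - 1) if per else 0].extend(unit)
    return chunks
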