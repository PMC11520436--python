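"""Pileup SNP/INDEL calling on coordinate-sorted alignments.

Stages, per region: duplicate marking, streaming pileup construction,
and per-column diploid genotyping.

The genotype model is a flat-prior diploid likelihood over {hom-ref,
het, hom-alt} for the strongest non-reference allele.  With per-base
error probability e_i = 10^(-Q_i/10):

    P(obs_i | hom-ref) = 1 - e_i   if obs_i is the reference base,
                         e_i / 3   otherwise,

symmetrically for hom-alt, and the het likelihood is the average of the
two homozygous terms.  A site is emitted when the posterior favours a
non-reference genotype and QUAL = -10 log10 P(hom-ref | data) clears the
threshold.  Indels are genotyped with the same machinery, treating
presence/absence of the indel allele as the two alleles; their printed
representation is left-aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .io_formats import FLAG_DUPLICATE, SamRecord, parse_cigar


@dataclass
class CallerConfig:
    min_depth: int = 4
    min_qual: float = 20.0
    min_mapq: int = 10
    min_baseq: int = 10
    indel_min_count: int = 3
    indel_min_fraction: float = 0.25
    # confidence of a per-read indel presence/absence observation; kept
    # deliberately modest (Q10, e=0.1) because clipping and placement
    # ambiguity make this evidence much noisier than base calls
    indel_obs_qual: int = 10
    qual_cap: float = 5000.0


@dataclass
class PileupColumn:
    """Observations stacked on one reference position.

    ``observations`` holds (base or "*" deletion marker, quality, strand,
    read id); ``insertions`` holds sequences anchored immediately after
    this position, as (inserted bases, read id).
    """

    contig: str
    pos: int
    ref_base: str
    observations: list[tuple[str, int, str, str]] = field(default_factory=list)
    insertions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class VariantCall:
    contig: str
    pos: int            # 0-based anchor
    ref: str
    alt: str
    genotype: str       # "het" | "hom"
    qual: float
    gq: int
    depth: int
    ref_depth: int
    alt_depth: int

    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# duplicate marking
# ---------------------------------------------------------------------------

def _unclipped_start(rec: SamRecord) -> int:
    ops = parse_cigar(rec.cigar) if rec.cigar not in ("*", "") else []
    lead = ops[0][1] if ops and ops[0][0] == "S" else 0
    return rec.pos - lead


def _qual_sum(rec: SamRecord) -> int:
    if rec.qual == "*":
        return 0
    return sum(ord(c) - 33 for c in rec.qual)


def mark_duplicates(records: Sequence[SamRecord]) -> list[SamRecord]:
    """Flag PCR/optical duplicates among coordinate-sorted records.

    Records sharing (contig, unclipped start, strand, mate position if
    paired) form a group; the member with the highest base-quality sum
    (ties: first read name) stays primary, the rest get the duplicate
    flag.  Returns the same records, flags updated in place.
    """
    groups: dict[tuple, list[SamRecord]] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        key = (rec.rname, _unclipped_start(rec), rec.is_reverse,
               rec.rnext, rec.pnext)
        groups.setdefault(key, []).append(rec)
    for members in groups.values():
        if len(members) == 1:
            continue
        keeper = min(members, key=lambda r: (-_qual_sum(r), r.qname))
        for rec in members:
            if rec is not keeper:
                rec.flag |= FLAG_DUPLICATE
    return list(records)


# ---------------------------------------------------------------------------
# pileup construction
# ---------------------------------------------------------------------------

def _record_observations(rec: SamRecord):
    """Walk the CIGAR once; yield ("B", ref pos, base, qual),
    ("D", ref pos) deletion markers, and ("I", anchor pos, seq) insertion
    events.  Soft-clips contribute nothing.  Raises ValueError if the
    CIGAR does not consume the sequence exactly."""
    ops = parse_cigar(rec.cigar)
    consumed = sum(n for op, n in ops if op in "MIS=X")
    if consumed != len(rec.seq):
        raise ValueError(f"{rec.qname}: CIGAR consumes {consumed} of "
                         f"{len(rec.seq)} bases")
    rpos = rec.pos
    qpos = 0
    for op, n in ops:
        if op in "M=X":
            for k in range(n):
                qual = ord(rec.qual[qpos + k]) - 33 if rec.qual != "*" else 30
                yield ("B", rpos + k, rec.seq[qpos + k], qual)
            rpos += n
            qpos += n
        elif op == "I":
            if rpos > rec.pos:  # needs an anchor column to attach to
                yield ("I", rpos - 1, rec.seq[qpos:qpos + n])
            qpos += n
        elif op == "D":
            for k in range(n):
                yield ("D", rpos + k)
            rpos += n
        elif op == "S":
            qpos += n
        else:
            raise ValueError(f"{rec.qname}: unsupported CIGAR op {op!r}")


def build_pileups(records: Sequence[SamRecord], contig_name: str,
                  contig_bases: str,
                  span: Optional[tuple[int, int]] = None,
                  config: Optional[CallerConfig] = None,
                  rejected: Optional[list] = None) -> Iterator[PileupColumn]:
    """Stream pileup columns (ascending position) for one contig.

    Duplicate, unmapped and low-MAPQ records are excluded.  Records whose
    CIGAR disagrees with their sequence length are rejected (collected in
    ``rejected`` if given) rather than aborting the run.  ``span`` limits
    the emitted columns to [start, end).
    """
    config = config or CallerConfig()
    start, end = span if span is not None else (0, len(contig_bases))
    pending: dict[int, PileupColumn] = {}

    def column(pos: int) -> PileupColumn:
        col = pending.get(pos)
        if col is None:
            col = PileupColumn(contig_name, pos, contig_bases[pos])
            pending[pos] = col
        return col

    def flush(upto: int):
        for pos in sorted(p for p in pending if p < upto):
            col = pending.pop(pos)
            if start <= pos < end:
                yield col

    for rec in records:
        if rec.is_unmapped or rec.is_duplicate or rec.mapq < config.min_mapq:
            continue
        if rec.rname != contig_name:
            continue
        try:
            events = list(_record_observations(rec))
        except ValueError:
            if rejected is not None:
                rejected.append(rec.qname)
            continue
        # records are start-sorted: columns left of this start are final
        yield from flush(rec.pos)
        strand = "-" if rec.is_reverse else "+"
        for ev in events:
            if ev[0] == "B":
                _, pos, base, qual = ev
                if pos < end:
                    column(pos).observations.append((base, qual, strand,
                                                     rec.qname))
            elif ev[0] == "D":
                _, pos = ev
                if pos < end:
                    column(pos).observations.append(("*", config.indel_obs_qual,
                                                     strand, rec.qname))
            else:
                _, pos, seq = ev
                if pos < end:
                    column(pos).insertions.append((seq, rec.qname))
    yield from flush(len(contig_bases) + 1)


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

def _diploid_posteriors(n_ref: int, n_alt: int, n_other: int,
                        e_ref: Sequence[float], e_alt: Sequence[float],
                        e_other: Sequence[float]) -> tuple[float, float, float]:
    """Log-likelihoods -> posteriors over (hom-ref, het, hom-alt) with a
    flat prior.  e_* are the error probabilities of the observations
    supporting ref, alt, and any third allele."""
    log_rr = log_aa = log_ra = 0.0
    for e in e_ref:
        p_r, p_a = 1.0 - e, e / 3.0
        log_rr += math.log(p_r)
        log_aa += math.log(p_a)
        log_ra += math.log(0.5 * (p_r + p_a))
    for e in e_alt:
        p_r, p_a = e / 3.0, 1.0 - e
        log_rr += math.log(p_r)
        log_aa += math.log(p_a)
        log_ra += math.log(0.5 * (p_r + p_a))
    for e in e_other:
        p = e / 3.0
        log_rr += math.log(p)
        log_aa += math.log(p)
        log_ra += math.log(p)
    mx = max(log_rr, log_ra, log_aa)
    w = [math.exp(log_rr - mx), math.exp(log_ra - mx), math.exp(log_aa - mx)]
    total = sum(w)
    return w[0] / total, w[1] / total, w[2] / total


def _phred(p: float, cap: float) -> float:
    if p <= 0.0:
        return cap
    return min(cap, -10.0 * math.log10(p))


def call_column(col: PileupColumn,
                config: Optional[CallerConfig] = None) -> Optional[VariantCall]:
    """Genotype the strongest non-reference substitution allele at one
    column; returns None below the depth/quality thresholds."""
    config = config or CallerConfig()
    obs = [(b, q) for b, q, _, _ in col.observations
           if b != "*" and q >= config.min_baseq]
    if len(obs) < config.min_depth:
        return None
    counts: dict[str, int] = {}
    for base, _ in obs:
        if base != col.ref_base:
            counts[base] = counts.get(base, 0) + 1
    if not counts:
        return None
    alt = max(counts, key=lambda b: (counts[b], b))
    e_ref = [10.0 ** (-q / 10.0) for b, q in obs if b == col.ref_base]
    e_alt = [10.0 ** (-q / 10.0) for b, q in obs if b == alt]
    e_other = [10.0 ** (-q / 10.0) for b, q in obs
               if b not in (col.ref_base, alt)]
    p_rr, p_ra, p_aa = _diploid_posteriors(len(e_ref), len(e_alt),
                                           len(e_other), e_ref, e_alt, e_other)
    best = max((p_rr, "ref"), (p_ra, "het"), (p_aa, "hom"))[1]
    if best == "ref":
        return None
    qual = _phred(p_rr, config.qual_cap)
    if qual < config.min_qual:
        return None
    p_best = {"het": p_ra, "hom": p_aa}[best]
    gq = int(min(99, _phred(1.0 - p_best, 99.0)))
    return VariantCall(contig=col.contig, pos=col.pos, ref=col.ref_base,
                       alt=alt, genotype=best, qual=qual, gq=gq,
                       depth=len(obs), ref_depth=len(e_ref),
                       alt_depth=len(e_alt))


def _genotype_indel(n_with: int, n_without: int,
                    config: CallerConfig) -> Optional[tuple[str, float, int]]:
    e = 10.0 ** (-config.indel_obs_qual / 10.0)
    p_rr, p_ra, p_aa = _diploid_posteriors(
        n_without, n_with, 0, [e] * n_without, [e] * n_with, [])
    best = max((p_rr, "ref"), (p_ra, "het"), (p_aa, "hom"))[1]
    if best == "ref":
        return None
    qual = _phred(p_rr, config.qual_cap)
    if qual < config.min_qual:
        return None
    p_best = {"het": p_ra, "hom": p_aa}[best]
    return best, qual, int(min(99, _phred(1.0 - p_best, 99.0)))


def left_align_indel(contig_bases: str, pos: int, ref: str,
                     alt: str) -> tuple[int, str, str]:
    """Shift an anchored indel left while the base preceding the anchor
    equals the last base of the varying sequence (standard VCF
    normalization)."""
    if len(ref) == len(alt):
        return pos, ref, alt
    if len(ref) > len(alt):        # deletion: ref = anchor + deleted
        moving = ref[1:]
    else:                          # insertion: alt = anchor + inserted
        moving = alt[1:]
    while pos > 0 and moving and moving[-1] == contig_bases[pos]:
        moving = contig_bases[pos] + moving[:-1]
        pos -= 1
        base = contig_bases[pos]
        if len(ref) > len(alt):
            ref = base + moving
            alt = base
        else:
            alt = base + moving
            ref = base
    return pos, ref, alt


def call_insertions(columns: Sequence[PileupColumn], contig_bases: str,
                    contig_name: str,
                    config: Optional[CallerConfig] = None,
                    emit_span: Optional[tuple[int, int]] = None
                    ) -> list[VariantCall]:
    """Genotype insertion alleles.

    Alignment placement of an insertion inside a repeat is ambiguous, so
    each read's observation is left-aligned to its canonical anchored
    representation *before* grouping; support for the same event then
    accumulates regardless of where the aligner put it.
    """
    config = config or CallerConfig()
    cover: dict[int, set[str]] = {}
    canon: dict[tuple[int, str, str], set[str]] = {}
    for col in columns:
        cover[col.pos] = {rid for _, _, _, rid in col.observations}
        for seq, rid in col.insertions:
            key = left_align_indel(contig_bases, col.pos,
                                   contig_bases[col.pos],
                                   contig_bases[col.pos] + seq)
            canon.setdefault(key, set()).add(rid)
    calls: list[VariantCall] = []
    for (pos, ref, alt), readers in sorted(canon.items()):
        if emit_span is not None and not emit_span[0] <= pos < emit_span[1]:
            continue
        covering = cover.get(pos, set())
        depth = len(covering)
        count = len(readers)
        if depth < config.min_depth or count < config.indel_min_count:
            continue
        if count / depth < config.indel_min_fraction:
            continue
        geno = _genotype_indel(count, max(depth - count, 0), config)
        if geno is None:
            continue
        gt, qual, gq = geno
        calls.append(VariantCall(contig_name, pos, ref, alt, gt, qual, gq,
                                 depth, max(depth - count, 0), count))
    return calls


def group_deletions(columns: Sequence[PileupColumn], contig_bases: str,
                    contig_name: str,
                    config: Optional[CallerConfig] = None,
                    emit_span: Optional[tuple[int, int]] = None
                    ) -> list[VariantCall]:
    """Assemble per-read deletion runs from deletion markers and genotype
    each distinct deleted interval, anchored one base left."""
    config = config or CallerConfig()
    # per read, deletion markers are consecutive columns: collect runs
    marks: dict[str, list[int]] = {}
    cover: dict[int, set[str]] = {}
    for col in columns:
        for base, _, _, rid in col.observations:
            cover.setdefault(col.pos, set()).add(rid)
            if base == "*":
                marks.setdefault(rid, []).append(col.pos)
    runs: dict[tuple[int, int], set[str]] = {}
    for rid, positions in marks.items():
        positions.sort()
        run_start = positions[0]
        prev = positions[0]
        for pos in positions[1:] + [None]:
            if pos is not None and pos == prev + 1:
                prev = pos
                continue
            runs.setdefault((run_start, prev + 1), set()).add(rid)
            if pos is not None:
                run_start = prev = pos
    # canonicalize each run before grouping (placement in repeats is
    # alignment-ambiguous, same as insertions)
    canon: dict[tuple[int, str, str], set[str]] = {}
    for (dstart, dend), readers in runs.items():
        if dstart == 0:
            continue  # no left anchor base
        key = left_align_indel(contig_bases, dstart - 1,
                               contig_bases[dstart - 1:dend],
                               contig_bases[dstart - 1])
        canon.setdefault(key, set()).update(readers)
    calls: list[VariantCall] = []
    for (pos, ref, alt), readers in sorted(canon.items()):
        if emit_span is not None and not emit_span[0] <= pos < emit_span[1]:
            continue  # owned by the neighbouring region
        covering = cover.get(pos + 1, cover.get(pos, set()))
        depth = len(covering)
        count = len(readers)
        if depth < config.min_depth or count < config.indel_min_count:
            continue
        if count / depth < config.indel_min_fraction:
            continue
        geno = _genotype_indel(count, max(depth - count, 0), config)
        if geno is None:
            continue
        gt, qual, gq = geno
        calls.append(VariantCall(contig_name, pos, ref, alt, gt, qual, gq,
                                 depth, max(depth - count, 0), count))
    return calls


def call_indels(columns: Sequence[PileupColumn], contig_bases: str,
                contig_name: str,
                config: Optional[CallerConfig] = None,
                emit_span: Optional[tuple[int, int]] = None
                ) -> list[VariantCall]:
    """All indel calls (insertions + deletions) from a column stream."""
    calls = call_insertions(columns, contig_bases, contig_name, config,
                            emit_span)
    calls += group_deletions(columns, contig_bases, contig_name, config,
                             emit_span)
    calls.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return calls


def call_region(records: Sequence[SamRecord], contig_name: str,
                contig_bases: str, span: Optional[tuple[int, int]] = None,
                config: Optional[CallerConfig] = None,
                counters: Optional[dict] = None) -> list[VariantCall]:
    """Full per-region calling: duplicates -> pileups -> SNPs + indels.

    A variant is emitted by the region owning its *un-normalized* anchor
    column, so per-region calling is exactly region-count invariant;
    left-alignment afterwards only rewrites the representation.
    """
    config = config or CallerConfig()
    mark_duplicates(records)
    rejected: list = []
    start, end = span if span is not None else (0, len(contig_bases))
    # deletions beginning inside the region may extend past its right
    # edge; pile a margin of extra columns so their runs are complete,
    # but emit only variants anchored inside [start, end)
    margin = 64
    pile_span = (start, min(end + margin, len(contig_bases)))
    columns = list(build_pileups(records, contig_name, contig_bases,
                                 span=pile_span, config=config,
                                 rejected=rejected))
    calls: list[VariantCall] = []
    for col in columns:
        if not start <= col.pos < end:
            continue
        snp = call_column(col, config)
        if snp is not None:
            calls.append(snp)
    calls.extend(call_insertions(columns, contig_bases, contig_name, config,
                                 emit_span=(start, end)))
    calls.extend(group_deletions(columns, contig_bases, contig_name, config,
                                 emit_span=(start, end)))
    if counters is not None:
        counters["columns"] = counters.get("columns", 0) + len(columns)
        counters["calls"] = counters.get("calls", 0) + len(calls)
        counters["rejected"] = counters.get("rejected", 0) + len(rejected)
    calls.sort(key=lambda c: (c.contig, c.pos, c.ref, c.alt))
    return calls
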