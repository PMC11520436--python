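"""End-to-end orchestration: index -> per-chunk matching -> region
scatter -> per-region variant calling.

Parallelism follows the file/region plan: input chunks are independent
work units for matching (no shared mutable state beyond the read-only
index) and regions are independent units for calling, so the output is
byte-identical for any thread count.
"""

from __future__ import annotations

import logging
import os
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

from . import io_formats
from .extension import (AlignmentResult, ScoringScheme, choose_best,
                        perfect_match_result, quality_adjusted_score,
                        swg_align)
from .hybrid_index import HybridIndex
from .io_formats import (FLAG_FIRST, FLAG_MATE_REVERSE, FLAG_MATE_UNMAPPED,
                         FLAG_PAIRED, FLAG_PROPER, FLAG_REVERSE, FLAG_SECOND,
                         FLAG_UNMAPPED, Read, ReferenceSequence, SamRecord)
from .region_sort import (RegionPartition, fragment_path, gather_region,
                          make_partition, scatter, sort_key)
from .seeding import reverse_complement, seed_both_strands
from .variant_caller import CallerConfig, VariantCall, call_region

logger = logging.getLogger("hhtalign")


@dataclass
class PipelineConfig:
    """All knobs in one place; serialized into output headers."""

    l: int = 11                 # hash key length (15 at production scale)
    collapse: int = 2           # bases per collapsed tree level
    stride: int = 5             # fixed-stride mode only
    mode: str = "low"           # search exhaustiveness: low | high
    threads: int = 1
    regions: int = 16
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    caller: CallerConfig = field(default_factory=CallerConfig)
    window_margin: int = 32     # reference padding around a candidate
    min_raw_score: int = 20     # below this the read is reported unmapped
    boundary_overlap: int = 512  # left-fetch for region pileups
    seed: int = 0

    @property
    def max_candidates(self) -> int:
        return 20 if self.mode == "high" else 5

    def provenance(self) -> str:
        return (f"l={self.l};collapse={self.collapse};mode={self.mode};"
                f"regions={self.regions};stride={self.stride};"
                f"match={self.scheme.match_bonus};"
                f"mismatch={self.scheme.mismatch_penalty};"
                f"gap_open={self.scheme.gap_open_penalty};"
                f"gap_extend={self.scheme.gap_extend_penalty};"
                f"min_depth={self.caller.min_depth};"
                f"min_qual={self.caller.min_qual};seed={self.seed}")


# ---------------------------------------------------------------------------
# single-read mapping
# ---------------------------------------------------------------------------

def _unmapped_record(read: Read, flag_extra: int = 0) -> SamRecord:
    qual = "".join(chr(q + 33) for q in read.quals)
    return SamRecord(qname=read.id, flag=FLAG_UNMAPPED | flag_extra,
                     rname="*", pos=-1, mapq=0, cigar="*",
                     seq=read.bases, qual=qual)


def map_read(index: HybridIndex, read: Read,
             config: PipelineConfig) -> SamRecord:
    """Seed both strands, extend the best candidates, pick a primary."""
    fwd, rev = seed_both_strands(index, read.bases, config.mode)
    hits = sorted(fwd.hits + rev.hits,
                  key=lambda h: (-h.p, h.ref_start, h.strand))
    hits = hits[:config.max_candidates]
    if not hits:
        return _unmapped_record(read)

    m = read.m
    contigs = index.contigs
    oriented = {
        "+": (read.bases, read.quals),
        "-": (reverse_complement(read.bases), read.quals[::-1]),
    }
    results: list[AlignmentResult] = []
    for hit in hits:
        seq, quals = oriented[hit.strand]
        hit_abs = hit.ref_start + hit.read_offset
        contig_end = contigs.contig_end(hit_abs)
        contig_start = contig_end - contigs.lengths[
            contigs.names.index(contigs.to_local(hit_abs)[0])]
        c = hit.ref_start
        if (hit.p == m and c >= contig_start and c + m <= contig_end
                and index.bases[c:c + m] == seq):
            result = perfect_match_result(m, config.scheme, hit.strand)
            result.ref_start = c
        else:
            wstart = max(contig_start, c - config.window_margin)
            wend = min(contig_end, c + m + config.window_margin)
            if wend - wstart < 1:
                continue
            result = swg_align(index.bases[wstart:wend], seq, config.scheme)
            result.strand = hit.strand
            result.ref_start += wstart
        if config.scheme.quality_aware:
            result.final_score = quality_adjusted_score(result, quals,
                                                        config.scheme)
        else:
            result.final_score = float(result.raw_score)
        results.append(result)

    results = [r for r in results if r.raw_score >= config.min_raw_score]
    if not results:
        return _unmapped_record(read)
    # two seeds of one placement (e.g. the segments flanking an indel)
    # converge to the same alignment; collapse them so they do not read
    # as an ambiguous mapping
    unique: dict[tuple[str, int], AlignmentResult] = {}
    for result in results:
        key = (result.strand, result.ref_start)
        prev = unique.get(key)
        if prev is None or result.final_score > prev.final_score:
            unique[key] = result
    primary, mapq = choose_best(list(unique.values()))
    seq, quals = oriented[primary.strand]
    rname, local_pos = contigs.to_local(primary.ref_start)
    # position points at the first aligned (non-clipped) base
    flag = FLAG_REVERSE if primary.strand == "-" else 0
    tags = {"AS": int(primary.final_score), "NM": primary.nm}
    if primary.second_best_score != float("-inf"):
        tags["XS"] = int(primary.second_best_score)
    return SamRecord(
        qname=read.id, flag=flag, rname=rname, pos=local_pos, mapq=mapq,
        cigar=primary.cigar, seq=seq,
        qual="".join(chr(q + 33) for q in quals), tags=tags)


def _pair_flags(rec1: SamRecord, rec2: SamRecord,
                max_insert: int = 2000) -> None:
    """Fill mate fields and pairing flags for two mates of a pair."""
    for rec, mate, first in ((rec1, rec2, True), (rec2, rec1, False)):
        rec.flag |= FLAG_PAIRED | (FLAG_FIRST if first else FLAG_SECOND)
        if mate.is_unmapped:
            rec.flag |= FLAG_MATE_UNMAPPED
            rec.rnext, rec.pnext, rec.tlen = "*", -1, 0
            continue
        if mate.is_reverse:
            rec.flag |= FLAG_MATE_REVERSE
        rec.rnext = "=" if mate.rname == rec.rname else mate.rname
        rec.pnext = mate.pos
    if (not rec1.is_unmapped and not rec2.is_unmapped
            and rec1.rname == rec2.rname
            and rec1.is_reverse != rec2.is_reverse):
        left, right = sorted((rec1, rec2), key=lambda r: r.pos)
        span = (right.pos + io_formats.cigar_read_length(right.cigar)
                - left.pos)
        if 0 < span <= max_insert and not left.is_reverse:
            rec1.flag |= FLAG_PROPER
            rec2.flag |= FLAG_PROPER
            left.tlen = span
            right.tlen = -span


# ---------------------------------------------------------------------------
# chunk matching
# ---------------------------------------------------------------------------

def match_chunk(index: HybridIndex, chunk_id: int, fastq1, fastq2,
                partition: RegionPartition, out_dir,
                config: PipelineConfig) -> dict:
    """Map one chunk's reads and scatter the records by region."""
    records: list[SamRecord] = []
    counters = {"reads": 0, "mapped": 0}
    for unit in io_formats.read_fastq_pair(fastq1, fastq2):
        recs = [map_read(index, read, config) for read in unit]
        counters["reads"] += len(unit)
        counters["mapped"] += sum(not r.is_unmapped for r in recs)
        if len(recs) == 2:
            _pair_flags(recs[0], recs[1])
        records.extend(recs)
    scatter(records, partition, index.contigs, chunk_id, out_dir)
    return counters


def run_match(index: HybridIndex, chunk_files: list[tuple], out_dir,
              config: PipelineConfig) -> dict:
    """Process all chunks, optionally with a thread pool.

    ``chunk_files`` is a list of (fastq1, fastq2-or-None).  Results are
    independent of the thread count: chunks share only the read-only
    index and write disjoint files.
    """
    os.makedirs(out_dir, exist_ok=True)

    def work(item):
        i, (f1, f2) = item
        try:
            return match_chunk(index, i, f1, f2, partition=partition,
                               out_dir=out_dir, config=config)
        except Exception as exc:
            # a bad chunk aborts only itself; the others proceed
            logger.error("chunk %d (%s) failed: %s", i, f1, exc)
            return {"reads": 0, "mapped": 0, "failed": i}

    partition = make_partition(index.contigs.total_length, config.regions)
    items = list(enumerate(chunk_files))
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            all_counters = list(pool.map(work, items))
    else:
        all_counters = [work(item) for item in items]
    total = {"reads": 0, "mapped": 0, "failed_chunks": []}
    for c in all_counters:
        total["reads"] += c["reads"]
        total["mapped"] += c["mapped"]
        if "failed" in c:
            total["failed_chunks"].append(c["failed"])
    logger.info("matched %d/%d reads over %d chunks",
                total["mapped"], total["reads"], len(items))
    return total


# ---------------------------------------------------------------------------
# region variant calling
# ---------------------------------------------------------------------------

def _region_records(j: int, q: int, frag_dir, index: HybridIndex,
                    partition: RegionPartition,
                    overlap: int) -> list[SamRecord]:
    """Region j's records plus left-overlap records from earlier regions
    (reads starting before the boundary that still cover it)."""
    records = gather_region(j, q, frag_dir, index.contigs)
    start = partition.boundaries[j]
    fetch_from = start - overlap
    k = j - 1
    while k >= 0 and partition.boundaries[k + 1] > fetch_from:
        for rec in gather_region(k, q, frag_dir, index.contigs):
            gpos = index.contigs.to_global(rec.rname, rec.pos)
            if gpos >= fetch_from:
                records.append(rec)
        k -= 1
    # the overlap fetch appended out-of-order records; the caller needs
    # a single coordinate-sorted stream
    records.sort(key=lambda rec: sort_key(rec, index.contigs))
    return records


def call_regions(frag_dir, q: int, index: HybridIndex,
                 contigs: list[ReferenceSequence],
                 config: PipelineConfig) -> list[VariantCall]:
    """Run the caller region by region; the result equals a single
    whole-genome pass by the anchored-ownership rule."""
    partition = make_partition(index.contigs.total_length, config.regions)
    by_name = {c.name: c for c in contigs}

    def work(j: int) -> list[VariantCall]:
        records = _region_records(j, q, frag_dir, index, partition,
                                  config.boundary_overlap)
        a, b = partition.bounds(j)
        calls: list[VariantCall] = []
        for ci, name in enumerate(index.contigs.names):
            c_start = index.contigs.offsets[ci]
            c_end = c_start + index.contigs.lengths[ci]
            lo, hi = max(a, c_start), min(b, c_end)
            if lo >= hi:
                continue
            contig_records = [r for r in records if r.rname == name]
            calls.extend(call_region(contig_records, name,
                                     by_name[name].bases,
                                     span=(lo - c_start, hi - c_start),
                                     config=config.caller))
        return calls

    region_ids = list(range(partition.r))
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            per_region = list(pool.map(work, region_ids))
    else:
        per_region = [work(j) for j in region_ids]
    calls = [c for region in per_region for c in region]
    order = {name: i for i, name in enumerate(index.contigs.names)}
    calls.sort(key=lambda c: (order[c.contig], c.pos, c.ref, c.alt))
    return calls


# ---------------------------------------------------------------------------
# whole pipeline
# ---------------------------------------------------------------------------

def run_pipeline(ref_path, chunk_files: list[tuple], work_dir,
                 config: PipelineConfig,
                 vcf_path=None, sam_path=None) -> dict:
    """FASTQ -> SAM fragments -> VCF in one call; returns counters."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    contigs = io_formats.read_fasta(ref_path)
    index = HybridIndex.build(contigs, config.l)
    timings["index_s"] = time.perf_counter() - t0
    frag_dir = os.path.join(work_dir, "fragments")
    t0 = time.perf_counter()
    counters = run_match(index, chunk_files, frag_dir, config)
    timings["match_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    calls = call_regions(frag_dir, len(chunk_files), index, contigs, config)
    timings["vcall_s"] = time.perf_counter() - t0
    counters["calls"] = len(calls)
    counters["timings"] = timings
    for stage, secs in timings.items():
        logger.info("%s: %.2f s", stage, secs)
    if vcf_path is not None:
        io_formats.write_vcf(calls, contigs, vcf_path,
                             extra_meta=[f"##hhtalign_config={config.provenance()}"])
    if sam_path is not None:
        partition = make_partition(index.contigs.total_length, config.regions)
        records = []
        for j in range(partition.r):
            records.extend(gather_region(j, len(chunk_files), frag_dir,
                                         index.contigs))
        io_formats.write_sam(records, contigs, sam_path,
                             program_info={"ID": "hhtalign", "PN": "hhtalign",
                                           "CL": config.provenance()})
    counters["variant_calls"] = calls
    return counters
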