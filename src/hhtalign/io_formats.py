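"""File formats: FASTA, FASTQ (paired, gzip-aware), text SAM and VCF.

This is the only module that touches files.  All coordinates are 0-based
half-open in memory; the 1-based shift happens here, at serialization,
and nowhere else.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

VALID_BASES = frozenset("ACGTN")
PHRED_OFFSET = 33


class FormatError(ValueError):
    """Malformed input file; message carries the path and line number."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSequence:
    """One contig: a name and an uppercase sequence over {A,C,G,T,N}."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ValueError(f"contig {self.name!r}: invalid bases {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Read:
    """A sequencing read with Phred base qualities.

    ``mate`` is "none" for single-end data, "first"/"second" for the two
    ends of a pair.
    """

    id: str
    bases: str
    quals: tuple[int, ...]
    mate: str = "none"

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(f"read {self.id!r}: {len(self.quals)} qualities "
                             f"for {len(self.bases)} bases")
        if len(self.bases) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")

    @property
    def m(self) -> int:
        return len(self.bases)


# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_DUPLICATE = 0x400


@dataclass
class SamRecord:
    """One alignment line.  ``pos`` is the internal 0-based position;
    the POS column is written 1-based."""

    qname: str
    flag: int
    rname: str
    pos: int            # 0-based; -1 for unmapped
    mapq: int
    cigar: str
    rnext: str = "*"
    pnext: int = -1     # 0-based; -1 for unset
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: dict = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    def to_line(self) -> str:
        tags = []
        for key, val in self.tags.items():
            if isinstance(val, int):
                tags.append(f"{key}:i:{val}")
            elif isinstance(val, float):
                tags.append(f"{key}:f:{val}")
            else:
                tags.append(f"{key}:Z:{val}")
        fields = [
            self.qname, str(self.flag),
            self.rname if not self.is_unmapped or self.rname != "*" else "*",
            str(self.pos + 1 if self.pos >= 0 else 0),
            str(self.mapq), self.cigar or "*",
            self.rnext, str(self.pnext + 1 if self.pnext >= 0 else 0),
            str(self.tlen), self.seq, self.qual,
        ]
        return "\t".join(fields + tags)

    @classmethod
    def from_line(cls, line: str) -> "SamRecord":
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 11:
            raise FormatError(f"SAM line has {len(parts)} fields, expected >= 11")
        tags: dict = {}
        for raw in parts[11:]:
            key, typ, val = raw.split(":", 2)
            if typ == "i":
                tags[key] = int(val)
            elif typ == "f":
                tags[key] = float(val)
            else:
                tags[key] = val
        return cls(
            qname=parts[0], flag=int(parts[1]), rname=parts[2],
            pos=int(parts[3]) - 1, mapq=int(parts[4]), cigar=parts[5],
            rnext=parts[6], pnext=int(parts[7]) - 1, tlen=int(parts[8]),
            seq=parts[9], qual=parts[10], tags=tags,
        )


def cigar_read_length(cigar: str) -> int:
    """Sum of read-consuming operation lengths (M, I, S, =, X)."""
    if cigar in ("*", ""):
        return 0
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                total += int(num)
            num = ""
    return total


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _open_text(path) -> io.TextIOBase:
    path = os.fspath(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path) -> list[ReferenceSequence]:
    """Parse a (multi-)FASTA file into ReferenceSequence records.

    Lowercase bases are folded to uppercase.  Raises FormatError, naming
    the offending line, on a missing header or an empty file.
    """
    contigs: list[ReferenceSequence] = []
    name: Optional[str] = None
    chunks: list[str] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    contigs.append(ReferenceSequence(name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence before any header at line {lineno}")
                seq = line.upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}: invalid characters {sorted(bad)} at line {lineno}")
                chunks.append(seq)
    if name is None:
        raise FormatError(f"{path}: empty FASTA file (no header at line 1)")
    contigs.append(ReferenceSequence(name, "".join(chunks)))
    return contigs


def write_fasta(contigs: Sequence[ReferenceSequence], path, width: int = 70) -> None:
    with open(path, "wt") as out:
        for contig in contigs:
            out.write(f">{contig.name}\n")
            for i in range(0, contig.n, width):
                out.write(contig.bases[i:i + width] + "\n")


#: quality imputed for FASTA read input, which has no quality line
FASTA_READ_QUALITY = 30


def _read_fasta_reads(path, mate: str) -> Iterator[Read]:
    for contig in read_fasta(path):
        yield Read(id=contig.name, bases=contig.bases,
                   quals=(FASTA_READ_QUALITY,) * contig.n, mate=mate)


def _read_fastq_single(path, mate: str) -> Iterator[Read]:
    with _open_text(path) as probe:
        first = probe.read(1)
    if first == ">":   # FASTA fallback: qualities imputed as a fixed Q
        yield from _read_fasta_reads(path, mate)
        return
    with _open_text(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}: expected '@' header at line {lineno}")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}: truncated record at line {lineno}")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError(f"{path}: expected '+' separator at line {lineno - 1}")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: sequence/quality length mismatch at line {lineno}")
            rid = header[1:].split()[0]
            # strip a trailing /1 or /2 mate suffix so pairs share a name
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            quals = tuple(ord(ch) - PHRED_OFFSET for ch in qual)
            if any(q < 0 for q in quals):
                raise FormatError(
                    f"{path}: quality below '!' at line {lineno}; only Phred+33 "
                    f"is supported")
            yield Read(id=rid, bases=seq.upper(), quals=quals, mate=mate)


def read_fastq_pair(path1, path2=None) -> Iterator[tuple[Read, ...]]:
    """Stream reads from one FASTQ file, or synchronized pairs from two.

    gzip-compressed files are decompressed transparently.  In paired mode
    a record-count mismatch raises FormatError once the shorter file ends.
    """
    if path2 is None:
        for read in _read_fastq_single(path1, "none"):
            yield (read,)
        return
    it1 = _read_fastq_single(path1, "first")
    it2 = _read_fastq_single(path2, "second")
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = path1 if r1 is None else path2
            raise FormatError(f"paired FASTQ record-count mismatch: "
                              f"{short} ended first")
        yield (r1, r2)


def write_fastq(reads: Sequence[Read], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            suffix = {"first": "/1", "second": "/2"}.get(read.mate, "")
            out.write(f"@{read.id}{suffix}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def sam_header_lines(contigs: Sequence[ReferenceSequence],
                     program_info: Optional[dict] = None) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for contig in contigs:
        lines.append(f"@SQ\tSN:{contig.name}\tLN:{contig.n}")
    if program_info:
        fields = "\t".join(f"{k}:{v}" for k, v in program_info.items())
        lines.append(f"@PG\t{fields}")
    return lines


def write_sam(records: Sequence[SamRecord],
              contigs: Sequence[ReferenceSequence], path,
              program_info: Optional[dict] = None) -> None:
    names = {c.name for c in contigs}
    with open(path, "wt") as out:
        for line in sam_header_lines(contigs, program_info):
            out.write(line + "\n")
        for rec in records:
            if not rec.is_unmapped and rec.rname not in names:
                raise ValueError(f"record {rec.qname!r} references unknown "
                                 f"contig {rec.rname!r}")
            out.write(rec.to_line() + "\n")


def read_sam(path) -> tuple[list[str], list[SamRecord]]:
    """Return (header lines, records) from a text SAM file."""
    header: list[str] = []
    records: list[SamRecord] = []
    with _open_text(path) as handle:
        for line in handle:
            if line.startswith("@"):
                header.append(line.rstrip("\n"))
            elif line.strip():
                records.append(SamRecord.from_line(line))
    return header, records


def write_sam_fragment(records: Sequence[SamRecord], path) -> None:
    """Headerless SAM fragment (region-scatter files)."""
    with open(path, "wt") as out:
        for rec in records:
            out.write(rec.to_line() + "\n")


def read_sam_fragment(path) -> list[SamRecord]:
    with _open_text(path) as handle:
        return [SamRecord.from_line(line) for line in handle if line.strip()]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(calls, contigs: Sequence[ReferenceSequence], path,
              extra_meta: Optional[Sequence[str]] = None,
              sample_name: str = "SAMPLE") -> None:
    """Write diploid calls as VCF 4.2 with GT, GQ, DP, AD fields.

    ``calls`` is a sequence of variant_caller.VariantCall; positions are
    internal 0-based and serialized 1-based.
    """
    names = {c.name for c in contigs}
    with open(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=hhtalign\n")
        for line in extra_meta or ():
            out.write(line.rstrip("\n") + "\n")
        for contig in contigs:
            out.write(f"##contig=<ID={contig.name},length={contig.n}>\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  f"{sample_name}\n")
        for call in calls:
            if call.contig not in names:
                raise ValueError(f"call references unknown contig {call.contig!r}")
            gt = "0/1" if call.genotype == "het" else "1/1"
            out.write("\t".join([
                call.contig, str(call.pos + 1), ".", call.ref, call.alt,
                f"{call.qual:.0f}", "PASS", f"DP={call.depth}",
                "GT:GQ:DP:AD",
                f"{gt}:{call.gq}:{call.depth}:{call.ref_depth},{call.alt_depth}",
            ]) + "\n")
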