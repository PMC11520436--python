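"""Off-core bucket sort of alignment records by genomic region.

The reference is split into ``r`` regions of (near-)equal size over the
concatenated-genome coordinate line.  Each input chunk ``i`` scatters its
records into per-region SAM fragments ``chunk{i}.region{j}.sam``; a
region's records are then gathered by concatenating the fragments from
every chunk and sorting them in memory.  The end result is provably the
same as a single global coordinate sort, but each piece fits in memory
and chunks can be produced independently.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

from .hybrid_index import ContigTable
from .io_formats import SamRecord, read_sam_fragment, write_sam_fragment


@dataclass(frozen=True)
class RegionPartition:
    """r regions over [0, total_length) in concatenated coordinates."""

    boundaries: tuple[int, ...]

    @property
    def r(self) -> int:
        return len(self.boundaries) - 1

    def region_of(self, gpos: int) -> int:
        return bisect_right(self.boundaries, gpos) - 1

    def bounds(self, j: int) -> tuple[int, int]:
        return self.boundaries[j], self.boundaries[j + 1]


def make_partition(total_length: int, r: int) -> RegionPartition:
    """Equal regions up to integer division; errors if r exceeds the
    genome length (regions must be non-empty)."""
    if r < 1:
        raise ValueError("need at least one region")
    if r > total_length:
        raise ValueError(f"cannot split {total_length} bases into {r} "
                         f"non-empty regions")
    boundaries = tuple(i * total_length // r for i in range(r + 1))
    return RegionPartition(boundaries)


def fragment_path(out_dir, chunk: int, region: int) -> str:
    return os.path.join(out_dir, f"chunk{chunk}.region{region}.sam")


def sink_path(out_dir, chunk: int) -> str:
    return os.path.join(out_dir, f"chunk{chunk}.unmapped.sam")


def scatter(records: Sequence[SamRecord], partition: RegionPartition,
            contigs: ContigTable, chunk: int, out_dir) -> None:
    """Write each mapped record to the fragment of the region containing
    its start coordinate (records spanning a boundary are assigned by
    start only); unmapped records go to a dedicated sink file.  All r
    fragment files are created, empty ones included."""
    byregion: list[list[SamRecord]] = [[] for _ in range(partition.r)]
    unmapped: list[SamRecord] = []
    for rec in records:
        if rec.is_unmapped:
            unmapped.append(rec)
        else:
            gpos = contigs.to_global(rec.rname, rec.pos)
            byregion[partition.region_of(gpos)].append(rec)
    os.makedirs(out_dir, exist_ok=True)
    for j in range(partition.r):
        write_sam_fragment(byregion[j], fragment_path(out_dir, chunk, j))
    write_sam_fragment(unmapped, sink_path(out_dir, chunk))


def sort_key(rec: SamRecord, contigs: ContigTable):
    return (contigs.names.index(rec.rname), rec.pos,
            1 if rec.is_reverse else 0, rec.qname)


def gather_region(j: int, q: int, out_dir,
                  contigs: ContigTable) -> list[SamRecord]:
    """Concatenate fragments chunk0..chunk{q-1} for region j and sort by
    (contig, position, strand, read name), stably.  A missing fragment
    is an error naming the (chunk, region) pair."""
    records: list[SamRecord] = []
    for i in range(q):
        path = fragment_path(out_dir, i, j)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"missing scatter fragment for chunk {i}, region {j}: {path}")
        records.extend(read_sam_fragment(path))
    records.sort(key=lambda rec: sort_key(rec, contigs))
    return records


def global_sort(records: Sequence[SamRecord],
                contigs: ContigTable) -> list[SamRecord]:
    """Single in-memory coordinate sort — the oracle the scatter/gather
    route must reproduce exactly."""
    return sorted((r for r in records if not r.is_unmapped),
                  key=lambda rec: sort_key(rec, contigs))
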