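"""Hybrid hash-tree index over a reference genome.

The index couples a length-``l`` k-mer hash table with per-bucket suffix
subtrees.  A hash lookup replaces the first ``l`` levels of a suffix tree,
so a query pays one table access instead of ``l`` node traversals; below
the bucket, collapsed nodes consume two bases per level (at most 16
children plus an end-of-sequence sentinel), halving the remaining descent.

The module also provides the two classical structures the hybrid is built
from — the suffix array and the (uncollapsed, one-base-per-level) suffix
tree — mainly so the hybrid can be property-checked against them.

Coordinates are 0-based throughout.  Multi-contig references are handled
by scanning each contig with a global offset; a k-mer window never spans
a contig boundary, and matches never extend past a contig end.
"""

from __future__ import annotations

import pickle
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_formats import ReferenceSequence

INDEX_FORMAT_VERSION = 1

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

#: sentinel child key marking end-of-sequence ("X" leaf in a suffix tree)
SENTINEL = "$"

#: refuse hash key lengths whose dense table could not fit in memory anyway
MAX_KEY_LENGTH = 28


class CapacityError(ValueError):
    """Key length too large for the configured memory budget."""


def encode_key(seq: str) -> Optional[int]:
    """Encode a DNA string as a base-4 integer (A,C,G,T -> 0,1,2,3).

    The leftmost base is most significant, so the encoding is bijective
    over {A,C,G,T}^l.  Returns None ("no key") if the window contains N
    or any other non-ACGT character.
    """
    value = 0
    for base in seq:
        code = _BASE_CODE.get(base)
        if code is None:
            return None
        value = (value << 2) | code
    return value


def decode_key(key: int, l: int) -> str:
    out = []
    for shift in range(2 * (l - 1), -1, -2):
        out.append(_CODE_BASE[(key >> shift) & 3])
    return "".join(out)


# ---------------------------------------------------------------------------
# contig table: global <-> (contig, local) coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigTable:
    names: tuple[str, ...]
    lengths: tuple[int, ...]
    offsets: tuple[int, ...]   # cumulative start offset of each contig

    @classmethod
    def from_contigs(cls, contigs: Sequence[ReferenceSequence]) -> "ContigTable":
        names, lengths, offsets = [], [], []
        total = 0
        for contig in contigs:
            names.append(contig.name)
            lengths.append(contig.n)
            offsets.append(total)
            total += contig.n
        return cls(tuple(names), tuple(lengths), tuple(offsets))

    @property
    def total_length(self) -> int:
        return self.offsets[-1] + self.lengths[-1] if self.names else 0

    def to_local(self, gpos: int) -> tuple[str, int]:
        i = bisect_right(self.offsets, gpos) - 1
        return self.names[i], gpos - self.offsets[i]

    def to_global(self, name: str, pos: int) -> int:
        return self.offsets[self.names.index(name)] + pos

    def contig_end(self, gpos: int) -> int:
        """Global end offset of the contig containing ``gpos``."""
        i = bisect_right(self.offsets, gpos) - 1
        return self.offsets[i] + self.lengths[i]


# ---------------------------------------------------------------------------
# plain hash table
# ---------------------------------------------------------------------------

@dataclass
class HashTable:
    """k-mer hash: integer key -> ascending list of 0-based positions."""

    l: int
    buckets: dict[int, list[int]]
    n_windows: int = 0     # windows scanned (N-free)

    def lookup(self, seq_or_key) -> list[int]:
        key = seq_or_key if isinstance(seq_or_key, int) else encode_key(seq_or_key)
        if key is None:
            return []
        return self.buckets.get(key, [])


def _check_capacity(l: int) -> None:
    if l < 1:
        raise ValueError("key length must be >= 1")
    if l > MAX_KEY_LENGTH:
        raise CapacityError(
            f"key length {l} implies a 4^{l} key space beyond the memory "
            f"budget; use a shorter key (sparse mode caps at {MAX_KEY_LENGTH})")


def _scan_keys(bases: str, l: int, offset: int = 0) -> Iterable[tuple[int, int]]:
    """Yield (key, global position) for every N-free length-l window,
    maintaining the key with a rolling update."""
    n = len(bases)
    mask = (1 << (2 * l)) - 1
    key = 0
    valid = 0  # length of current N-free run ending at i
    for i, base in enumerate(bases):
        code = _BASE_CODE.get(base)
        if code is None:
            valid = 0
            key = 0
            continue
        key = ((key << 2) | code) & mask
        valid += 1
        if valid >= l:
            yield key, offset + i - l + 1


def build_hash_table(ref: ReferenceSequence, l: int) -> HashTable:
    """Record, for every length-l key, the reference positions matching it."""
    _check_capacity(l)
    if ref.n < l:
        raise ValueError(f"reference shorter ({ref.n}) than key length ({l})")
    buckets: dict[int, list[int]] = {}
    count = 0
    for key, pos in _scan_keys(ref.bases, l):
        buckets.setdefault(key, []).append(pos)
        count += 1
    return HashTable(l=l, buckets=buckets, n_windows=count)


# ---------------------------------------------------------------------------
# suffix array and uncollapsed suffix tree (reference structures)
# ---------------------------------------------------------------------------

@dataclass
class SuffixArray:
    order: list[int]


def build_suffix_array(ref: ReferenceSequence) -> SuffixArray:
    """Lexicographically sorted suffix start positions, end-of-string
    sentinel smallest (a shorter prefix sorts before its extensions)."""
    bases = ref.bases
    return SuffixArray(order=sorted(range(ref.n), key=lambda i: bases[i:]))


class TrieNode:
    """Uncollapsed suffix-tree node: one base per edge."""

    __slots__ = ("children", "leaf_positions")

    def __init__(self) -> None:
        self.children: dict[str, "TrieNode"] = {}
        self.leaf_positions: list[int] = []


def build_suffix_tree(ref: ReferenceSequence) -> TrieNode:
    """Suffix trie with one base per level; each suffix terminates in a
    sentinel child holding its start position (the paper-style "X" leaf)."""
    root = TrieNode()
    bases = ref.bases
    for start in range(ref.n):
        node = root
        for i in range(start, ref.n):
            node = node.children.setdefault(bases[i], TrieNode())
        leaf = node.children.setdefault(SENTINEL, TrieNode())
        leaf.leaf_positions.append(start)
    return root


def trie_positions(root: TrieNode, pattern: str) -> set[int]:
    """All positions whose suffix starts with ``pattern``."""
    node = root
    for base in pattern:
        child = node.children.get(base)
        if child is None:
            return set()
        node = child
    return set(_collect_trie(node))


def _collect_trie(node: TrieNode) -> Iterable[int]:
    stack = [node]
    while stack:
        cur = stack.pop()
        yield from cur.leaf_positions
        stack.extend(cur.children.values())


class CollapsedNode:
    """Suffix-tree node consuming two bases per level (<=16 children plus
    a sentinel).  Terminal odd remainders use a one-base edge."""

    __slots__ = ("children", "leaf_positions")

    def __init__(self) -> None:
        self.children: dict[str, "CollapsedNode"] = {}
        self.leaf_positions: list[int] = []


def collapse_tree(root: TrieNode) -> CollapsedNode:
    """Fold pairs of one-base levels into single two-base levels.

    Query results are identical to the uncollapsed tree; odd-length
    suffix paths end in a one-base edge followed by the sentinel.
    """
    out = CollapsedNode()
    # sentinel directly below: suffix ends exactly here
    for base, child in root.children.items():
        if base == SENTINEL:
            out.leaf_positions.extend(child.leaf_positions)
            continue
        for base2, grandchild in child.children.items():
            if base2 == SENTINEL:
                # odd remainder: one-base terminal edge
                node = out.children.setdefault(base, CollapsedNode())
                node.leaf_positions.extend(grandchild.leaf_positions)
            else:
                out.children[base + base2] = collapse_tree(grandchild)
    return out


def collapsed_positions(root: CollapsedNode, pattern: str) -> set[int]:
    """All positions whose suffix starts with ``pattern`` (collapsed tree)."""
    node = root
    i = 0
    while i + 2 <= len(pattern):
        child = node.children.get(pattern[i:i + 2])
        if child is None:
            return set()
        node = child
        i += 2
    if i < len(pattern):
        # one trailing base: union over matching two-base children plus the
        # one-base terminal edge
        result: set[int] = set()
        last = pattern[i]
        for label, child in node.children.items():
            if label[0] == last:
                result.update(_collect_collapsed(child))
        return result
    return set(_collect_collapsed(node))


def _collect_collapsed(node: CollapsedNode) -> Iterable[int]:
    stack = [node]
    while stack:
        cur = stack.pop()
        yield from cur.leaf_positions
        stack.extend(cur.children.values())


# ---------------------------------------------------------------------------
# hybrid hash-tree
# ---------------------------------------------------------------------------

class _BucketNode:
    """Collapsed subtree node under a hash bucket.

    ``positions`` is the aggregate of all reference positions beneath the
    node.  A node with ``children is None`` is a shortcut leaf: its
    positions share the full path so far and the query continues by direct
    comparison against the reference (behaviour identical to the tree the
    shortcut replaces).
    """

    __slots__ = ("positions", "children", "terminal")

    def __init__(self, positions: list[int]) -> None:
        self.positions = positions
        self.children: Optional[dict[str, "_BucketNode"]] = None
        self.terminal: list[int] = []   # suffixes ending exactly at this depth


@dataclass
class HybridIndex:
    """Hash table over length-l keys whose buckets root collapsed suffix
    subtrees (or bare positions, for singleton buckets)."""

    l: int
    collapse: int
    contigs: ContigTable
    bases: str                     # concatenated contig sequence
    buckets: dict[int, object]     # key -> int | _BucketNode
    max_tree_depth: int = 512

    # ---- construction ----

    @classmethod
    def build(cls, contigs: Sequence[ReferenceSequence], l: int,
              max_tree_depth: int = 512) -> "HybridIndex":
        _check_capacity(l)
        table = ContigTable.from_contigs(contigs)
        bases = "".join(c.bases for c in contigs)
        raw: dict[int, list[int]] = {}
        for contig, offset in zip(contigs, table.offsets):
            if contig.n < l:
                continue
            for key, pos in _scan_keys(contig.bases, l, offset):
                raw.setdefault(key, []).append(pos)
        index = cls(l=l, collapse=2, contigs=table, bases=bases,
                    buckets={}, max_tree_depth=max_tree_depth)
        for key, positions in raw.items():
            if len(positions) == 1:
                index.buckets[key] = positions[0]
            else:
                index.buckets[key] = index._build_subtree(positions, 0)
        return index

    def _build_subtree(self, positions: list[int], depth: int) -> _BucketNode:
        node = _BucketNode(positions)
        if len(positions) == 1 or depth >= self.max_tree_depth:
            return node   # shortcut leaf (or depth-capped): resolve by comparison
        groups: dict[str, list[int]] = {}
        terminal: list[int] = []
        for pos in positions:
            start = pos + self.l + depth
            end = self.contigs.contig_end(pos)
            label = self.bases[start:min(start + 2, end)]
            if not label:
                terminal.append(pos)
            else:
                groups.setdefault(label, []).append(pos)
        node.terminal = terminal
        node.children = {}
        for label, group in groups.items():
            if len(label) == 2:
                node.children[label] = self._build_subtree(group, depth + 2)
            else:
                # one base left before contig end: terminal one-base edge
                child = _BucketNode(group)
                node.children[label] = child
        return node

    # ---- queries ----

    def key_positions(self, key_or_seq) -> list[int]:
        """All reference positions of a length-l key (= hash bucket)."""
        key = key_or_seq if isinstance(key_or_seq, int) else encode_key(key_or_seq)
        if key is None:
            return []
        entry = self.buckets.get(key)
        if entry is None:
            return []
        if isinstance(entry, int):
            return [entry]
        return sorted(entry.positions)

    def _lcp_from(self, gpos: int, query: str, qstart: int) -> int:
        """Longest common prefix of reference[gpos:contig end] and
        query[qstart:]."""
        end = self.contigs.contig_end(gpos)
        limit = min(end - gpos, len(query) - qstart)
        bases = self.bases
        k = 0
        while k < limit and bases[gpos + k] == query[qstart + k]:
            k += 1
        return k

    def longest_match(self, read_bases: str, start: int) -> tuple[int, set[int]]:
        """Longest exact match of ``read_bases[start:]`` in the reference.

        Returns (p, positions): ``p`` is the maximum q >= l such that
        read[start:start+q] occurs in the reference, and ``positions`` all
        its occurrences.  If the l-prefix contains N or is absent from the
        reference, returns (0, empty set).
        """
        l = self.l
        if start + l > len(read_bases):
            return 0, set()
        key = encode_key(read_bases[start:start + l])
        if key is None:
            return 0, set()
        entry = self.buckets.get(key)
        if entry is None:
            return 0, set()
        if isinstance(entry, int):
            ext = self._lcp_from(entry + l, read_bases, start + l)
            return l + ext, {entry}

        # descend the collapsed subtree
        node: _BucketNode = entry
        depth = 0
        while True:
            if node.children is None:
                # shortcut leaf / depth cap: finish by direct comparison
                best = -1
                best_pos: set[int] = set()
                for pos in node.positions:
                    ext = self._lcp_from(pos + l + depth, read_bases,
                                         start + l + depth)
                    if ext > best:
                        best, best_pos = ext, {pos}
                    elif ext == best:
                        best_pos.add(pos)
                return l + depth + best, best_pos
            remaining = len(read_bases) - (start + l + depth)
            if remaining >= 2:
                label = read_bases[start + l + depth:start + l + depth + 2]
                child = node.children.get(label)
                if child is not None and "N" not in label:
                    node = child
                    depth += 2
                    continue
            # cannot take a full two-base step: try a single-base extension
            matched_one: set[int] = set()
            if remaining >= 1:
                last = read_bases[start + l + depth]
                if last != "N":
                    for label, child in node.children.items():
                        if label[0] == last:
                            matched_one.update(child.positions)
            if matched_one:
                return l + depth + 1, matched_one
            return l + depth, set(node.positions)

    # ---- serialization ----
    # bucket subtrees are flattened to (positions, terminal, child-index)
    # rows so arbitrarily deep chains never recurse while pickling

    def _flatten(self, root: _BucketNode) -> list[tuple]:
        rows: list[tuple] = []
        stack = [(root, None, None)]
        while stack:
            node, parent_idx, label = stack.pop()
            idx = len(rows)
            rows.append([node.positions, node.terminal,
                         None if node.children is None else {},
                         parent_idx, label])
            if node.children is not None:
                for lab, child in node.children.items():
                    stack.append((child, idx, lab))
        for idx, row in enumerate(rows):
            parent_idx, label = row[3], row[4]
            if parent_idx is not None:
                rows[parent_idx][2][label] = idx
        return [tuple(row[:3]) for row in rows]

    @staticmethod
    def _unflatten(rows: list[tuple]) -> _BucketNode:
        nodes = []
        for positions, terminal, children in rows:
            node = _BucketNode(positions)
            node.terminal = terminal
            nodes.append(node)
        for node, (_, _, children) in zip(nodes, rows):
            if children is not None:
                node.children = {lab: nodes[i] for lab, i in children.items()}
        return nodes[0]

    def save(self, path) -> None:
        flat_buckets = {
            key: entry if isinstance(entry, int) else self._flatten(entry)
            for key, entry in self.buckets.items()
        }
        payload = {
            "format": "hhtalign-index",
            "version": INDEX_FORMAT_VERSION,
            "l": self.l,
            "collapse": self.collapse,
            "max_tree_depth": self.max_tree_depth,
            "contigs": (self.contigs.names, self.contigs.lengths,
                        self.contigs.offsets),
            "bases": self.bases,
            "buckets": flat_buckets,
        }
        with open(path, "wb") as out:
            pickle.dump(payload, out, protocol=4)

    @classmethod
    def load(cls, path) -> "HybridIndex":
        with open(path, "rb") as handle:
            payload = pickle.load(handle)
        if payload.get("format") != "hhtalign-index":
            raise ValueError(f"{path}: not an hhtalign index file")
        if payload.get("version") != INDEX_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported index version "
                             f"{payload.get('version')}")
        names, lengths, offsets = payload["contigs"]
        buckets = {
            key: entry if isinstance(entry, int) else cls._unflatten(entry)
            for key, entry in payload["buckets"].items()
        }
        return cls(l=payload["l"], collapse=payload["collapse"],
                   contigs=ContigTable(tuple(names), tuple(lengths),
                                       tuple(offsets)),
                   bases=payload["bases"], buckets=buckets,
                   max_tree_depth=payload["max_tree_depth"])

    # ---- statistics ----

    def stats(self) -> dict:
        n_keys = len(self.buckets)
        max_bucket = 0
        n_tree = 0
        for entry in self.buckets.values():
            if isinstance(entry, int):
                max_bucket = max(max_bucket, 1)
            else:
                max_bucket = max(max_bucket, len(entry.positions))
                n_tree += 1
        return {"keys_occupied": n_keys, "tree_buckets": n_tree,
                "max_bucket": max_bucket,
                "total_length": self.contigs.total_length}
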