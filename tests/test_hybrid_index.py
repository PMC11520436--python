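import numpy as np
import pytest

from hhtalign import (CapacityError, HybridIndex, ReferenceSequence,
                      build_hash_table, build_suffix_array, build_suffix_tree,
                      collapse_tree, encode_key)
from hhtalign.hybrid_index import (SENTINEL, TrieNode, collapsed_positions,
                                   decode_key, trie_positions)

from conftest import EXAMPLE_REF, brute_force_longest_match, random_ref


class TestEncodeKey:
    @pytest.mark.parametrize("seq,expected", [
        ("AA", 0),
        ("AG", 2),          # 0*4 + 2 under the ACGT=0123 encoding
        ("TT", 15),
        ("ACGT", 0 * 64 + 1 * 16 + 2 * 4 + 3),
    ])
    def test_values(self, seq, expected):
        assert encode_key(seq) == expected

    def test_n_yields_no_key(self):
        assert encode_key("AN") is None

    def test_bijective_at_l3(self):
        keys = {encode_key(a + b + c)
                for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        assert keys == set(range(64))

    def test_decode_inverts(self):
        for key in range(64):
            assert encode_key(decode_key(key, 3)) == key


class TestHashTable:
    def test_example_buckets(self, example_table):
        assert example_table.lookup("AG") == [0, 7, 9]
        assert example_table.lookup("GA") == [8, 10]
        assert example_table.lookup("AA") == []

    def test_window_count(self, example_table):
        # n - l + 1 N-free windows scanned
        assert example_table.n_windows == 15

    def test_bucket_invariants(self):
        rng = np.random.default_rng(3)
        ref = random_ref(rng, 300)
        table = build_hash_table(ref, 4)
        seen = set()
        for key, positions in table.buckets.items():
            assert positions == sorted(positions)
            for pos in positions:
                assert encode_key(ref.bases[pos:pos + 4]) == key
            seen.update(positions)
        assert seen == set(range(ref.n - 4 + 1))

    def test_n_windows_excluded(self):
        ref = ReferenceSequence("r", "ACGTNACGT")
        table = build_hash_table(ref, 3)
        positions = {p for plist in table.buckets.values() for p in plist}
        # windows overlapping the N (2,3,4) are skipped
        assert positions == {0, 1, 5, 6}

    def test_capacity_error(self, example_ref):
        with pytest.raises(CapacityError, match="sparse"):
            build_hash_table(example_ref, 40)


class TestSuffixArray:
    def test_example(self, example_ref):
        sa = build_suffix_array(example_ref)
        assert len(sa.order) == 16
        assert sa.order[0] == 4      # "ACCAGAGATGGC" is least
        assert sorted(sa.order) == list(range(16))
        suffixes = [example_ref.bases[i:] for i in sa.order]
        assert suffixes == sorted(suffixes)

    def test_sentinel_smallest(self):
        sa = build_suffix_array(ReferenceSequence("r", "AAAA"))
        assert sa.order == [3, 2, 1, 0]


class TestSuffixTree:
    def test_leaf_count_equals_n(self):
        rng = np.random.default_rng(5)
        ref = random_ref(rng, 50)
        root = build_suffix_tree(ref)
        leaves = list(_iter_leaf_positions(root))
        assert len(leaves) == 50

    def test_root_to_leaf_paths_spell_suffixes(self):
        ref = ReferenceSequence("r", "AGTCAG")
        root = build_suffix_tree(ref)
        paths = set()
        _collect_paths(root, "", paths)
        assert paths == {ref.bases[i:] for i in range(ref.n)}

    def test_example_ag_subtree(self, example_ref):
        root = build_suffix_tree(example_ref)
        assert trie_positions(root, "AG") == {0, 7, 9}

    def test_single_base_reference(self):
        root = build_suffix_tree(ReferenceSequence("r", "A"))
        assert trie_positions(root, "A") == {0}

    def test_suffix_tree_matches_suffix_array_order(self, example_ref):
        # leaves read in lexicographic order reproduce the suffix array
        root = build_suffix_tree(example_ref)
        order = list(_leaves_lexicographic(root))
        assert order == build_suffix_array(example_ref).order


class TestCollapseTree:
    @pytest.mark.parametrize("seed,n", [(0, 40), (1, 80), (2, 120)])
    def test_collapse_neutrality(self, seed, n):
        rng = np.random.default_rng(seed)
        ref = random_ref(rng, n)
        trie = build_suffix_tree(ref)
        collapsed = collapse_tree(trie)
        for _ in range(30):
            start = int(rng.integers(0, n))
            length = int(rng.integers(1, 12))
            pattern = ref.bases[start:start + length]
            assert collapsed_positions(collapsed, pattern) == \
                trie_positions(trie, pattern)
        # absent patterns agree too
        assert collapsed_positions(collapsed, "X" * 3 if "X" in "ACGT" else
                                   "TTTTTTTTTTTTTTTTTTTTTT") == \
            trie_positions(trie, "TTTTTTTTTTTTTTTTTTTTTT")

    def test_child_count_bounded(self, example_ref):
        collapsed = collapse_tree(build_suffix_tree(example_ref))
        stack = [collapsed]
        while stack:
            node = stack.pop()
            assert len(node.children) <= 17
            stack.extend(node.children.values())

    def test_odd_suffix_terminal_edge(self):
        # 3-base reference: suffix "AGT" collapses into "AG" + terminal "T"
        collapsed = collapse_tree(build_suffix_tree(
            ReferenceSequence("r", "AGT")))
        assert collapsed_positions(collapsed, "AGT") == {0}
        assert collapsed_positions(collapsed, "T") == {2}


class TestHybridIndex:
    def test_example_buckets(self, example_index):
        assert example_index.key_positions("AG") == [0, 7, 9]
        assert example_index.key_positions("AA") == []

    def test_all_keys_match_brute_force(self, example_ref, example_index):
        for key in range(16):
            pattern = decode_key(key, 2)
            expected = sorted(_occurrences(example_ref.bases, pattern))
            assert example_index.key_positions(key) == expected

    @pytest.mark.parametrize("case,query,expected", [
        ("agaga", "AGAGA", (5, {7})),
        ("agtc", "AGTC", (4, {0})),
        ("cccc", "CCCC", (2, {5})),
    ])
    def test_longest_match_examples(self, example_index, case, query,
                                    expected):
        assert example_index.longest_match(query, 0) == expected

    def test_longest_match_absent_prefix(self, example_index):
        # "AA" never occurs: p < l reported with no positions
        assert example_index.longest_match("AATT", 0) == (0, set())

    def test_longest_match_n_in_key(self, example_index):
        assert example_index.longest_match("ANAGA", 0) == (0, set())

    def test_multi_contig_positions_are_global(self):
        contigs = [ReferenceSequence("a", "ACGTACGT"),
                   ReferenceSequence("b", "TTTACGTT")]
        index = HybridIndex.build(contigs, 3)
        assert index.key_positions("ACG") == [0, 4, 11]
        # position 4 (contig a) stops at the contig end with p=4; only
        # position 11 (contig b, "ACGTT...") reaches p=5
        p, positions = index.longest_match("ACGTTTT", 0)
        assert p == 5 and positions == {11}

    def test_match_does_not_cross_contig_end(self):
        contigs = [ReferenceSequence("a", "AAACG"),
                   ReferenceSequence("b", "TCGGG")]
        index = HybridIndex.build(contigs, 2)
        p, positions = index.longest_match("CGT", 0)
        assert p == 2 and positions == {3, 6}

    def test_save_load_round_trip(self, example_index, tmp_path):
        path = tmp_path / "idx.bin"
        example_index.save(path)
        back = HybridIndex.load(path)
        assert back.l == 2
        assert back.key_positions("AG") == [0, 7, 9]
        assert back.longest_match("AGAGA", 0) == (5, {7})

    def test_load_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "junk.bin"
        import pickle
        path.write_bytes(pickle.dumps({"something": 1}))
        with pytest.raises(ValueError, match="not an hhtalign index"):
            HybridIndex.load(path)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random(self, seed):
        """longest_match == brute-force longest-common-prefix scan."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(50, 2000))
        ref = random_ref(rng, n)
        l = int(rng.integers(2, 7))
        index = HybridIndex.build([ref], l)
        for _ in range(25):
            if rng.random() < 0.5:
                start = int(rng.integers(0, n - 20))
                query = ref.bases[start:start + 20]
            else:
                query = "".join(np.array(list("ACGT"))[
                    rng.integers(0, 4, size=20)])
            expected = brute_force_longest_match(ref.bases, query, l)
            assert index.longest_match(query, 0) == expected

    def test_repeat_heavy_reference(self):
        # deep shared context exercises the subtree depth cap
        ref = ReferenceSequence("r", "ACGTT" * 200)
        index = HybridIndex.build([ref], 4, max_tree_depth=16)
        query = "ACGTT" * 8
        expected = brute_force_longest_match(ref.bases, query, 4)
        assert index.longest_match(query, 0) == expected


def _iter_leaf_positions(root: TrieNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield from node.leaf_positions
        stack.extend(node.children.values())


def _collect_paths(node: TrieNode, prefix: str, out: set):
    for base, child in node.children.items():
        if base == SENTINEL:
            out.add(prefix)
        else:
            _collect_paths(child, prefix + base, out)


def _leaves_lexicographic(node: TrieNode):
    for base in sorted(node.children, key=lambda b: "" if b == SENTINEL else b):
        child = node.children[base]
        if base == SENTINEL:
            yield from sorted(child.leaf_positions)
        else:
            yield from _leaves_lexicographic(child)


def _occurrences(text: str, pattern: str) -> list[int]:
    out = []
    start = text.find(pattern)
    while start != -1:
        out.append(start)
        start = text.find(pattern, start + 1)
    return out
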