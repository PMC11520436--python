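import numpy as np
import pytest

from hhtalign import HybridIndex, ReferenceSequence, build_hash_table

# the 16-base reference used throughout the worked examples
EXAMPLE_REF = "AGTCACCAGAGATGGC"


@pytest.fixture(scope="session")
def example_ref() -> ReferenceSequence:
    return ReferenceSequence("r", EXAMPLE_REF)


@pytest.fixture(scope="session")
def example_table(example_ref):
    return build_hash_table(example_ref, 2)


@pytest.fixture(scope="session")
def example_index(example_ref) -> HybridIndex:
    return HybridIndex.build([example_ref], 2)


def random_ref(rng: np.random.Generator, n: int,
               name: str = "chr") -> ReferenceSequence:
    bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
    return ReferenceSequence(name, bases)


def brute_force_longest_match(ref_bases: str, query: str,
                              min_len: int) -> tuple[int, set[int]]:
    """Independent oracle: longest q such that query[:q] occurs in the
    reference, found by substring search, with all its occurrences.
    Reports (0, {}) when even the min_len prefix is absent."""
    if min_len > len(query) or query[:min_len] not in ref_bases:
        return 0, set()
    p = min_len
    while p < len(query) and query[:p + 1] in ref_bases:
        p += 1
    positions = set()
    start = ref_bases.find(query[:p])
    while start != -1:
        positions.add(start)
        start = ref_bases.find(query[:p], start + 1)
    return p, positions


def naive_affine_dp(a: str, b: str, match: int = 1, mismatch: int = 4,
                    gap_open: int = 6, gap_extend: int = 1) -> int:
    """Textbook O(nm) local affine-gap DP, score only — the independent
    oracle for the SWG kernel."""
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else -mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
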