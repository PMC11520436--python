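# Methods

## The index

The reference (one or more contigs) is scanned once per contig with a
rolling base-4 encoding (`A,C,G,T → 0,1,2,3`, leftmost base most
significant).  Every N-free window of length *l* contributes its start
position to the bucket of its key; windows containing N form no key, and a
window never spans a contig boundary, so inter-contig matches are
impossible by construction.  Positions are kept global (concatenated
coordinates) and mapped back to (contig, offset) at output time.

Buckets are held in a sparse mapping rather than a dense 4^*l* array; the
two are observably identical and the sparse form is the only sensible one
at the genome sizes this package targets.  Key lengths above 28 are
rejected with a capacity error.

Each bucket with more than one position roots a small suffix subtree over
the text following the key.  Nodes consume two bases per level (≤ 16
two-base children, plus one-base terminal edges and an end-of-sequence
slot where a suffix runs out at a contig end), halving the descent depth
relative to a one-base-per-level trie.  Two structural shortcuts keep the
subtrees tiny without changing any query answer:

* **stop-at-singleton** — once only one position remains under a node, the
  node stores the bare position and queries finish by direct comparison
  against the reference;
* **depth cap** (default 512 bases) — deep shared context (long repeats)
  stops splitting and falls back to per-position comparison.

Both shortcuts are property-tested against a brute-force scan: for every
key the reachable position set equals the plain hash bucket, and
`longest_match` agrees exactly (match length and full occurrence set) with
a longest-common-prefix scan over the whole reference.

The classical structures the hybrid is derived from — the lexicographic
suffix array (end-of-string sentinel smallest) and the uncollapsed suffix
trie — are provided for verification: the trie's leaves read in
lexicographic order reproduce the suffix array, and collapsing the trie
two bases per level answers every query identically.

`longest_match(read, start)` returns the maximal *p* ≥ *l* with
`read[start:start+p]` present in the reference together with **all** its
occurrences; if the *l*-prefix is absent (or contains N) it reports
*p* = 0 with no positions and the caller advances one base.

## Seeding

Adaptive-stride search: query the longest match at offset 0, record the
hits (offset-corrected to the read's first base; negative corrections
dropped), advance by max(1, ⌊*p*/2⌋), and repeat until the last full key
window.  After the scan, hits with *p* ≤ *p*<sub>max</sub>/2 are
discarded (strictly) and hits sharing a corrected start are merged keeping
the larger *p*.  Advancing by half the match length keeps the number of
descents *O(m/l)* for clean reads (asserted in the tests as
≤ 2·*m*/*l* + 2 per error-free 150-bp read) while the half-maximum
retention guarantees a surviving hit of length at least (*p*+2)/2 for the
true longest match.

Two auxiliary modes exist.  The fixed-stride mode enumerates key offsets
{0, s, 2s, …} — the tail offset *m*−*l* is always appended so the read end
is covered — and ranks corrected starts by how many offsets voted for
them; buckets larger than a repeat-guard cap (default 500) are skipped
there.  The published count formula for stride-s keys disagrees with
direct enumeration for s > 1; this implementation enumerates.  The
chimeric mode advances by a fixed small shift and retains every hit at or
above a length floor, so both loci of a split read surface.

Search exhaustiveness is a two-level knob: "low" uses shift *p*/2,
half-maximum retention, and extends the top 5 candidates; "high" uses
*p*/4, third-of-maximum retention, and the top 20.  These mappings are
this package's own definition of the accuracy modes; nothing in the
sources pins them down.

Both strands are always seeded (the reverse complement of the read is
searched against the forward index) unless the caller disables it.

## Extension and scoring

Candidates are extended with a Smith-Waterman-Gotoh local DP: match +1,
mismatch −4, gap open 6, gap extend 1 by default (a gap of length *k*
costs 6 + *k*), all configurable.  The reference window is the corrected
start padded by 32 bases on each side, clamped to the contig.  Unaligned
read ends become soft clips; N matches nothing.  The kernel is one plain
Python function compiled with numba when importable; a separately coded
naive DP is the oracle in the tests (exact integer agreement on hundreds
of random pairs).

A verified full-length exact match skips the DP (the common case the
adaptive search is designed around).  When a read carries an indel, the
prefix and suffix segments seed two different corrected starts whose
extensions converge to one alignment; results are therefore deduplicated
by (strand, aligned start) before the primary is chosen, otherwise every
indel-bearing read would look multimapped and be lost to the caller's
mapping-quality filter.

Final scores are quality-aware: each mismatch's penalty is scaled by
(1 − 10^(−Q/10)), i.e. a mismatch at an error-prone base is forgiven in
proportion to its error probability.  This is a deliberate, lightweight
reading of quality recalibration — no empirical covariate table is fitted,
because no covariate structure (machine cycle, context) exists in the
inputs.  Matches and gaps are unscaled, so the adjusted score is ≥ the raw
score, with equality exactly when the alignment has no mismatches, and
raising a mismatching base's quality can only lower the score.

Mapping quality: 60 for a unique candidate, 0 on an exact score tie
(ties resolve to the forward strand, then the smallest coordinate), else
min(60, round(6·Δ/ln 10)) where Δ is the final-score gap to the runner-up.
The constant places a 10-point gap at MAPQ 26 and saturates near Δ ≈ 23.

## Region bucket sort

The concatenated genome is divided into *r* near-equal regions (integer
division boundaries).  Each input chunk writes one headerless SAM fragment
per region — `chunk{i}.region{j}.sam`, all *r* files created even when
empty, unmapped reads to a per-chunk sink — and a region is recovered by
concatenating its fragments over all chunks and sorting by (contig,
position, strand, read name); the name is in the key purely for
determinism.  The tests assert multiset conservation and exact equality
with a single global sort for arbitrary (q, r).

## Variant calling

Per region: records are gathered together with a left-overlap fetch
(default 512 bases) from preceding regions so pileups at region starts are
complete, re-sorted, and duplicate-marked.  Duplicate groups share
(contig, soft-clip-unclipped start, strand, mate position); the member
with the highest base-quality sum survives (ties: first read name).

Pileups are built streaming: M columns contribute (base, quality),
deletions contribute markers, insertions attach to the column before
them, soft clips contribute nothing; duplicate, unmapped, or MAPQ < 10
records are excluded, and a record whose CIGAR disagrees with its
sequence length is rejected and counted rather than fatal.

Genotyping is a flat-prior diploid likelihood for the strongest
non-reference allele.  With per-base error *e*ᵢ = 10^(−Qᵢ/10):
P(obsᵢ | hom-ref) = 1 − *e*ᵢ if the base matches the reference else
*e*ᵢ/3, symmetrically for hom-alt, and the heterozygous likelihood is the
mean of the two homozygous terms.  A site is called when the posterior
favours a non-reference genotype and QUAL = −10 log₁₀ P(hom-ref | data)
≥ 20, with depth ≥ 4 after a base-quality floor of 10.  This is the
simplest model consistent with a per-position SNP/INDEL check and is
validated by parameter recovery rather than by reference to any published
caller internals.

Indels use the same machinery with presence/absence as the two alleles.
Each read's indel observation is first **left-aligned to its canonical
anchored representation** and only then grouped — alignment places an
indel inside a repeat ambiguously, and without canonicalization the
support for one event fragments across anchors.  An allele needs ≥ 3
supporting reads and ≥ 25 % of the covering reads.  Indel observations
carry a deliberately modest confidence (Q10): presence/absence evidence is
far noisier than a base call because reads whose alignment clips near the
event silently vote "absent", and a Q30 model mis-genotypes homozygous
indels as heterozygous for exactly that reason.

Region-count invariance is structural: a variant is owned by the region
containing its **un-normalized** anchor column (pileups extend 64 bases
past the region end so deletion runs complete), and left-alignment
afterwards only rewrites the representation — so r = 1 and r = 16 emit
identical call sets, which the tests check verbatim.  Overlapping mates
are both counted at a shared column (no overlap clipping); a documented
simplification that slightly double-counts evidence at fragment centers.

## The simulator

The generator emulates the study conditions the recovery suite runs
under: a uniform-random ACGT reference (optionally with a planted tandem
repeat to exercise high-frequency keys), 300 SNPs + 30 indels of 1–5 bp
on a 100 kb diploid genome, genotypes het/hom 50/50, 30× paired 150-bp
reads with inserts ~N(350, 20²), strands 50/50, and per-base substitution
errors at a uniform rate with every quality set to Q = −10 log₁₀(rate)
(capped at Q40).  One integer seed drives everything; each stage derives
a child stream, so changing read depth cannot perturb the reference.
Variants keep a 10-bp mutual gap and a margin from contig ends scaled to
uniform-coverage reach (default 200 bp), mirroring how benchmark truth
sets exclude under-covered reference edges.  Optional exact PCR copies of
a chosen fraction of fragments exercise duplicate marking.

What the simulator does **not** model — per-cycle quality profiles,
context-dependent and indel sequencing errors, coverage bias, structural
variants — bounds what the passing tests show: they demonstrate the
pipeline's correctness and its recovery of implanted germline small
variants under idealized noise, not field accuracy on real instruments.

## Parallel execution contract

Matching parallelizes over input chunks, calling over regions; workers
share only the read-only index and write disjoint files, and results are
collected in input order, so every artifact is byte-identical for any
thread count (tested for 1 vs 4 and 1 vs 8).  The sequential path is the
reference implementation.

## Problem sizes and defaults

Desk-scale defaults — key length 11, 16 regions, 4 input chunks, 100 kb
genomes — keep the full recovery suite in minutes on one core while
leaving every code path (multi-chunk scatter, multi-region gather,
boundary overlap, both strands) exercised.  Key length 15 and r ≈ 1000
are the sensible production-scale settings; both are plain knobs.

## Known limitations

* No pair rescue: each mate is placed independently; the pair only
  influences flags/TLEN, never placement.
* No split/supplementary alignment records; the chimeric seeding mode
  finds the loci but emission is out of scope.
* MAPQ is a score-gap heuristic, not a calibrated posterior.
* The caller is germline small-variant only — no somatic model and no
  structural variants.
* Index (de)serialization is a version-stamped pickle; it is a cache
  format, not an interchange format.
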