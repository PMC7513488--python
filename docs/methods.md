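# Methods

## The compression model

A molecule is represented as an undirected heavy-atom graph 𝒢 = (𝒱, ℰ).
Hydrogens are implicit (a per-atom count), aromatic rings are kekulized on
input so every bond is single, double or triple, and stereochemistry is
discarded — the feature set has no stereo slots, so round-trip equality is
defined on stereo-stripped canonical SMILES throughout.

A *bridge* is a path of one or two heavy atoms (the intermediates), each of
degree exactly 2, connecting two anchor atoms. Compression Φ deletes the
intermediates of designated bridges and records each deletion as a count on
the anchor-pair edge; decompression Φ⁻¹ re-inserts them from the registry's
atom specs and bond orders. Because an intermediate of degree > 2 would
carry a substituent that deletion would orphan, the degree-2 requirement is
what makes the codec lossless. Anchors are never deleted and may carry any
features.

### The default registry

| id | bridge | bond orders | intermediates | max count/edge |
|----|--------|-------------|---------------|----------------|
| 1 | amine `-NH-` | s,s | N (1 H) | 3 |
| 2 | ether `-O-` | s,s | O (0 H) | 3 |
| 3 | ethylene `-CH2-CH2-` | s,s,s | C (2 H) ×2 | 2 |
| 4 | vinylene `-CH=CH-` | s,d,s | C (1 H) ×2 | 1 |
| 5 | allyl `-CH2-CH=` | s,s,d | C (2 H), C (1 H) | 2 |
| 6 | aza `=N-` | d,s | N (0 H) | 1 |

These are the prevalent one- and two-atom C/N/O bridges of drug-like
chemistry once rings are kekulized: secondary amines and amides (1), ethers
and esters (2), aliphatic chains and rings (3), the alternating-bond unit
of kekulized aromatic rings (4), allylic units (5) and azomethine/aza-
aromatic nitrogen (6). Two structural constraints shaped the set: patterns
with a single intermediate must not match *inside* an occurrence of a
two-intermediate pattern (a bare `-CH2-` pattern alongside `-CH2-CH2-`
would always pre-empt it under priority resolution, so single-intermediate
patterns are heteroatom bridges only), and every intermediate's hydrogen
count is exactly what its element's standard valence leaves after the
bridge bonds, so re-inserted atoms are chemically consistent by
construction. The max counts cap how many simultaneous occurrences between
one anchor pair the edge features can express; they fix the one-hot widths
(3+3+2+1+2+1 = 12) and hence q = 3 + 12 = 15. Excess occurrences beyond a
cap are simply left uncompressed rather than rejecting the molecule.
Custom registries extend q accordingly (q = 3 + Σ max counts).

### Canonical ordering, priority and orientation

Atom ranks come from RDKit's canonical ranking with full tie-breaking,
computed on the sanitized, stereo-stripped molecule; `parse_smiles` orders
nodes by rank, making downstream behavior independent of how the input
SMILES was spelled. Within an automorphism orbit any full ranking must pick
arbitrarily, so rank-per-atom is only canonical up to automorphism; the
canonical *form* (the graph reordered by ranks) is invariant, which is the
property the codec relies on.

Overlapping bridges are resolved greedily in priority order. A match's
priority key is the ascending tuple of its atoms' canonical ranks:
overlapping matches share a key prefix, so the first difference is decided
by a non-overlapping atom, implementing "smaller canonical numbers win".
Ties (possible when two matches cover the same atom set, either as
different patterns or as one pattern with anchor/intermediate roles
swapped) break by pattern id, then by the stored path — fully
deterministic. A match is accepted iff none of its atoms was deleted by an
earlier acceptance, none of its intermediates already serves as the
endpoint of a converted edge (deleting it would orphan that edge), and its
pattern's per-pair cap has room. Greedy sequential semantics are used
rather than any coverage-maximizing search: conversion is defined as a
sequential procedure, not an optimization.

Asymmetric bridges (5 and 6) read differently from each end, but an edge
stores only a count, which cannot record orientation. Convention: a match
is eligible only when the registered bond-order sequence reads from the
anchor with the smaller canonical rank; decompression re-attaches the first
intermediate to the edge endpoint with the smaller retained index. To make
these two conventions coincide for every input, `compress` works in
canonical-rank node order (reordering first if a hand-built graph arrives
in another order). The cost is that roughly half of the asymmetric
occurrences — those pointing the "wrong" way — stay uncompressed; the gain
is exact invertibility and byte-identical compressed output across input
relabelings.

## Tensor encoding and argmax decoding

Nodes encode as 12 + 4 + 3 = 19 one-hot features (atom type; formal charge
−1/1/2/3; hydrogen count 1/2/3), with the zero charge and zero H-count
categories as all-zero blocks — the widths force this convention. Edges
encode as 3 + 12 = 15 features (bond type single/double/triple, "none"
all-zero; one count block per pattern); an absent edge is the zero vector,
which is why an edge must carry a bond or at least one count. The edge
tensor is dense, symmetric, and zero on the diagonal.

Probabilistic decoder outputs are scored per block with an explicit leading
"none"/"absent" category (node scores are 22 wide, edge scores 22 wide for
the default registry). Decoding takes the per-block argmax independently,
after averaging the (i,j) and (j,i) edge cells; ties break toward the
lowest category index, so an exactly tied block decodes as "none". The
maximum node count of decoder outputs is a free parameter of the model, so
`ProbabilisticGraph` takes whatever n_max its arrays imply. Decoded graphs
may be chemically invalid; validity is judged downstream by the metrics
module, mirroring how generated samples are actually evaluated.

## Metrics

Validity = fraction of outputs RDKit parses and sanitizes; uniqueness and
novelty are computed over the *valid* subset (some benchmarks divide by all
generated samples instead — the definitions here follow the
distribution-learning convention this package targets), with duplicates
defined by stereo-stripped canonical SMILES. Corpus compression statistics
stream molecule by molecule (memory is bounded by histogram bins), and
report per-pattern bridge counts both as *found* by the matcher and as
*converted* after overlap resolution, since the two differ whenever
bridges overlap or exceed caps.

## The synthetic generator

`synthdata` emulates a drug-like corpus well enough to exercise every code
path: molecules are grown atom-by-atom under standard valences from a
carbon-dominated element distribution (~70% C, ~12% O, ~11% N, trace
B/Si/P/Se/I so all 12 encodable elements occur), occasionally closed into
rings, given rare ±1 charged centers, and then bridge motifs are spliced in
by subdividing existing single bonds at per-pattern Poisson rates. The
default rates (1.10, 1.31, 1.44, 1.03, 0.65, 0.60 per molecule) match the
per-molecule frequencies of the six bridges reported for a 1.6M-molecule
ChEMBL subset, and the default size range of 6–50 heavy atoms gives a mean
near 28 — so the synthetic corpus exercises the codec at realistic bridge
density. What it does not emulate: real functional-group statistics,
aromatic-ring abundance (rings here are mostly saturated), tautomer or
protonation conventions, or property distributions (logP, MW). Passing
tests therefore demonstrate the codec's correctness and determinism on
feature-domain-complete molecules, not that compression ratios on real
corpora will match the synthetic ones; the `stats` CLI can stream any real
SMILES corpus to measure those directly.

Determinism: molecule *t* of a corpus is generated from the seed pair
`(seed, t)`, so corpora are reproducible and extendable without shifting
earlier molecules. The ground-truth log records, per molecule, both the
motifs inserted and the motifs still eligible at finalization (recomputed
with the matcher), because later ring closures or the orientation
convention can make an inserted motif ineligible. The packaged fixture
corpus is 500 molecules from seed 2020, regenerated and byte-compared by a
regression test.

## Numerical and degenerate-input choices

- Multi-fragment inputs are rejected (`FragmentError`) rather than silently
  compressing the largest fragment; cross-fragment behavior is undefined.
- Radicals, charges outside {−1..3}, hydrogen counts above 3, and elements
  outside the 12-element set raise `DomainError` naming the atom.
- A compressed-graph count above its registry cap, or a record whose count
  vector length does not match the registry, raises `DecompressError`
  (registry mismatch), and the round-trip checker reports it as a failure.
- Matches whose two anchors coincide (a bridge closing back onto one atom,
  as in a 3-ring traversal) are never generated: a compressed edge needs
  two distinct endpoints.
- The compressed JSON-lines format is versioned and sorts edges by
  endpoint pair, so serialization is byte-deterministic.

## Problem sizes used by the test suite and acceptance script

The suite verifies losslessness on the 500-molecule fixture corpus plus
10,000 freshly generated molecules, checks matcher and overlap resolution
against exhaustive brute-force oracles on 1,000 random molecules of ≤ 12
heavy atoms, and checks the tensor round trip exhaustively over the
240-element node domain and on sampled corpus graphs. The acceptance
script measures round-trip equality on 10,000 molecules and compression/
decoding statistics on 1,000–2,000-molecule subsets — sizes at which the
sampled statistics are stable to well under a percent.

## Known limitations

- The six-pattern registry is fixed a priori; data-specific registries can
  compress better and are supported via the JSON config, but no automatic
  pattern-mining is provided.
- Compression of an already-compressed graph is undefined (it is not a
  molecule) and unsupported.
- Asymmetric bridges pointing against the canonical orientation stay
  uncompressed (see above), so the converted counts of patterns 5 and 6
  undershoot their true occurrence counts by about half.
- KLD and FCD benchmark scores require the external benchmark's descriptor
  machinery and a trained ChemNet and are deliberately not implemented;
  the metrics CLI points users to the external benchmark.
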