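# graphpress

Reversible molecular-graph compression for scalable graph generation.

Dense graph generative models consume a molecule as a node matrix
**V** ∈ {0,1}^(|𝒱|×p) and an edge tensor **E** ∈ {0,1}^(|𝒱|×|𝒱|×q), so their
cost grows as O(|𝒱|²) in the number of heavy atoms — prohibitive for the
large molecules that dominate real collections. `graphpress` shrinks |𝒱|
losslessly: six bridge substructures that are ubiquitous between heavy-atom
pairs in drug-like molecules are deleted from the graph and re-expressed as
*edge features* (per-pattern counts) on the pair they connected. The map
𝒢′ = Φ(𝒢) is exactly invertible, 𝒢 = Φ⁻¹(Φ(𝒢)), so nothing about the
molecule is lost — the model simply learns on a smaller graph.

The default bridge registry (amine `-NH-`, ether `-O-`, ethylene
`-CH2-CH2-`, vinylene `-CH=CH-`, allyl `-CH2-CH=`, aza `=N-`) yields node
features of width p = 19 (atom type, formal charge, hydrogen count) and edge
features of width q = 15 (bond type plus one count block per pattern).
Alternative registries can be supplied as a small JSON config.

The package is aimed at people building molecular generative models: it
provides the codec, the (V, E) tensor encoding and its inverse, argmax
decoding of probabilistic decoder outputs, GuacaMol-style
validity/uniqueness/novelty metrics, corpus compression statistics, a
seeded synthetic-molecule generator, and a CLI.

## Worked example

```python
>>> import graphpress as gp
>>> reg = gp.load_default_registry()
>>> g = gp.parse_smiles("C=NOC(C)(C)OC")     # an oxime ether, 8 heavy atoms
>>> [(m.pattern_id, m.atoms) for m in gp.find_matches(g, reg)]
[(6, (0, 4, 6)), (2, (1, 5, 7)), (2, (4, 6, 7))]
>>> cg = gp.compress(g, reg)
>>> cg.n_nodes
6
>>> gp.write_smiles(gp.decompress(cg, reg)) == gp.write_smiles(g)
True
```

Three bridges are found: an aza bridge (pattern 6) and two ether bridges
(pattern 2). The aza bridge and one ether bridge overlap, so only the one
whose atoms carry the smaller canonical numbers converts; together with the
disjoint ether bridge, two intermediates are deleted and the graph shrinks
from 8 to 6 nodes. Decompression restores the exact molecule.

When two bridges connect the *same* pair of atoms they stack on one edge:

```python
>>> cg = gp.compress(gp.parse_smiles("CC1CCSC=C1"), reg)   # 7 heavy atoms
>>> cg.n_nodes, [e for e in cg.edges if any(e.pattern_counts)]
(3, [CompressedEdge(endpoints=(1, 2), bond='none', pattern_counts=(0, 0, 1, 1, 0, 0))])
```

The ring's ethylene and vinylene bridges both convert onto a single
bond-less edge, and the 7-atom molecule becomes a 3-node graph — the edge
tensor shrinks from 7×7×15 to 3×3×15 cells.

From the shell:

```bash
graphpress synth --n 1000 --seed 7 --out corpus.smi
graphpress compress corpus.smi --out corpus.jsonl
graphpress check corpus.smi                      # verifies the round trip
graphpress stats corpus.smi                      # node reduction + bridge counts
graphpress tensorize corpus.jsonl --out corpus.npz
```

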