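import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import EXAMPLE_1, EXAMPLE_2
from oracles import simulate_sequential_resolution

from graphpress.chemgraph import Atom, MolecularGraph, parse_smiles, write_smiles
from graphpress.codec import (
    CompressedEdge,
    CompressedGraph,
    compress,
    decompress,
    from_json_record,
    resolve_overlaps,
    roundtrip_check,
    to_json_record,
)
from graphpress.errors import DecompressError, DomainError
from graphpress.patterns import find_matches


def four_parallel_amine_bridges() -> MolecularGraph:
    """Two carbons joined by four parallel -NH- bridges (a tetraamine cage)."""
    g = MolecularGraph(
        atoms=[Atom("C", 0, 0), Atom("C", 0, 0)] + [Atom("N", 0, 1)] * 4
    )
    for n in (2, 3, 4, 5):
        g.add_bond(0, n, "single")
        g.add_bond(1, n, "single")
    return g


class TestResolveOverlaps:
    def test_worked_example_1_overlap(self, registry):
        """Of the two overlapping bridges the one with smaller canonical
        numbers converts; the disjoint ether bridge converts regardless."""
        g = parse_smiles(EXAMPLE_1)
        matches = find_matches(g, registry)
        accepted = resolve_overlaps(matches, registry)
        assert len(accepted) == 2
        aza = next(m for m in matches if m.pattern_id == 6)
        overlapped = next(
            m for m in matches if m.pattern_id == 2 and set(m.atoms) & set(aza.atoms)
        )
        disjoint = next(
            m for m in matches if m.pattern_id == 2 and not set(m.atoms) & set(aza.atoms)
        )
        winner = min([aza, overlapped], key=lambda m: (m.priority_key, m.pattern_id))
        assert set(accepted) == {winner, disjoint}

    def test_anchor_sharing_matches_both_accepted(self, registry):
        """Parallel bridges sharing only their anchors all convert."""
        g = parse_smiles(EXAMPLE_2)
        accepted = resolve_overlaps(find_matches(g, registry), registry)
        assert sorted(m.pattern_id for m in accepted) == [3, 4]
        assert accepted[0].anchors == accepted[1].anchors

    def test_count_cap_rejects_fourth_parallel_bridge(self, registry):
        g = four_parallel_amine_bridges()
        matches = find_matches(g, registry)
        assert [m.pattern_id for m in matches] == [1, 1, 1, 1]
        accepted = resolve_overlaps(matches, registry)
        assert len(accepted) == 3  # amine count cap
        got = [(m.pattern_id, m.anchors, m.intermediate_nodes) for m in accepted]
        assert got == simulate_sequential_resolution(g, registry)

    def test_equals_sequential_simulation(self, registry, small_graphs):
        for g in small_graphs:
            accepted = resolve_overlaps(find_matches(g, registry), registry)
            got = [(m.pattern_id, m.anchors, m.intermediate_nodes) for m in accepted]
            assert got == simulate_sequential_resolution(g, registry)


class TestCompress:
    def test_ethane_unchanged(self, registry):
        cg = compress(parse_smiles("CC"), registry)
        assert cg.n_nodes == 2
        assert len(cg.edges) == 1
        assert cg.edges[0].bond == "single"
        assert cg.edges[0].pattern_counts == (0,) * 6

    def test_worked_example_1_six_nodes(self, registry):
        g = parse_smiles(EXAMPLE_1)
        cg = compress(g, registry)
        assert (g.n_atoms, cg.n_nodes) == (8, 6)

    def test_worked_example_2_merged_edge(self, registry):
        g = parse_smiles(EXAMPLE_2)
        cg = compress(g, registry)
        assert (g.n_atoms, cg.n_nodes) == (7, 3)
        merged = next(e for e in cg.edges if any(e.pattern_counts))
        assert merged.bond == "none"
        assert merged.pattern_counts == (0, 0, 1, 1, 0, 0)

    def test_node_count_identity(self, registry, small_graphs):
        for g in small_graphs:
            accepted = resolve_overlaps(find_matches(g, registry), registry)
            cg = compress(g, registry)
            n_removed = sum(len(m.intermediate_nodes) for m in accepted)
            assert cg.n_nodes == g.n_atoms - n_removed
            assert cg.n_nodes <= g.n_atoms

    def test_serialization_deterministic_across_spellings(self, registry):
        spellings = ["OCC1CC1N", "NC1CC1CO", "C1(CO)C(N)C1"]
        records = {to_json_record(compress(parse_smiles(s), registry)) for s in spellings}
        assert len(records) == 1

    def test_rejects_out_of_domain_graph(self, registry):
        g = MolecularGraph(atoms=[Atom("C", -2, 0), Atom("C", 0, 3)])
        g.add_bond(0, 1, "single")
        with pytest.raises(DomainError):
            compress(g, registry)


class TestDecompress:
    def test_pattern_free_graph_is_identity(self, registry):
        cg = compress(parse_smiles("CC(=O)C"), registry)
        assert not any(any(e.pattern_counts) for e in cg.edges)
        g = decompress(cg, registry)
        assert write_smiles(g) == write_smiles(parse_smiles("CC(=O)C"))

    def test_count_beyond_cap_raises(self, registry):
        cg = CompressedGraph(
            nodes=[Atom("C", 0, 0), Atom("C", 0, 0)],
            edges=[CompressedEdge((0, 1), "none", (0, 0, 0, 2, 0, 0))],  # vinylene cap is 1
        )
        with pytest.raises(DecompressError):
            decompress(cg, registry)

    def test_wrong_registry_arity_raises(self, registry):
        cg = CompressedGraph(
            nodes=[Atom("C", 0, 3), Atom("C", 0, 3)],
            edges=[CompressedEdge((0, 1), "single", (0, 0))],
        )
        with pytest.raises(DecompressError):
            decompress(cg, registry)

    def test_reinserted_node_count(self, registry, small_graphs):
        for g in small_graphs[:100]:
            cg = compress(g, registry)
            restored = decompress(cg, registry)
            n_inserted = sum(
                c * registry[k + 1].n_intermediates
                for e in cg.edges
                for k, c in enumerate(e.pattern_counts)
            )
            assert restored.n_atoms == cg.n_nodes + n_inserted == g.n_atoms


class TestRoundTrip:
    def test_ethane(self, registry):
        assert roundtrip_check(parse_smiles("CC"), registry).ok

    def test_fixture_corpus_lossless(self, registry, fixture_graphs):
        bad = [
            r.original_smiles
            for r in (roundtrip_check(g, registry) for g in fixture_graphs)
            if not r.ok
        ]
        assert bad == []

    def test_cage_roundtrip(self, registry):
        g = four_parallel_amine_bridges()
        assert roundtrip_check(g, registry).ok

    def test_corrupted_graph_reports_failure(self, registry):
        g = parse_smiles("CCOCC")
        cg = compress(g, registry)
        bad_edges = [
            CompressedEdge(e.endpoints, e.bond, tuple(c * 5 for c in e.pattern_counts))
            if any(e.pattern_counts)
            else e
            for e in cg.edges
        ]
        cg.edges = bad_edges
        with pytest.raises(DecompressError):
            decompress(cg, registry)


class TestRoundTripProperty:
    """Losslessness as a property over the generator's whole seed space."""

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_any_generated_molecule_roundtrips(self, seed):
        from graphpress.patterns import load_default_registry
        from graphpress.synthdata import GenParams, generate_molecule

        reg = load_default_registry()
        rec = generate_molecule(GenParams(seed=seed), np.random.default_rng(seed))
        report = roundtrip_check(rec.graph, reg)
        assert report.ok, report.detail


class TestJsonl:
    def test_record_roundtrip(self, registry, fixture_graphs):
        for g in fixture_graphs[:50]:
            cg = compress(g, registry)
            cg2 = from_json_record(to_json_record(cg))
            assert to_json_record(cg2) == to_json_record(cg)
            assert write_smiles(decompress(cg2, registry)) == write_smiles(g)

    def test_malformed_record_raises(self):
        with pytest.raises(DecompressError):
            from_json_record('{"nodes": "oops"}')
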