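import itertools

import numpy as np
import pytest

from conftest import EXAMPLE_2

from graphpress.chemgraph import Atom, parse_smiles
from graphpress.codec import CompressedEdge, compress, to_json_record
from graphpress.errors import DomainError, MalformedTensorError
from graphpress.tensorize import (
    GraphTensors,
    ProbabilisticGraph,
    decode_edge,
    decode_node,
    decode_probabilistic,
    embed_probabilistic,
    encode_edge,
    encode_node,
    graph_to_tensors,
    load_bundle,
    save_bundle,
    tensors_to_graph,
)


class TestSchema:
    def test_default_dimensionalities(self, schema):
        assert schema.p == 19
        assert schema.q == 15
        assert [w for _, w in schema.node_blocks] == [12, 4, 3]
        assert [w for _, w in schema.edge_blocks] == [3, 3, 3, 2, 1, 2, 1]


class TestNodeCodec:
    def test_carbon_two_hydrogens(self, schema):
        v = encode_node(Atom("C", 0, 2), schema)
        assert v.shape == (19,)
        assert list(np.flatnonzero(v)) == [1, 18 - 1]  # C slot; H-count slot "2"
        assert v[12:16].sum() == 0  # zero charge block all-zero

    def test_boron_bare_single_bit(self, schema):
        v = encode_node(Atom("B", 0, 0), schema)
        assert v.sum() == 1 and v[0] == 1

    def test_exhaustive_bijection(self, schema):
        from graphpress.chemgraph import CHARGES, ELEMENTS, H_COUNTS

        for el, q, h in itertools.product(ELEMENTS, CHARGES, H_COUNTS):
            a = Atom(el, q, h)
            b = decode_node(encode_node(a, schema), schema)
            assert (b.element, b.formal_charge, b.n_hydrogens) == (el, q, h)

    def test_out_of_domain_rejected(self, schema):
        with pytest.raises(DomainError):
            encode_node(Atom("U", 0, 0), schema)
        with pytest.raises(DomainError):
            encode_node(Atom("C", -2, 0), schema)


class TestEdgeCodec:
    def test_plain_single_bond(self, schema):
        v = encode_edge(CompressedEdge((0, 1), "single", (0,) * 6), schema)
        assert v.shape == (15,)
        assert list(v) == [1] + [0] * 14

    def test_merged_bridge_edge(self, schema):
        # bond none + ethylene count 1 + vinylene count 1
        v = encode_edge(CompressedEdge((0, 1), "none", (0, 0, 1, 1, 0, 0)), schema)
        assert v[:3].sum() == 0
        assert list(np.flatnonzero(v)) == [3 + 3 + 3 + 0, 3 + 3 + 3 + 2 + 0]

    def test_count_overflow_rejected(self, schema):
        with pytest.raises(DomainError):
            encode_edge(CompressedEdge((0, 1), "single", (4, 0, 0, 0, 0, 0)), schema)

    def test_all_zero_vector_is_not_an_edge(self, schema):
        with pytest.raises(DomainError):
            encode_edge(CompressedEdge((0, 1), "none", (0,) * 6), schema)

    def test_random_roundtrip(self, schema):
        rng = np.random.default_rng(3)
        for _ in range(200):
            counts = tuple(int(rng.integers(0, cap + 1)) for cap in schema.max_counts)
            bond = ["single", "double", "triple", "none"][int(rng.integers(4))]
            if bond == "none" and not any(counts):
                continue
            e = CompressedEdge((0, 1), bond, counts)
            e2 = decode_edge(encode_edge(e, schema), (0, 1), schema)
            assert (e2.bond, e2.pattern_counts) == (bond, counts)


class TestGraphTensors:
    def test_ethane_shapes(self, registry, schema):
        t = graph_to_tensors(compress(parse_smiles("CC"), registry), schema)
        assert t.node_matrix.shape == (2, 19)
        assert t.edge_tensor.shape == (2, 2, 15)
        assert t.edge_tensor[0, 1].sum() == 1 and (t.edge_tensor[0, 1] == t.edge_tensor[1, 0]).all()

    def test_compressed_example_shrinks_cells(self, registry, schema):
        g = parse_smiles(EXAMPLE_2)
        t = graph_to_tensors(compress(g, registry), schema)
        assert t.edge_tensor.shape == (3, 3, 15)  # vs 7x7x15 uncompressed

    def test_bijection_on_corpus(self, registry, schema, fixture_graphs):
        for g in fixture_graphs[:80]:
            cg = compress(g, registry)
            cg2 = tensors_to_graph(graph_to_tensors(cg, schema), registry_id=cg.registry_id)
            cg2.provenance = cg.provenance
            assert to_json_record(cg2) == to_json_record(cg)

    def test_symmetry_violation_detected(self, registry, schema):
        t = graph_to_tensors(compress(parse_smiles("CCO"), registry), schema)
        t.edge_tensor[0, 1, 0] = 1 - t.edge_tensor[0, 1, 0]
        with pytest.raises(MalformedTensorError, match="asymmetric"):
            tensors_to_graph(t)

    def test_diagonal_violation_detected(self, registry, schema):
        t = graph_to_tensors(compress(parse_smiles("CCO"), registry), schema)
        t.edge_tensor[1, 1, 0] = 1
        with pytest.raises(MalformedTensorError, match="diagonal"):
            tensors_to_graph(t)

    def test_multi_hot_detected(self, registry, schema):
        t = graph_to_tensors(compress(parse_smiles("CCO"), registry), schema)
        t.edge_tensor[0, 1, 0] = 1  # two bits in one bond block
        t.edge_tensor[0, 1, 1] = 1
        t.edge_tensor[1, 0, 0] = 1
        t.edge_tensor[1, 0, 1] = 1
        with pytest.raises(MalformedTensorError, match="bits set"):
            tensors_to_graph(t)

    def test_zero_tensor_single_node(self, schema):
        V = np.zeros((1, schema.p), dtype=np.int8)
        V[0, 1] = 1  # a bare carbon
        t = GraphTensors(V, np.zeros((1, 1, schema.q), dtype=np.int8), schema)
        cg = tensors_to_graph(t)
        assert cg.n_nodes == 1 and cg.edges == []


class TestProbabilisticDecoding:
    def test_one_hot_identity(self, registry, schema, fixture_graphs):
        for g in fixture_graphs[:40]:
            cg = compress(g, registry)
            decoded = decode_probabilistic(embed_probabilistic(cg, schema), schema)
            decoded.provenance = cg.provenance
            assert to_json_record(decoded) == to_json_record(cg)

    def test_padding_rows_are_dropped(self, registry, schema):
        cg = compress(parse_smiles("CCO"), registry)
        pg = embed_probabilistic(cg, schema, n_max=10)
        assert decode_probabilistic(pg, schema).n_nodes == cg.n_nodes

    def test_uniform_ties_break_to_lowest_category(self, schema):
        n = 2
        pg = ProbabilisticGraph(
            node_scores=np.zeros((n, schema.node_score_width)),
            edge_scores=np.zeros((n, n, schema.edge_score_width)),
        )
        # all-tied node scores: the "absent" category (index 0) wins
        assert decode_probabilistic(pg, schema).n_nodes == 0

    def test_argmax_stable_under_small_noise(self, registry, schema, fixture_graphs):
        rng = np.random.default_rng(9)
        for g in fixture_graphs[:20]:
            cg = compress(g, registry)
            pg = embed_probabilistic(cg, schema)
            noisy = ProbabilisticGraph(
                node_scores=pg.node_scores + rng.uniform(-0.49, 0.49, pg.node_scores.shape),
                edge_scores=pg.edge_scores
                + _symmetric_noise(rng, pg.edge_scores.shape, 0.49),
            )
            decoded = decode_probabilistic(noisy, schema)
            decoded.provenance = cg.provenance
            assert to_json_record(decoded) == to_json_record(cg)

    def test_nonfinite_scores_rejected(self, schema):
        pg = ProbabilisticGraph(
            node_scores=np.full((1, schema.node_score_width), np.nan),
            edge_scores=np.zeros((1, 1, schema.edge_score_width)),
        )
        with pytest.raises(MalformedTensorError):
            decode_probabilistic(pg, schema)


def _symmetric_noise(rng, shape, mag):
    eps = rng.uniform(-mag, mag, shape)
    return 0.5 * (eps + np.swapaxes(eps, 0, 1))


class TestBundleIO:
    def test_save_load(self, registry, schema, fixture_graphs, tmp_path):
        tensors = [graph_to_tensors(compress(g, registry), schema) for g in fixture_graphs[:5]]
        path = str(tmp_path / "bundle.npz")
        assert save_bundle(path, tensors) == 5
        loaded = load_bundle(path)
        assert len(loaded) == 5
        for a, b in zip(tensors, loaded):
            assert (a.node_matrix == b.node_matrix).all()
            assert (a.edge_tensor == b.edge_tensor).all()
            assert b.schema.q == schema.q
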