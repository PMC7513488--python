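"""Binary tensor encoding of compressed graphs, and argmax decoding.

A graph is encoded as a node matrix ``V`` of shape ``(n, p)`` and an edge
tensor ``E`` of shape ``(n, n, q)``, the dense pair a graph generative model
consumes.  Node features concatenate three one-hot blocks — atom type (12),
formal charge (4 slots for -1, 1, 2, 3) and attached-hydrogen count (3 slots
for 1, 2, 3) — giving ``p = 19``; the zero charge and zero H-count categories
are encoded as all-zero blocks.  Edge features concatenate the bond type
(3 slots for single/double/triple, "none" all-zero) and one count block per
registered bridge pattern whose width is that pattern's count cap, giving
``q = 15`` for the default six-pattern registry; an absent edge is the zero
vector.

``decode_probabilistic`` turns a generative decoder's raw per-node and
per-pair category scores into a discrete compressed graph by independent
per-block argmax, with explicit "absent node" / "none" categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .chemgraph import Atom, BOND_ORDERS, CHARGES, ELEMENTS, H_COUNTS
from .codec import CompressedEdge, CompressedGraph, NONE_BOND
from .errors import DomainError, MalformedTensorError
from .patterns import PatternRegistry, load_default_registry

_NONZERO_CHARGES = tuple(c for c in CHARGES if c != 0)  # (-1, 1, 2, 3)
_NONZERO_HS = tuple(h for h in H_COUNTS if h != 0)  # (1, 2, 3)


@dataclass(frozen=True)
class FeatureSchema:
    """One-hot layout for a pattern registry (``p = 19``, ``q = 15`` by default)."""

    max_counts: tuple[int, ...]
    registry_id: str

    @classmethod
    def for_registry(cls, reg: PatternRegistry) -> "FeatureSchema":
        return cls(max_counts=reg.max_counts, registry_id=reg.registry_id)

    @property
    def p(self) -> int:
        return len(ELEMENTS) + len(_NONZERO_CHARGES) + len(_NONZERO_HS)

    @property
    def q(self) -> int:
        return len(BOND_ORDERS) + sum(self.max_counts)

    @property
    def node_blocks(self) -> tuple[tuple[str, int], ...]:
        return (
            ("atom_type", len(ELEMENTS)),
            ("formal_charge", len(_NONZERO_CHARGES)),
            ("n_hydrogens", len(_NONZERO_HS)),
        )

    @property
    def edge_blocks(self) -> tuple[tuple[str, int], ...]:
        return (("bond_type", len(BOND_ORDERS)),) + tuple(
            (f"pattern_{k + 1}_count", w) for k, w in enumerate(self.max_counts)
        )

    # Score layouts for probabilistic decoding: every block gains an explicit
    # leading "none" category (absent node / zero charge / zero H / no bond /
    # count zero), so scores are plain categoricals.
    @property
    def node_score_width(self) -> int:
        return (1 + len(ELEMENTS)) + (1 + len(_NONZERO_CHARGES)) + (1 + len(_NONZERO_HS))

    @property
    def edge_score_width(self) -> int:
        return (1 + len(BOND_ORDERS)) + sum(1 + w for w in self.max_counts)


def default_schema() -> FeatureSchema:
    return FeatureSchema.for_registry(load_default_registry())


def encode_node(atom: Atom, schema: FeatureSchema) -> np.ndarray:
    """One-hot encode an atom as a length-``p`` binary vector."""
    v = np.zeros(schema.p, dtype=np.int8)
    try:
        v[ELEMENTS.index(atom.element)] = 1
    except ValueError:
        raise DomainError(f"element {atom.element!r} not encodable") from None
    if atom.formal_charge != 0:
        if atom.formal_charge not in _NONZERO_CHARGES:
            raise DomainError(f"charge {atom.formal_charge} not encodable")
        v[len(ELEMENTS) + _NONZERO_CHARGES.index(atom.formal_charge)] = 1
    if atom.n_hydrogens != 0:
        if atom.n_hydrogens not in _NONZERO_HS:
            raise DomainError(f"H count {atom.n_hydrogens} not encodable")
        v[len(ELEMENTS) + len(_NONZERO_CHARGES) + _NONZERO_HS.index(atom.n_hydrogens)] = 1
    return v


def decode_node(v: np.ndarray, schema: FeatureSchema) -> Atom:
    """Inverse of :func:`encode_node` on its image."""
    v = np.asarray(v)
    if v.shape != (schema.p,):
        raise MalformedTensorError(f"node vector has shape {v.shape}, expected ({schema.p},)")
    blocks = _split(v, [w for _, w in schema.node_blocks])
    el = _one_hot_index(blocks[0], "atom type")
    if el is None:
        raise MalformedTensorError("node vector has no atom-type bit set")
    qi = _one_hot_index(blocks[1], "formal charge")
    hi = _one_hot_index(blocks[2], "H count")
    return Atom(
        element=ELEMENTS[el],
        formal_charge=0 if qi is None else _NONZERO_CHARGES[qi],
        n_hydrogens=0 if hi is None else _NONZERO_HS[hi],
    )


def encode_edge(e: CompressedEdge, schema: FeatureSchema) -> np.ndarray:
    """One-hot encode an edge as a length-``q`` binary vector (never all-zero)."""
    v = np.zeros(schema.q, dtype=np.int8)
    if e.bond != NONE_BOND:
        v[BOND_ORDERS.index(e.bond)] = 1
    if len(e.pattern_counts) != len(schema.max_counts):
        raise DomainError(
            f"edge carries {len(e.pattern_counts)} counts, schema has "
            f"{len(schema.max_counts)} patterns"
        )
    offset = len(BOND_ORDERS)
    for count, cap in zip(e.pattern_counts, schema.max_counts):
        if count < 0 or count > cap:
            raise DomainError(f"pattern count {count} outside [0, {cap}]")
        if count > 0:
            v[offset + count - 1] = 1
        offset += cap
    if not v.any():
        raise DomainError("all-zero edge vector denotes 'no edge'; cannot encode")
    return v


def decode_edge(v: np.ndarray, endpoints: tuple[int, int], schema: FeatureSchema) -> CompressedEdge:
    """Inverse of :func:`encode_edge` on its image."""
    v = np.asarray(v)
    if v.shape != (schema.q,):
        raise MalformedTensorError(f"edge vector has shape {v.shape}, expected ({schema.q},)")
    blocks = _split(v, [w for _, w in schema.edge_blocks])
    bi = _one_hot_index(blocks[0], "bond type")
    bond = NONE_BOND if bi is None else BOND_ORDERS[bi]
    counts = []
    for block in blocks[1:]:
        ci = _one_hot_index(block, "pattern count")
        counts.append(0 if ci is None else ci + 1)
    return CompressedEdge(endpoints, bond, tuple(counts))


def _split(v: np.ndarray, widths: Sequence[int]) -> list[np.ndarray]:
    out, off = [], 0
    for w in widths:
        out.append(v[off : off + w])
        off += w
    return out


def _one_hot_index(block: np.ndarray, what: str) -> Optional[int]:
    nz = np.flatnonzero(block)
    if len(nz) == 0:
        return None
    if len(nz) > 1:
        raise MalformedTensorError(f"{what} block has {len(nz)} bits set")
    return int(nz[0])


@dataclass
class GraphTensors:
    """Dense binary encoding of one compressed graph."""

    node_matrix: np.ndarray  # (n, p)
    edge_tensor: np.ndarray  # (n, n, q), symmetric, zero diagonal
    schema: FeatureSchema

    @property
    def n_nodes(self) -> int:
        return int(self.node_matrix.shape[0])


def graph_to_tensors(cg: CompressedGraph, schema: FeatureSchema) -> GraphTensors:
    """Encode a compressed graph as its ``(V, E)`` tensor pair."""
    n = cg.n_nodes
    V = np.zeros((n, schema.p), dtype=np.int8)
    E = np.zeros((n, n, schema.q), dtype=np.int8)
    for i, atom in enumerate(cg.nodes):
        V[i] = encode_node(atom, schema)
    for e in cg.edges:
        i, j = e.endpoints
        vec = encode_edge(e, schema)
        E[i, j] = vec
        E[j, i] = vec
    return GraphTensors(node_matrix=V, edge_tensor=E, schema=schema)


def tensors_to_graph(t: GraphTensors, registry_id: Optional[str] = None) -> CompressedGraph:
    """Exact inverse of :func:`graph_to_tensors` on its image."""
    V, E, schema = t.node_matrix, t.edge_tensor, t.schema
    n = V.shape[0]
    if V.shape != (n, schema.p) or E.shape != (n, n, schema.q):
        raise MalformedTensorError(
            f"inconsistent shapes V{V.shape} / E{E.shape} for p={schema.p}, q={schema.q}"
        )
    if not np.array_equal(E, np.swapaxes(E, 0, 1)):
        bad = np.argwhere(E != np.swapaxes(E, 0, 1))[0]
        raise MalformedTensorError(f"edge tensor asymmetric at cell {tuple(bad[:2])}")
    diag = np.arange(n)
    if n and E[diag, diag].any():
        bad_i = int(np.flatnonzero(E[diag, diag].any(axis=1))[0])
        raise MalformedTensorError(f"edge tensor has a nonzero diagonal cell ({bad_i},{bad_i})")
    nodes = [decode_node(V[i], schema) for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if E[i, j].any():
                edges.append(decode_edge(E[i, j], (i, j), schema))
    return CompressedGraph(
        nodes=nodes,
        edges=edges,
        registry_id=registry_id if registry_id is not None else schema.registry_id,
    )


# ---------------------------------------------------------------------------
# Probabilistic decoding


@dataclass
class ProbabilisticGraph:
    """Raw category scores emitted by a generative decoder.

    ``node_scores`` has shape ``(n_max, node_score_width)`` and
    ``edge_scores`` has shape ``(n_max, n_max, edge_score_width)``; each block
    leads with its "none"/"absent" category.  Scores need not be normalized —
    only their ranking matters.
    """

    node_scores: np.ndarray
    edge_scores: np.ndarray

    @property
    def n_max(self) -> int:
        return int(self.node_scores.shape[0])


def decode_probabilistic(pg: ProbabilisticGraph, schema: FeatureSchema) -> CompressedGraph:
    """Node-wise and edge-wise argmax decoding of decoder scores.

    Per node and per block the top-scoring category wins, ties breaking toward
    the lowest index (so "none" wins exact ties).  Edge scores are symmetrized
    by averaging the ``(i, j)`` and ``(j, i)`` cells before the argmax.  Nodes
    decoded as absent are dropped and the survivors reindexed; all-none edges
    and edges at dropped nodes disappear.  The result is a structurally valid
    compressed graph that may still be chemically invalid — chemistry is
    judged downstream.
    """
    ns = np.asarray(pg.node_scores, dtype=float)
    es = np.asarray(pg.edge_scores, dtype=float)
    n_max = ns.shape[0]
    if ns.shape != (n_max, schema.node_score_width):
        raise MalformedTensorError(
            f"node scores have shape {ns.shape}, expected ({n_max}, {schema.node_score_width})"
        )
    if es.shape != (n_max, n_max, schema.edge_score_width):
        raise MalformedTensorError(
            f"edge scores have shape {es.shape}, expected "
            f"({n_max}, {n_max}, {schema.edge_score_width})"
        )
    if not (np.isfinite(ns).all() and np.isfinite(es).all()):
        raise MalformedTensorError("scores must be finite")

    node_widths = [1 + len(ELEMENTS), 1 + len(_NONZERO_CHARGES), 1 + len(_NONZERO_HS)]
    edge_widths = [1 + len(BOND_ORDERS)] + [1 + w for w in schema.max_counts]

    nodes: list[Atom] = []
    keep: list[int] = []
    for i in range(n_max):
        b_el, b_q, b_h = _split(ns[i], node_widths)
        el = int(np.argmax(b_el))
        if el == 0:  # absent node
            continue
        qi = int(np.argmax(b_q))
        hi = int(np.argmax(b_h))
        nodes.append(
            Atom(
                element=ELEMENTS[el - 1],
                formal_charge=0 if qi == 0 else _NONZERO_CHARGES[qi - 1],
                n_hydrogens=0 if hi == 0 else _NONZERO_HS[hi - 1],
                canonical_rank=len(nodes),
            )
        )
        keep.append(i)

    es = 0.5 * (es + np.swapaxes(es, 0, 1))
    edges: list[CompressedEdge] = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            blocks = _split(es[keep[a], keep[b]], edge_widths)
            bi = int(np.argmax(blocks[0]))
            counts = tuple(int(np.argmax(blk)) for blk in blocks[1:])
            if bi == 0 and not any(counts):
                continue  # all-none: no edge
            bond = NONE_BOND if bi == 0 else BOND_ORDERS[bi - 1]
            edges.append(CompressedEdge((a, b), bond, counts))
    return CompressedGraph(nodes=nodes, edges=edges, registry_id=schema.registry_id)


def embed_probabilistic(
    cg: CompressedGraph, schema: FeatureSchema, n_max: Optional[int] = None
) -> ProbabilisticGraph:
    """Exact one-hot scores for a compressed graph (decoding them is identity)."""
    n = cg.n_nodes
    if n_max is None:
        n_max = n
    if n_max < n:
        raise ValueError(f"n_max={n_max} smaller than graph ({n} nodes)")
    ns = np.zeros((n_max, schema.node_score_width))
    # Padding rows score 1 on every "none"/"absent" category.
    node_widths = [1 + len(ELEMENTS), 1 + len(_NONZERO_CHARGES), 1 + len(_NONZERO_HS)]
    edge_widths = [1 + len(BOND_ORDERS)] + [1 + w for w in schema.max_counts]
    for i in range(n_max):
        off = 0
        for w in node_widths:
            ns[i, off] = 1.0
            off += w
    for i, atom in enumerate(cg.nodes):
        off = 0
        ns[i, off] = 0.0
        ns[i, off + 1 + ELEMENTS.index(atom.element)] = 1.0
        off += node_widths[0]
        if atom.formal_charge != 0:
            ns[i, off] = 0.0
            ns[i, off + 1 + _NONZERO_CHARGES.index(atom.formal_charge)] = 1.0
        off += node_widths[1]
        if atom.n_hydrogens != 0:
            ns[i, off] = 0.0
            ns[i, off + 1 + _NONZERO_HS.index(atom.n_hydrogens)] = 1.0

    es = np.zeros((n_max, n_max, schema.edge_score_width))
    for i in range(n_max):
        for j in range(n_max):
            off = 0
            for w in edge_widths:
                es[i, j, off] = 1.0
                off += w
    for e in cg.edges:
        i, j = e.endpoints
        vec = np.zeros(schema.edge_score_width)
        off = 0
        if e.bond == NONE_BOND:
            vec[off] = 1.0
        else:
            vec[off + 1 + BOND_ORDERS.index(e.bond)] = 1.0
        off += edge_widths[0]
        for count, cap in zip(e.pattern_counts, schema.max_counts):
            vec[off if count == 0 else off + count] = 1.0
            off += 1 + cap
        es[i, j] = vec
        es[j, i] = vec
    return ProbabilisticGraph(node_scores=ns, edge_scores=es)


# ---------------------------------------------------------------------------
# Tensor bundle I/O (NumPy .npz container)


def save_bundle(
    path: str, tensors: Iterable[GraphTensors], molecule_ids: Optional[Sequence[str]] = None
) -> int:
    """Write a list of graph tensors to one ``.npz`` bundle."""
    arrays: dict[str, np.ndarray] = {}
    tensors = list(tensors)
    for t, tensor in enumerate(tensors):
        arrays[f"nodes_{t}"] = tensor.node_matrix
        arrays[f"edges_{t}"] = tensor.edge_tensor
    if tensors:
        schema = tensors[0].schema
        arrays["max_counts"] = np.array(schema.max_counts)
        arrays["registry"] = np.array(schema.registry_id)
    arrays["n_molecules"] = np.array(len(tensors))
    if molecule_ids is not None:
        arrays["molecule_ids"] = np.array(list(molecule_ids))
    np.savez_compressed(path, **arrays)
    return len(tensors)


def load_bundle(path: str) -> list[GraphTensors]:
    with np.load(path, allow_pickle=False) as data:
        n = int(data["n_molecules"])
        if n == 0:
            return []
        schema = FeatureSchema(
            max_counts=tuple(int(c) for c in data["max_counts"]),
            registry_id=str(data["registry"]),
        )
        return [
            GraphTensors(
                node_matrix=data[f"nodes_{t}"], edge_tensor=data[f"edges_{t}"], schema=schema
            )
            for t in range(n)
        ]
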