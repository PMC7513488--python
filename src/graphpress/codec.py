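"""Reversible graph compression: bridge substructures become edge features.

``compress`` finds every registered bridge occurrence, resolves overlaps by
canonical priority, deletes the accepted bridges' intermediate atoms and
records each conversion as a per-pattern count on the anchor-pair edge.
``decompress`` is its exact inverse: it re-inserts the counted intermediates
with the registry's atom specs and bond orders.  The round trip is lossless
for every encodable molecule — the codec's defining property.

Compressed graphs serialize to a JSON-lines interchange format (one molecule
per line)::

    {"nodes": [[element, charge, nH], ...],
     "edges": [[i, j, bond, [c1, ..., cK]], ...],
     "registry": "default-6", "smiles": "..."}

with 0-based node indices, ``bond`` one of ``single|double|triple|none`` and
``ck`` the conversion count of pattern ``k`` on that edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .chemgraph import (
    Atom,
    BOND_ORDERS,
    MolecularGraph,
    canonical_ranks,
    relabeled,
    validate_features,
    write_smiles,
)
from .errors import DecompressError, DomainError
from .patterns import PatternMatch, PatternRegistry, find_matches

#: Edge marker for anchor pairs held together only by converted bridges.
NONE_BOND = "none"

FORMAT_VERSION = 1


@dataclass
class CompressedEdge:
    """An edge of the compressed graph: a bond and/or converted-bridge counts."""

    endpoints: tuple[int, int]  # lower retained-order index first
    bond: str  # single|double|triple|none
    pattern_counts: tuple[int, ...]  # indexed by pattern_id - 1

    def __post_init__(self) -> None:
        if self.bond not in BOND_ORDERS and self.bond != NONE_BOND:
            raise DomainError(f"unknown bond type {self.bond!r}")
        if self.bond == NONE_BOND and not any(self.pattern_counts):
            raise DomainError("an edge must carry a bond or at least one pattern count")


@dataclass
class CompressedGraph:
    """A molecular graph after bridge-to-edge substitution.

    Nodes are the surviving atoms in their original relative order; the node
    count never exceeds that of the source graph.
    """

    nodes: list[Atom]
    edges: list[CompressedEdge] = field(default_factory=list)
    registry_id: str = "default-6"
    provenance: Optional[str] = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_between(self, i: int, j: int) -> Optional[CompressedEdge]:
        key = (min(i, j), max(i, j))
        for e in self.edges:
            if e.endpoints == key:
                return e
        return None


def resolve_overlaps(
    matches: list[PatternMatch], reg: PatternRegistry
) -> list[PatternMatch]:
    """Greedy sequential overlap resolution in priority order.

    ``matches`` must be sorted by priority key (as :func:`find_matches`
    returns them).  A match is accepted iff none of its atoms has been deleted
    by an earlier acceptance, none of its intermediates already serves as the
    endpoint of a converted edge (deleting it would orphan that edge), and
    the pattern's per-anchor-pair count cap is not exceeded.
    """
    consumed: set[int] = set()
    anchored: set[int] = set()
    counts: dict[tuple[tuple[int, int], int], int] = {}
    accepted: list[PatternMatch] = []
    for m in matches:
        if any(n in consumed for n in m.intermediate_nodes):
            continue
        if any(n in anchored for n in m.intermediate_nodes):
            continue
        if any(a in consumed for a in m.anchors):
            continue
        key = (m.anchors, m.pattern_id)
        if counts.get(key, 0) >= reg[m.pattern_id].max_count:
            continue
        counts[key] = counts.get(key, 0) + 1
        consumed.update(m.intermediate_nodes)
        anchored.update(m.anchors)
        accepted.append(m)
    return accepted


def compress(g: MolecularGraph, reg: PatternRegistry) -> CompressedGraph:
    """Apply bridge-to-edge substitution; deterministic for a given molecule."""
    violations = validate_features(g)
    if violations:
        v = violations[0]
        raise DomainError(f"atom {v.atom_index}: {v.message} (value {v.value!r})")

    # Work in canonical-rank node order so the stored edge endpoint order
    # (lower retained index first) coincides with the matcher's orientation
    # convention (lower canonical rank first); graphs from parse_smiles are
    # already ordered this way.  This also makes the serialized output
    # byte-identical across input atom relabelings.
    ranks = canonical_ranks(g)
    if ranks != list(range(g.n_atoms)):
        g = relabeled(g, ranks)
        ranks = list(range(g.n_atoms))
    accepted = resolve_overlaps(find_matches(g, reg, ranks=ranks), reg)

    deleted = {n for m in accepted for n in m.intermediate_nodes}
    survivors = [i for i in range(g.n_atoms) if i not in deleted]
    new_index = {old: new for new, old in enumerate(survivors)}

    records: dict[tuple[int, int], tuple[str, list[int]]] = {}

    def record(i: int, j: int, bond: str) -> tuple[str, list[int]]:
        key = (min(i, j), max(i, j))
        if key not in records:
            records[key] = (bond, [0] * len(reg))
        return records[key]

    # Untouched bonds (both endpoints survive) carry over unchanged.  Bonds of
    # a deleted intermediate are consumed by its match path by construction.
    for (i, j), order in sorted(g.bonds.items()):
        if i in deleted or j in deleted:
            continue
        record(new_index[i], new_index[j], order)

    for m in accepted:
        i, j = (new_index[m.anchors[0]], new_index[m.anchors[1]])
        direct = g.bond_order(m.anchors[0], m.anchors[1])
        _, counts = record(i, j, direct if direct is not None else NONE_BOND)
        counts[m.pattern_id - 1] += 1

    return CompressedGraph(
        nodes=[g.atoms[i] for i in survivors],
        edges=[
            CompressedEdge(key, bond, tuple(counts))
            for key, (bond, counts) in sorted(records.items())
        ],
        registry_id=reg.registry_id,
        provenance=write_smiles(g),
    )


def decompress(cg: CompressedGraph, reg: PatternRegistry) -> MolecularGraph:
    """Exact inverse of :func:`compress`.

    Re-inserted intermediates are appended after the existing nodes; for
    asymmetric patterns the first intermediate attaches to the edge endpoint
    with the smaller retained-order index, mirroring the matcher's canonical
    orientation.
    """
    g = MolecularGraph(atoms=list(cg.nodes), source_smiles=None)
    for e in cg.edges:
        if len(e.pattern_counts) != len(reg):
            raise DecompressError(
                f"edge {e.endpoints}: {len(e.pattern_counts)} pattern counts for a "
                f"{len(reg)}-pattern registry"
            )
        if e.bond != NONE_BOND:
            g.add_bond(e.endpoints[0], e.endpoints[1], e.bond)
        for pid_minus1, count in enumerate(e.pattern_counts):
            if count == 0:
                continue
            pattern = reg[pid_minus1 + 1]
            if count > pattern.max_count:
                raise DecompressError(
                    f"edge {e.endpoints}: pattern {pattern.pattern_id} count {count} "
                    f"exceeds cap {pattern.max_count} (registry mismatch?)"
                )
            for _ in range(count):
                chain = [e.endpoints[0]]
                for spec in pattern.intermediates:
                    g.atoms.append(
                        Atom(
                            element=spec.element,
                            formal_charge=spec.formal_charge,
                            n_hydrogens=spec.n_hydrogens,
                            canonical_rank=len(g.atoms),
                        )
                    )
                    chain.append(len(g.atoms) - 1)
                chain.append(e.endpoints[1])
                for k in range(len(chain) - 1):
                    g.add_bond(chain[k], chain[k + 1], pattern.bond_orders[k])
    return g


@dataclass
class RoundTripReport:
    ok: bool
    original_smiles: str
    restored_smiles: str
    detail: str = ""


def roundtrip_check(g: MolecularGraph, reg: PatternRegistry) -> RoundTripReport:
    """Verify ``decompress(compress(g))`` restores the same molecule."""
    original = write_smiles(g)
    try:
        restored = write_smiles(decompress(compress(g, reg), reg))
    except Exception as exc:  # noqa: BLE001 - report, don't mask, codec failures
        return RoundTripReport(False, original, "", detail=f"codec error: {exc}")
    if restored == original:
        return RoundTripReport(True, original, restored)
    return RoundTripReport(
        False, original, restored, detail="canonical SMILES differ after round trip"
    )


# ---------------------------------------------------------------------------
# JSON-lines interchange format


def to_json_record(cg: CompressedGraph) -> str:
    """One-line JSON serialization (deterministic field and edge order)."""
    obj = {
        "nodes": [[a.element, a.formal_charge, a.n_hydrogens] for a in cg.nodes],
        "edges": [
            [e.endpoints[0], e.endpoints[1], e.bond, list(e.pattern_counts)]
            for e in sorted(cg.edges, key=lambda e: e.endpoints)
        ],
        "registry": cg.registry_id,
        "version": FORMAT_VERSION,
    }
    if cg.provenance is not None:
        obj["smiles"] = cg.provenance
    return json.dumps(obj, separators=(",", ":"))


def from_json_record(line: str) -> CompressedGraph:
    try:
        obj = json.loads(line)
        nodes = [
            Atom(element=el, formal_charge=int(q), n_hydrogens=int(nh), canonical_rank=i)
            for i, (el, q, nh) in enumerate(obj["nodes"])
        ]
        edges = [
            CompressedEdge((int(i), int(j)), bond, tuple(int(c) for c in counts))
            for i, j, bond, counts in obj["edges"]
        ]
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise DecompressError(f"malformed compressed-graph record: {exc}") from exc
    return CompressedGraph(
        nodes=nodes,
        edges=edges,
        registry_id=obj.get("registry", "unknown"),
        provenance=obj.get("smiles"),
    )


def write_jsonl(path: str, graphs: Iterable[CompressedGraph]) -> int:
    n = 0
    with open(path, "w") as fh:
        for cg in graphs:
            fh.write(to_json_record(cg) + "\n")
            n += 1
    return n


def read_jsonl(path: str) -> Iterable[CompressedGraph]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield from_json_record(line)
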