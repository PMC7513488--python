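"""Independent brute-force oracles used to cross-check the matcher and codec.

These deliberately avoid the library's matching code paths: occurrences are
found by exhaustive simple-path enumeration over all node pairs, and overlap
resolution is simulated on an explicitly mutated atom set.
"""

from __future__ import annotations

from graphpress.chemgraph import MolecularGraph, canonical_ranks
from graphpress.patterns import PatternRegistry


def brute_force_matches(g: MolecularGraph, reg: PatternRegistry) -> set[tuple]:
    """All pattern occurrences by exhaustive path enumeration.

    Returns tuples ``(pattern_id, anchors, intermediates)`` in the canonical
    storage orientation (anchors rank-ordered, intermediates running from the
    lower-ranked anchor).
    """
    ranks = canonical_ranks(g)
    adj = g.adjacency()
    degree = {i: len(ns) for i, ns in adj.items()}
    found: set[tuple] = set()

    # Enumerate every ordered simple path of 3 or 4 nodes.
    paths = []
    for a in range(g.n_atoms):
        for m1 in adj[a]:
            for b in adj[m1]:
                if b not in (a, m1):
                    paths.append((a, m1, b))
                for m2 in adj[m1]:
                    if m2 in (a, m1):
                        continue
                    for c in adj[m2]:
                        if c not in (a, m1, m2):
                            paths.append((a, m1, m2, c))

    for path in paths:
        a, b = path[0], path[-1]
        if ranks[a] > ranks[b]:
            continue  # the reversed traversal covers it
        mids = path[1:-1]
        for pattern in reg.patterns:
            if len(mids) != pattern.n_intermediates:
                continue
            if any(degree[m] != 2 for m in mids):
                continue
            if tuple(
                g.bond_order(path[k], path[k + 1]) for k in range(len(path) - 1)
            ) != pattern.bond_orders:
                continue
            specs_ok = all(
                spec.matches(
                    g.atoms[m].element, g.atoms[m].n_hydrogens, g.atoms[m].formal_charge
                )
                for m, spec in zip(mids, pattern.intermediates)
            )
            if specs_ok:
                found.add((pattern.pattern_id, (a, b), mids))
    return found


def simulate_sequential_resolution(
    g: MolecularGraph, reg: PatternRegistry
) -> list[tuple]:
    """Sequential conversion of bridges in canonical priority order.

    Works on an explicitly mutated structure: converting a bridge removes its
    intermediate atoms and marks its anchors as endpoints of a compressed
    edge.  A later occurrence can only convert if all its atoms still exist,
    none of its intermediates is such an endpoint, and the per-pair count cap
    of its pattern still has room.
    """
    ranks = canonical_ranks(g)
    candidates = sorted(
        brute_force_matches(g, reg),
        key=lambda t: (
            tuple(sorted(ranks[n] for n in (t[1][0], *t[2], t[1][1]))),
            t[0],
            t[1],
            t[2],
        ),
    )
    present = set(range(g.n_atoms))
    compressed_endpoints: set[int] = set()
    cap_used: dict[tuple, int] = {}
    converted = []
    for pid, anchors, mids in candidates:
        atoms = {anchors[0], anchors[1], *mids}
        if not atoms <= present:
            continue
        if any(m in compressed_endpoints for m in mids):
            continue
        key = (anchors, pid)
        if cap_used.get(key, 0) >= reg[pid].max_count:
            continue
        present -= set(mids)
        compressed_endpoints |= set(anchors)
        cap_used[key] = cap_used.get(key, 0) + 1
        converted.append((pid, anchors, mids))
    return converted
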