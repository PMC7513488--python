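"""Bridge-pattern registry and substructure matching.

A *bridge* is a path of one or two degree-2 heavy atoms (the intermediates)
connecting two anchor atoms.  The default registry designates the six bridges
that dominate drug-like molecules once aromatic rings are kekulized:

==  ==============  ============  ===============  =========
id  bridge          bond orders   intermediates    max count
==  ==============  ============  ===============  =========
1   ``-NH-``        s, s          N (1 H)          3
2   ``-O-``         s, s          O (0 H)          3
3   ``-CH2-CH2-``   s, s, s       C (2 H) x2       2
4   ``-CH=CH-``     s, d, s       C (1 H) x2       1
5   ``-CH2-CH=``    s, s, d       C (2 H), C (1 H) 2
6   ``=N-``         d, s          N (0 H)          1
==  ==============  ============  ===============  =========

The max count caps how many simultaneous occurrences between one anchor pair
the edge feature vector can encode (it fixes the one-hot width downstream).
Patterns 5 and 6 are asymmetric: reading the bridge from the other anchor
gives a different bond-order sequence, and only occurrences whose canonical
orientation (read from the anchor with the smaller canonical rank) matches
the registered sequence are eligible for conversion — a count cannot record
orientation.

Custom registries can be loaded from a small JSON config; in strict mode the
intermediates are restricted to C, N and O, which suffice in practice.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional

from .chemgraph import BOND_ORDERS, DOUBLE, SINGLE, MolecularGraph, canonical_ranks
from .errors import ConfigError

logger = logging.getLogger(__name__)

#: Elements allowed as bridge intermediates in strict mode.
STRICT_INTERMEDIATE_ELEMENTS = ("C", "N", "O")


@dataclass(frozen=True)
class AtomSpec:
    """Required features of one bridge intermediate atom."""

    element: str
    n_hydrogens: int
    formal_charge: int = 0

    def matches(self, element: str, n_hydrogens: int, formal_charge: int) -> bool:
        return (
            element == self.element
            and n_hydrogens == self.n_hydrogens
            and formal_charge == self.formal_charge
        )


@dataclass(frozen=True)
class BridgePattern:
    """One designated bridge substructure.

    ``bond_orders`` runs along the path anchor-intermediate(s)-anchor and has
    length ``len(intermediates) + 1``.
    """

    pattern_id: int
    intermediates: tuple[AtomSpec, ...]
    bond_orders: tuple[str, ...]
    max_count: int
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.intermediates) not in (1, 2):
            raise ConfigError(
                f"pattern {self.pattern_id}: bridges contain one or two heavy atoms, "
                f"got {len(self.intermediates)}"
            )
        if len(self.bond_orders) != len(self.intermediates) + 1:
            raise ConfigError(
                f"pattern {self.pattern_id}: need {len(self.intermediates) + 1} bond "
                f"orders, got {len(self.bond_orders)}"
            )
        for o in self.bond_orders:
            if o not in BOND_ORDERS:
                raise ConfigError(f"pattern {self.pattern_id}: unknown bond order {o!r}")
        if self.max_count < 1:
            raise ConfigError(f"pattern {self.pattern_id}: max_count must be >= 1")

    @property
    def symmetric(self) -> bool:
        """True when the reversed bridge describes the same pattern."""
        return (
            self.intermediates == self.intermediates[::-1]
            and self.bond_orders == self.bond_orders[::-1]
        )

    @property
    def n_intermediates(self) -> int:
        return len(self.intermediates)


@dataclass(frozen=True)
class PatternRegistry:
    """Ordered collection of bridge patterns with contiguous ids from 1."""

    patterns: tuple[BridgePattern, ...]
    registry_id: str = "custom"

    def __post_init__(self) -> None:
        ids = [p.pattern_id for p in self.patterns]
        if ids != list(range(1, len(ids) + 1)):
            raise ConfigError(f"pattern ids must be contiguous from 1, got {ids}")

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, pattern_id: int) -> BridgePattern:
        if not 1 <= pattern_id <= len(self.patterns):
            raise KeyError(f"no pattern with id {pattern_id}")
        return self.patterns[pattern_id - 1]

    @property
    def edge_feature_width(self) -> int:
        """Total one-hot width contributed by pattern counts (12 by default)."""
        return sum(p.max_count for p in self.patterns)

    @property
    def max_counts(self) -> tuple[int, ...]:
        return tuple(p.max_count for p in self.patterns)


def load_default_registry() -> PatternRegistry:
    """The six designated bridge patterns (see module docstring)."""
    C2H = AtomSpec("C", 2)
    C1H = AtomSpec("C", 1)
    return PatternRegistry(
        patterns=(
            BridgePattern(1, (AtomSpec("N", 1),), (SINGLE, SINGLE), 3, "amine -NH-"),
            BridgePattern(2, (AtomSpec("O", 0),), (SINGLE, SINGLE), 3, "ether -O-"),
            BridgePattern(3, (C2H, C2H), (SINGLE, SINGLE, SINGLE), 2, "ethylene -CH2-CH2-"),
            BridgePattern(4, (C1H, C1H), (SINGLE, DOUBLE, SINGLE), 1, "vinylene -CH=CH-"),
            BridgePattern(5, (C2H, C1H), (SINGLE, SINGLE, DOUBLE), 2, "allyl -CH2-CH="),
            BridgePattern(6, (AtomSpec("N", 0),), (DOUBLE, SINGLE), 1, "aza =N-"),
        ),
        registry_id="default-6",
    )


def load_registry(path: str, strict: bool = True) -> PatternRegistry:
    """Load a registry from a JSON config file.

    Schema: ``{"registry_id": str, "patterns": [{"id": int, "intermediates":
    [[element, n_hydrogens, formal_charge], ...], "bond_orders": [str, ...],
    "max_count": int, "name": str?}, ...]}``.  In strict mode intermediates
    must be C, N or O; otherwise out-of-set elements only warn.
    """
    try:
        with open(path) as fh:
            cfg = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read registry config {path!r}: {exc}") from exc
    try:
        patterns = []
        seen_ids = set()
        for p in cfg["patterns"]:
            if p["id"] in seen_ids:
                raise ConfigError(f"duplicate pattern id {p['id']}")
            seen_ids.add(p["id"])
            specs = tuple(AtomSpec(el, int(nh), int(q)) for el, nh, q in p["intermediates"])
            for spec in specs:
                if spec.element not in STRICT_INTERMEDIATE_ELEMENTS:
                    msg = (
                        f"pattern {p['id']}: intermediate element {spec.element!r} "
                        f"outside {STRICT_INTERMEDIATE_ELEMENTS}"
                    )
                    if strict:
                        raise ConfigError(msg)
                    warnings.warn(msg, stacklevel=2)
            patterns.append(
                BridgePattern(
                    pattern_id=int(p["id"]),
                    intermediates=specs,
                    bond_orders=tuple(p["bond_orders"]),
                    max_count=int(p["max_count"]),
                    name=p.get("name", ""),
                )
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed registry config {path!r}: {exc}") from exc
    return PatternRegistry(
        patterns=tuple(sorted(patterns, key=lambda p: p.pattern_id)),
        registry_id=str(cfg.get("registry_id", "custom")),
    )


def save_registry(reg: PatternRegistry, path: str) -> None:
    """Write a registry as the JSON config accepted by :func:`load_registry`."""
    cfg = {
        "registry_id": reg.registry_id,
        "patterns": [
            {
                "id": p.pattern_id,
                "intermediates": [
                    [s.element, s.n_hydrogens, s.formal_charge] for s in p.intermediates
                ],
                "bond_orders": list(p.bond_orders),
                "max_count": p.max_count,
                "name": p.name,
            }
            for p in reg.patterns
        ],
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2)
        fh.write("\n")


@dataclass(frozen=True)
class PatternMatch:
    """One occurrence of a bridge pattern in a molecular graph.

    ``anchors`` is ordered with the lower *canonical rank* first and
    ``intermediate_nodes`` runs along the path from ``anchors[0]``.
    ``priority_key`` is the ascending tuple of canonical ranks of all atoms of
    the match; comparing overlapping matches by this key implements the rule
    that the match whose non-overlapping atoms have the smaller canonical
    numbers is converted first (shared atoms contribute equal prefix entries).
    """

    pattern_id: int
    anchors: tuple[int, int]
    intermediate_nodes: tuple[int, ...]
    priority_key: tuple[int, ...]

    @property
    def atoms(self) -> tuple[int, ...]:
        return (self.anchors[0], *self.intermediate_nodes, self.anchors[1])


def match_priority(m: PatternMatch) -> tuple[int, ...]:
    """Sorted canonical ranks of the match's atoms (its conversion priority)."""
    return m.priority_key


def _specs_match(
    g: MolecularGraph, nodes: tuple[int, ...], specs: tuple[AtomSpec, ...]
) -> bool:
    return all(
        spec.matches(g.atoms[n].element, g.atoms[n].n_hydrogens, g.atoms[n].formal_charge)
        for n, spec in zip(nodes, specs)
    )


def find_matches(
    g: MolecularGraph,
    reg: PatternRegistry,
    ranks: Optional[list[int]] = None,
) -> list[PatternMatch]:
    """Every occurrence of every registered pattern in ``g``.

    Intermediates must have degree exactly 2 (no substituents: they are
    deleted by compression).  Each occurrence is reported once per unordered
    anchor pair; for asymmetric patterns only the canonical orientation (read
    from the anchor with the smaller canonical rank) is reported, because a
    bare count on an edge cannot record which way a bridge pointed.  The list
    is sorted by ``priority_key``, ties broken by ``pattern_id`` and path.
    """
    if ranks is None:
        ranks = canonical_ranks(g)
    adj = g.adjacency()
    degree = {i: len(ns) for i, ns in adj.items()}
    matches: list[PatternMatch] = []

    def path_orders(nodes: tuple[int, ...]) -> tuple[str, ...]:
        return tuple(
            g.bond_order(nodes[k], nodes[k + 1])  # type: ignore[misc]
            for k in range(len(nodes) - 1)
        )

    def emit(pattern: BridgePattern, a: int, b: int, mids: tuple[int, ...]) -> None:
        # Canonical storage: anchors ordered by canonical rank, intermediates
        # running from the lower-ranked anchor (permutation invariant).
        if ranks[a] > ranks[b]:
            a, b = b, a
            mids = mids[::-1]
        path = (a, *mids, b)
        if path_orders(path) != pattern.bond_orders:
            return
        if not _specs_match(g, mids, pattern.intermediates):
            return
        matches.append(
            PatternMatch(
                pattern_id=pattern.pattern_id,
                anchors=(a, b),
                intermediate_nodes=mids,
                priority_key=tuple(sorted(ranks[n] for n in path)),
            )
        )

    for pattern in reg.patterns:
        if pattern.n_intermediates == 1:
            spec = pattern.intermediates[0]
            for m in range(g.n_atoms):
                if degree[m] != 2:
                    continue
                atom = g.atoms[m]
                if not spec.matches(atom.element, atom.n_hydrogens, atom.formal_charge):
                    continue
                a, b = adj[m]
                if a == b:  # impossible (no parallel bonds), kept for clarity
                    continue
                emit(pattern, a, b, (m,))
        else:
            for (m1, m2), _order in sorted(g.bonds.items()):
                if degree[m1] != 2 or degree[m2] != 2:
                    continue
                a = next(n for n in adj[m1] if n != m2)
                b = next(n for n in adj[m2] if n != m1)
                if a == b or a in (m1, m2) or b in (m1, m2):
                    continue  # 3- or 4-ring closing back: anchors must be distinct
                emit(pattern, a, b, (m1, m2))

    # Ties on the rank key are possible for matches over one atom set (same
    # pattern with anchor/intermediate roles swapped, or different patterns);
    # break by pattern id, then by the stored path, for full determinism.
    matches.sort(
        key=lambda m: (m.priority_key, m.pattern_id, m.anchors, m.intermediate_nodes)
    )
    return matches
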