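"""Molecule <-> graph conversion, canonical atom ordering, and SMILES/SDF I/O.

A molecule is held as an undirected heavy-atom graph: hydrogens are folded
into a per-atom count, aromatic rings are kekulized on input so every bond
has an explicit integer order, and stereochemistry is discarded.  The node
feature domains are deliberately narrow — 12 elements, formal charges in
{-1, 0, 1, 2, 3}, hydrogen counts in {0..3} — because every atom must be
expressible as a fixed-width one-hot vector downstream.

Atoms of a parsed molecule are stored in canonical-rank order (rank == index),
so the priority rules of the compression codec and the orientation convention
of decompression coincide for every graph produced by :func:`parse_smiles`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import DomainError, FragmentError, ParseError

logger = logging.getLogger(__name__)

# RDKit is chatty about rejected molecules; errors are surfaced as exceptions.
RDLogger.DisableLog("rdApp.*")

#: The encodable elements, in one-hot slot order.
ELEMENTS: tuple[str, ...] = ("B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I")
#: Encodable formal charges (0 is the implicit all-zero category).
CHARGES: tuple[int, ...] = (-1, 0, 1, 2, 3)
#: Encodable attached-hydrogen counts (0 is the implicit all-zero category).
H_COUNTS: tuple[int, ...] = (0, 1, 2, 3)

SINGLE = "single"
DOUBLE = "double"
TRIPLE = "triple"
#: Bond orders an edge of the molecular graph may carry.
BOND_ORDERS: tuple[str, ...] = (SINGLE, DOUBLE, TRIPLE)

_RDKIT_BOND = {
    SINGLE: Chem.BondType.SINGLE,
    DOUBLE: Chem.BondType.DOUBLE,
    TRIPLE: Chem.BondType.TRIPLE,
}
_FROM_RDKIT_BOND = {v: k for k, v in _RDKIT_BOND.items()}


@dataclass(frozen=True)
class Atom:
    """A heavy atom with its encodable features.

    ``n_hydrogens`` is the total number of attached hydrogens (implicit plus
    explicit) of the heavy atom; hydrogens are never nodes of the graph.
    """

    element: str
    formal_charge: int = 0
    n_hydrogens: int = 0
    canonical_rank: int = 0


@dataclass(frozen=True)
class Violation:
    """One atom feature outside the encodable domain."""

    atom_index: int
    feature: str
    value: object
    message: str


@dataclass
class MolecularGraph:
    """Undirected heavy-atom graph with implicit hydrogens.

    ``bonds`` maps an index pair ``(i, j)`` with ``i < j`` to a bond order in
    :data:`BOND_ORDERS`.  Self-loops and parallel bonds are impossible by
    construction of the key.
    """

    atoms: list[Atom]
    bonds: dict[tuple[int, int], str] = field(default_factory=dict)
    source_smiles: Optional[str] = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def degree(self, i: int) -> int:
        return sum(1 for (a, b) in self.bonds if a == i or b == i)

    def bond_order(self, i: int, j: int) -> Optional[str]:
        return self.bonds.get((min(i, j), max(i, j)))

    def add_bond(self, i: int, j: int, order: str) -> None:
        if i == j:
            raise ValueError("self-loops are not allowed")
        if order not in _RDKIT_BOND:
            raise ValueError(f"unknown bond order {order!r}")
        self.bonds[(min(i, j), max(i, j))] = order

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for (a, b) in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass(frozen=True)
class PropertyVector:
    """Real-valued molecular properties carried alongside a structure."""

    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.values)


def _check_domains(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ELEMENTS:
            raise DomainError(
                f"atom {atom.GetIdx()}: element {sym!r} is not encodable "
                f"(allowed: {', '.join(ELEMENTS)})"
            )
        if atom.GetFormalCharge() not in CHARGES:
            raise DomainError(
                f"atom {atom.GetIdx()} ({sym}): formal charge "
                f"{atom.GetFormalCharge()} outside {CHARGES}"
            )
        if atom.GetTotalNumHs() not in H_COUNTS:
            raise DomainError(
                f"atom {atom.GetIdx()} ({sym}): {atom.GetTotalNumHs()} attached "
                f"hydrogens outside {H_COUNTS}"
            )
        if atom.GetNumRadicalElectrons() != 0:
            raise DomainError(
                f"atom {atom.GetIdx()} ({sym}): radical electrons are not encodable"
            )


def parse_smiles(s: str) -> MolecularGraph:
    """Parse a SMILES string into a kekulized, canonically ordered graph.

    Stereochemistry is discarded.  Raises :class:`ParseError` for syntactically
    invalid input, :class:`FragmentError` for multi-fragment input and
    :class:`DomainError` when an atom lies outside the encodable domains.
    """
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ParseError(f"invalid SMILES: {s!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise FragmentError(f"molecule has multiple fragments: {s!r}")
    Chem.RemoveStereochemistry(mol)
    _check_domains(mol)

    # Renumber so node index == canonical rank, then kekulize; the kekule
    # assignment is therefore a deterministic function of the molecule alone.
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = sorted(range(mol.GetNumAtoms()), key=lambda i: ranks[i])
    mol = Chem.RenumberAtoms(mol, order)
    Chem.Kekulize(mol, clearAromaticFlags=True)

    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
            canonical_rank=a.GetIdx(),
        )
        for a in mol.GetAtoms()
    ]
    g = MolecularGraph(atoms=atoms, source_smiles=s)
    for bond in mol.GetBonds():
        order_name = _FROM_RDKIT_BOND.get(bond.GetBondType())
        if order_name is None:  # pragma: no cover - kekulize guarantees integer orders
            raise DomainError(f"unencodable bond type {bond.GetBondType()}")
        g.add_bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order_name)
    return g


def to_rdkit(g: MolecularGraph, sanitize: bool = True) -> Chem.Mol:
    """Rebuild an RDKit molecule from a graph (explicit H counts, no stereo)."""
    rw = Chem.RWMol()
    for atom in g.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNumExplicitHs(atom.n_hydrogens)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for (i, j), order in sorted(g.bonds.items()):
        rw.AddBond(i, j, _RDKIT_BOND[order])
    mol = rw.GetMol()
    if sanitize:
        Chem.SanitizeMol(mol)
    return mol


def write_smiles(g: MolecularGraph) -> str:
    """Canonical (stereo-free, aromatic-perceived) SMILES of a graph."""
    return Chem.MolToSmiles(to_rdkit(g))


def canonical_ranks(g: MolecularGraph) -> list[int]:
    """Deterministic, permutation-invariant atom ranking (a bijection onto 0..n-1).

    Graphs produced by :func:`parse_smiles` satisfy ``canonical_ranks(g)[i] == i``.
    """
    mol = to_rdkit(g)
    return list(Chem.CanonicalRankAtoms(mol, breakTies=True))


def relabeled(g: MolecularGraph, perm: Sequence[int]) -> MolecularGraph:
    """Return a copy with atom ``i`` moved to position ``perm[i]`` (test helper)."""
    n = g.n_atoms
    perm = [int(x) for x in perm]
    if sorted(perm) != list(range(n)):
        raise ValueError("perm must be a permutation of 0..n-1")
    atoms: list[Optional[Atom]] = [None] * n
    for i, a in enumerate(g.atoms):
        atoms[perm[i]] = a
    out = MolecularGraph(atoms=list(atoms), source_smiles=g.source_smiles)  # type: ignore[arg-type]
    for (i, j), order in g.bonds.items():
        out.add_bond(perm[i], perm[j], order)
    return out


def validate_features(g: MolecularGraph) -> list[Violation]:
    """Report every atom feature outside the encodable domains (empty == encodable)."""
    out: list[Violation] = []
    for i, atom in enumerate(g.atoms):
        if atom.element not in ELEMENTS:
            out.append(Violation(i, "element", atom.element, "element not encodable"))
        if atom.formal_charge not in CHARGES:
            out.append(
                Violation(i, "formal_charge", atom.formal_charge, f"charge outside {CHARGES}")
            )
        if atom.n_hydrogens not in H_COUNTS:
            out.append(
                Violation(i, "n_hydrogens", atom.n_hydrogens, f"H count outside {H_COUNTS}")
            )
    return out


# ---------------------------------------------------------------------------
# Streaming file I/O


@dataclass
class ReadSummary:
    n_read: int = 0
    n_skipped: int = 0


def read_smiles_file(
    path: str,
    strict: bool = False,
    summary: Optional[ReadSummary] = None,
) -> Iterator[tuple[MolecularGraph, Optional[PropertyVector]]]:
    """Stream ``(graph, properties)`` pairs from a SMILES file.

    One molecule per line; optional tab-separated numeric columns after the
    SMILES become a :class:`PropertyVector`.  Lines starting with ``#`` and
    blank lines are ignored.  Malformed records are logged and skipped unless
    ``strict`` is set, in which case the first error aborts the stream.
    """
    if summary is None:
        summary = ReadSummary()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                graph = parse_smiles(fields[0])
                props = (
                    PropertyVector(tuple(float(x) for x in fields[1:])) if len(fields) > 1 else None
                )
            except (ParseError, FragmentError, DomainError, ValueError) as exc:
                if strict:
                    raise
                summary.n_skipped += 1
                logger.warning("%s:%d: skipped record: %s", path, lineno, exc)
                continue
            summary.n_read += 1
            yield graph, props


def read_sdf(
    path: str,
    strict: bool = False,
    summary: Optional[ReadSummary] = None,
) -> Iterator[tuple[MolecularGraph, Optional[PropertyVector]]]:
    """Stream graphs from an SDF (V2000) file; records are converted via SMILES."""
    if summary is None:
        summary = ReadSummary()
    supplier = Chem.SDMolSupplier(path, sanitize=True)
    for idx, mol in enumerate(supplier):
        try:
            if mol is None:
                raise ParseError(f"unreadable SDF record {idx}")
            graph = parse_smiles(Chem.MolToSmiles(mol))
        except (ParseError, FragmentError, DomainError) as exc:
            if strict:
                raise
            summary.n_skipped += 1
            logger.warning("%s: record %d skipped: %s", path, idx, exc)
            continue
        summary.n_read += 1
        yield graph, None


def write_smiles_file(path: str, graphs: Iterable[MolecularGraph]) -> int:
    """Write canonical SMILES, one per line; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(write_smiles(g) + "\n")
            n += 1
    return n
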