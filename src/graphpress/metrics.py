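"""Distribution-learning metrics and corpus compression statistics.

Validity / uniqueness / novelty follow the GuacaMol distribution-learning
definitions: a generated graph is *valid* iff RDKit can parse and sanitize
it; *uniqueness* is the fraction of valid graphs that are distinct;
*novelty* is the fraction of valid graphs absent from the training set.
Uniqueness and novelty are computed over the valid subset (not over all
generated graphs), and duplicates are defined by stereo-stripped canonical
SMILES equality.

``compression_stats`` streams a corpus through the codec and accumulates the
node-count reduction and per-pattern bridge frequencies without holding the
corpus in memory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from rdkit import Chem

from .chemgraph import MolecularGraph, write_smiles
from .codec import compress, resolve_overlaps
from .errors import EmptyInputError, GraphPressError
from .patterns import PatternRegistry, find_matches


def canonicalize(smiles: str) -> Optional[str]:
    """Stereo-stripped canonical SMILES, or None if RDKit rejects the input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class GenerationMetrics:
    validity: float
    uniqueness: float
    novelty: float
    n_total: int
    n_valid: int

    def to_dict(self) -> dict:
        return {
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "n_total": self.n_total,
            "n_valid": self.n_valid,
        }


def validity(outputs: Iterable[Union[str, MolecularGraph]]) -> tuple[float, list[str]]:
    """Fraction of outputs RDKit sanitizes, plus their canonical SMILES.

    Accepts SMILES strings or molecular graphs (graphs are rendered to SMILES
    first; a graph whose SMILES RDKit then rejects counts as invalid).
    """
    outputs = list(outputs)
    if not outputs:
        raise EmptyInputError("validity of an empty list is undefined")
    valid: list[str] = []
    for out in outputs:
        if isinstance(out, MolecularGraph):
            try:
                out = write_smiles(out)
            except Exception:  # noqa: BLE001 - unsanitizable graph == invalid
                continue
        can = canonicalize(out)
        if can is not None:
            valid.append(can)
    return len(valid) / len(outputs), valid


def uniqueness(valid_smiles: list[str]) -> float:
    """|distinct| / |valid| over canonicalized SMILES."""
    if not valid_smiles:
        raise EmptyInputError("uniqueness of an empty list is undefined")
    canonical = [canonicalize(s) or s for s in valid_smiles]
    return len(set(canonical)) / len(canonical)


def novelty(valid_smiles: list[str], training_smiles: set[str]) -> float:
    """Fraction of valid graphs absent from the training set."""
    if not valid_smiles:
        raise EmptyInputError("novelty of an empty list is undefined")
    canonical = [canonicalize(s) or s for s in valid_smiles]
    return sum(1 for s in canonical if s not in training_smiles) / len(canonical)


def generation_metrics(
    outputs: Iterable[Union[str, MolecularGraph]], training_smiles: set[str]
) -> GenerationMetrics:
    outputs = list(outputs)
    ratio, valid = validity(outputs)
    return GenerationMetrics(
        validity=ratio,
        uniqueness=uniqueness(valid) if valid else 0.0,
        novelty=novelty(valid, training_smiles) if valid else 0.0,
        n_total=len(outputs),
        n_valid=len(valid),
    )


def reduction_rate(original: float, compressed: float) -> float:
    """Percent node reduction: ``(original - compressed) / original * 100``."""
    if original <= 0:
        raise ValueError("original count must be positive")
    return (original - compressed) / original * 100.0


@dataclass
class CompressionStats:
    """Streaming summary of corpus compression."""

    n_molecules: int = 0
    n_skipped: int = 0
    mean_nodes_original: float = 0.0
    mean_nodes_compressed: float = 0.0
    max_nodes_original: int = 0
    max_nodes_compressed: int = 0
    mean_reduction_rate: float = 0.0  # of the corpus means
    max_reduction_rate: float = 0.0  # of the corpus maxima
    patterns_found_per_molecule: list[float] = field(default_factory=list)
    patterns_converted_per_molecule: list[float] = field(default_factory=list)
    histogram_original: dict[int, int] = field(default_factory=dict)
    histogram_compressed: dict[int, int] = field(default_factory=dict)
    scatter: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_molecules": self.n_molecules,
            "n_skipped": self.n_skipped,
            "mean_nodes_original": self.mean_nodes_original,
            "mean_nodes_compressed": self.mean_nodes_compressed,
            "max_nodes_original": self.max_nodes_original,
            "max_nodes_compressed": self.max_nodes_compressed,
            "mean_reduction_rate": self.mean_reduction_rate,
            "max_reduction_rate": self.max_reduction_rate,
            "patterns_found_per_molecule": self.patterns_found_per_molecule,
            "patterns_converted_per_molecule": self.patterns_converted_per_molecule,
            "histogram_original": {str(k): v for k, v in sorted(self.histogram_original.items())},
            "histogram_compressed": {
                str(k): v for k, v in sorted(self.histogram_compressed.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [
            f"molecules processed : {self.n_molecules} ({self.n_skipped} skipped)",
            f"avg nodes           : {self.mean_nodes_original:.2f} -> "
            f"{self.mean_nodes_compressed:.2f} ({self.mean_reduction_rate:.2f}% reduction)",
            f"max nodes           : {self.max_nodes_original} -> "
            f"{self.max_nodes_compressed} ({self.max_reduction_rate:.2f}% reduction)",
            "bridges per molecule (found / converted):",
        ]
        for k, (f_, c) in enumerate(
            zip(self.patterns_found_per_molecule, self.patterns_converted_per_molecule), start=1
        ):
            lines.append(f"  pattern {k}: {f_:.2f} / {c:.2f}")
        return "\n".join(lines)


def compression_stats(
    corpus: Iterable[MolecularGraph],
    reg: PatternRegistry,
    scatter_limit: int = 10000,
) -> CompressionStats:
    """Stream a corpus through the codec and accumulate compression statistics.

    Un-encodable molecules are counted as skipped and excluded.  Both the
    bridges *found* by matching and the bridges actually *converted* after
    overlap resolution are reported per pattern.
    """
    n = 0
    n_skipped = 0
    sum_orig = 0
    sum_comp = 0
    max_orig = 0
    max_comp = 0
    found = [0] * len(reg)
    converted = [0] * len(reg)
    hist_o: dict[int, int] = {}
    hist_c: dict[int, int] = {}
    scatter: list[tuple[int, int]] = []
    for g in corpus:
        try:
            matches = find_matches(g, reg)
            accepted = resolve_overlaps(matches, reg)
            cg = compress(g, reg)
        except GraphPressError:
            n_skipped += 1
            continue
        n += 1
        sum_orig += g.n_atoms
        sum_comp += cg.n_nodes
        max_orig = max(max_orig, g.n_atoms)
        max_comp = max(max_comp, cg.n_nodes)
        for m in matches:
            found[m.pattern_id - 1] += 1
        for m in accepted:
            converted[m.pattern_id - 1] += 1
        hist_o[g.n_atoms] = hist_o.get(g.n_atoms, 0) + 1
        hist_c[cg.n_nodes] = hist_c.get(cg.n_nodes, 0) + 1
        if len(scatter) < scatter_limit:
            scatter.append((g.n_atoms, cg.n_nodes))
    if n == 0:
        raise EmptyInputError("no encodable molecules in corpus")
    stats = CompressionStats(
        n_molecules=n,
        n_skipped=n_skipped,
        mean_nodes_original=sum_orig / n,
        mean_nodes_compressed=sum_comp / n,
        max_nodes_original=max_orig,
        max_nodes_compressed=max_comp,
        mean_reduction_rate=reduction_rate(sum_orig / n, sum_comp / n),
        max_reduction_rate=reduction_rate(max_orig, max_comp),
        patterns_found_per_molecule=[f / n for f in found],
        patterns_converted_per_molecule=[c / n for c in converted],
        histogram_original=hist_o,
        histogram_compressed=hist_c,
        scatter=scatter,
    )
    assert math.isclose(
        stats.mean_reduction_rate,
        (stats.mean_nodes_original - stats.mean_nodes_compressed)
        / stats.mean_nodes_original
        * 100.0,
    )
    return stats


def write_histograms_csv(stats: CompressionStats, path: str) -> None:
    """Node-count histograms for both representations as a tidy CSV."""
    with open(path, "w") as fh:
        fh.write("representation,n_nodes,count\n")
        for k in sorted(stats.histogram_original):
            fh.write(f"original,{k},{stats.histogram_original[k]}\n")
        for k in sorted(stats.histogram_compressed):
            fh.write(f"compressed,{k},{stats.histogram_compressed[k]}\n")


def write_scatter_csv(stats: CompressionStats, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("nodes_original,nodes_compressed\n")
        for o, c in stats.scatter:
            fh.write(f"{o},{c}\n")


def plot_compression(stats: CompressionStats, path: str) -> None:
    """Histogram + scatter figure of the compression results (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, hist, title in (
        (axes[0], stats.histogram_original, "original"),
        (axes[1], stats.histogram_compressed, "compressed"),
    ):
        ks = sorted(hist)
        ax.bar(ks, [hist[k] for k in ks], width=1.0)
        ax.set_xlabel("number of nodes")
        ax.set_ylabel("molecules")
        ax.set_title(title)
    if stats.scatter:
        o, c = zip(*stats.scatter)
        axes[2].scatter(o, c, s=4, alpha=0.3)
        lim = max(stats.max_nodes_original, 1)
        axes[2].plot([0, lim], [0, lim], "k--", linewidth=0.8)
    axes[2].set_xlabel("nodes (original)")
    axes[2].set_ylabel("nodes (compressed)")
    axes[2].set_title("per-molecule compression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
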