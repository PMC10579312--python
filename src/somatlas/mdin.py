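"""Mass-difference network (MDiN) reconstruction and statistics.

An MDiN is an undirected graph whose nodes are molecular formulas (or raw
peak masses) and whose edges connect pairs separated by one of a small
catalogue of chemically meaningful exact-mass differences — methylation
(CH2), hydrogenation (H2), oxygenation (O), hydration (H2O),
decarboxylation-scale CO2, nitrogenations (HCN, NH, NH3) and
sulfurizations (S, SO, SO2, SO3, SO4).  The canonical network is built on
formulas by exact elemental matching, which is equivalent to (and verified
against) an all-pairs exact-mass-difference search; a tolerance-based
variant over raw peak lists enables network construction before any
formula assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .formula_assign import (
    MolecularFormula,
    delta_from_dict,
    monoisotopic_mass,
)
from .peaklist_io import PeakList

__all__ = [
    "Transformation",
    "MDiNetwork",
    "default_transformations",
    "paper12_transformations",
    "build_network",
    "network_stats",
    "share_pct",
    "mass_based_network",
    "export_network",
    "import_edge_tsv",
]

#: Transformation labels counted as nitrogen- and sulfur-based groups.
NITROGEN_SET = ("HCN", "NH", "NH3")
SULFUR_SET = ("S", "SO", "SO2", "SO3", "SO4")
TOP4_SET = ("CH2", "H2", "O", "H2O")


@dataclass(frozen=True)
class Transformation:
    """A named elemental delta with its exact monoisotopic mass."""

    label: str
    delta: tuple[int, ...]
    exact_mass: float

    def __post_init__(self) -> None:
        if abs(self.exact_mass - monoisotopic_mass(self.delta)) > 1e-9:
            raise ValueError(
                f"exact_mass of {self.label} inconsistent with its delta"
            )


def _t(label: str, counts: Mapping[str, int]) -> Transformation:
    delta = delta_from_dict(counts)
    return Transformation(label, delta, monoisotopic_mass(delta))


_DEFAULT = (
    _t("CH2", {"C": 1, "H": 2}),
    _t("H2", {"H": 2}),
    _t("O", {"O": 1}),
    _t("H2O", {"H": 2, "O": 1}),
    _t("CO2", {"C": 1, "O": 2}),
    _t("HCN", {"C": 1, "H": 1, "N": 1}),
    _t("NH", {"N": 1, "H": 1}),
    _t("NH3", {"N": 1, "H": 3}),
    _t("S", {"S": 1}),
    _t("SO", {"S": 1, "O": 1}),
    _t("SO2", {"S": 1, "O": 2}),
    _t("SO3", {"S": 1, "O": 3}),
    _t("SO4", {"S": 1, "O": 4}),
)


def default_transformations() -> tuple[Transformation, ...]:
    """The full 13-difference catalogue: CH2, H2, O, H2O, CO2, HCN, NH,
    NH3, S, SO, SO2, SO3, SO4."""
    return _DEFAULT


def paper12_transformations() -> tuple[Transformation, ...]:
    """The 12-difference subset without CO2 (methylation, hydration,
    hydrogenation, oxygenation, sulfurizations, nitrogenations)."""
    return tuple(t for t in _DEFAULT if t.label != "CO2")


@dataclass
class MDiNetwork:
    """Undirected, simple graph over formulas with one transformation label
    per edge."""

    graph: nx.Graph
    catalogue: tuple[Transformation, ...]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_connected_nodes(self) -> int:
        return sum(1 for n in self.graph.nodes if self.graph.degree[n] >= 1)

    @property
    def per_transformation_counts(self) -> dict[str, int]:
        counts = {t.label: 0 for t in self.catalogue}
        for _, _, data in self.graph.edges(data=True):
            counts[data["transformation"]] += 1
        return counts


class DuplicateFormulaError(ValueError):
    pass


def build_network(
    formulas: Sequence[MolecularFormula],
    catalogue: Optional[Sequence[Transformation]] = None,
) -> MDiNetwork:
    """Build the formula-based MDiN by exact elemental matching.

    An undirected edge joins f and g iff ``g - f`` equals some catalogue
    delta elementwise; the catalogue deltas are elementally distinct, so
    each qualifying pair yields exactly one labelled edge.
    """
    catalogue = tuple(catalogue) if catalogue is not None else default_transformations()
    seen: set[MolecularFormula] = set()
    dups = [f for f in formulas if f in seen or seen.add(f)]
    if dups:
        raise DuplicateFormulaError(
            f"duplicate formulas: {sorted({f.hill for f in dups})}"
        )
    g = nx.Graph()
    g.add_nodes_from(formulas)
    pop = set(formulas)
    for f in formulas:
        for t in catalogue:
            partner = f.shift(t.delta)
            if partner is not None and partner in pop:
                g.add_edge(f, partner, transformation=t.label)
    return MDiNetwork(g, catalogue)


def share_pct(counts: Mapping[str, int], labels: Iterable[str], total: int) -> float:
    """Percentage of ``total`` edges carried by the given labels — usable
    directly on a published per-transformation edge-count table."""
    if total == 0:
        return 0.0
    return 100.0 * sum(counts.get(lb, 0) for lb in labels) / total


def network_stats(net: MDiNetwork) -> dict:
    """Summary statistics: totals, per-transformation counts and
    percentages, and the grouped top-4 / nitrogen / sulfur shares."""
    counts = net.per_transformation_counts
    total = net.n_edges
    pct = {
        lb: (100.0 * c / total if total else 0.0) for lb, c in counts.items()
    }
    return {
        "n_nodes": net.n_nodes,
        "n_edges": total,
        "n_connected_nodes": net.n_connected_nodes,
        "n_unconnected_nodes": net.n_nodes - net.n_connected_nodes,
        "counts": counts,
        "percentages": pct,
        "top4_share_pct": share_pct(counts, TOP4_SET, total),
        "nitrogen_share_pct": share_pct(counts, NITROGEN_SET, total),
        "sulfur_share_pct": share_pct(counts, SULFUR_SET, total),
    }


def mass_based_network(
    pl: PeakList,
    catalogue: Optional[Sequence[Transformation]] = None,
    tol_ppm: float = 1.0,
) -> nx.Graph:
    """Tolerance-based MDiN over a raw peak list, without any assignment.

    Nodes are peak indices (with ``mz``/``intensity`` attributes); an edge
    joins peaks whose m/z difference matches a catalogue exact mass within
    ``tol_ppm`` (the tolerance is evaluated against the larger m/z).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    catalogue = tuple(catalogue) if catalogue is not None else default_transformations()
    g = nx.Graph()
    mz = pl.mz
    for i, p in enumerate(pl.peaks):
        g.add_node(i, mz=p.mz, intensity=p.intensity)
    for t in catalogue:
        targets = mz + t.exact_mass
        j_lo = np.searchsorted(mz, targets * (1 - 2e-6 * tol_ppm))
        j_hi = np.searchsorted(mz, targets * (1 + 2e-6 * tol_ppm), side="right")
        for i in range(len(mz)):
            for j in range(int(j_lo[i]), int(j_hi[i])):
                if j == i:
                    continue
                if abs(mz[j] - targets[i]) <= tol_ppm * 1e-6 * mz[j]:
                    g.add_edge(i, j, transformation=t.label)
    return g


def export_network(
    net: MDiNetwork, path: str | Path, format: str = "edge_tsv"
) -> None:
    """Write an MDiN as an edge TSV or as GraphML.

    GraphML nodes carry formula, family, H/C, O/C and monoisotopic mass
    attributes; edges carry the transformation label.  The edge TSV holds
    one row per edge (source, target, transformation); re-importing it
    recovers the connected part of the network exactly.
    """
    path = Path(path)
    if format == "edge_tsv":
        with path.open("w") as fh:
            fh.write("source\ttarget\ttransformation\n")
            for f, g, data in sorted(
                net.graph.edges(data=True), key=lambda e: (e[0].hill, e[1].hill)
            ):
                a, b = sorted((f.hill, g.hill))
                fh.write(f"{a}\t{b}\t{data['transformation']}\n")
    elif format == "graphml":
        from .descriptors import classify_family

        out = nx.Graph()
        for f in net.graph.nodes:
            out.add_node(
                f.hill,
                formula=f.hill,
                family=classify_family(f),
                hc_ratio=(f["H"] / f["C"]) if f["C"] else 0.0,
                oc_ratio=(f["O"] / f["C"]) if f["C"] else 0.0,
                mass=monoisotopic_mass(f),
            )
        for f, g, data in net.graph.edges(data=True):
            out.add_edge(f.hill, g.hill, transformation=data["transformation"])
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_edge_tsv(
    path: str | Path,
    catalogue: Optional[Sequence[Transformation]] = None,
) -> MDiNetwork:
    """Rebuild an MDiN from an edge TSV written by :func:`export_network`."""
    catalogue = tuple(catalogue) if catalogue is not None else default_transformations()
    g = nx.Graph()
    with Path(path).open() as fh:
        header = fh.readline().strip().split("\t")
        if header != ["source", "target", "transformation"]:
            raise ValueError(f"unexpected edge TSV header {header}")
        for line in fh:
            a, b, label = line.rstrip("\n").split("\t")
            fa, fb = MolecularFormula.parse(a), MolecularFormula.parse(b)
            g.add_edge(fa, fb, transformation=label)
    return MDiNetwork(g, catalogue)
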