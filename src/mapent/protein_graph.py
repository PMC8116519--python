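"""Attributed contact-graph representation of a protein structure.

Every heavy atom of one protein chain becomes a vertex carrying 10 binary
features: a one-hot element class (C, N, O, S), a one-hot residue class
(hydrophobic, amphipathic, polar, charged), a backbone flag, and a "Site"
flag that marks the atom as retained by the current coarse-grained mapping.
Undirected edges connect atoms closer than a distance cutoff (1 nm by
default) and carry the inverse inter-atomic distance (nm^-1) as their weight.

The graph is static: it is built once from a single reference conformation,
and different mappings are encoded by rewriting the Site column only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .mapping_space import Mapping

__all__ = [
    "AtomTable",
    "ProteinGraph",
    "StructureParseError",
    "EmptyStructureError",
    "UnsupportedElementError",
    "UnknownResidueError",
    "DegenerateGeometryError",
    "RESIDUE_CLASSES",
    "FEATURE_NAMES",
    "load_structure",
    "classify_residue",
    "vertex_features",
    "feature_matrix",
    "build_graph",
    "encode_mapping",
    "save_graph",
    "load_graph",
]


class StructureParseError(ValueError):
    """The input could not be parsed as a PDB structure."""


class EmptyStructureError(ValueError):
    """No heavy protein atoms remain after filtering."""


class UnsupportedElementError(ValueError):
    """A heavy atom has an element outside {C, N, O, S}."""


class UnknownResidueError(KeyError):
    """A residue name outside the 20 standard amino acids."""


class DegenerateGeometryError(ValueError):
    """Two atoms share identical coordinates (infinite inverse distance)."""


#: Order of the 10 binary vertex features.
FEATURE_NAMES = ("C", "N", "O", "S", "HPhob", "Amph", "Pol", "Ch", "Bkb", "Site")

_ELEMENTS = ("C", "N", "O", "S")

#: Residue-class assignment of the 20 standard amino acids.  The four classes
#: follow a standard hydropathy grouping; the table is a single constant so an
#: alternative assignment can be swapped in.
RESIDUE_CLASSES: dict[str, str] = {
    **{r: "HPhob" for r in ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "GLY")},
    **{r: "Amph" for r in ("TRP", "TYR", "THR")},
    **{r: "Pol" for r in ("SER", "CYS", "ASN", "GLN", "HIS")},
    **{r: "Ch" for r in ("ASP", "GLU", "LYS", "ARG")},
}

_CLASS_BIT = {"HPhob": 4, "Amph": 5, "Pol": 6, "Ch": 7}
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass
class AtomTable:
    """Heavy atoms of one protein chain.

    Positions are in nm.  ``atom_index`` is implicit: row i is atom i.
    """

    element: np.ndarray  # (n,) str, each in {C, N, O, S}
    atom_name: np.ndarray  # (n,) str, PDB atom names
    residue_name: np.ndarray  # (n,) str, 3-letter codes
    residue_index: np.ndarray  # (n,) int
    is_backbone: np.ndarray  # (n,) bool
    positions: np.ndarray  # (n, 3) float, nm

    def __post_init__(self) -> None:
        n = len(self.element)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        bad = [e for e in np.unique(self.element) if e not in _ELEMENTS]
        if bad:
            i = int(np.flatnonzero(np.isin(self.element, bad))[0])
            raise UnsupportedElementError(
                f"atom {i} ({self.atom_name[i]} of {self.residue_name[i]}"
                f" {int(self.residue_index[i])}) has unsupported element"
                f" {self.element[i]!r}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    def __len__(self) -> int:
        return self.n_atoms

    def take(self, indices) -> "AtomTable":
        """Sub-table of the given atoms (indices are renumbered 0..k-1)."""
        idx = np.asarray(indices, dtype=int)
        return AtomTable(
            element=self.element[idx],
            atom_name=self.atom_name[idx],
            residue_name=self.residue_name[idx],
            residue_index=self.residue_index[idx],
            is_backbone=self.is_backbone[idx],
            positions=self.positions[idx],
        )


def classify_residue(residue_name: str) -> str:
    """Residue class of a standard amino acid: HPhob, Amph, Pol or Ch."""
    try:
        return RESIDUE_CLASSES[residue_name.upper()]
    except KeyError:
        raise UnknownResidueError(
            f"residue {residue_name!r} is not one of the 20 standard amino acids"
        ) from None


def load_structure(pdb_source: str | Path, chain_selector: str | None = None) -> AtomTable:
    """Parse a PDB file (or PDB text) into an :class:`AtomTable`.

    Hydrogens, waters, ions and hetero ligands are excluded; the first model
    is used; one chain is selected (the first protein chain when no selector
    is given).  Alternate locations keep the highest-occupancy copy.
    Coordinates are converted from Angstrom to nm.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(pdb_source, Path):
        text = pdb_source.read_text()
    else:
        s = str(pdb_source)
        if "\n" in s or s.lstrip().startswith(("ATOM", "HETATM", "MODEL", "HEADER")):
            text = s
        else:
            text = Path(s).read_text()
    try:
        pdb = PDBFile.read(io.StringIO(text))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various error types
        raise StructureParseError(f"could not parse PDB input: {exc}") from exc

    mask = struc.filter_amino_acids(atoms)
    mask &= ~np.isin(atoms.element, ("H", "D"))
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise EmptyStructureError("no heavy protein atoms after filtering")

    chains = list(dict.fromkeys(atoms.chain_id))
    if chain_selector is not None:
        if chain_selector not in chains:
            raise EmptyStructureError(
                f"chain {chain_selector!r} not found (available: {chains})"
            )
        chain = chain_selector
    else:
        chain = chains[0]
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"chain {chain!r} has no heavy protein atoms")

    element = np.array([e.upper() for e in atoms.element], dtype="U2")
    name = np.array(atoms.atom_name, dtype="U4")
    return AtomTable(
        element=element,
        atom_name=name,
        residue_name=np.array(atoms.res_name, dtype="U3"),
        residue_index=np.asarray(atoms.res_id, dtype=int),
        is_backbone=np.isin(name, tuple(_BACKBONE_NAMES)),
        positions=atoms.coord / 10.0,  # Angstrom -> nm
    )


def vertex_features(atoms: AtomTable, index: int, mapping: Mapping | None = None) -> np.ndarray:
    """10-bit feature vector of one atom under an optional mapping."""
    bits = np.zeros(10, dtype=np.int8)
    element = atoms.element[index]
    if element not in _ELEMENTS:
        raise UnsupportedElementError(f"atom {index} has element {element!r}")
    bits[_ELEMENTS.index(element)] = 1
    bits[_CLASS_BIT[classify_residue(atoms.residue_name[index])]] = 1
    bits[8] = 1 if atoms.is_backbone[index] else 0
    if mapping is not None and index in mapping.retained:
        bits[9] = 1
    return bits


def feature_matrix(atoms: AtomTable, mapping: Mapping | None = None) -> np.ndarray:
    """(n, 10) binary feature matrix; Site column all zero without a mapping."""
    n = atoms.n_atoms
    feats = np.zeros((n, 10), dtype=np.int8)
    for i, e in enumerate(atoms.element):
        feats[i, _ELEMENTS.index(e)] = 1
        feats[i, _CLASS_BIT[classify_residue(atoms.residue_name[i])]] = 1
    feats[:, 8] = atoms.is_backbone.astype(np.int8)
    if mapping is not None:
        feats[:, 9] = mapping.indicator().astype(np.int8)
    return feats


@dataclass
class ProteinGraph:
    """Static attributed contact graph of one protein conformation.

    Undirected edges are stored once as index pairs ``edges[k] = (u, v)`` with
    ``u < v``; ``directed_edge_count`` reports ``2 * len(edges)`` to match the
    ordered-pair bookkeeping conventionally used for average degrees.
    """

    features: np.ndarray  # (n, 10) int8
    edges: np.ndarray  # (m, 2) int, u < v
    edge_weight: np.ndarray  # (m,) float, 1/distance in nm^-1
    cutoff: float = 1.0

    @property
    def n_vertices(self) -> int:
        return self.features.shape[0]

    @property
    def n_edges(self) -> int:
        """Stored undirected pair count."""
        return self.edges.shape[0]

    @property
    def directed_edge_count(self) -> int:
        return 2 * self.n_edges

    @property
    def average_degree(self) -> int:
        """Directed edges per vertex, truncated to an integer."""
        return self.directed_edge_count // self.n_vertices

    def adjacency(self, dtype=np.float64) -> np.ndarray:
        """Dense symmetric weighted adjacency matrix (n, n)."""
        n = self.n_vertices
        A = np.zeros((n, n), dtype=dtype)
        u, v = self.edges[:, 0], self.edges[:, 1]
        A[u, v] = self.edge_weight
        A[v, u] = self.edge_weight
        return A

    def site_column(self) -> np.ndarray:
        return self.features[:, 9].copy()


def build_graph(atoms: AtomTable, cutoff: float = 1.0) -> ProteinGraph:
    """Build the contact graph: edge {u,v} iff 0 < dist(u,v) < cutoff.

    Edge weights are inverse distances in nm^-1.  Features are initialized
    with Site = 0 everywhere.  Coincident atoms are an error.
    """
    if atoms.n_atoms < 1:
        raise EmptyStructureError("cannot build a graph from zero atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = atoms.n_atoms
    d = pdist(atoms.positions)
    iu, ju = np.triu_indices(n, k=1)
    zero = np.flatnonzero(d < 1e-12)
    if zero.size:
        k = int(zero[0])
        raise DegenerateGeometryError(
            f"atoms {int(iu[k])} and {int(ju[k])} have identical coordinates"
        )
    keep = d < cutoff
    edges = np.stack([iu[keep], ju[keep]], axis=1).astype(int)
    weights = 1.0 / d[keep]
    return ProteinGraph(
        features=feature_matrix(atoms),
        edges=edges,
        edge_weight=weights,
        cutoff=float(cutoff),
    )


def encode_mapping(graph: ProteinGraph, mapping: Mapping) -> ProteinGraph:
    """Return a graph whose Site column is the indicator of ``mapping``.

    All other feature columns and the edge set are untouched; encoding is an
    idempotent overwrite.  An empty retained set is allowed here (all-zero
    Site column).
    """
    if mapping.n != graph.n_vertices:
        raise ValueError(
            f"mapping is over n={mapping.n} atoms but graph has"
            f" {graph.n_vertices} vertices"
        )
    feats = graph.features.copy()
    feats[:, 9] = 0
    feats[list(mapping.retained), 9] = 1
    return replace(graph, features=feats)


def save_graph(graph: ProteinGraph, prefix: str | Path) -> None:
    """Write the graph as a text edge list + feature CSV, plus an .npz cache."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("u\tv\tweight\n")
        for (u, v), w in zip(graph.edges, graph.edge_weight):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")
    header = ",".join(FEATURE_NAMES)
    np.savetxt(
        f"{prefix}.features.csv", graph.features, fmt="%d", delimiter=",",
        header=header, comments="",
    )
    np.savez(
        f"{prefix}.npz",
        features=graph.features,
        edges=graph.edges,
        edge_weight=graph.edge_weight,
        cutoff=np.array(graph.cutoff),
    )


def load_graph(prefix: str | Path) -> ProteinGraph:
    """Reload a graph written by :func:`save_graph` (from the .npz cache)."""
    path = Path(f"{prefix}.npz") if not str(prefix).endswith(".npz") else Path(prefix)
    with np.load(path) as data:
        return ProteinGraph(
            features=data["features"].astype(np.int8),
            edges=data["edges"].astype(int),
            edge_weight=data["edge_weight"].astype(float),
            cutoff=float(data["cutoff"]),
        )
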