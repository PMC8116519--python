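"""Self-contained synthetic fixtures: toy structures, oracles, ensembles.

Every other module is exercised without external data through three
generators: a procedural self-avoiding chain of pseudo-residues standing in
for a protein conformation, an analytic mapping-scoring oracle whose smooth
part shares the contact graph's inverse-distance structure (so the surrogate
architecture can represent it), and discrete ensembles whose macrostate
partition is recoverable exactly.  An exhaustive enumerator provides the
ground-truth density of states on small mapping spaces.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np

from .mapping_space import Mapping, SAConfig, count_mappings, simulated_annealing
from .protein_graph import RESIDUE_CLASSES, AtomTable, ProteinGraph, build_graph
from .smap import DiscreteSystem, Ensemble, KB
from .surrogate import MappingSample

__all__ = [
    "SpaceTooLargeError",
    "ToyOracle",
    "make_toy_structure",
    "toy_oracle_score",
    "make_dataset",
    "make_discrete_ensemble",
    "enumerate_scores",
    "exhaustive_dos",
    "write_pdb",
    "SA_STEP_PRESETS",
]

#: Annealing run lengths used for optimized dataset entries (four groups).
SA_STEP_PRESETS = (20_000, 10_000, 5_000, 2_500)

_RESIDUE_NAMES = tuple(sorted(RESIDUE_CLASSES))
_BACKBONE_NAMES = ("N", "CA", "C", "O")
_SIDECHAIN_NAMES = ("CB", "CG", "CD", "CE")
_SIDECHAIN_ELEMENTS = ("C", "N", "O", "S")


class SpaceTooLargeError(ValueError):
    """Exhaustive enumeration refused: the mapping space is too big."""


def make_toy_structure(n_residues: int, seed: int) -> AtomTable:
    """Procedural heavy-atom chain: 1-8 atoms per pseudo-residue.

    Residue centres follow a self-avoiding random walk with a 0.38 nm step
    (the usual CA-CA distance); atoms scatter around their centre with a
    minimum inter-atom separation of 0.05 nm.  Deterministic under ``seed``.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)

    centers = [np.zeros(3)]
    while len(centers) < n_residues:
        for _ in range(200):
            step = rng.normal(size=3)
            step = 0.38 * step / np.linalg.norm(step)
            cand = centers[-1] + step
            if all(np.linalg.norm(cand - c) >= 0.30 for c in centers[:-1]):
                centers.append(cand)
                break
        else:  # extremely unlikely: restart the walk from a jittered point
            centers.append(centers[-1] + rng.normal(scale=0.5, size=3))

    element, name, res_name, res_index, positions = [], [], [], [], []
    placed: list[np.ndarray] = []
    for ri in range(n_residues):
        k = int(rng.integers(1, 9))
        rname = _RESIDUE_NAMES[rng.integers(len(_RESIDUE_NAMES))]
        for j in range(k):
            if j < 4:
                aname = _BACKBONE_NAMES[j]
                elem = "N" if aname == "N" else ("O" if aname == "O" else "C")
            else:
                aname = _SIDECHAIN_NAMES[j - 4]
                elem = _SIDECHAIN_ELEMENTS[
                    rng.choice(4, p=(0.6, 0.15, 0.15, 0.1))
                ]
            scale = 0.08
            for attempt in range(500):
                pos = centers[ri] + rng.normal(scale=scale, size=3)
                arr = np.asarray(placed)
                if not placed or np.linalg.norm(arr - pos, axis=1).min() >= 0.05:
                    break
                if attempt % 50 == 49:  # widen the shell if the centre is crowded
                    scale *= 1.5
            placed.append(pos)
            element.append(elem)
            name.append(aname)
            res_name.append(rname)
            res_index.append(ri + 1)
            positions.append(pos)

    return AtomTable(
        element=np.array(element, dtype="U2"),
        atom_name=np.array(name, dtype="U4"),
        residue_name=np.array(res_name, dtype="U3"),
        residue_index=np.array(res_index, dtype=int),
        is_backbone=np.isin(np.array(name), _BACKBONE_NAMES),
        positions=np.array(positions),
    )


def _roughness(retained: tuple[int, ...], seed: int) -> float:
    """Seeded hash of the retained set, uniform in [-1, 1]."""
    payload = (",".join(map(str, retained)) + f"#{seed}").encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "little") / 2**63 - 1.0


@dataclass
class ToyOracle:
    """Analytic pseudo-mapping-entropy: smooth graph term + roughness.

    score(M) = a * sum of edge weights among retained atoms
             + b * |retained backbone atoms|
             + c * seeded hash perturbation in [-1, 1].

    With c = 0 the landscape is smooth and representable by the surrogate;
    large c makes it unlearnable.  The score does not depend on the listing
    order of the retained indices.
    """

    graph: ProteinGraph
    a: float = 1.0
    b: float = 1.0
    c: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self._W = self.graph.adjacency()
        self._bkb = self.graph.features[:, 8].astype(bool)

    def __call__(self, mapping: Mapping) -> float:
        idx = list(mapping.retained)
        smooth = 0.5 * float(self._W[np.ix_(idx, idx)].sum())
        score = self.a * smooth + self.b * float(self._bkb[idx].sum())
        if self.c:
            score += self.c * _roughness(mapping.retained, self.seed)
        return score

    def score_batch(self, retained: np.ndarray) -> np.ndarray:
        """Vectorized scoring of many mappings, rows of retained indices.

        Requires c = 0 (the hash perturbation is inherently per-mapping).
        """
        if self.c:
            raise ValueError("batch scoring requires a smooth oracle (c = 0)")
        retained = np.asarray(retained, dtype=int)
        M, N = retained.shape
        smooth = np.zeros(M)
        for i in range(N):
            for j in range(i + 1, N):
                smooth += self._W[retained[:, i], retained[:, j]]
        return self.a * smooth + self.b * self._bkb[retained].sum(axis=1)


def toy_oracle_score(
    structure: AtomTable | ProteinGraph,
    mapping: Mapping,
    a: float = 1.0,
    b: float = 1.0,
    c: float = 0.0,
    seed: int = 0,
) -> float:
    """One-shot oracle evaluation; accepts a structure (graph built ad hoc) or graph."""
    graph = structure if isinstance(structure, ProteinGraph) else build_graph(structure)
    return ToyOracle(graph, a=a, b=b, c=c, seed=seed)(mapping)


def make_dataset(
    structure: AtomTable | ProteinGraph,
    oracle,
    n_random: int,
    n_optimized: int,
    N: int,
    seed: int,
    sa_step_presets: tuple[int, ...] = SA_STEP_PRESETS,
) -> list[MappingSample]:
    """Labeled mapping dataset: uniform random draws plus SA-optimized ones.

    Optimized entries come from independent annealing runs split evenly over
    the four preset run lengths, each labeled by the oracle at its best
    mapping.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    graph = structure if isinstance(structure, ProteinGraph) else build_graph(structure)
    n = graph.n_vertices
    if N > n:
        raise ValueError(f"N={N} exceeds atom count {n}")
    rng = np.random.default_rng(seed)
    samples: list[MappingSample] = []
    for _ in range(n_random):
        m = Mapping(n=n, retained=tuple(rng.choice(n, size=N, replace=False)))
        samples.append(MappingSample(mapping=m, smap=float(oracle(m)), origin="random"))

    shares = [n_optimized // len(sa_step_presets)] * len(sa_step_presets)
    for i in range(n_optimized - sum(shares)):
        shares[i] += 1
    for steps, share in zip(sa_step_presets, shares):
        for _ in range(share):
            cfg = SAConfig(steps=steps, seed=int(rng.integers(2**31)))
            res = simulated_annealing(oracle, n, N, cfg)
            samples.append(
                MappingSample(
                    mapping=res.best_mapping,
                    smap=float(res.best_score),
                    origin="optimized",
                )
            )
    return samples


def make_discrete_ensemble(
    system: DiscreteSystem,
    n_frames: int,
    energy_map: np.ndarray,
    seed: int,
    beta: float = 1.0 / (KB * 300.0),
) -> tuple[Ensemble, np.ndarray]:
    """Sample an ensemble from a discrete system; returns (ensemble, labels).

    Frames are drawn i.i.d. from the microstate probabilities.  Each frame
    has two atoms: atom 0 encodes the macrostate (so a mapping retaining
    atom 0 recovers the partition exactly at tolerance 0) and atom 1 the
    microstate.  ``energy_map[r]`` is the potential energy of microstate r.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    energy_map = np.asarray(energy_map, dtype=float)
    if energy_map.shape != (system.n_microstates,):
        raise ValueError("energy_map must have one entry per microstate")
    rng = np.random.default_rng(seed)
    micro = rng.choice(system.n_microstates, size=n_frames, p=system.probabilities)
    _, macro_of = np.unique(system.partition, return_inverse=True)
    frames = np.zeros((n_frames, 2, 3))
    frames[:, 0, 0] = macro_of[micro].astype(float)
    frames[:, 1, 0] = micro.astype(float)
    ensemble = Ensemble(frames=frames, energies=energy_map[micro], beta=beta)
    return ensemble, macro_of[micro]


def enumerate_scores(oracle, n: int, N: int) -> np.ndarray:
    """Scores of every mapping in the space (refuses beyond 10^6 mappings)."""
    total = count_mappings(n, N)
    if total > 1_000_000:
        raise SpaceTooLargeError(
            f"C({n}, {N}) = {total} mappings exceed the enumeration limit of 10^6"
        )
    scores = np.empty(total)
    for i, combo in enumerate(itertools.combinations(range(n), N)):
        scores[i] = float(oracle(Mapping(n=n, retained=combo)))
    return scores


def exhaustive_dos(
    oracle, n: int, N: int, bins
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-bin mapping counts by full enumeration.

    ``bins`` is either an integer (equal-width bins over the observed score
    range) or an array of bin edges.  Returns (counts, edges); counts sum to
    C(n, N).
    """
    scores = enumerate_scores(oracle, n, N)
    counts, edges = np.histogram(scores, bins=bins)
    return counts, edges


def write_pdb(atoms: AtomTable, path) -> None:
    """Write an AtomTable as minimal PDB text (positions nm -> Angstrom)."""
    with open(path, "w") as fh:
        for i in range(atoms.n_atoms):
            x, y, z = atoms.positions[i] * 10.0
            fh.write(
                f"ATOM  {i + 1:5d} {atoms.atom_name[i]:<4s} {atoms.residue_name[i]:<3s}"
                f" A{int(atoms.residue_index[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atoms.element[i]:>2s}\n"
            )
        fh.write("END\n")
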