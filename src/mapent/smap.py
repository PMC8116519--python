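"""Mapping entropy: exact discrete computation and the variance estimator.

The mapping entropy S_map of a decimation mapping is the Kullback-Leibler
divergence between the microscopic configurational distribution p_r and the
distribution obtained by pushing the probability of each coarse-grained
macrostate back down uniformly onto its microstates,

    S_map = k_B * sum_r p_r ln(p_r / pbar_r),
    pbar_r = P(macrostate of r) / (number of microstates in that macrostate).

For discrete toy systems this is computed exactly.  For sampled ensembles,
a second-order cumulant expansion turns S_map into a weighted average over
macrostates of the variance of the atomistic potential energy within each
macrostate; this module implements that estimator together with the
single-linkage grouping of frames into macrostates.

Units: k_B = 0.0083145 kJ/mol/K, energies kJ/mol, beta mol/kJ; the ensemble
estimator returns kJ/mol/K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .mapping_space import Mapping

__all__ = [
    "KB",
    "DiscreteSystem",
    "Ensemble",
    "exact_smap_discrete",
    "assign_macrostates",
    "estimate_smap",
    "load_ensemble",
]

#: Boltzmann constant in kJ/mol/K.
KB = 0.0083145


@dataclass
class DiscreteSystem:
    """A finite system: microstate probabilities plus a macrostate partition."""

    probabilities: np.ndarray  # (m,) non-negative, sums to 1
    partition: np.ndarray  # (m,) integer macrostate label per microstate

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        labels = np.asarray(self.partition)
        if p.size == 0:
            raise ValueError("empty discrete system")
        if p.size != labels.size:
            raise ValueError("one macrostate label per microstate is required")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
        self.probabilities = p
        self.partition = labels

    @property
    def n_microstates(self) -> int:
        return self.probabilities.size


def exact_smap_discrete(system: DiscreteSystem) -> float:
    """Exact mapping entropy of a discrete system, in units of k_B.

    Multiply by :data:`KB` for kJ/mol/K.  Terms with p_r = 0 contribute 0;
    the result is a KL divergence and hence non-negative.
    """
    p = system.probabilities
    _, inverse = np.unique(system.partition, return_inverse=True)
    n_macro = inverse.max() + 1
    macro_p = np.bincount(inverse, weights=p, minlength=n_macro)
    macro_size = np.bincount(inverse, minlength=n_macro)
    pbar = macro_p[inverse] / macro_size[inverse]
    mask = p > 0
    val = float(np.sum(p[mask] * np.log(p[mask] / pbar[mask])))
    return max(val, 0.0)  # clip the occasional -1e-17 from rounding


@dataclass
class Ensemble:
    """Sampled configurations with per-frame potential energies.

    ``frames`` has shape (F, n_atoms, 3) in nm; ``energies`` has one entry
    per frame in kJ/mol; ``beta`` = 1/(k_B T) in mol/kJ.
    """

    frames: np.ndarray
    energies: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, n_atoms, 3)")
        if self.energies.shape != (self.frames.shape[0],):
            raise ValueError("need exactly one energy per frame")
        if self.frames.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if not self.beta > 0:
            raise ValueError("beta must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def load_ensemble(
    coordinates_path, beta: float, energies_path=None
) -> Ensemble:
    """Load an ensemble from disk.

    Two formats are supported: a structured ``.npz`` with a ``frames``
    (F, n_atoms, 3; nm) block and an ``energies`` (kJ/mol) vector, or a
    multi-model PDB (coordinates in Angstrom, converted to nm) paired with a
    one-column text file of per-frame energies via ``energies_path``.
    """
    path = str(coordinates_path)
    if path.endswith(".npz"):
        with np.load(path) as data:
            energies = (
                data["energies"]
                if energies_path is None
                else np.loadtxt(energies_path, ndmin=1)
            )
            return Ensemble(frames=data["frames"], energies=energies, beta=beta)
    if energies_path is None:
        raise ValueError("a PDB ensemble needs a separate energy file")
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    stack = pdb.get_structure()  # AtomArrayStack: one model per frame
    frames = stack.coord / 10.0
    energies = np.loadtxt(energies_path, ndmin=1)
    return Ensemble(frames=frames, energies=energies, beta=beta)


def assign_macrostates(
    ensemble: Ensemble, mapping: Mapping, tolerance: float
) -> np.ndarray:
    """Group frames into CG macrostates by their retained-atom coordinates.

    Two frames belong to the same macrostate iff they are connected by a
    chain of frames in which consecutive members differ by at most
    ``tolerance`` in the maximum per-atom distance over the retained atoms
    (single-linkage grouping).  ``tolerance = 0`` demands exact coordinate
    equality; ``tolerance = inf`` yields a single macrostate.  Labels are
    dense integers 0..K-1 ordered by first occurrence.
    """
    if mapping.N == 0:
        raise ValueError("macrostates are undefined for a mapping with no retained atoms")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    coords = ensemble.frames[:, list(mapping.retained), :]
    F = coords.shape[0]
    flat = coords.reshape(F, -1)
    if math.isinf(tolerance):
        return np.zeros(F, dtype=int)
    # max-per-atom Euclidean distance between every pair of frames,
    # chunked to bound memory at large F
    dmat = np.zeros((F, F))
    chunk = max(1, int(2e7 // max(1, F * coords.shape[1])))
    for start in range(0, F, chunk):
        stop = min(F, start + chunk)
        diff = coords[start:stop, None, :, :] - coords[None, :, :, :]
        dmat[start:stop] = np.sqrt((diff**2).sum(-1)).max(-1)
    adj = csr_matrix(dmat <= tolerance)
    _, comp = connected_components(adj, directed=False)
    # relabel by first occurrence
    order: dict[int, int] = {}
    labels = np.empty(F, dtype=int)
    for i, c in enumerate(comp):
        labels[i] = order.setdefault(int(c), len(order))
    return labels


def estimate_smap(
    ensemble: Ensemble,
    labels: np.ndarray,
    prefactor_mode: str = "cumulant",
    weights: np.ndarray | None = None,
) -> float:
    """Variance-over-macrostates estimator of the mapping entropy.

    Returns ``prefactor * sum_R w_R * Var_R(u)`` where ``w_R`` is the
    (weighted) fraction of frames in macrostate R and ``Var_R`` is the
    population variance of the frame energies within R.  ``prefactor`` is
    ``k_B * beta**2 / 2`` in ``cumulant`` mode (second-order cumulant
    expansion of the KL divergence; result in kJ/mol/K) and 1 in ``unit``
    mode.  Optional per-frame ``weights`` allow exact-weight ensembles;
    default is uniform.
    """
    labels = np.asarray(labels)
    u = ensemble.energies
    if labels.shape != u.shape:
        raise ValueError("labels and energies must have matching lengths")
    if prefactor_mode not in ("cumulant", "unit"):
        raise ValueError(f"unknown prefactor mode {prefactor_mode!r}")
    if weights is None:
        w = np.full(u.size, 1.0 / u.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != u.shape:
            raise ValueError("weights must have one entry per frame")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    _, inverse = np.unique(labels, return_inverse=True)
    n_macro = inverse.max() + 1
    w_R = np.bincount(inverse, weights=w, minlength=n_macro)
    mean_R = np.bincount(inverse, weights=w * u, minlength=n_macro)
    nz = w_R > 0
    mean_R[nz] /= w_R[nz]
    var_R = np.bincount(inverse, weights=w * (u - mean_R[inverse]) ** 2, minlength=n_macro)
    var_R[nz] /= w_R[nz]
    total = float(np.sum(w_R * var_R))
    if prefactor_mode == "cumulant":
        total *= KB * ensemble.beta**2 / 2.0
    return total
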