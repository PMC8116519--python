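"""Coarse-grained mappings and the combinatorial space they live in.

A decimation mapping keeps exactly ``N`` of the ``n`` heavy atoms of a
molecule and integrates the rest out.  The space of such mappings is the set
of all C(n, N) fixed-size subsets; the elementary move connecting neighbouring
mappings is the swap of one retained atom with one discarded atom.  This
module provides the :class:`Mapping` value type, uniform sampling, swap
moves, exact counting, and a simulated-annealing minimizer of an arbitrary
mapping-scoring oracle with the exponential cooling schedule
``T(i) = T0 * exp(-i / v)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Mapping",
    "SAConfig",
    "SAResult",
    "random_mapping",
    "swap_move",
    "count_mappings",
    "simulated_annealing",
]


@dataclass(frozen=True)
class Mapping:
    """A fixed-cardinality subset of retained atom indices.

    Parameters
    ----------
    n:
        Total number of atoms in the molecule.
    retained:
        Distinct 0-based indices of the retained atoms; stored sorted.
    """

    n: int
    retained: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be non-negative, got {self.n}")
        ret = tuple(sorted(int(i) for i in self.retained))
        if len(set(ret)) != len(ret):
            raise ValueError("retained indices must be distinct")
        if ret and (ret[0] < 0 or ret[-1] >= self.n):
            raise IndexError(
                f"retained index out of range [0, {self.n}): {ret[0]}..{ret[-1]}"
            )
        object.__setattr__(self, "retained", ret)

    @property
    def N(self) -> int:
        """Number of retained atoms (CG sites)."""
        return len(self.retained)

    def indicator(self) -> np.ndarray:
        """Boolean length-``n`` vector, True at retained positions."""
        ind = np.zeros(self.n, dtype=bool)
        ind[list(self.retained)] = True
        return ind

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "retained": list(self.retained)})

    @classmethod
    def from_json(cls, text: str) -> "Mapping":
        obj = json.loads(text)
        return cls(n=int(obj["n"]), retained=tuple(obj["retained"]))


def random_mapping(n: int, N: int, rng: np.random.Generator) -> Mapping:
    """Draw a mapping uniformly over all C(n, N) subsets."""
    if not 0 < N <= n:
        raise ValueError(f"need 0 < N <= n, got N={N}, n={n}")
    idx = rng.choice(n, size=N, replace=False)
    return Mapping(n=n, retained=tuple(int(i) for i in idx))


def swap_move(mapping: Mapping, rng: np.random.Generator) -> Mapping:
    """Swap one retained atom with one non-retained atom, uniformly.

    The proposal is symmetric: every ordered neighbour pair has probability
    1 / (N * (n - N)) in both directions.
    """
    n, N = mapping.n, mapping.N
    if N == 0 or N == n:
        raise ValueError(f"no swap move possible for N={N}, n={n}")
    retained = mapping.retained
    ind = mapping.indicator()
    out_idx = np.flatnonzero(~ind)
    leave = retained[rng.integers(N)]
    enter = int(out_idx[rng.integers(n - N)])
    new = set(retained)
    new.discard(leave)
    new.add(enter)
    return Mapping(n=n, retained=tuple(new))


def count_mappings(n: int, N: int) -> int:
    """Exact number of decimation mappings with N retained atoms: C(n, N)."""
    if N < 0 or N > n:
        raise ValueError(f"need 0 <= N <= n, got N={N}, n={n}")
    return math.comb(n, N)


@dataclass
class SAConfig:
    """Simulated-annealing run parameters.

    ``T0`` and ``v`` default to None, in which case ``T0`` is set to the score
    spread over 100 random mappings and ``v = steps / 5``; the resolved values
    are recorded on the returned :class:`SAResult`.
    """

    steps: int
    T0: float | None = None
    v: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.T0 is not None and self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if self.v is not None and self.v <= 0:
            raise ValueError("v must be positive")


@dataclass
class SAResult:
    best_mapping: Mapping
    best_score: float
    best_trace: np.ndarray  # best-so-far score after each step (non-increasing)
    accepted: int
    T0: float
    v: float
    final_mapping: Mapping = field(repr=False, default=None)  # type: ignore[assignment]
    final_score: float = float("nan")


def temperature_schedule(T0: float, v: float, i: int | np.ndarray) -> float | np.ndarray:
    """Effective temperature at annealing step i: T(i) = T0 * exp(-i / v)."""
    return T0 * np.exp(-np.asarray(i, dtype=float) / v)


def _default_t0(
    oracle: Callable[[Mapping], float], n: int, N: int, rng: np.random.Generator
) -> float:
    scores = [float(oracle(random_mapping(n, N, rng))) for _ in range(100)]
    spread = max(scores) - min(scores)
    return spread if spread > 0 else 1.0


def simulated_annealing(
    oracle: Callable[[Mapping], float],
    n: int,
    N: int,
    config: SAConfig,
    start: Mapping | None = None,
) -> SAResult:
    """Metropolis minimization of ``oracle`` under exponential cooling.

    At step i a swap move is proposed and accepted with probability
    ``min{1, exp(-(S' - S) / T(i))}`` where ``T(i) = T0 * exp(-i / v)``.
    The best-so-far mapping and score are tracked; the returned trace is
    non-increasing by construction.
    """
    rng = np.random.default_rng(config.seed)
    T0 = config.T0 if config.T0 is not None else _default_t0(oracle, n, N, rng)
    v = config.v if config.v is not None else config.steps / 5.0

    current = start if start is not None else random_mapping(n, N, rng)
    score = float(oracle(current))
    if not math.isfinite(score):
        raise ValueError(f"oracle returned non-finite score for mapping {current}")

    best_mapping, best_score = current, score
    trace = np.empty(config.steps + 1)
    trace[0] = best_score
    accepted = 0

    for i in range(config.steps):
        proposal = swap_move(current, rng)
        new_score = float(oracle(proposal))
        if not math.isfinite(new_score):
            raise ValueError(
                f"oracle returned non-finite score for mapping {proposal}"
            )
        delta = new_score - score
        T = T0 * math.exp(-i / v)
        if delta <= 0:
            accept = True
        elif T <= 0:
            accept = False
        else:
            accept = rng.random() < math.exp(-delta / T)
        if accept:
            current, score = proposal, new_score
            accepted += 1
            if score < best_score:
                best_mapping, best_score = current, score
        trace[i + 1] = best_score

    return SAResult(
        best_mapping=best_mapping,
        best_score=best_score,
        best_trace=trace,
        accepted=accepted,
        T0=T0,
        v=v,
        final_mapping=current,
        final_score=score,
    )
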