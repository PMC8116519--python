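"""Wang-Landau flat-histogram reconstruction of the mapping-space density of states.

The density of states Omega_N(S_map) counts, among all C(n, N) mappings with
N retained atoms, those whose score falls in a given bin.  A Wang-Landau walk
over mappings accepts a swap move M -> M' with probability
min{1, exp(Sigma[bin(M)] - Sigma[bin(M')])} where Sigma = ln Omega is the
running log density-of-states estimate; every visit adds ln f to Sigma at the
visited bin and increments the visit histogram.  When the histogram is flat
(each bin within a p_flat band around the mean) the modification factor is
halved in log space, ln f_{k+1} = ln f_k / 2, until ln f drops below a
convergence threshold.  Proposals whose score falls outside the configured
[s_min, s_max] window are rejected, and a rejected move re-registers the
current bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mapping_space import Mapping, random_mapping, swap_move

__all__ = [
    "WLConfig",
    "WLState",
    "WLResult",
    "bin_index",
    "wl_accept",
    "wl_update",
    "is_flat",
    "wl_run",
    "dos_to_probability",
]


@dataclass
class WLConfig:
    """Wang-Landau run parameters (score window in the oracle's units)."""

    s_min: float
    s_max: float
    delta_s: float = 0.2
    p_flat: float = 0.8
    ln_f0: float = 1.0
    ln_f_end: float = 1e-6
    check_interval: int = 1000
    seed: int = 0
    seeding_budget: int = 100_000  # random draws allowed to find an in-range start
    max_moves: int | None = None  # optional safety cap on total MC moves

    def __post_init__(self) -> None:
        if not self.s_min < self.s_max:
            raise ValueError("need s_min < s_max")
        if self.delta_s <= 0:
            raise ValueError("delta_s must be positive")
        if not 0 < self.p_flat <= 1:
            raise ValueError("p_flat must be in (0, 1]")
        if not 0 < self.ln_f_end < self.ln_f0:
            raise ValueError("need 0 < ln_f_end < ln_f0")
        if self.check_interval < 1:
            raise ValueError("check_interval must be >= 1")

    @property
    def n_bins(self) -> int:
        return max(1, int(math.ceil((self.s_max - self.s_min) / self.delta_s - 1e-12)))

    def bin_centers(self) -> np.ndarray:
        return self.s_min + (np.arange(self.n_bins) + 0.5) * self.delta_s


def bin_index(s: float, config: WLConfig) -> int | None:
    """Bin of score ``s``: floor((s - s_min)/delta_s); top edge closed.

    Returns ``None`` (the out-of-range marker) outside [s_min, s_max].
    """
    if s < config.s_min or s > config.s_max:
        return None
    if s == config.s_max:
        return config.n_bins - 1
    b = int((s - config.s_min) // config.delta_s)
    return min(b, config.n_bins - 1)


@dataclass
class WLState:
    """Mutable state of one Wang-Landau walk."""

    sigma: np.ndarray  # (n_bins,) running log density of states
    hist: np.ndarray  # (n_bins,) visit counts of the current iteration
    ln_f: float
    current: Mapping
    current_score: float
    current_bin: int
    ever_visited: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ever_visited is None:
            self.ever_visited = np.zeros(self.sigma.shape, dtype=bool)


def wl_accept(
    sigma: np.ndarray, bin_current: int, bin_proposed: int, rng: np.random.Generator
) -> bool:
    """Accept with probability min{1, exp(Sigma[current] - Sigma[proposed])}."""
    diff = sigma[bin_current] - sigma[bin_proposed]
    if diff >= 0:
        return True
    return rng.random() < math.exp(diff)


def wl_update(state: WLState, visited_bin: int) -> WLState:
    """Register a visit: hist += 1 and sigma += ln f at ``visited_bin``.

    On a rejected move the visited bin is the *current* bin.  Mutates and
    returns ``state``.
    """
    if visited_bin is None or not 0 <= visited_bin < state.sigma.size:
        raise ValueError(f"visited bin {visited_bin!r} is out of range")
    state.hist[visited_bin] += 1
    state.sigma[visited_bin] += state.ln_f
    state.ever_visited[visited_bin] = True
    return state


def is_flat(hist: np.ndarray, p_flat: float) -> bool:
    """True iff every count lies strictly inside the p_flat band around the mean."""
    hist = np.asarray(hist)
    if hist.size == 0:
        return False
    mean = hist.mean()
    if mean == 0:
        return False
    return bool(np.all((hist > p_flat * mean) & (hist < (2.0 - p_flat) * mean)))


@dataclass
class WLResult:
    sigma: np.ndarray  # log density of states; -inf at never-visited bins
    hist: np.ndarray  # final-iteration histogram
    ln_f_log: list[float]  # modification factor of each completed iteration
    moves_per_iteration: list[int]
    total_moves: int
    bin_centers: np.ndarray
    ever_visited: np.ndarray
    config: WLConfig


def _find_start(
    oracle: Callable[[Mapping], float], n: int, N: int, config: WLConfig,
    rng: np.random.Generator,
) -> tuple[Mapping, float, int]:
    for _ in range(config.seeding_budget):
        m = random_mapping(n, N, rng)
        s = float(oracle(m))
        if not math.isfinite(s):
            raise ValueError(f"oracle returned non-finite score for mapping {m}")
        b = bin_index(s, config)
        if b is not None:
            return m, s, b
    raise RuntimeError(
        f"no mapping with score inside [{config.s_min}, {config.s_max}] found"
        f" in {config.seeding_budget} random draws"
    )


def wl_run(
    oracle: Callable[[Mapping], float], n: int, N: int, config: WLConfig
) -> WLResult:
    """Run the full Wang-Landau self-consistent scheme.

    With the default ln_f0 = 1 and ln_f_end = 1e-6 exactly 20 halving
    iterations occur (2^-20 < 1e-6 <= 2^-19).  The returned sigma is defined
    up to an additive constant; never-visited bins carry -inf.
    """
    rng = np.random.default_rng(config.seed)
    start, start_score, start_bin = _find_start(oracle, n, N, config, rng)
    state = WLState(
        sigma=np.zeros(config.n_bins),
        hist=np.zeros(config.n_bins, dtype=np.int64),
        ln_f=config.ln_f0,
        current=start,
        current_score=start_score,
        current_bin=start_bin,
    )
    ln_f_log: list[float] = []
    moves_per_iteration: list[int] = []
    total = 0

    while state.ln_f >= config.ln_f_end:
        state.hist[:] = 0
        moves = 0
        while True:
            proposal = swap_move(state.current, rng)
            s = float(oracle(proposal))
            if not math.isfinite(s):
                raise ValueError(
                    f"oracle returned non-finite score for mapping {proposal}"
                )
            b = bin_index(s, config)
            if b is not None and wl_accept(state.sigma, state.current_bin, b, rng):
                state.current, state.current_score, state.current_bin = proposal, s, b
            wl_update(state, state.current_bin)
            moves += 1
            total += 1
            if config.max_moves is not None and total > config.max_moves:
                raise RuntimeError(f"exceeded max_moves = {config.max_moves}")
            if moves % config.check_interval == 0 and is_flat(
                state.hist[state.ever_visited], config.p_flat
            ):
                break
        ln_f_log.append(state.ln_f)
        moves_per_iteration.append(moves)
        state.ln_f /= 2.0

    sigma = np.where(state.ever_visited, state.sigma, -np.inf)
    return WLResult(
        sigma=sigma,
        hist=state.hist.copy(),
        ln_f_log=ln_f_log,
        moves_per_iteration=moves_per_iteration,
        total_moves=total,
        bin_centers=config.bin_centers(),
        ever_visited=state.ever_visited.copy(),
        config=config,
    )


def dos_to_probability(sigma: np.ndarray) -> np.ndarray:
    """Normalize exp(sigma) to a probability vector (log-sum-exp stabilized).

    Bins with sigma = -inf (never visited) get probability 0.
    """
    sigma = np.asarray(sigma, dtype=float)
    finite = np.isfinite(sigma)
    if not finite.any():
        raise ValueError("all bins are unvisited; no density of states to normalize")
    out = np.zeros(sigma.size)
    shifted = sigma[finite] - sigma[finite].max()
    expd = np.exp(shifted)
    out[finite] = expd / expd.sum()
    return out
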