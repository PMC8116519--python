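"""Simulated-annealing search for low-scoring coarse-grained mappings.

On a 10-atom toy whose 120-element mapping space can be enumerated, the
annealer's result is compared against the true global minimum.
"""

import numpy as np

import mapent as me
from mapent.mapping_space import SAConfig
from mapent.synthetic import enumerate_scores

atoms = me.make_toy_structure(6, seed=3).take(range(10))
graph = me.build_graph(atoms)
oracle = me.ToyOracle(graph)

scores = enumerate_scores(oracle, n=10, N=3)
print(f"mapping space: {scores.size} subsets,"
      f" scores in [{scores.min():.2f}, {scores.max():.2f}]")

result = me.simulated_annealing(oracle, n=10, N=3, config=SAConfig(steps=2000, seed=1))
print(f"annealing: T0 = {result.T0:.2f} (score spread), v = {result.v:.0f} steps")
print(f"best mapping {result.best_mapping.retained} with score {result.best_score:.3f}")
print(f"true global minimum: {scores.min():.3f}")
print(f"best-score trace is non-increasing: "
      f"{bool(np.all(np.diff(result.best_trace) <= 0))}")
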