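"""Spider-wasp metaheuristic on a known test function.

Latin-hypercube initialisation, 70/30 search/follow roles, Cauchy elite
perturbation, inheritance with differential mutation and 20% culling.
The best-ever fitness trace is monotone; on the 2-D sphere the optimum
(zero) is approached to ~1e-5 within 100 generations.
"""

import numpy as np

from strokerisk import SWOConfig, optimize

config = SWOConfig(
    bounds=((-5.12, 5.12), (-5.12, 5.12)),
    population=30,
    max_generations=100,
    patience=100,
    seed=1,
)
result = optimize(lambda p: float(np.sum(p**2)), config)

print(f"best position: {np.round(result.best_position, 4)} (optimum: [0, 0])")
print(f"best fitness:  {result.best_fitness:.2e} after {result.generations} generations "
      f"({result.evaluations} objective evaluations)")
marks = [0, 5, 10, 25, 50, 100]
print("best-ever trace:", {g: f"{result.trace[g]:.3g}" for g in marks if g < len(result.trace)})
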