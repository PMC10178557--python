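"""Minimize a benchmark function with the Runge-Kutta optimizer (RUN).

RUN is a population metaheuristic whose moves are assembled like a
fourth-order Runge-Kutta step from slope terms around the better/worse of
the current solution and a random partner, plus an Enhanced Solution
Quality phase that blends the population average with the global best.
"""

import numpy as np

from runsvm import RunParams, optimize


def sphere(y):
    return float(np.sum(y**2))


params = RunParams(pop_size=30, max_iter=100, r_min=-5.0, r_max=5.0, seed=1)
result = optimize(sphere, params, d=10)

print(f"10-d sphere, bounds [-5, 5], {params.pop_size} agents, "
      f"{params.max_iter} iterations")
print(f"final best objective: {result.best.fitness:.3e} "
      f"(0 is the global minimum)")
print(f"objective evaluations: {result.evaluations} "
      f"(bound: N(1+3T) = {params.pop_size * (1 + 3 * params.max_iter)})")
print(f"best-so-far trace is non-increasing: {bool(np.all(np.diff(result.trace) <= 0))}")
print("trace milestones (iteration: best):",
      {t: f"{result.trace[t]:.2e}" for t in (0, 9, 49, 99)})
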