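"""Bayesian optimization of an analytic objective.

Minimizes f(x) = (x - 0.3)^2 on [0, 1] with a 30-evaluation budget and
the 1e-4 stop threshold: four random seed trials, then fit-surrogate /
maximize-EI / evaluate until the threshold or budget is hit.
"""

from smearopt import run_bayesian_optimization
from smearopt.search import SearchSpace, SearchVariable

space = SearchSpace([SearchVariable("x", 0.0, 1.0)])
result = run_bayesian_optimization(
    lambda p: (p["x"] - 0.3) ** 2,
    space,
    max_evaluations=30,
    stop_threshold=1e-4,
    n_initial=4,
    rng=1,
)

print("iter   x        f(x)")
for t in result.history:
    print(f"{t.iteration:>4} {t.point_raw['x']:8.4f} {t.objective:10.6f}")
print(f"\nstopped by {result.stopped_by} after {len(result.history)} trials")
print(f"best point x = {result.best_point['x']:.4f} "
      f"(true minimum 0.3), f = {result.best_objective:.2e}")
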