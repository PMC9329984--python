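"""Expected-Improvement Bayesian optimization over a search space.

The loop seeds the history with random trials, fits the Matérn 5/2 GP
surrogate (:mod:`smearopt.gp`) to all finished trials, maximizes Expected
Improvement over quasi-random candidates with local refinement, evaluates
the chosen point, and repeats until the evaluation budget is exhausted or
the objective falls to the stop threshold.  Everything is driven by one
seeded generator, so a run on a deterministic objective is reproducible
bit for bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, qmc

from .gp import GPFitConfig, GPModel, gp_fit
from .search import SearchSpace

__all__ = [
    "TrialRecord",
    "BOResult",
    "expected_improvement",
    "maximize_acquisition",
    "run_bayesian_optimization",
    "write_trace_csv",
]


@dataclass
class TrialRecord:
    """One objective evaluation: where, what it scored, and whether it ran."""

    iteration: int
    point_raw: dict[str, float]
    point_unit: np.ndarray
    objective: float
    status: str = "ok"  # "ok" | "failed"


@dataclass
class BOResult:
    """Full optimization trace plus the incumbent."""

    history: list[TrialRecord]
    best_point: dict[str, float]
    best_objective: float
    stopped_by: str  # "budget" | "threshold"

    def running_minimum(self) -> np.ndarray:
        """Best ok objective seen up to each iteration."""
        best, out = np.inf, []
        for t in self.history:
            if t.status == "ok":
                best = min(best, t.objective)
            out.append(best)
        return np.array(out)


def expected_improvement(mean, sd, f_best):
    """Closed-form EI for minimization.

    EI = (f_best - mu) * Phi(z) + s * phi(z),  z = (f_best - mu) / s,
    with the s -> 0 limit max(f_best - mu, 0).  Accepts scalars or arrays.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    scalar = mean.ndim == 0 and sd.ndim == 0
    mean, sd = np.atleast_1d(mean), np.atleast_1d(sd)
    improve = f_best - mean
    ei = np.maximum(improve, 0.0)
    pos = sd > 0
    if np.any(pos):
        z = improve[pos] / sd[pos]
        ei = ei.copy()
        ei[pos] = improve[pos] * norm.cdf(z) + sd[pos] * norm.pdf(z)
    ei = np.maximum(ei, 0.0)
    return float(ei[0]) if scalar else ei


def _is_duplicate(x: np.ndarray, X_seen: np.ndarray, tol: float = 1e-12) -> bool:
    if X_seen.size == 0:
        return False
    return bool(np.any(np.all(np.abs(X_seen - x[None, :]) <= tol, axis=1)))


def maximize_acquisition(
    model: GPModel,
    space: SearchSpace,
    f_best: float,
    rng: np.random.Generator | int | None = None,
    n_candidates: int = 2048,
    n_refine: int = 5,
) -> np.ndarray:
    """Pick the next unit-cube point by maximizing Expected Improvement.

    Scores ``n_candidates`` scrambled-Sobol points (integer dimensions
    snapped to their admissible grid before scoring), then polishes the
    ``n_refine`` best with bounded quasi-Newton moves in the continuous
    coordinates.  Exact duplicates of already-evaluated points fall back
    to the best non-duplicate candidate.
    """
    if model.n == 0:
        raise RuntimeError("acquisition requires a fitted model with history")
    rng = np.random.default_rng(rng)
    d = space.dimension

    sobol = qmc.Sobol(d, scramble=True, seed=int(rng.integers(2**31 - 1)))
    cand = sobol.random(n_candidates)
    cand = space.snap(cand)

    mean, sd = model.predict(cand)
    ei = expected_improvement(mean, sd, f_best)
    order = np.argsort(-ei)

    cont = [j for j, v in enumerate(space.variables) if v.kind == "continuous"]

    def neg_ei_cont(z, base):
        x = base.copy()
        x[cont] = np.clip(z, 0.0, 1.0)
        m, s = model.predict(x)
        return -expected_improvement(float(m[0]), float(s[0]), f_best)

    refined = [(ei[i], cand[i]) for i in order]
    if cont:
        for i in order[:n_refine]:
            base = cand[i].copy()
            res = minimize(
                neg_ei_cont,
                base[cont],
                args=(base,),
                method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * len(cont),
                options={"maxiter": 60},
            )
            x = base.copy()
            x[cont] = np.clip(res.x, 0.0, 1.0)
            x = space.snap(x)
            m, s = model.predict(x)
            refined.append(
                (float(expected_improvement(float(m[0]), float(s[0]), f_best)), x)
            )

    refined.sort(key=lambda t: -t[0])
    for _, x in refined:
        if not _is_duplicate(x, model.X):
            return x
    # every candidate duplicates history: perturb the best one randomly
    x = refined[0][1] + 1e-6 * rng.standard_normal(d)
    return space.snap(x)


def run_bayesian_optimization(
    objective: Callable[[Mapping[str, float]], float],
    space: SearchSpace,
    max_evaluations: int = 30,
    stop_threshold: float = 1e-4,
    n_initial: int = 4,
    rng: np.random.Generator | int | None = None,
    gp_config: GPFitConfig | None = None,
    callback: Callable[[TrialRecord], None] | None = None,
) -> BOResult:
    """Minimize ``objective`` over ``space`` under an evaluation budget.

    ``objective`` receives a point as a mapping of variable names to values
    in natural units and returns a real score (lower is better).  A trial
    whose objective raises is recorded as failed and assigned the worst ok
    objective observed so far (1.0 before any ok trial), keeping the
    surrogate informed without aborting the search.

    Stops at the first ok objective ``<= stop_threshold`` or when
    ``max_evaluations`` trials have run.
    """
    if not 1 <= n_initial <= max_evaluations:
        raise ValueError("need max_evaluations >= n_initial >= 1")
    rng = np.random.default_rng(rng)

    history: list[TrialRecord] = []
    X: list[np.ndarray] = []
    y: list[float] = []
    stopped_by = "budget"

    def record(x_unit: np.ndarray) -> TrialRecord:
        raw = space.denormalize(x_unit)
        # re-normalize so the stored unit point matches the (rounded) raw point
        x_unit = space.normalize(raw)
        try:
            value = float(objective(raw))
            if not np.isfinite(value):
                raise FloatingPointError("objective returned non-finite value")
            status = "ok"
        except Exception:
            ok_vals = [t.objective for t in history if t.status == "ok"]
            value = max(ok_vals) if ok_vals else 1.0
            status = "failed"
        trial = TrialRecord(
            iteration=len(history) + 1,
            point_raw=raw,
            point_unit=x_unit,
            objective=value,
            status=status,
        )
        history.append(trial)
        X.append(x_unit)
        y.append(value)
        if callback is not None:
            callback(trial)
        return trial

    for _ in range(n_initial):
        trial = record(space.snap(rng.random(space.dimension)))
        if trial.status == "ok" and trial.objective <= stop_threshold:
            stopped_by = "threshold"
            break

    while stopped_by == "budget" and len(history) < max_evaluations:
        fit_seed = int(rng.integers(2**31 - 1))
        acq_seed = int(rng.integers(2**31 - 1))
        model = gp_fit(np.array(X), np.array(y), config=gp_config, rng=fit_seed)
        ok_vals = [t.objective for t in history if t.status == "ok"]
        f_best = min(ok_vals) if ok_vals else min(y)
        x_next = maximize_acquisition(model, space, f_best, rng=acq_seed)
        trial = record(x_next)
        if trial.status == "ok" and trial.objective <= stop_threshold:
            stopped_by = "threshold"

    ok = [t for t in history if t.status == "ok"]
    pool = ok if ok else history
    best = min(pool, key=lambda t: t.objective)
    return BOResult(
        history=history,
        best_point=dict(best.point_raw),
        best_objective=best.objective,
        stopped_by=stopped_by,
    )


def write_trace_csv(result: BOResult, path, columns: Sequence[str] | None = None):
    """Write the optimization trace as a CSV.

    The header is ``iteration,objective`` followed by each search variable
    in natural units.  By default variables appear alphabetically, which
    for the standard four-variable CNN space yields
    ``iteration,objective,cbd,initial_learning_rate,momentum,regularization``.
    """
    if not result.history:
        raise ValueError("empty history")
    if columns is None:
        columns = sorted(result.history[0].point_raw)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "objective", *columns])
        for t in result.history:
            writer.writerow(
                [t.iteration, repr(t.objective)]
                + [repr(t.point_raw[c]) for c in columns]
            )
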