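"""The Runge-Kutta optimizer (RUN): a population metaheuristic for box-bounded
continuous minimization.

RUN moves each member of a population of candidate solutions with a search
direction assembled like a fourth-order Runge-Kutta step: four slope terms
``k1..k4`` evaluated around the better/worse of the current solution and a
random partner, combined as ``yRK = k1 + 2 k2 + 2 k3 + k4`` and scaled into
the search mechanism ``SM = Δy · yRK / 6``.  Each main update is followed,
with probability 0.5, by an Enhanced Solution Quality (ESQ) phase that mixes
the population average with the global best and optionally extrapolates along
the RK direction, with greedy acceptance throughout.  Greedy acceptance makes
the best-so-far trace non-increasing for every seed.

All stochastic draws come from a single seeded generator in a fixed order, so
a run is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, EvaluationError

__all__ = [
    "RunParams",
    "Candidate",
    "RKTerms",
    "OptimizationResult",
    "initialize_population",
    "scale_factor",
    "rk_search_direction",
    "solution_update",
    "esq_step",
    "optimize",
]

#: floor keeping the position increment away from zero (division guard)
DELTA_EPS = 1e-12

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class RunParams:
    """Configuration of one RUN search.

    ``pop_size``/``max_iter`` default to the 30-agents / 100-iterations
    protocol.  ``a`` and ``b`` shape the adaptive scale factor
    ``SF = 2 (0.5 - rand) · a · exp(-b · rand · t/T)``: ``a`` bounds |SF| and
    ``b`` controls how fast its magnitude decays over iterations (exploration
    early, exploitation late).
    """

    pop_size: int = 30
    max_iter: int = 100
    r_min: float | np.ndarray = 0.0
    r_max: float | np.ndarray = 1.0
    a: float = 20.0
    b: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ConfigurationError(
                f"pop_size must be >= 4 (ESQ needs three random partners), got {self.pop_size}"
            )
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("scale-factor constants a, b must be positive")
        if np.any(np.asarray(self.r_min) > np.asarray(self.r_max)):
            raise ConfigurationError("r_min must be <= r_max componentwise")

    def bounds(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.broadcast_to(np.asarray(self.r_min, dtype=float), (d,)).copy()
        hi = np.broadcast_to(np.asarray(self.r_max, dtype=float), (d,)).copy()
        return lo, hi


@dataclass(frozen=True)
class Candidate:
    """A position in the search box together with its objective value."""

    position: np.ndarray
    fitness: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).copy()
        )


@dataclass(frozen=True)
class RKTerms:
    """The four RK slope vectors and their assembly.

    Invariants: ``y_rk == k1 + 2 k2 + 2 k3 + k4`` and
    ``sm == delta_y * y_rk / 6`` hold exactly (they are assembled, not
    re-derived).
    """

    k1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    k4: np.ndarray
    delta_y: np.ndarray
    y_rk: np.ndarray = field(init=False)
    sm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        y_rk = self.k1 + 2.0 * self.k2 + 2.0 * self.k3 + self.k4
        object.__setattr__(self, "y_rk", y_rk)
        object.__setattr__(self, "sm", self.delta_y * y_rk / 6.0)


@dataclass(frozen=True)
class OptimizationResult:
    best: Candidate
    trace: np.ndarray  # best-so-far fitness per iteration, non-increasing
    evaluations: int


def _evaluate(objective: Objective, position: np.ndarray, context: str) -> float:
    value = float(objective(position))
    if not np.isfinite(value):
        raise EvaluationError(f"objective returned non-finite value {value} at {context}")
    return value


def initialize_population(
    params: RunParams, d: int, objective: Objective, rng: np.random.Generator
) -> list[Candidate]:
    """Uniform random population ``y = r_min + rand · (r_max - r_min)``."""
    if d < 1:
        raise ConfigurationError(f"dimension must be >= 1, got {d}")
    lo, hi = params.bounds(d)
    population = []
    for n in range(params.pop_size):
        position = lo + rng.uniform(size=d) * (hi - lo)
        population.append(
            Candidate(position, _evaluate(objective, position, f"init candidate {n}"))
        )
    return population


def scale_factor(t: int, params: RunParams, rng: np.random.Generator) -> float:
    """Adaptive scale factor ``SF = 2 (0.5 - rand) · f``, ``f = a e^{-b·rand·t/T}``.

    Draw order: first the sign/magnitude uniform, then the decay uniform.
    |SF| <= a always; its expected magnitude decays with the iteration count,
    shifting the search from exploration to exploitation.
    """
    sign_rand = rng.uniform()
    decay_rand = rng.uniform()
    f = params.a * np.exp(-params.b * decay_rand * t / params.max_iter)
    return 2.0 * (0.5 - sign_rand) * f


def rk_search_direction(
    yn: Candidate,
    pool: Sequence[Candidate],
    params: RunParams,
    d: int,
    t: int,
    rng: np.random.Generator,
) -> RKTerms:
    """Build the RK slope terms around the current solution and its partners.

    ``yb``/``yw`` are the better/worse of the current solution and the best of
    the three random partners.  The position increment is
    ``Δy = 2 rand ⊙ |Stp| + ε`` with
    ``Stp = rand ⊙ ((yb - rand · yavg) + γ)`` and
    ``γ = rand ⊙ (yn - rand ⊙ (r_max - r_min)) · exp(-4t/T)``;
    the ε floor keeps the 1/(2Δy) slopes finite.  k2..k4 re-evaluate the k1
    expression with fresh uniform draws at positions advanced by ``k1·Δy``,
    ``k2/2·Δy`` and ``k3·Δy``.
    """
    lo, hi = params.bounds(d)
    pool_best = min(pool, key=lambda c: c.fitness)
    if yn.fitness < pool_best.fitness:
        better, worse = yn.position, pool_best.position
    else:
        better, worse = pool_best.position, yn.position
    y_avg = np.mean([c.position for c in pool], axis=0)

    gamma = (
        rng.uniform(size=d)
        * (yn.position - rng.uniform(size=d) * (hi - lo))
        * np.exp(-4.0 * t / params.max_iter)
    )
    stp = rng.uniform(size=d) * ((better - rng.uniform() * y_avg) + gamma)
    delta_y = 2.0 * rng.uniform(size=d) * np.abs(stp) + DELTA_EPS

    u = np.round(1.0 + rng.uniform()) * (1.0 - rng.uniform())

    def slope(advance: np.ndarray) -> np.ndarray:
        return (rng.uniform() * (worse + advance) - u * (better + advance)) / (
            2.0 * delta_y
        )

    k1 = slope(np.zeros(d))
    k2 = slope(k1 * delta_y)
    k3 = slope(k2 / 2.0 * delta_y)
    k4 = slope(k3 * delta_y)
    return RKTerms(k1=k1, k2=k2, k3=k3, k4=k4, delta_y=delta_y)


def _clip(position: np.ndarray, params: RunParams) -> np.ndarray:
    lo, hi = params.bounds(len(position))
    return np.clip(position, lo, hi)


def solution_update(
    yn: Candidate,
    pool: Sequence[Candidate],
    ybest: Candidate,
    yb: Candidate,
    rk: RKTerms,
    t: int,
    params: RunParams,
    objective: Objective,
    rng: np.random.Generator,
) -> Candidate:
    """The main RUN position update with greedy acceptance.

    Local anchors: ``yc = φ yn + (1-φ) yr1`` and ``ym = φ ybest + (1-φ) yb``
    with φ ~ U[0,1].  With probability 0.5 the move is made around ``yc``
    (exploitation near the current solution), otherwise around ``ym``
    (attraction to the best solutions)::

        y' = (yc·SF·r·g + yc) + SF·SM + μ·ξ·(ym - yc)      (branch 1)
        y' = (ym·SF·r·g + ym) + SF·SM + μ·ξ·(yr1 - yr2)    (branch 2)

    with r ∈ {-1, 1}, g ~ U[0,2], μ = 0.5 + 0.1·ξ' and ξ, ξ' standard normal.
    The result is clipped to the box and the better of yn / y' is returned.
    """
    yr1, yr2 = pool[0], pool[1]
    sf = scale_factor(t, params, rng)
    r = 1 if rng.uniform() < 0.5 else -1
    g = rng.uniform(0.0, 2.0)
    mu = 0.5 + 0.1 * rng.standard_normal()
    xi = rng.standard_normal()
    phi = rng.uniform()
    yc = phi * yn.position + (1.0 - phi) * yr1.position
    ym = phi * ybest.position + (1.0 - phi) * yb.position

    if rng.uniform() < 0.5:
        position = (yc * sf * r * g + yc) + sf * rk.sm + mu * xi * (ym - yc)
    else:
        position = (ym * sf * r * g + ym) + sf * rk.sm + mu * xi * (
            yr1.position - yr2.position
        )
    position = _clip(position, params)
    candidate = Candidate(position, _evaluate(objective, position, f"update t={t}"))
    return candidate if candidate.fitness < yn.fitness else yn


def esq_step(
    current: Candidate,
    population: Sequence[Candidate],
    index: int,
    ybest: Candidate,
    yb: Candidate,
    rk: RKTerms,
    t: int,
    params: RunParams,
    objective: Objective,
    rng: np.random.Generator,
) -> Candidate:
    """Enhanced Solution Quality: escape local optima via blended candidates.

    Executed with probability 0.5.  Three random partners (distinct from the
    current index) give ``yavg``; ``ynew1 = β ⊙ yavg + (1-β) ⊙ ybest`` with
    β ~ U[0,1]^d pulls between the neighborhood average and the global best.
    ``ynew2`` perturbs it by ``w·r·|…+ξ|`` where ``w = U[0,2]·e^{-c·t/T}``
    (c = 5·rand) shrinks over iterations and r ∈ {-1, 0, 1}.  If ``ynew2``
    does not improve on the current solution, with probability min(w, 1) a
    final extrapolation ``ynew3`` along the RK direction is tried.  Greedy:
    the returned candidate is never worse than the input.
    """
    if rng.uniform() >= 0.5:
        return current
    n = len(population)
    choices = np.array([j for j in range(n) if j != index])
    partners = rng.permutation(choices)[:3]
    yavg = np.mean([population[j].position for j in partners], axis=0)
    d = len(current.position)

    beta = rng.uniform(size=d)
    ynew1 = beta * yavg + (1.0 - beta) * ybest.position
    w = rng.uniform(0.0, 2.0) * np.exp(-(5.0 * rng.uniform()) * t / params.max_iter)
    r = int(rng.integers(-1, 2))
    xi = rng.standard_normal()
    u = rng.uniform()
    if w < 1.0:
        ynew2 = w * r * np.abs((ynew1 - yavg) + xi) + ynew1
    else:
        ynew2 = w * r * np.abs((u * ynew1 - yavg) + xi) + (ynew1 - yavg)
    ynew2 = _clip(ynew2, params)
    cand2 = Candidate(ynew2, _evaluate(objective, ynew2, f"esq ynew2 t={t}"))
    if cand2.fitness < current.fitness:
        return cand2

    if rng.uniform() < w:
        sf = scale_factor(t, params, rng)
        v = 2.0 * rng.uniform()
        ynew3 = sf * (
            (v * yb.position - cand2.position) + rng.uniform() * rk.y_rk
        ) + (cand2.position - rng.uniform() * cand2.position)
        ynew3 = _clip(ynew3, params)
        cand3 = Candidate(ynew3, _evaluate(objective, ynew3, f"esq ynew3 t={t}"))
        if cand3.fitness < current.fitness:
            return cand3
    return current


def optimize(objective: Objective, params: RunParams, d: int) -> OptimizationResult:
    """Run the full RUN loop for ``max_iter`` iterations.

    Per iteration the iteration-best ``yb`` is fixed at the iteration start;
    every candidate undergoes the main update followed by the (probabilistic)
    ESQ phase; the global best is refreshed after each candidate so later
    candidates see it.  Objective calls are counted; the total never exceeds
    ``N (1 + 3 T)``.
    """
    rng = np.random.default_rng(params.seed)
    calls = 0

    def counted(position: np.ndarray) -> float:
        nonlocal calls
        calls += 1
        return objective(position)

    population = initialize_population(params, d, counted, rng)
    ybest = min(population, key=lambda c: c.fitness)
    trace = np.empty(params.max_iter)
    for t in range(params.max_iter):
        yb = min(population, key=lambda c: c.fitness)
        for n in range(params.pop_size):
            choices = np.array([j for j in range(params.pop_size) if j != n])
            pool = [population[j] for j in rng.permutation(choices)[:3]]
            rk = rk_search_direction(population[n], pool, params, d, t, rng)
            cand = solution_update(
                population[n], pool, ybest, yb, rk, t, params, counted, rng
            )
            cand = esq_step(
                cand, population, n, ybest, yb, rk, t, params, counted, rng
            )
            population[n] = cand
            if cand.fitness < ybest.fitness:
                ybest = cand
        trace[t] = ybest.fitness
    return OptimizationResult(best=ybest, trace=trace, evaluations=calls)
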