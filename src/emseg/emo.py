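"""Electromagnetism-Like Optimization (EMO) over a bounded box.

EMO is a population metaheuristic for maximising a function f on a box
X = prod_i [l_i, u_i].  Each candidate point carries a "charge" derived from
its relative fitness,

    q_i = exp( -n * (f_best - f_i) / sum_j (f_best - f_j) ),

so the best point has charge 1 and worse points exponentially less.  Points
exert Coulomb-like pairwise forces of magnitude q_i q_j / d^2: a point is
attracted toward better points and repelled from worse ones.  Every point
except the incumbent best moves along its net force direction, scaled per
coordinate by a uniform random fraction of the distance to the box wall,
and is then refined by a bounded random local search.  The best point is
elitist: it never moves, so the best-score trace is non-decreasing.

Two numerical guards keep the force computation finite: fitness values are
capped at a large constant before charge computation, and pairwise
separations are clamped below by ``eps_sep``.  An optional anti-stagnation
device resamples one non-best point uniformly ("perturbed point") whenever
the population's coordinate-wise spread collapses below 1% of the box
width, and lets it act as a co-best attractor for that iteration's forces.

For integer search spaces (threshold vectors), positions evolve in
continuous coordinates; candidates are rounded, sorted and de-duplicated
before each objective evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "EMOParams",
    "Population",
    "EMOResult",
    "initialize_population",
    "compute_charges",
    "compute_total_forces",
    "move_population",
    "local_search",
    "emo_optimize",
    "save_trace_csv",
]

_FITNESS_CAP = 1e100


@dataclass
class EMOParams:
    """Parameters of the EMO search.

    Attributes
    ----------
    bounds : ndarray, shape (m, 2)
        Per-dimension lower/upper limits ``[l_i, u_i]``.
    n_pop : int
        Population size N (>= 2).
    k_max : int
        Number of iterations.
    k_local : int
        Local-search budget multiplier: up to ``m * k_local`` candidates
        are probed around each moved point.
    lambda_local : float
        Local-search neighborhood radius as a fraction of the box width
        per dimension, in (0, 1].
    eps_sep : float
        Minimum inter-point separation used in the force denominator
        (same units as the box); default 1e-9 x the largest box width.
    integer : bool
        Round/sort/repair candidate coordinates to a strictly increasing
        integer vector before every objective evaluation.
    perturb : bool
        Enable the perturbed-point anti-stagnation device.
    seed : int
        RNG seed; the entire run is reproducible given the seed.
    """

    bounds: np.ndarray
    n_pop: int = 30
    k_max: int = 100
    k_local: int = 10
    lambda_local: float = 0.25
    eps_sep: Optional[float] = None
    integer: bool = False
    perturb: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.bounds.shape[1] != 2:
            raise ValueError("bounds must be an (m, 2) array of [l, u]")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("every lower bound must be < its upper bound")
        if self.n_pop < 2:
            raise ValueError("population size must be >= 2")
        if self.m < 1 or self.k_max < 1 or self.k_local < 0:
            raise ValueError("m >= 1, k_max >= 1 and k_local >= 0 required")
        if not (0.0 < self.lambda_local <= 1.0):
            raise ValueError("lambda_local must be in (0, 1]")
        if self.eps_sep is None:
            self.eps_sep = 1e-9 * float(np.max(self.widths))
        if self.eps_sep <= 0:
            raise ValueError("eps_sep must be > 0")

    @property
    def m(self) -> int:
        return self.bounds.shape[0]

    @property
    def lower(self) -> np.ndarray:
        return self.bounds[:, 0]

    @property
    def upper(self) -> np.ndarray:
        return self.bounds[:, 1]

    @property
    def widths(self) -> np.ndarray:
        return self.bounds[:, 1] - self.bounds[:, 0]


@dataclass
class Population:
    points: np.ndarray        # (N, m) positions inside the box
    fitness: np.ndarray       # (N,)
    charges: np.ndarray       # (N,) in (0, 1]
    best_index: int
    iteration: int = 1


@dataclass
class EMOResult:
    best_point: np.ndarray
    best_score: float
    trace_scores: np.ndarray   # per-iteration incumbent best score
    trace_points: np.ndarray   # per-iteration incumbent best point
    params: EMOParams = field(repr=False, default=None)


def _decode_integer_tuple(x, lo: int, hi: int) -> tuple:
    """Round to integers, sort ascending, repair duplicates within [lo, hi].

    Duplicates after rounding are repaired by incrementing collided values;
    overflow past the upper bound is pulled back while keeping strict order
    (caps hi - (m-1-i) decrease by exactly 1 per position, so the pulled-back
    vector stays strictly increasing).
    """
    v = sorted(int(round(float(c))) for c in x)
    m = len(v)
    prev = lo - 1
    for i in range(m):
        if v[i] <= prev:
            v[i] = prev + 1
        prev = v[i]
    for i in range(m - 1, -1, -1):
        cap = hi - (m - 1 - i)
        if v[i] > cap:
            v[i] = cap
        else:
            break
    return tuple(v)


class _Evaluator:
    """Wraps the raw objective with integer decoding and memoisation."""

    def __init__(self, objective: Callable, params: EMOParams):
        self._objective = objective
        self._params = params
        self._cache: dict = {}
        self._lo = int(np.floor(params.lower[0]))
        self._hi = int(np.floor(params.upper[-1]))
        if params.integer and self._hi - self._lo + 1 < params.m:
            raise ValueError("integer box too narrow for m distinct values")

    def decode(self, x: np.ndarray) -> np.ndarray:
        if self._params.integer:
            return np.asarray(_decode_integer_tuple(x, self._lo, self._hi),
                              dtype=np.int64)
        return np.asarray(x, dtype=float)

    def __call__(self, x: np.ndarray) -> float:
        if self._params.integer:
            key = _decode_integer_tuple(x, self._lo, self._hi)
            hit = self._cache.get(key)
            if hit is None:
                hit = float(self._objective(np.asarray(key, dtype=np.int64)))
                self._cache[key] = hit
            return hit
        return float(self._objective(np.asarray(x, dtype=float)))


def initialize_population(objective: Callable, params: EMOParams,
                          rng: np.random.Generator) -> Population:
    """Draw N points i.i.d. uniform over the box and evaluate them."""
    pts = rng.uniform(params.lower, params.upper, size=(params.n_pop, params.m))
    fit = np.array([objective(p) for p in pts])
    charges = compute_charges(fit, params.m)
    return Population(points=pts, fitness=fit, charges=charges,
                      best_index=int(np.argmax(fit)), iteration=1)


def compute_charges(fitness: Sequence[float], m: int) -> np.ndarray:
    """Fitness-relative charges q_i = exp(-m (f_best - f_i) / sum_j (f_best - f_j)).

    The best point gets charge 1; charges are monotone in fitness.  An
    all-equal population gets uniform charge 1 (avoids 0/0).
    """
    f = np.clip(np.asarray(fitness, dtype=float), -_FITNESS_CAP, _FITNESS_CAP)
    if f.size == 0:
        raise ValueError("fitness vector is empty")
    gaps = f.max() - f
    denom = gaps.sum()
    if denom <= 0.0:
        return np.ones_like(f)
    return np.exp(-m * gaps / denom)


def compute_total_forces(pop: Population, eps_sep: float,
                         fitness: Optional[np.ndarray] = None) -> np.ndarray:
    """Net Coulomb-like force on every point.

    The force on i from j has magnitude q_i q_j / d^2 (d clamped below by
    ``eps_sep``) and points toward j when f_j > f_i, away otherwise.
    ``fitness`` overrides the population fitness for direction decisions
    (used by the perturbed-point device).
    """
    f = pop.fitness if fitness is None else fitness
    x, q = pop.points, pop.charges
    diff = x[None, :, :] - x[:, None, :]          # diff[i, j] = x_j - x_i
    dist = np.maximum(np.linalg.norm(diff, axis=2), eps_sep)
    mag = (q[:, None] * q[None, :]) / dist**2
    # toward j when f_j > f_i (attraction), away otherwise (repulsion)
    sign = np.where(f[None, :] > f[:, None], 1.0, -1.0)
    contrib = (sign * mag / dist)[:, :, None] * diff
    np.einsum("iik->ik", contrib)[:] = 0.0        # no self-force
    return contrib.sum(axis=1)


def move_population(pop: Population, forces: np.ndarray, params: EMOParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Move every non-best point along its normalised net force.

    Per coordinate the step is ``mu * fhat_d * range_d`` with mu ~ U(0,1)
    and range_d the distance to the box wall in the force direction, so a
    full step lands exactly on the wall and never beyond.  The best point
    and zero-force points stay put.
    """
    new_pts = pop.points.copy()
    for i in range(params.n_pop):
        if i == pop.best_index:
            continue
        norm = float(np.linalg.norm(forces[i]))
        if norm == 0.0:
            continue
        fhat = forces[i] / norm
        mu = rng.uniform(0.0, 1.0, size=params.m)
        x = new_pts[i]
        room = np.where(fhat > 0, params.upper - x, x - params.lower)
        x = x + mu * fhat * room
        new_pts[i] = np.clip(x, params.lower, params.upper)
    return new_pts


def local_search(point: np.ndarray, objective: Callable, params: EMOParams,
                 rng: np.random.Generator):
    """Random probing within lambda_local * box width around ``point``.

    Samples up to ``m * k_local`` candidates uniformly in the neighborhood
    (clipped to the box) and returns ``(z, f(z))`` for the first candidate
    strictly improving the objective, else the input unchanged.
    """
    f0 = objective(point)
    budget = params.m * params.k_local
    if budget == 0:
        return point.copy(), f0
    radius = params.lambda_local * params.widths
    cand = point + rng.uniform(-1.0, 1.0, size=(budget, params.m)) * radius
    np.clip(cand, params.lower, params.upper, out=cand)
    for z in cand:
        fz = objective(z)
        if fz > f0:
            return z.copy(), fz
    return point.copy(), f0


def emo_optimize(objective: Callable, params: EMOParams) -> EMOResult:
    """Run the full EMO loop: init, then k_max rounds of
    charges -> forces -> move -> local search -> selection.

    Returns the best point found (decoded to a sorted integer vector when
    ``params.integer``), its score, and the per-iteration incumbent trace.
    Bit-identical across reruns with the same params and objective.
    """
    rng = np.random.default_rng(params.seed)
    evaluate = _Evaluator(objective, params)
    pop = initialize_population(evaluate, params, rng)

    trace_scores = np.empty(params.k_max)
    trace_points = np.empty((params.k_max, params.m))

    for k in range(params.k_max):
        pop.charges = compute_charges(pop.fitness, params.m)

        force_fitness = pop.fitness
        if params.perturb:
            spread = pop.points.max(axis=0) - pop.points.min(axis=0)
            if np.all(spread < 0.01 * params.widths):
                candidates = [i for i in range(params.n_pop)
                              if i != pop.best_index]
                p_idx = int(rng.choice(candidates))
                pop.points[p_idx] = rng.uniform(params.lower, params.upper)
                pop.fitness[p_idx] = evaluate(pop.points[p_idx])
                pop.charges = compute_charges(pop.fitness, params.m)
                # the freshly-seeded point acts as a co-best attractor
                force_fitness = pop.fitness.copy()
                force_fitness[p_idx] = force_fitness.max()

        forces = compute_total_forces(pop, params.eps_sep, fitness=force_fitness)
        moved = move_population(pop, forces, params, rng)

        for i in range(params.n_pop):
            if i == pop.best_index:
                continue
            y = moved[i]
            z, fz = local_search(y, evaluate, params, rng)
            pop.points[i] = z
            pop.fitness[i] = fz

        pop.best_index = int(np.argmax(pop.fitness))
        pop.iteration = k + 1
        trace_scores[k] = pop.fitness[pop.best_index]
        trace_points[k] = pop.points[pop.best_index]

    best = evaluate.decode(pop.points[pop.best_index])
    return EMOResult(best_point=best,
                     best_score=float(pop.fitness[pop.best_index]),
                     trace_scores=trace_scores, trace_points=trace_points,
                     params=params)


def save_trace_csv(path, result: EMOResult) -> None:
    """Write the optimizer trace as CSV: iteration, best_score, best point."""
    m = result.trace_points.shape[1]
    header = "iteration,best_score," + ",".join(f"x{d}" for d in range(m))
    rows = np.column_stack([
        np.arange(1, len(result.trace_scores) + 1),
        result.trace_scores,
        result.trace_points,
    ])
    np.savetxt(path, rows, delimiter=",", header=header, comments="")
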