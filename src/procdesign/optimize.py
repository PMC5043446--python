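"""Multi-objective parameter estimation with Generalized Differential
Evolution (GDE3).

GDE3 extends differential evolution to multiple objectives: trial
vectors are generated with DE/rand/1/bin, selection is by Pareto
dominance (a trial replaces its parent only if it weakly dominates it;
if neither dominates, both survive), and the grown population is pruned
back to size with non-dominated sorting plus crowding-distance
truncation.  The final archive's non-dominated set is returned as the
Pareto front.

The evaluation callback must be total: simulation failures are expected
to be pre-mapped to worst-case objective vectors.  Out-of-box trial
components are clipped to the bounds, so the optimizer never evaluates
outside the box.  Runs are reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "OptimizerBudget",
    "ParetoFront",
    "dominates",
    "extract_front",
    "gde3_minimize",
]


@dataclass(frozen=True)
class OptimizerBudget:
    population: int = 40
    generations: int = 100
    F: float = 0.5
    CR: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.population < 4:
            raise ValueError("population must be at least 4")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")


@dataclass
class ParetoFront:
    """Mutually non-dominated (parameter vector, objective vector) pairs."""

    params: np.ndarray  # (n_points, n_dims)
    objectives: np.ndarray  # (n_points, n_objectives)
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.objectives)


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance for minimization: a <= b componentwise and a != b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal dimension")
    return bool(np.all(a <= b) and np.any(a < b))


def _nondominated_mask(objs: np.ndarray) -> np.ndarray:
    n = len(objs)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        for j in range(n):
            if i != j and keep[j]:
                le = np.all(objs[j] <= objs[i])
                lt = np.any(objs[j] < objs[i])
                if le and lt:
                    keep[i] = False
                    break
    return keep


def extract_front(points: list[tuple[np.ndarray, np.ndarray]]) -> ParetoFront:
    """Maximal non-dominated subset; duplicate objective/parameter pairs
    are collapsed deterministically (first occurrence kept)."""
    if not points:
        raise ValueError("extract_front needs at least one point")
    params = np.array([np.atleast_1d(p) for p, _ in points], dtype=float)
    objs = np.array([np.atleast_1d(o) for _, o in points], dtype=float)
    keep = _nondominated_mask(objs)
    params, objs = params[keep], objs[keep]
    seen: set[bytes] = set()
    uniq = np.zeros(len(objs), dtype=bool)
    for i in range(len(objs)):
        key = params[i].tobytes() + objs[i].tobytes()
        if key not in seen:
            seen.add(key)
            uniq[i] = True
    return ParetoFront(params[uniq], objs[uniq])


def _fast_nondominated_sort(objs: np.ndarray) -> list[np.ndarray]:
    n = len(objs)
    dominated_by = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = np.where(dom_count == 0)[0]
    while len(current):
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(nxt), dtype=int)
    return fronts


def _crowding_distance(objs: np.ndarray) -> np.ndarray:
    n, d = objs.shape
    dist = np.zeros(n)
    for m in range(d):
        order = np.argsort(objs[:, m], kind="stable")
        span = objs[order[-1], m] - objs[order[0], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            dist[order[1:-1]] += (objs[order[2:], m] - objs[order[:-2], m]) / span
    return dist


def gde3_minimize(
    evaluate: Callable[[np.ndarray], np.ndarray],
    box: list[tuple[float, float]] | np.ndarray,
    budget: OptimizerBudget,
) -> ParetoFront:
    """Minimize a vector-valued objective over a box with GDE3."""
    box = np.asarray(box, dtype=float)
    if box.ndim != 2 or box.shape[1] != 2 or not np.all(np.isfinite(box)):
        raise ValueError("box must be a finite (n_dims, 2) array")
    lo, hi = box[:, 0], box[:, 1]
    d = len(box)
    rng = np.random.default_rng(budget.seed)
    N, F, CR = budget.population, budget.F, budget.CR

    # Latin-hypercube start: stratified coverage of the box
    pop = np.empty((N, d))
    for j in range(d):
        strata = (np.arange(N) + rng.random(N)) / N
        pop[:, j] = lo[j] + rng.permutation(strata) * (hi[j] - lo[j])
    objs = np.array([np.atleast_1d(evaluate(x)) for x in pop], dtype=float)

    for _gen in range(budget.generations):
        new_pop = []
        new_objs = []
        for i in range(len(pop)):
            idx = rng.choice(len(pop) - 1, size=3, replace=False)
            idx[idx >= i] += 1
            r1, r2, r3 = pop[idx]
            trial = pop[i].copy()
            jrand = rng.integers(d)
            cross = rng.random(d) < CR
            cross[jrand] = True
            mutant = r1 + F * (r2 - r3)
            trial[cross] = mutant[cross]
            np.clip(trial, lo, hi, out=trial)
            t_obj = np.atleast_1d(evaluate(trial))
            if dominates(t_obj, objs[i]) or np.array_equal(t_obj, objs[i]):
                new_pop.append(trial)
                new_objs.append(t_obj)
            elif dominates(objs[i], t_obj):
                new_pop.append(pop[i])
                new_objs.append(objs[i])
            else:
                new_pop.append(pop[i])
                new_objs.append(objs[i])
                new_pop.append(trial)
                new_objs.append(t_obj)
        pop = np.array(new_pop)
        objs = np.array(new_objs)
        if len(pop) > N:
            keep: list[int] = []
            for front in _fast_nondominated_sort(objs):
                if len(keep) + len(front) <= N:
                    keep.extend(front.tolist())
                else:
                    dist = _crowding_distance(objs[front])
                    order = np.argsort(-dist, kind="stable")
                    keep.extend(front[order[: N - len(keep)]].tolist())
                    break
            keep = sorted(keep)
            pop, objs = pop[keep], objs[keep]

    front = extract_front(list(zip(pop, objs)))
    front.provenance = {
        "population": N,
        "generations": budget.generations,
        "F": F,
        "CR": CR,
        "seed": budget.seed,
    }
    return front
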