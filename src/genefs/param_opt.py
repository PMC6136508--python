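"""Kernel-parameter search: exhaustive grid, particle swarm, genetic algorithm.

All three optimizers maximize a user-supplied fitness (cross-validated
accuracy in this package) over the (C, gamma) plane, working in log2
coordinates as is conventional for RBF-SVM tuning.  Each returns the best
pair together with the full evaluation trace, and is pure given (fitness,
space, hyperparameters, seed).  A small exhaustive search over random-forest
(max_features, n_estimators) grids lives here too.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ParamPair",
    "SearchSpace",
    "OptimizerResult",
    "RfParamPair",
    "RfGridResult",
    "grid_search",
    "pso_search",
    "ga_search",
    "rf_grid_search",
]


@dataclasses.dataclass(frozen=True)
class ParamPair:
    """An (error penalty C, RBF width gamma) pair; both strictly positive."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    @property
    def log2(self) -> tuple[float, float]:
        return (float(np.log2(self.C)), float(np.log2(self.gamma)))

    @staticmethod
    def from_log2(log2C: float, log2gamma: float) -> "ParamPair":
        return ParamPair(C=float(2.0**log2C), gamma=float(2.0**log2gamma))


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    """Box in log2 space: (lo, hi, step) per coordinate.

    Defaults follow the established RBF-SVM convention: C in 2^[-5, 15]
    step 2, gamma in 2^[-15, 3] step 2.
    """

    log2C_range: tuple[float, float, float] = (-5.0, 15.0, 2.0)
    log2gamma_range: tuple[float, float, float] = (-15.0, 3.0, 2.0)

    def __post_init__(self) -> None:
        for lo, hi, step in (self.log2C_range, self.log2gamma_range):
            if not (lo < hi and step > 0):
                raise ValueError("each range needs lo < hi and step > 0")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.log2C_range[0], self.log2gamma_range[0]])
        hi = np.array([self.log2C_range[1], self.log2gamma_range[1]])
        return lo, hi

    def grid_points(self) -> list[tuple[float, float]]:
        """Lexicographically ordered (log2C, log2gamma) lattice, hi inclusive."""
        def axis(lo: float, hi: float, step: float) -> np.ndarray:
            n = int(np.floor((hi - lo) / step + 1e-9)) + 1
            return lo + step * np.arange(n)

        cs = axis(*self.log2C_range)
        gs = axis(*self.log2gamma_range)
        return [(float(c), float(g)) for c in cs for g in gs]


@dataclasses.dataclass
class OptimizerResult:
    """Best pair, its fitness, and the ordered evaluation trace."""

    best: ParamPair
    fitness: float
    evaluations: list[tuple[ParamPair, float]]
    seed: int | None = None

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("log2C\tlog2gamma\tC\tgamma\tfitness\n")
            for pair, fit in self.evaluations:
                l2c, l2g = pair.log2
                fh.write(f"{l2c!r}\t{l2g!r}\t{pair.C!r}\t{pair.gamma!r}\t{fit!r}\n")
        return path


@dataclasses.dataclass(frozen=True)
class RfParamPair:
    """Random-forest tuning pair: max_features per split and tree count."""

    max_features: int
    n_estimators: int

    def __post_init__(self) -> None:
        if self.max_features < 1 or self.n_estimators < 1:
            raise ValueError("max_features and n_estimators must be positive")


@dataclasses.dataclass
class RfGridResult:
    best: RfParamPair
    fitness: float
    evaluations: list[tuple[RfParamPair, float]]


def grid_search(
    fitness: Callable[[ParamPair], float], space: SearchSpace
) -> OptimizerResult:
    """Evaluate every lattice point once; ties go to the lexicographically
    smallest (log2C, log2gamma)."""
    trace: list[tuple[ParamPair, float]] = []
    best_pair: ParamPair | None = None
    best_fit = -np.inf
    for l2c, l2g in space.grid_points():
        pair = ParamPair.from_log2(l2c, l2g)
        fit = float(fitness(pair))
        trace.append((pair, fit))
        if fit > best_fit:  # strict: first (lexicographically smallest) max wins
            best_fit, best_pair = fit, pair
    return OptimizerResult(best=best_pair, fitness=best_fit, evaluations=trace)


def _clip(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, lo), hi)


def pso_search(
    fitness: Callable[[ParamPair], float],
    space: SearchSpace,
    swarm_size: int = 20,
    iterations: int = 50,
    inertia: float = 0.7,
    c1: float = 1.5,
    c2: float = 1.5,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> OptimizerResult:
    """Canonical global-best particle swarm over (log2C, log2gamma).

    Velocity update v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x) with
    per-coordinate uniform r1, r2; positions clipped to the box.  Initial
    velocities are zero; initial positions are uniform in the box unless
    ``init`` (shape (swarm_size, 2), log2 coordinates) is supplied.
    """
    if swarm_size < 1 or iterations < 1:
        raise ValueError("swarm_size and iterations must be >= 1")
    lo, hi = space.bounds
    rng = np.random.default_rng(seed)
    if init is None:
        x = rng.uniform(lo, hi, size=(swarm_size, 2))
    else:
        x = _clip(np.asarray(init, dtype=float).reshape(swarm_size, 2), lo, hi)
    v = np.zeros_like(x)
    trace: list[tuple[ParamPair, float]] = []

    def evaluate(pos: np.ndarray) -> float:
        pair = ParamPair.from_log2(pos[0], pos[1])
        fit = float(fitness(pair))
        trace.append((pair, fit))
        return fit

    pbest = x.copy()
    pbest_fit = np.array([evaluate(x[i]) for i in range(swarm_size)])
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    for _ in range(iterations):
        r1 = rng.uniform(size=(swarm_size, 2))
        r2 = rng.uniform(size=(swarm_size, 2))
        v = inertia * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest[None, :] - x)
        x = _clip(x + v, lo, hi)
        for i in range(swarm_size):
            fit = evaluate(x[i])
            if fit > pbest_fit[i]:
                pbest_fit[i] = fit
                pbest[i] = x[i]
                if fit > gbest_fit:
                    gbest_fit, gbest = fit, x[i].copy()
    return OptimizerResult(
        best=ParamPair.from_log2(gbest[0], gbest[1]),
        fitness=gbest_fit,
        evaluations=trace,
        seed=seed,
    )


def ga_search(
    fitness: Callable[[ParamPair], float],
    space: SearchSpace,
    population: int = 30,
    generations: int = 40,
    crossover_rate: float = 0.9,
    mutation_rate: float = 0.1,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> OptimizerResult:
    """Real-coded genetic algorithm over (log2C, log2gamma).

    Tournament selection (size 2), BLX-0.5 blend crossover, per-coordinate
    Gaussian mutation with sigma = 10% of the coordinate range, elitism of
    one.  The best fitness is therefore non-decreasing across generations.
    """
    if population < 2 or generations < 1:
        raise ValueError("population must be >= 2 and generations >= 1")
    lo, hi = space.bounds
    span = hi - lo
    sigma = 0.1 * span
    rng = np.random.default_rng(seed)
    if init is None:
        pop = rng.uniform(lo, hi, size=(population, 2))
    else:
        pop = _clip(np.asarray(init, dtype=float).reshape(population, 2), lo, hi)
    trace: list[tuple[ParamPair, float]] = []

    def evaluate(pos: np.ndarray) -> float:
        pair = ParamPair.from_log2(pos[0], pos[1])
        fit = float(fitness(pair))
        trace.append((pair, fit))
        return fit

    fits = np.array([evaluate(pop[i]) for i in range(population)])

    for _ in range(generations):
        elite_i = int(np.argmax(fits))
        elite, elite_fit = pop[elite_i].copy(), float(fits[elite_i])

        def tournament() -> np.ndarray:
            a, b = rng.integers(population, size=2)
            return pop[a] if fits[a] >= fits[b] else pop[b]

        children = []
        while len(children) < population - 1:
            p1, p2 = tournament().copy(), tournament().copy()
            if rng.uniform() < crossover_rate:
                # BLX-0.5: sample each coordinate from the parent interval
                # extended by half its width on both sides.
                lo_p = np.minimum(p1, p2)
                hi_p = np.maximum(p1, p2)
                d = hi_p - lo_p
                c1_ = rng.uniform(lo_p - 0.5 * d, hi_p + 0.5 * d)
                c2_ = rng.uniform(lo_p - 0.5 * d, hi_p + 0.5 * d)
            else:
                c1_, c2_ = p1, p2
            for child in (c1_, c2_):
                mask = rng.uniform(size=2) < mutation_rate
                child = child + mask * rng.normal(0.0, sigma)
                children.append(_clip(child, lo, hi))
        pop = np.vstack([elite] + children[: population - 1])
        fits = np.concatenate(
            [[elite_fit], [evaluate(p) for p in pop[1:]]]
        )
    best_i = int(np.argmax(fits))
    return OptimizerResult(
        best=ParamPair.from_log2(pop[best_i][0], pop[best_i][1]),
        fitness=float(fits[best_i]),
        evaluations=trace,
        seed=seed,
    )


def rf_grid_search(
    fitness: Callable[[RfParamPair], float],
    max_features_grid: Sequence[int],
    n_estimators_grid: Sequence[int],
) -> RfGridResult:
    """Exhaustive maximization over the RF grid.

    Ties break to the smaller n_estimators, then the smaller max_features.
    """
    if not max_features_grid or not n_estimators_grid:
        raise ValueError("grids must be non-empty")
    trace: list[tuple[RfParamPair, float]] = []
    best: RfParamPair | None = None
    best_fit = -np.inf
    for n_est in sorted(set(int(n) for n in n_estimators_grid)):
        for mf in sorted(set(int(m) for m in max_features_grid)):
            pair = RfParamPair(max_features=mf, n_estimators=n_est)
            fit = float(fitness(pair))
            trace.append((pair, fit))
            if fit > best_fit:
                best_fit, best = fit, pair
    return RfGridResult(best=best, fitness=best_fit, evaluations=trace)
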