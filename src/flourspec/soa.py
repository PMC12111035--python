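"""Starfish optimization algorithm (SOA): a bounded continuous metaheuristic.

SOA is a population algorithm organised around two phases. Early iterations
emphasise *exploration*: each starfish moves toward the current best
solution while adding a perturbation built from the difference of two
random population members, which keeps proposal directions adapted to the
shape of the landscape. Late iterations emphasise *exploitation*: small
Gaussian refinements around the elite solutions with a step size that
shrinks to zero over the budget. Each iteration the worst starfish is
*regenerated* uniformly inside the box (an escape mechanism), and every
move is accepted greedily — a candidate only replaces its predecessor if it
improves the fitness — so the best-so-far trace is non-increasing by
construction.

The optimizer is used here to minimize the cross-validated RMSE of an SVR
over (C, epsilon, gamma); :func:`decode_hyperparams` maps the unit box onto
the hyperparameter space with log-uniform scaling for C and gamma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import SvrHyperparams, cv_fitness

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "HyperparamBounds",
    "soa_minimize",
    "decode_hyperparams",
    "encode_hyperparams",
    "tune_svr",
    "OptimizationError",
]

logger = logging.getLogger(__name__)


class OptimizationError(RuntimeError):
    """All candidates of an iteration evaluated to NaN."""


@dataclass
class OptimizerConfig:
    """SOA configuration.

    ``explore_weight`` scales the difference-vector perturbation during
    exploration; ``exploit_sigma`` is the initial elite-refinement step as a
    fraction of the box width (it decays cubically to zero over the budget);
    ``elite_fraction`` sets how many top solutions seed exploitation moves.
    """

    lower: np.ndarray
    upper: np.ndarray
    population: int = 30
    iterations: int = 50
    seed: int = 0
    explore_weight: float = 0.8
    exploit_sigma: float = 0.3
    elite_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float).ravel()
        self.upper = np.asarray(self.upper, dtype=float).ravel()
        if self.lower.size != self.upper.size or self.lower.size == 0:
            raise ValueError("lower/upper bounds must have equal nonzero length")
        if not (np.all(np.isfinite(self.lower)) and np.all(np.isfinite(self.upper))):
            raise ValueError("bounds must be finite")
        if np.any(self.lower >= self.upper):
            raise ValueError("need low < high in every dimension")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def n_dim(self) -> int:
        return self.lower.size


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness after each iteration (incl. init)
    n_evaluations: int

    def trace_csv(self) -> str:
        lines = ["iteration,best_fitness"]
        lines += [f"{i},{v!r}" for i, v in enumerate(self.trace)]
        return "\n".join(lines) + "\n"


def _evaluate(objective, x) -> float:
    v = objective(x)
    try:
        v = float(v)
    except (TypeError, ValueError):
        return math.nan
    return v


def soa_minimize(
    objective: Callable[[np.ndarray], float], config: OptimizerConfig
) -> OptimizationResult:
    """Minimize ``objective`` over the box with the starfish algorithm.

    Every candidate is evaluated inside the bounds (out-of-box proposals are
    clamped); proposals whose fitness is NaN are rejected and logged; the run
    is fully reproducible from ``config.seed``; the objective is called at
    most ``population * (iterations + 1)`` times.
    """
    rng = np.random.default_rng(config.seed)
    d = config.n_dim
    lo, hi = config.lower, config.upper
    width = hi - lo
    pop_n = config.population
    T = config.iterations

    pop = lo + rng.random((pop_n, d)) * width
    fit = np.array([_evaluate(objective, pop[i]) for i in range(pop_n)])
    n_eval = pop_n
    if np.all(np.isnan(fit)):
        raise OptimizationError("objective returned NaN for the entire population")
    fit = np.where(np.isnan(fit), np.inf, fit)

    best_i = int(np.argmin(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    trace = [best_f]
    n_elite = max(1, int(round(config.elite_fraction * pop_n)))

    for t in range(T):
        theta = t / T
        p_explore = 1.0 - theta  # schedule: global early, local late
        sigma = config.exploit_sigma * (1.0 - theta) ** 3
        order = np.argsort(fit)
        worst = int(order[-1])
        any_finite = False
        for i in range(pop_n):
            if i == worst:
                # regeneration: resample the worst starfish uniformly
                cand = lo + rng.random(d) * width
            elif rng.random() < p_explore:
                a, b = rng.choice(pop_n, size=2, replace=False)
                cand = (
                    pop[i]
                    + rng.random(d) * (best_x - pop[i])
                    + config.explore_weight * rng.random(d) * (pop[a] - pop[b])
                )
            else:
                elite = pop[int(order[rng.integers(n_elite)])]
                cand = elite + sigma * rng.standard_normal(d) * width
            cand = np.clip(cand, lo, hi)
            f = _evaluate(objective, cand)
            n_eval += 1
            if math.isnan(f):
                logger.info("SOA iter %d: NaN fitness, candidate rejected", t)
                continue
            any_finite = True
            if f < fit[i]:  # greedy replacement
                pop[i], fit[i] = cand, f
                if f < best_f:
                    best_x, best_f = cand.copy(), float(f)
        if not any_finite:
            raise OptimizationError(f"all candidates NaN at iteration {t}")
        trace.append(best_f)
        logger.info("SOA iter %d: best fitness %.6g", t, best_f)

    return OptimizationResult(
        best_position=best_x,
        best_fitness=best_f,
        trace=np.asarray(trace),
        n_evaluations=n_eval,
    )


@dataclass(frozen=True)
class HyperparamBounds:
    """Search box for (C, epsilon, gamma); C and gamma are searched on a
    log scale, epsilon linearly. Defaults comfortably cover the optima
    typical of NIR calibration (C up to 1e3, gamma down to 1e-4)."""

    c_low: float = 1e-2
    c_high: float = 1e3
    eps_low: float = 1e-3
    eps_high: float = 1.0
    gamma_low: float = 1e-4
    gamma_high: float = 1.0


def decode_hyperparams(
    position: Sequence[float], bounds: HyperparamBounds = HyperparamBounds()
) -> SvrHyperparams:
    """Map a point of the unit box onto (C, epsilon, gamma)."""
    pos = np.asarray(position, dtype=float).ravel()
    if pos.size != 3 or np.any(pos < 0) or np.any(pos > 1):
        raise ValueError("position must lie in the unit box [0,1]^3")
    b = bounds
    C = math.exp(math.log(b.c_low) + pos[0] * (math.log(b.c_high) - math.log(b.c_low)))
    eps = b.eps_low + pos[1] * (b.eps_high - b.eps_low)
    gamma = math.exp(
        math.log(b.gamma_low) + pos[2] * (math.log(b.gamma_high) - math.log(b.gamma_low))
    )
    return SvrHyperparams(C=C, epsilon=eps, gamma=gamma)


def encode_hyperparams(
    h: SvrHyperparams, bounds: HyperparamBounds = HyperparamBounds()
) -> np.ndarray:
    """Inverse of :func:`decode_hyperparams` (round-trips within 1e-10)."""
    b = bounds
    return np.array(
        [
            (math.log(h.C) - math.log(b.c_low))
            / (math.log(b.c_high) - math.log(b.c_low)),
            (h.epsilon - b.eps_low) / (b.eps_high - b.eps_low),
            (math.log(h.gamma) - math.log(b.gamma_low))
            / (math.log(b.gamma_high) - math.log(b.gamma_low)),
        ]
    )


def tune_svr(
    X: np.ndarray,
    y: np.ndarray,
    population: int = 30,
    iterations: int = 50,
    seed: int = 0,
    bounds: HyperparamBounds = HyperparamBounds(),
    folds: int = 5,
    cv_seed: int = 0,
    kernel: str = "rbf",
) -> tuple[SvrHyperparams, OptimizationResult]:
    """SOA search over the unit box minimizing SVR cross-validated RMSE."""

    def objective(pos: np.ndarray) -> float:
        h = decode_hyperparams(pos, bounds)
        return cv_fitness(X, y, h, folds=folds, seed=cv_seed, kernel=kernel)

    config = OptimizerConfig(
        lower=np.zeros(3),
        upper=np.ones(3),
        population=population,
        iterations=iterations,
        seed=seed,
    )
    result = soa_minimize(objective, config)
    return decode_hyperparams(result.best_position, bounds), result
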