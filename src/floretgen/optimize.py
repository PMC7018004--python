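"""Genetic-algorithm calibration of growth models.

The calibration objective compares a candidate parameter set's simulated
dataset against a reference dataset through two Jensen-Shannon
divergences on shared-bin probability histograms:

    J(theta) = alpha * JS(lengths_ref || lengths_sim)
             + (1 - alpha) * JS(asym_ref || asym_sim)

where *lengths* are the pooled segment lengths and *asym* the per-floret
length-weighted asymmetries; ``alpha = 0.9`` by default, weighting the
global length distribution over individual morphology.

The GA is a standard real-coded scheme: 10% elitism (elite fitness is
cached, never re-evaluated, so the best-of-generation trace is
non-increasing), tournament selection, uniform crossover and bounded
Gaussian mutation.  Every fitness evaluation draws a fresh deterministic
sub-seed from (master seed, generation, individual), so runs are exactly
reproducible.  The run halts at ``max_generations`` (10 x number of
parameters by default) or when the mean improvement of the best
objective over the last ``stall_generations`` falls below ``stall_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import galton_watson as gw
from . import generator as gen
from .distfit import js_divergence
from .errors import EmptyDatasetError, InvalidParamsError, IterationCapError
from .metrics import length_weighted_asymmetry
from .morphology import Floret

__all__ = [
    "Objective",
    "GAConfig",
    "GAResult",
    "evaluate_objective",
    "ga_optimize",
    "optimize_floret_generator",
    "optimize_galton_watson",
]


@dataclass
class Objective:
    """Reference data plus weighting/simulation settings for Eq-style
    divergence calibration."""

    reference_lengths: np.ndarray
    reference_asymmetries: np.ndarray
    alpha: float = 0.9
    n_sim: int = 500
    bins: str | int = "fd"

    def __post_init__(self) -> None:
        self.reference_lengths = np.asarray(self.reference_lengths, float)
        self.reference_asymmetries = np.asarray(self.reference_asymmetries, float)
        if self.reference_lengths.size == 0:
            raise EmptyDatasetError("empty reference length sample")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParamsError("alpha must be in [0, 1]")

    @classmethod
    def from_florets(cls, florets: Sequence[Floret], **kw) -> "Objective":
        if not florets:
            raise EmptyDatasetError("empty reference dataset")
        lengths = np.concatenate([f.lengths for f in florets])
        asym = np.array([length_weighted_asymmetry(f) for f in florets])
        return cls(lengths, asym, **kw)

    def score(self, florets: Sequence[Floret]) -> float:
        lengths = np.concatenate([f.lengths for f in florets])
        value = self.alpha * js_divergence(
            self.reference_lengths, lengths, bins=self.bins
        )
        if self.alpha < 1.0:
            asym = np.array([length_weighted_asymmetry(f) for f in florets])
            value += (1 - self.alpha) * js_divergence(
                self.reference_asymmetries, asym, bins=self.bins
            )
        return float(value)


def _simulate(params, n: int, seed: int) -> list[Floret]:
    if isinstance(params, gen.GrowthParams):
        return gen.generate_dataset(params, n, seed=seed)
    if isinstance(params, gw.GWParams):
        return gw.gw_generate_dataset(params, n, seed=seed)
    raise InvalidParamsError(f"unsupported parameter type {type(params)!r}")


def evaluate_objective(params, obj: Objective, seed: int = 0) -> float:
    """Simulate ``obj.n_sim`` florets with ``params`` and score them.

    Deterministic given ``(params, seed)``.  ``params`` may be
    :class:`~floretgen.generator.GrowthParams` or
    :class:`~floretgen.galton_watson.GWParams`.
    """
    return obj.score(_simulate(params, obj.n_sim, seed))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


@dataclass
class GAConfig:
    bounds: dict[str, tuple[float, float]]
    population_size: int = 40
    elite_fraction: float = 0.10
    crossover_fraction: float = 0.8
    mutation_rate: float = 0.25          #: per-gene mutation probability
    mutation_sigma: float = 0.1          #: Gaussian step, fraction of range
    max_generations: int | None = None   #: default 10 x n_params
    stall_generations: int = 50
    stall_tol: float = 1e-6
    seed: int = 0
    #: optional in-place repair enforcing extra constraints
    repair: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds.values()])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds.values()])


@dataclass
class GAResult:
    best_params: dict[str, float]
    best_objective: float
    trace: pd.DataFrame          #: per-generation best/mean objective
    n_evaluations: int
    seed: int
    operators: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(
            best_params=self.best_params,
            best_objective=self.best_objective,
            n_evaluations=self.n_evaluations,
            seed=self.seed,
            operators=self.operators,
            trace=self.trace.to_dict(orient="list"),
        )


def _sub_seed(master: int, generation: int, individual: int) -> int:
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, generation, individual])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def ga_optimize(
    fitness: Callable[[np.ndarray, int], float],
    cfg: GAConfig,
) -> GAResult:
    """Minimize ``fitness(vector, seed)`` over the box in ``cfg.bounds``.

    ``fitness`` receives the parameter vector (ordered as ``cfg.names``)
    and a deterministic evaluation seed.  Elites carry their cached
    fitness into the next generation.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.lower, cfg.upper
    n_params = lo.size
    max_gen = cfg.max_generations or 10 * n_params
    n_elite = max(1, int(round(cfg.elite_fraction * cfg.population_size)))

    def clip_repair(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, lo, hi)
        if cfg.repair is not None:
            x = np.clip(cfg.repair(x), lo, hi)
        return x

    pop = [clip_repair(rng.uniform(lo, hi)) for _ in range(cfg.population_size)]
    fits = np.full(cfg.population_size, np.nan)
    n_evals = 0
    trace_rows = []
    best_hist: list[float] = []

    for gen_i in range(max_gen):
        for i in range(cfg.population_size):
            if np.isnan(fits[i]):
                fits[i] = fitness(pop[i], _sub_seed(cfg.seed, gen_i, i))
                n_evals += 1
        order = np.argsort(fits)
        pop = [pop[i] for i in order]
        fits = fits[order]
        trace_rows.append(
            dict(generation=gen_i, best=float(fits[0]), mean=float(fits.mean()))
        )
        best_hist.append(float(fits[0]))
        if len(best_hist) > cfg.stall_generations:
            window = best_hist[-cfg.stall_generations - 1:]
            if (window[0] - window[-1]) / cfg.stall_generations < cfg.stall_tol:
                break
        if gen_i == max_gen - 1:
            break

        def tournament() -> np.ndarray:
            i, j = rng.integers(0, cfg.population_size, size=2)
            return pop[min(i, j)]  # population sorted by fitness

        children: list[np.ndarray] = []
        while len(children) < cfg.population_size - n_elite:
            if rng.random() < cfg.crossover_fraction:
                p1, p2 = tournament(), tournament()
                mask = rng.random(n_params) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = tournament().copy()
            mutate = rng.random(n_params) < cfg.mutation_rate
            child = child + mutate * rng.normal(
                0.0, cfg.mutation_sigma * (hi - lo), size=n_params
            )
            children.append(clip_repair(child))
        pop = pop[:n_elite] + children
        fits = np.concatenate([fits[:n_elite],
                               np.full(len(children), np.nan)])

    order = np.argsort(fits)
    best = pop[order[0]]
    return GAResult(
        best_params=dict(zip(cfg.names, (float(v) for v in best))),
        best_objective=float(fits[order[0]]),
        trace=pd.DataFrame(trace_rows),
        n_evaluations=n_evals,
        seed=cfg.seed,
        operators=dict(
            selection="tournament(k=2)",
            crossover=f"uniform({cfg.crossover_fraction})",
            mutation=f"gaussian(rate={cfg.mutation_rate}, "
                     f"sigma={cfg.mutation_sigma}*range)",
            elitism=cfg.elite_fraction,
        ),
    )


def optimize_floret_generator(
    obj: Objective,
    cfg: GAConfig | None = None,
    **cfg_kw,
) -> GAResult:
    """Calibrate all ten floret-generator parameters against ``obj``."""
    cfg = cfg or GAConfig(bounds=dict(gen.PARAM_BOUNDS), **cfg_kw)

    def fitness(vec: np.ndarray, seed: int) -> float:
        params = gen.GrowthParams.from_vector(vec)
        try:
            return evaluate_objective(params, obj, seed)
        except IterationCapError:
            # non-terminating / explosive candidate: worst fitness
            return float("inf")

    return ga_optimize(fitness, cfg)


GW_BOUNDS = {"p_growth": (0.5, 0.995), "p_branch": (1e-4, 0.2)}


def _gw_repair(x: np.ndarray) -> np.ndarray:
    # enforce subcriticality 2 p_b + p_gr < 1 by shrinking p_b
    p_gr, p_b = x
    limit = (1.0 - p_gr) / 2.0
    if p_b >= limit:
        p_b = max(1e-4, 0.95 * limit)
    return np.array([p_gr, p_b])


def optimize_galton_watson(
    obj: Objective,
    cfg: GAConfig | None = None,
    **cfg_kw,
) -> GAResult:
    """Calibrate the Galton-Watson (p_growth, p_branch) against ``obj``."""
    cfg = cfg or GAConfig(bounds=dict(GW_BOUNDS), repair=_gw_repair, **cfg_kw)
    if cfg.repair is None:
        cfg.repair = _gw_repair

    def fitness(vec: np.ndarray, seed: int) -> float:
        params = gw.GWParams(p_growth=float(vec[0]), p_branch=float(vec[1]))
        try:
            return evaluate_objective(params, obj, seed)
        except IterationCapError:
            # near-critical candidate with an explosive tree: worst fitness
            return float("inf")

    return ga_optimize(fitness, cfg)
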