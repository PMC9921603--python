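"""Genetic-algorithm identification of the 24 model parameters.

A real-coded GA with roulette-wheel selection, uniform (scattered) crossover,
Gaussian mutation truncated to the bounds, and elitism searches the
24-dimensional box for the parameter vector whose forward simulation best
reproduces the measured elbow angle.  The fitness of a candidate is the
time integral of the absolute angle error (trapezoidal rule, evaluated in
degrees so its magnitude reads directly as deg·s); candidates whose
simulation diverges, or whose piecewise-spring lengths are inconsistent,
receive a large finite penalty so selection weights stay defined.

Defaults follow the published setup: population 20, crossover fraction 0.7,
2 elite individuals, stall tolerance 1e-6 over 20 generations.  At population
20 each generation is composed of exactly 14 crossover children, 2 elites and
4 mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path

import numpy as np

from . import _fastsim, hill
from .errors import DataError, ParameterError, StateError
from .parameters import N_PARAMS, PARAM_NAMES, split_vector, vector_valid
from .dynamics import SegmentProperties, SimConfig

__all__ = [
    "GAConfig",
    "GAResult",
    "PENALTY_FITNESS",
    "fitness",
    "init_population",
    "select_roulette",
    "crossover",
    "mutate",
    "evolve",
]

log = logging.getLogger(__name__)

#: Fitness assigned to invalid or divergent candidates (keeps weights finite).
PENALTY_FITNESS = 1e6

_ROULETTE_EPS = 1e-12


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters (defaults are the published setup)."""

    population_size: int = 20
    crossover_fraction: float = 0.7
    elite_count: int = 2
    mutation_rate: float = 1.0      # per-gene probability for mutant children
    mutation_sigma: float = 0.1     # Gaussian sigma as a fraction of the bound range
    stall_tol: float = 1e-6
    stall_generations: int = 20
    max_generations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_fraction <= 1:
            raise ParameterError("crossover_fraction must lie in [0, 1]")
        if self.elite_count >= self.population_size:
            raise ParameterError("elite_count must be smaller than population_size")
        if self.population_size < 2:
            raise ParameterError("population_size must be at least 2")
        if self.mutation_sigma <= 0:
            raise ParameterError("mutation_sigma must be > 0")


@dataclass
class GAResult:
    """Outcome of one identification run."""

    best_vector: np.ndarray
    best_fitness: float           # deg·s
    history: list = field(default_factory=list)  # per-generation best fitness
    generations: int = 0
    termination: str = ""

    @property
    def best_params(self):
        """(HillParams, PassiveJointParams) of the best candidate."""
        return split_vector(self.best_vector)

    def to_dict(self) -> dict:
        return {
            "parameters": dict(zip(PARAM_NAMES, (float(v) for v in self.best_vector))),
            "fitness_deg_s": float(self.best_fitness),
            "history": [float(h) for h in self.history],
            "generations": self.generations,
            "termination": self.termination,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GAResult":
        d = json.loads(Path(path).read_text())
        return cls(
            best_vector=np.array([d["parameters"][n] for n in PARAM_NAMES]),
            best_fitness=d["fitness_deg_s"],
            history=d.get("history", []),
            generations=d.get("generations", 0),
            termination=d.get("termination", ""),
        )


def generation_composition(cfg: GAConfig) -> tuple[int, int, int]:
    """(crossover children, elites, mutants) per generation.

    At the default population of 20 with crossover fraction 0.7 and 2 elites
    this is (14, 2, 4).
    """
    n_cross = int(round(cfg.crossover_fraction * cfg.population_size))
    n_cross = min(n_cross, cfg.population_size - cfg.elite_count)
    return n_cross, cfg.elite_count, cfg.population_size - cfg.elite_count - n_cross


def fitness(q_goni, q_sim, time) -> float:
    """Trapezoidal integral over time of |q_goni - q_sim| (input units × s)."""
    q_goni = np.asarray(q_goni, dtype=float)
    q_sim = np.asarray(q_sim, dtype=float)
    time = np.asarray(time, dtype=float)
    if not (len(q_goni) == len(q_sim) == len(time)):
        raise DataError("q_goni, q_sim and time must share one grid")
    return float(np.trapezoid(np.abs(q_goni - q_sim), time))


def init_population(bounds: tuple[np.ndarray, np.ndarray], n: int,
                    rng: np.random.Generator | int, *,
                    require_valid: bool = False) -> np.ndarray:
    """Uniform initial population within the bounds, shape (n, n_params).

    With ``require_valid=True`` (used for the 24-parameter model box, where
    the slack/linear-onset ordering constraints carve out a small feasible
    corner) each individual is redrawn until it satisfies the a-priori
    validity constraints, i.e. sampling is uniform on the feasible region.
    """
    if n < 2:
        raise ParameterError("population must contain at least 2 individuals")
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if np.any(lo >= hi):
        raise ParameterError("each lower bound must be below its upper bound")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pop = lo + (hi - lo) * rng.random((n, len(lo)))
    if require_valid:
        for k in range(n):
            for _ in range(10_000):
                if vector_valid(pop[k]):
                    break
                pop[k] = lo + (hi - lo) * rng.random(len(lo))
            else:
                raise StateError("could not sample a valid individual within the bounds")
    return pop


def select_roulette(fitnesses, rng: np.random.Generator | int) -> int:
    """Roulette-wheel parent index for minimization: weight 1/(F + eps)."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise DataError("cannot select from an empty population")
    if np.any(~np.isfinite(f)) or np.any(f < 0):
        raise DataError("fitness values must be finite and non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    w = 1.0 / (f + _ROULETTE_EPS)
    return int(rng.choice(f.size, p=w / w.sum()))


def crossover(parent1, parent2, rng: np.random.Generator | int) -> np.ndarray:
    """Scattered (uniform-mask) crossover: each child gene from one parent."""
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mask = rng.random(p1.shape) < 0.5
    return np.where(mask, p1, p2)


def mutate(individual, bounds, sigma_frac: float, rng: np.random.Generator | int,
           rate: float = 1.0) -> np.ndarray:
    """Add truncated Gaussian noise (sigma = sigma_frac × range) per gene."""
    if sigma_frac <= 0:
        raise ParameterError("sigma_frac must be > 0")
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    x = np.asarray(individual, dtype=float).copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    hit = rng.random(x.shape) < rate
    noise = rng.normal(0.0, sigma_frac * (hi - lo))
    x[hit] += noise[hit]
    return np.clip(x, lo, hi)


def _candidate_fitness(vec: np.ndarray, a_ag: np.ndarray, a_ant: np.ndarray,
                       q_goni_deg: np.ndarray, time: np.ndarray, dt_out: float,
                       n_sub: int, seg_arr: np.ndarray, mu: float, grav: float,
                       q_guard: float, integrator: int) -> float:
    if not vector_valid(vec):
        return PENALTY_FITNESS
    rec, status, _ = _fastsim.simulate_kernel(
        vec, seg_arr, mu, grav, q_guard, hill.ECCENTRIC_LIMIT, integrator,
        a_ag, a_ant, dt_out, n_sub, vec[2], vec[2],
    )
    if status != _fastsim.OK:
        return PENALTY_FITNESS
    return fitness(q_goni_deg, np.degrees(rec[:, 0]), time)


def evolve(a_AG, a_ANT, q_goni, time, bounds, cfg: GAConfig | None = None, *,
           seg: SegmentProperties | None = None, sim_cfg: SimConfig | None = None,
           initial_individuals=None) -> GAResult:
    """Run the identification GA against a measured angle trajectory.

    Parameters
    ----------
    a_AG, a_ANT : activation traces (objects with ``.a`` or plain arrays)
        on the same uniform grid as ``time``.
    q_goni : measured elbow angle [rad] on that grid.
    bounds : (lower, upper) arrays over the canonical 24-parameter order.
    initial_individuals : optional iterable of vectors injected into the
        initial population (e.g. a known reference solution).
    """
    cfg = cfg or GAConfig()
    seg = seg or SegmentProperties()
    sim_cfg = sim_cfg or SimConfig()

    a_ag = np.ascontiguousarray(a_AG.a if hasattr(a_AG, "a") else a_AG, dtype=float)
    a_ant = np.ascontiguousarray(a_ANT.a if hasattr(a_ANT, "a") else a_ANT, dtype=float)
    time = np.asarray(time, dtype=float)
    q_goni_deg = np.degrees(np.asarray(q_goni, dtype=float))
    dt_out = float(time[1] - time[0])
    n_sub = max(1, int(round(dt_out / sim_cfg.dt)))
    seg_arr = seg.to_array()
    mu = 1.0 if sim_cfg.sign_convention == "flexion_positive" else -1.0
    grav = 1.0 if sim_cfg.gravity_mode == "paper" else 0.0
    integrator = 0 if sim_cfg.integrator == "rk4" else 1

    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    rng = np.random.default_rng(cfg.seed)

    pop = init_population((lo, hi), cfg.population_size, rng,
                          require_valid=len(lo) == N_PARAMS)
    if initial_individuals is not None:
        for k, vec in enumerate(initial_individuals):
            if k >= cfg.population_size:
                break
            pop[k] = np.asarray(vec, dtype=float)

    def evaluate(vec: np.ndarray) -> float:
        return _candidate_fitness(vec, a_ag, a_ant, q_goni_deg, time, dt_out,
                                  n_sub, seg_arr, mu, grav, sim_cfg.q_guard, integrator)

    fit = np.array([evaluate(ind) for ind in pop])
    if np.all(fit >= PENALTY_FITNESS):
        raise StateError("every candidate in generation 0 diverged or was invalid")

    n_cross, _, n_mut = generation_composition(cfg)

    history: list[float] = [float(fit.min())]
    stall = 0
    termination = "max_generations"
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        order = np.argsort(fit, kind="stable")
        new_pop = np.empty_like(pop)
        new_fit = np.full(cfg.population_size, np.nan)
        # elitism: the lowest-fitness individuals survive unchanged
        for e in range(cfg.elite_count):
            new_pop[e] = pop[order[e]]
            new_fit[e] = fit[order[e]]
        k = cfg.elite_count
        for _ in range(n_cross):
            i = select_roulette(fit, rng)
            j = select_roulette(fit, rng)
            new_pop[k] = crossover(pop[i], pop[j], rng)
            k += 1
        for _ in range(n_mut):
            i = select_roulette(fit, rng)
            new_pop[k] = mutate(pop[i], (lo, hi), cfg.mutation_sigma, rng,
                                rate=cfg.mutation_rate)
            k += 1
        pop = new_pop
        for k in range(cfg.elite_count, cfg.population_size):
            new_fit[k] = evaluate(pop[k])
        fit = new_fit

        best = float(fit.min())
        improvement = history[-1] - best
        history.append(best)
        log.info("generation %d: best %.6g mean %.6g", gen, best, float(fit.mean()))
        if improvement <= cfg.stall_tol:
            stall += 1
        else:
            stall = 0
        if stall >= cfg.stall_generations:
            termination = "stall"
            break

    ibest = int(np.argmin(fit))
    return GAResult(best_vector=pop[ibest].copy(), best_fitness=float(fit[ibest]),
                    history=history, generations=gen, termination=termination)
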