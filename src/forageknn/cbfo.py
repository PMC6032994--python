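"""Bacterial foraging optimization with chaotic initialization and
Gaussian mutation of the incumbent best.

The optimizer simulates a swarm of ``S`` bacteria foraging on a continuous
objective.  Each *chemotaxis pass* every bacterium tumbles (a uniformly
random unit direction), takes a step of fixed length (``step_size`` times
the per-dimension search range) and, while the move improves its cost,
keeps swimming in the same direction for up to ``swim_length`` further
steps.  After every ``chemotaxis_steps`` passes the healthier half of the
swarm (lowest accumulated cost) displaces the weaker half (*reproduction*,
binary fission — the population size never changes).  After every
``reproduction_steps`` such blocks each bacterium is, with probability
``elimination_prob``, re-placed uniformly at random in the box
(*elimination-dispersal*).

Two enhancements, both optional, define the chaos-enhanced variant:

* **chaotic initialization** — the initial coordinates are drawn from a
  fully chaotic logistic map (``x -> 4 x (1 - x)``) and mapped affinely
  onto the box, giving a space-filling start;
* **Gaussian mutation of the best** — once per chemotaxis pass a Gaussian
  perturbation of the best-so-far point is proposed and accepted greedily.
  The perturbation scale anneals geometrically from
  ``mutation_sigma * range`` down to ``mutation_sigma_final * range`` over
  the run, so early proposals explore and late proposals polish the
  incumbent to high precision.

All randomness flows through a single :class:`numpy.random.Generator`, so a
fixed seed reproduces the trajectory bit for bit.  Objectives are called in
batch: ``objective(X)`` with ``X`` of shape ``(n, d)`` must return ``(n,)``
costs (use :func:`vectorize_objective` to wrap a scalar function).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .exceptions import ContractError

__all__ = [
    "CbfoConfig",
    "SwarmState",
    "OptimizeResult",
    "chaotic_init",
    "tumble_direction",
    "chemotaxis_pass",
    "reproduce",
    "eliminate_disperse",
    "gaussian_mutate_best",
    "optimize",
    "vectorize_objective",
]


@dataclass(frozen=True)
class CbfoConfig:
    """Optimizer settings.

    ``step_size`` and the mutation scales are expressed as fractions of the
    per-dimension search range, so the same configuration transfers across
    boxes of different extent.  ``mutation_sigma_final`` sets the terminal
    scale of the geometric annealing schedule; set it equal to
    ``mutation_sigma`` for a constant scale.
    """

    swarm_size: int = 50
    chemotaxis_steps: int = 50
    swim_length: int = 4
    reproduction_steps: int = 5
    elimination_events: int = 2
    elimination_prob: float = 0.25
    step_size: float = 0.1
    mutation_sigma: float = 0.1
    mutation_sigma_final: float = 1e-6
    use_chaos: bool = True
    use_mutation: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.swarm_size < 2 or self.swarm_size % 2:
            raise ContractError("swarm_size must be even and >= 2")
        if not 0.0 <= self.elimination_prob <= 1.0:
            raise ContractError("elimination_prob must lie in [0, 1]")
        if self.step_size <= 0:
            raise ContractError("step_size must be positive")
        for name in ("chemotaxis_steps", "swim_length", "reproduction_steps",
                     "elimination_events"):
            if getattr(self, name) < (0 if name == "swim_length" else 1):
                raise ContractError(f"{name} out of range")
        if self.mutation_sigma < 0 or self.mutation_sigma_final < 0:
            raise ContractError("mutation scales must be non-negative")

    @property
    def total_passes(self) -> int:
        return self.elimination_events * self.reproduction_steps * self.chemotaxis_steps

    @classmethod
    def benchmark_default(cls, **overrides) -> "CbfoConfig":
        """Profile used for benchmark-function experiments.

        50 bacteria and a 500-pass budget split as 2 dispersal events x 5
        reproduction blocks x 50 chemotaxis passes.
        """
        base = cls(swarm_size=50, chemotaxis_steps=50, reproduction_steps=5,
                   elimination_events=2)
        return replace(base, **overrides) if overrides else base

    @classmethod
    def tuning_default(cls, **overrides) -> "CbfoConfig":
        """Profile used for hyperparameter tuning of the classifier.

        A small swarm of 8 with 25 chemotaxis passes per block, swim length
        4, 3 reproduction blocks, 2 dispersal events, Ped = 0.25.
        """
        base = cls(swarm_size=8, chemotaxis_steps=25, reproduction_steps=3,
                   elimination_events=2)
        return replace(base, **overrides) if overrides else base


@dataclass
class SwarmState:
    """Mutable swarm bookkeeping threaded through the optimizer steps."""

    positions: np.ndarray  # (S, d)
    costs: np.ndarray  # (S,)
    health: np.ndarray  # (S,) accumulated cost over the current block
    best_position: np.ndarray
    best_cost: float
    evaluations: int = 0
    best_curve: list[float] = field(default_factory=list)

    def observe(self, points: np.ndarray, costs: np.ndarray) -> None:
        """Fold freshly evaluated points into the best-so-far record."""
        self.evaluations += len(costs)
        i = int(np.argmin(costs))
        if costs[i] < self.best_cost:
            self.best_cost = float(costs[i])
            self.best_position = points[i].copy()


@dataclass(frozen=True)
class OptimizeResult:
    best_position: np.ndarray
    best_cost: float
    best_curve: np.ndarray
    evaluations: int


def _as_bounds(bounds) -> np.ndarray:
    b = np.asarray(bounds, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2 or (b[:, 1] <= b[:, 0]).any() or not np.isfinite(b).all():
        raise ContractError("bounds must be a (d, 2) array of finite lo < hi")
    return b


def vectorize_objective(fn: Callable[[np.ndarray], float]) -> Callable[[np.ndarray], np.ndarray]:
    """Wrap a scalar objective ``fn(x) -> float`` for batched calls."""

    def batched(X: np.ndarray) -> np.ndarray:
        return np.array([fn(x) for x in np.atleast_2d(X)], dtype=float)

    return batched


def _checked_eval(objective, X: np.ndarray) -> np.ndarray:
    vals = np.asarray(objective(X), dtype=float)
    if vals.shape != (X.shape[0],):
        raise ContractError("objective must return one cost per row")
    if not np.isfinite(vals).all():
        raise ContractError("objective returned a non-finite cost")
    return vals


def chaotic_init(S: int, d: int, bounds, rng: np.random.Generator) -> np.ndarray:
    """Space-filling initial positions from a fully chaotic logistic map.

    A single seed coordinate is drawn uniformly in (0, 1), avoiding the
    degenerate points {0.25, 0.5, 0.75} whose orbits collapse, and iterated
    through ``x -> 4 x (1 - x)`` to yield ``S * d`` values in (0, 1).  Each
    value is mapped affinely onto its dimension's interval.
    """
    b = _as_bounds(bounds)
    if b.shape[0] != d:
        raise ContractError("bounds do not match dimension")
    x = rng.uniform()
    while x in (0.25, 0.5, 0.75) or x in (0.0, 1.0):
        x = rng.uniform()
    seq = np.empty(S * d)
    for i in range(S * d):
        x = 4.0 * x * (1.0 - x)
        if x <= 0.0 or x >= 1.0 or x in (0.25, 0.5, 0.75):  # numerical escape
            x = rng.uniform()
            while x in (0.0, 0.25, 0.5, 0.75, 1.0):
                x = rng.uniform()
        seq[i] = x
    raw = seq.reshape(S, d)
    return b[:, 0] + raw * (b[:, 1] - b[:, 0])


def tumble_direction(d: int, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Unit-norm tumble direction(s): uniform [-1, 1] draws, normalized."""
    if d < 1:
        raise ContractError("dimension must be >= 1")
    n = 1 if size is None else size
    delta = rng.uniform(-1.0, 1.0, size=(n, d))
    norms = np.linalg.norm(delta, axis=1)
    while (degenerate := norms < 1e-300).any():  # essentially impossible redraw
        delta[degenerate] = rng.uniform(-1.0, 1.0, size=(int(degenerate.sum()), d))
        norms = np.linalg.norm(delta, axis=1)
    out = delta / norms[:, None]
    return out[0] if size is None else out


def init_state(objective, bounds, config: CbfoConfig, rng: np.random.Generator) -> SwarmState:
    """Create and evaluate the initial swarm (chaotic or uniform)."""
    b = _as_bounds(bounds)
    d = b.shape[0]
    if config.use_chaos:
        pos = chaotic_init(config.swarm_size, d, b, rng)
    else:
        pos = rng.uniform(b[:, 0], b[:, 1], size=(config.swarm_size, d))
    costs = _checked_eval(objective, pos)
    state = SwarmState(
        positions=pos,
        costs=costs,
        health=np.zeros(config.swarm_size),
        best_position=pos[int(np.argmin(costs))].copy(),
        best_cost=float(costs.min()),
        evaluations=len(costs),
    )
    return state


def chemotaxis_pass(state: SwarmState, objective, bounds, config: CbfoConfig,
                    rng: np.random.Generator) -> SwarmState:
    """One tumble-and-swim pass over the whole swarm.

    Every bacterium takes its tumble step unconditionally (positions move
    even when the cost worsens); bacteria whose tumble improved their cost
    keep swimming along the same direction for up to ``swim_length`` extra
    steps while the improvement continues.  Costs of visited positions
    accumulate into the health record.
    """
    b = _as_bounds(bounds)
    S, d = state.positions.shape
    step = config.step_size * (b[:, 1] - b[:, 0])

    dirs = tumble_direction(d, rng, size=S)
    prev_costs = state.costs.copy()
    new_pos = np.clip(state.positions + step * dirs, b[:, 0], b[:, 1])
    new_costs = _checked_eval(objective, new_pos)
    state.observe(new_pos, new_costs)
    state.positions = new_pos
    state.costs = new_costs
    state.health += new_costs

    active = new_costs < prev_costs
    swims = 0
    while active.any() and swims < config.swim_length:
        idx = np.nonzero(active)[0]
        cand = np.clip(state.positions[idx] + step * dirs[idx], b[:, 0], b[:, 1])
        cand_costs = _checked_eval(objective, cand)
        state.observe(cand, cand_costs)
        better = cand_costs < state.costs[idx]
        take = idx[better]
        state.positions[take] = cand[better]
        state.costs[take] = cand_costs[better]
        state.health[take] += cand_costs[better]
        active[:] = False
        active[take] = True
        swims += 1
    return state


def reproduce(state: SwarmState) -> SwarmState:
    """Binary fission: the healthier half replaces the weaker half.

    Health is the cost accumulated during the chemotaxis block (lower is
    healthier).  The sort is stable, so ties resolve by bacterium index.
    Health accumulators reset afterwards; the population size is unchanged.
    """
    S = state.positions.shape[0]
    order = np.argsort(state.health, kind="stable")
    keep = order[: S // 2]
    state.positions = np.concatenate([state.positions[keep], state.positions[keep]])
    state.costs = np.concatenate([state.costs[keep], state.costs[keep]])
    state.health = np.zeros(S)
    return state


def eliminate_disperse(state: SwarmState, objective, bounds, config: CbfoConfig,
                       rng: np.random.Generator) -> SwarmState:
    """Random re-placement of each bacterium with probability ``Ped``."""
    b = _as_bounds(bounds)
    S, d = state.positions.shape
    mask = rng.random(S) < config.elimination_prob
    if mask.any():
        n = int(mask.sum())
        fresh = rng.uniform(b[:, 0], b[:, 1], size=(n, d))
        fresh_costs = _checked_eval(objective, fresh)
        state.observe(fresh, fresh_costs)
        state.positions[mask] = fresh
        state.costs[mask] = fresh_costs
    return state


def gaussian_mutate_best(state: SwarmState, objective, bounds, config: CbfoConfig,
                         rng: np.random.Generator,
                         sigma_fraction: float | None = None) -> SwarmState:
    """Greedy Gaussian mutation of the best-so-far point.

    Proposes ``best + eps`` with ``eps ~ N(0, (sigma * range)^2)`` per
    dimension (clamped to the box) and accepts it into the best record only
    if strictly better.  ``sigma_fraction`` overrides the configured scale;
    a zero scale is a no-op.
    """
    b = _as_bounds(bounds)
    sigma = config.mutation_sigma if sigma_fraction is None else sigma_fraction
    if sigma <= 0.0:
        return state
    scale = sigma * (b[:, 1] - b[:, 0])
    eps = rng.normal(0.0, 1.0, size=b.shape[0]) * scale
    cand = np.clip(state.best_position + eps, b[:, 0], b[:, 1])[None, :]
    cost = _checked_eval(objective, cand)
    state.observe(cand, cost)
    return state


def _mutation_schedule(config: CbfoConfig) -> np.ndarray:
    """Geometric annealing of the mutation scale across all passes."""
    T = config.total_passes
    s0 = config.mutation_sigma
    s1 = config.mutation_sigma_final
    if s0 <= 0.0:
        return np.zeros(T)
    s1 = min(max(s1, 1e-300), s0)
    if T == 1:
        return np.array([s0])
    t = np.arange(T) / (T - 1)
    return s0 * (s1 / s0) ** t


def optimize(objective, bounds, config: CbfoConfig | None = None,
             seed: int | np.random.Generator | np.random.SeedSequence | None = None,
             ) -> OptimizeResult:
    """Run the full nested foraging loop and return the all-time best.

    The loop nesting is ``elimination_events x reproduction_steps x
    chemotaxis_steps``; Gaussian mutation of the incumbent best (when
    enabled) runs once per chemotaxis pass, reproduction after each block of
    passes, elimination-dispersal after each block of reproductions.

    Parameters
    ----------
    objective : callable
        Batched objective: ``objective(X)`` with ``X`` of shape ``(n, d)``
        returns ``(n,)`` finite costs.
    bounds : array-like, shape (d, 2)
        Finite search box.
    config : CbfoConfig, optional
        Defaults to :meth:`CbfoConfig.benchmark_default`.
    seed : int, Generator or SeedSequence, optional
        Overrides ``config.seed``; a single generator drives every
        stochastic step, so a fixed seed is bit-reproducible.
    """
    if config is None:
        config = CbfoConfig.benchmark_default()
    if config.total_passes < 1:
        raise ContractError("zero optimization budget")
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = _as_bounds(bounds)

    state = init_state(objective, b, config, rng)
    sigmas = _mutation_schedule(config)
    t = 0
    for _ in range(config.elimination_events):
        for _ in range(config.reproduction_steps):
            for _ in range(config.chemotaxis_steps):
                chemotaxis_pass(state, objective, b, config, rng)
                if config.use_mutation:
                    gaussian_mutate_best(state, objective, b, config, rng,
                                         sigma_fraction=float(sigmas[t]))
                state.best_curve.append(state.best_cost)
                t += 1
            reproduce(state)
        eliminate_disperse(state, objective, b, config, rng)
        # dispersal may stumble on an improvement after the last recorded
        # pass; fold it into the last curve entry so the curve's minimum
        # always equals the returned best
        state.best_curve[-1] = state.best_cost
    return OptimizeResult(
        best_position=state.best_position.copy(),
        best_cost=state.best_cost,
        best_curve=np.asarray(state.best_curve),
        evaluations=state.evaluations,
    )
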