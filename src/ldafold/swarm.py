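"""Bounded particle-swarm optimization with collapse detection.

The reduced-space energy landscape is sampled with a particle swarm.  The
default variant is RR-PSO — the regressive/regressive discretization of the
continuous PSO dynamical system, in which both the velocity and the
position update are implicit (backward) steps:

    v(t+1) = [v(t) + φ1 (g - x(t)) + φ2 (p_i - x(t))] / [1 + (1-ω) + φ1 + φ2]
    x(t+1) = x(t) + v(t+1)

with inertia ω = 3 and per-dimension accelerations φ1, φ2 ~ U(0, 4.5) —
the published high-exploration parameter line φ̄ = 3(ω - 3/2) of this PSO
family.  A constriction-coefficient PSO (χ = 0.7298, c1 = c2 = 1.49618) is
available as the ``"constriction"`` variant.

Positions are confined to a prismatic search space: a coordinate that
exceeds a bound is clamped to it and its velocity component zeroed.

Convergence is monitored by the *median dispersion*: the median particle
distance to the swarm centroid, as a percentage of the same median at
iteration 1.  When it falls below the collapse threshold (default 3%) the
swarm is considered collapsed onto an optimum; from the collapse iteration
on, each iteration contributes a single representative (its best particle)
to the sampled-model list so collapsed swarms do not over-represent one
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .lda import SearchSpace

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "OptimizationResult",
    "DegenerateSpaceError",
    "initialize_swarm",
    "step",
    "dispersion",
    "optimize",
]

# RR-PSO high-exploration parameter line: omega = 3, mean total acceleration
# phi1 + phi2 = 3 * (omega - 3/2) = 4.5
RR_OMEGA = 3.0
RR_ACCEL_MAX = 4.5
# constriction-coefficient fallback (Clerc-Kennedy)
CHI = 0.7298
C_ACCEL = 1.49618

VARIANTS = ("rr-pso", "constriction")


class DegenerateSpaceError(ValueError):
    """Every coordinate of the search space has zero width."""


@dataclass
class SwarmConfig:
    """Swarm settings; defaults are 40 particles x 50 iterations, 3% collapse."""

    swarm_size: int = 40
    iterations: int = 50
    seed: int = 0
    collapse_threshold: float = 3.0
    variant: str = "rr-pso"

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.collapse_threshold < 100.0:
            raise ValueError("collapse_threshold must be in (0, 100)")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")


@dataclass
class SwarmState:
    """Mutable swarm state; one objective value per particle per iteration."""

    positions: np.ndarray
    velocities: np.ndarray
    values: np.ndarray
    personal_best_positions: np.ndarray
    personal_best_values: np.ndarray
    global_best_position: np.ndarray
    global_best_value: float
    iteration: int
    dispersion_pct: float
    baseline: float
    rng: np.random.Generator


@dataclass
class OptimizationResult:
    """Outcome of a swarm run."""

    best_position: np.ndarray
    best_value: float
    history: list  # (iteration, best value, dispersion %) tuples
    sampled_positions: np.ndarray
    sampled_values: np.ndarray
    collapsed_at: int | None


def _evaluate(objective: Callable, positions: np.ndarray) -> np.ndarray:
    values = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        v = float(objective(x))
        values[i] = v if np.isfinite(v) else np.inf
    return values


def _median_spread(positions: np.ndarray) -> float:
    centroid = positions.mean(axis=0)
    return float(np.median(np.linalg.norm(positions - centroid, axis=1)))


def dispersion(positions: np.ndarray, baseline: float) -> float:
    """Median particle distance to the centroid, % of the iteration-1 median.

    A zero baseline (all particles started identical) is defined as 0%
    dispersion, i.e. immediate collapse.
    """
    if baseline <= 0.0:
        return 0.0
    return 100.0 * _median_spread(positions) / baseline


def initialize_swarm(space: SearchSpace, config: SwarmConfig,
                     objective: Callable | None = None) -> SwarmState:
    """Uniform random swarm inside the bounds; velocities in ±(u-l)/2.

    Deterministic given ``config.seed``.  The iteration-1 dispersion is
    100% by construction (the initial median spread is the baseline).
    If ``objective`` is given, the initial particles are evaluated and the
    personal/global bests seeded; otherwise best values start at +inf.
    """
    lo, hi = space.lower, space.upper
    if np.all(hi - lo <= 0):
        raise DegenerateSpaceError("search space has zero width in every coordinate")
    rng = np.random.default_rng(config.seed)
    ns, dim = config.swarm_size, space.dim
    positions = lo + rng.uniform(size=(ns, dim)) * (hi - lo)
    velocities = rng.uniform(-1.0, 1.0, size=(ns, dim)) * (hi - lo) / 2.0

    if objective is not None:
        values = _evaluate(objective, positions)
    else:
        values = np.full(ns, np.inf)
    pb_pos = positions.copy()
    pb_val = values.copy()
    g_idx = int(np.argmin(pb_val))

    baseline = _median_spread(positions)
    disp = dispersion(positions, baseline) if baseline > 0 else 0.0
    if baseline > 0:
        disp = 100.0  # by definition of the baseline

    return SwarmState(
        positions=positions,
        velocities=velocities,
        values=values,
        personal_best_positions=pb_pos,
        personal_best_values=pb_val,
        global_best_position=pb_pos[g_idx].copy(),
        global_best_value=float(pb_val[g_idx]),
        iteration=1,
        dispersion_pct=disp,
        baseline=baseline,
        rng=rng,
    )


def _velocity_update(state: SwarmState, config: SwarmConfig) -> np.ndarray:
    ns, dim = state.positions.shape
    x = state.positions
    v = state.velocities
    p = state.personal_best_positions
    g = state.global_best_position[None, :]
    if config.variant == "rr-pso":
        phi1 = state.rng.uniform(0.0, RR_ACCEL_MAX, size=(ns, dim))
        phi2 = state.rng.uniform(0.0, RR_ACCEL_MAX, size=(ns, dim))
        denom = 1.0 + (1.0 - RR_OMEGA) + phi1 + phi2
        return (v + phi1 * (g - x) + phi2 * (p - x)) / denom
    # constriction
    r1 = state.rng.uniform(size=(ns, dim))
    r2 = state.rng.uniform(size=(ns, dim))
    return CHI * (v + C_ACCEL * r1 * (p - x) + C_ACCEL * r2 * (g - x))


def step(state: SwarmState, objective: Callable, space: SearchSpace,
         config: SwarmConfig) -> SwarmState:
    """One swarm iteration in place: move, clamp, evaluate, update bests.

    Every particle is evaluated exactly once.  Out-of-bounds components are
    clamped to the violated bound with the velocity component zeroed.
    Non-finite objective values are treated as +inf.
    """
    v_new = _velocity_update(state, config)
    x_new = state.positions + v_new

    below = x_new < space.lower
    above = x_new > space.upper
    x_new = np.clip(x_new, space.lower, space.upper)
    v_new[below | above] = 0.0

    values = _evaluate(objective, x_new)

    improved = values < state.personal_best_values
    state.personal_best_positions[improved] = x_new[improved]
    state.personal_best_values[improved] = values[improved]
    g_idx = int(np.argmin(state.personal_best_values))
    if state.personal_best_values[g_idx] < state.global_best_value:
        state.global_best_value = float(state.personal_best_values[g_idx])
        state.global_best_position = state.personal_best_positions[g_idx].copy()

    state.positions = x_new
    state.velocities = v_new
    state.values = values
    state.iteration += 1
    state.dispersion_pct = dispersion(x_new, state.baseline)
    return state


def optimize(objective: Callable, space: SearchSpace, config: SwarmConfig) -> OptimizationResult:
    """Run the swarm for ``config.iterations`` iterations.

    Iteration 1 is the evaluated initial swarm; iterations 2..N are update
    steps.  The first iteration whose dispersion drops below the collapse
    threshold is recorded as the collapse point.  The sampled-model list
    contains every particle of the pre-collapse iterations, and one
    representative (the iteration's best particle) per iteration from the
    collapse on.
    """
    state = initialize_swarm(space, config, objective=objective)
    history: list[tuple[int, float, float]] = []
    sampled_pos: list[np.ndarray] = []
    sampled_val: list[np.ndarray] = []
    collapsed_at: int | None = None

    def record(st: SwarmState) -> None:
        nonlocal collapsed_at
        if collapsed_at is None and st.dispersion_pct < config.collapse_threshold:
            collapsed_at = st.iteration
        history.append((st.iteration, st.global_best_value, st.dispersion_pct))
        if collapsed_at is None:
            sampled_pos.append(st.positions.copy())
            sampled_val.append(st.values.copy())
        else:
            best = int(np.argmin(st.values))
            sampled_pos.append(st.positions[best : best + 1].copy())
            sampled_val.append(st.values[best : best + 1].copy())

    record(state)
    for _ in range(config.iterations - 1):
        step(state, objective, space, config)
        record(state)

    return OptimizationResult(
        best_position=state.global_best_position.copy(),
        best_value=state.global_best_value,
        history=history,
        sampled_positions=np.vstack(sampled_pos),
        sampled_values=np.concatenate(sampled_val),
        collapsed_at=collapsed_at,
    )


def write_trace(result: OptimizationResult, path) -> None:
    """Write the optimizer history as TSV: iteration, best energy, dispersion %."""
    with open(path, "w") as fh:
        fh.write("iteration\tbest_energy\tdispersion_pct\n")
        for it, best, disp in result.history:
            fh.write(f"{it}\t{best:.10g}\t{disp:.6f}\n")
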