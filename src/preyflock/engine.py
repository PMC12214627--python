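"""Velocity-Verlet integration of the coupled prey-predator system.

Update scheme per step (synchronous for all agents):

1. positions advance with the cached accelerations,
   x(t+dt) = x + v dt + a dt^2 / 2, wrapped into [0, L);
2. half-kick v_half = v + a dt / 2;
3. forces are recomputed once at the new positions and half-kick velocities
   (fresh orientational noise is drawn here, once per agent per step);
4. velocities complete with the new acceleration, v(t+dt) = v_half + a' dt / 2;
5. the predation state machine runs on the updated positions (captures,
   timers, target selection);
6. prey behavioural modes (cruise/escape and flee directions) are re-evaluated
   on the updated positions and take effect from the next force evaluation.

For the velocity-dependent propulsion/drag terms this scheme is formally
first order in the velocity arguments but retains the standard Verlet
position update; see docs/methods.md.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .forces import prey_force_breakdown, prey_mode_update
from .geometry import wrap_positions
from .metrics import cluster_prey, default_min_pts
from .params import ModelParams
from .predator import predation_step, total_predator_force
from .state import WorldState

__all__ = ["compute_accelerations", "step", "run", "initialise"]

Observer = tuple[int, Callable[[WorldState, int], None]]


def _kernel_args(params: ModelParams):
    return (
        params.L, params.m_pr, params.d_pr, params.beta_pr_c, params.beta_pr_e,
        params.gamma, params.k_n, params.C_v, params.upsilon_a, params.m_fluid,
        params.w_rms, params.r_sep, params.r_alg, params.r_atr,
        math.cos(params.theta_b / 2.0), params.blind_angle_social,
        params.drag_coeff_prey(), params.m_pd, params.d_pd, params.beta_pd_sr,
        params.beta_pd_h, params.drag_coeff_predator(),
    )


def compute_accelerations(world: WorldState, params: ModelParams,
                          zeta: np.ndarray,
                          prey_v: np.ndarray | None = None,
                          pred_v: np.ndarray | None = None,
                          engine: str = "numba"
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Accelerations of all prey and predators at the given state.

    ``engine='numba'`` uses the compiled kernel; ``engine='numpy'`` the pure
    reference implementation (identical math, different summation order).
    """
    v_pr = world.prey_v if prey_v is None else prey_v
    v_pd = world.pred_v if pred_v is None else pred_v
    if engine == "numba":
        f_prey, f_pred = _kernels.compute_forces(
            world.prey_x, v_pr, world.prey_heading, world.mu, world.prey_mode,
            world.escape_dir, world.pred_x, v_pd, world.pred_heading,
            world.pred_mode, world.pred_target, zeta, *_kernel_args(params))
    elif engine == "numpy":
        f_prey = prey_force_breakdown(world, params, zeta, prey_v=v_pr).total
        f_pred = np.array([
            total_predator_force(world, params, k, pred_v=v_pd)
            for k in range(world.n_predators)
        ]).reshape(world.n_predators, 2)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return f_prey / params.m_pr, f_pred / params.m_pd


def _update_headings(heading: np.ndarray, v: np.ndarray) -> None:
    speed = np.linalg.norm(v, axis=1)
    moving = speed > 0
    heading[moving] = v[moving] / speed[moving, None]


def initialise(world: WorldState, params: ModelParams,
               rng: np.random.Generator, engine: str = "numba") -> None:
    """Evaluate behavioural modes and cache initial accelerations at t=0."""
    _detect(world, params, engine)
    zeta = rng.normal(0.0, params.sigma_zeta, world.n_prey)
    world.prey_acc, world.pred_acc = compute_accelerations(
        world, params, zeta, engine=engine)


def _detect(world: WorldState, params: ModelParams, engine: str) -> None:
    if engine == "numba" and world.n_predators > 0:
        mode, edir = _kernels.prey_detection(
            world.prey_x, world.prey_heading, world.mu, world.pred_x,
            params.r_d, math.cos(params.theta_b / 2.0), params.L,
            params.escape_from_nearest)
        world.prey_mode[:] = mode
        # keep previous flee direction for prey that stay in cruise mode
        esc = mode == 1
        world.escape_dir[esc] = edir[esc]
    else:
        prey_mode_update(world, params)


def step(world: WorldState, params: ModelParams, rng: np.random.Generator,
         strategy: str = "purely_NP", engine: str = "numba",
         max_cycles: int | None = None) -> None:
    """Advance the world by one timestep in place."""
    dt = params.dt
    if world.prey_acc is None or world.pred_acc is None:
        raise RuntimeError("call initialise() before stepping")
    # 1-2: drift + half kick
    world.prey_x = wrap_positions(
        world.prey_x + world.prey_v * dt + 0.5 * world.prey_acc * dt * dt,
        params.L)
    world.pred_x = wrap_positions(
        world.pred_x + world.pred_v * dt + 0.5 * world.pred_acc * dt * dt,
        params.L)
    v_half_prey = world.prey_v + 0.5 * world.prey_acc * dt
    v_half_pred = world.pred_v + 0.5 * world.pred_acc * dt
    # 3: single force evaluation with fresh noise
    zeta = rng.normal(0.0, params.sigma_zeta, world.n_prey)
    acc_prey, acc_pred = compute_accelerations(
        world, params, zeta, prey_v=v_half_prey, pred_v=v_half_pred,
        engine=engine)
    # 4: complete the kick
    world.prey_v = v_half_prey + 0.5 * acc_prey * dt
    world.pred_v = v_half_pred + 0.5 * acc_pred * dt
    world.prey_acc, world.pred_acc = acc_prey, acc_pred
    _update_headings(world.prey_heading, world.prey_v)
    _update_headings(world.pred_heading, world.pred_v)
    world.t += dt
    # 5: predation cycle on updated positions
    if world.n_predators > 0:
        phi_cache: dict[int, float] = {}

        def phi_of_target(tgt: int) -> float:
            if not phi_cache:
                live = world.mu.astype(bool)
                res = cluster_prey(world.prey_x[live], params.r_alg,
                                   default_min_pts(params.N), params.L,
                                   params.N)
                live_ids = np.flatnonzero(live)
                for lbl, pid in zip(res.labels, live_ids):
                    phi_cache[int(pid)] = (
                        1.0 / params.N if lbl < 0
                        else float(np.sum(res.labels == lbl) / params.N))
            return phi_cache.get(int(tgt), 1.0 / params.N)

        predation_step(world, params, strategy, rng, dt, phi_of_target,
                       max_cycles=max_cycles)
    # 6: behavioural modes for the next step
    _detect(world, params, engine)


def run(world: WorldState, params: ModelParams, rng: np.random.Generator,
        T_max: float, strategy: str = "purely_NP", engine: str = "numba",
        observers: Sequence[Observer] = (),
        stop_condition: Callable[[WorldState], bool] | None = None,
        stop_stride: int = 50, check_finite_stride: int = 200,
        max_cycles: int | None = None) -> WorldState:
    """Iterate :func:`step` until ``world.t >= T_max`` (or early termination).

    ``observers`` is a sequence of (stride_in_steps, callback) pairs invoked
    as callback(world, step_index); step 0 is sampled before stepping.
    Terminates early when every prey is captured or when ``stop_condition``
    (checked every ``stop_stride`` steps) returns True. Aborts with a
    diagnostic on non-finite state.
    """
    if world.prey_acc is None:
        initialise(world, params, rng, engine=engine)
    n_steps = int(round(max(T_max - world.t, 0.0) / params.dt))
    for (stride, cb) in observers:
        cb(world, 0)
    for s in range(1, n_steps + 1):
        step(world, params, rng, strategy=strategy, engine=engine,
             max_cycles=max_cycles)
        for (stride, cb) in observers:
            if s % stride == 0:
                cb(world, s)
        if s % check_finite_stride == 0:
            if not (np.isfinite(world.prey_x).all()
                    and np.isfinite(world.prey_v).all()
                    and np.isfinite(world.pred_x).all()):
                raise RuntimeError(
                    f"non-finite state at t={world.t:.4f} "
                    f"(step {s}); bad prey: "
                    f"{np.flatnonzero(~np.isfinite(world.prey_v).all(axis=1))[:5]}")
        if world.n_live() == 0:
            break
        if stop_condition is not None and s % stop_stride == 0:
            if stop_condition(world):
                break
    return world
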