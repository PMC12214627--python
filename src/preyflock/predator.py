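"""Predator behaviour: pursuit forces, targeting rules, and the hunting cycle.

A predator cycles through four stages: *search* (detection) -> *target
selection* -> *pursuit* (bounded by tau_P) -> *satisfied* (after a capture,
tau_S) or *refocus* (after a failed pursuit, tau_R), then back to search.
Targets are chosen as the nearest visible live prey (NP) or the live prey
closest to the algebraic centre of the visible group (MCP). Predators never
coordinate; they interact with each other through volume exclusion only.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import minimum_image
from .params import ModelParams
from .state import (NO_TARGET, PURSUIT, REFOCUS, SATISFIED, SEARCH,
                    PursuitEvent, WorldState)
from .forces import friction_force, separation_force, visible_mask

__all__ = [
    "NP", "MCP",
    "select_target", "strategy_mode", "predator_propulsion_force",
    "total_predator_force", "predation_step",
]

NP, MCP = 0, 1
_MODE_NAMES = {NP: "NP", MCP: "MCP"}


def candidate_set(world: WorldState, k: int, params: ModelParams) -> np.ndarray:
    """Ids of live prey in predator ``k``'s detection zone outside its blind cone."""
    mask = visible_mask(world.pred_x[k], world.pred_heading[k], world.prey_x,
                        params.R_d, params.theta_b, params.L)
    mask &= world.mu.astype(bool)
    return np.flatnonzero(mask)


def select_target(predator_pos: np.ndarray, prey_pos: np.ndarray,
                  candidate_ids: np.ndarray, mode: int, L: float) -> int | None:
    """Pick a target among the candidates; ties broken by lowest prey id.

    NP: minimum minimum-image distance to the predator. MCP: minimum distance
    to the algebraic centre of the candidate set, the centre being computed
    from displacements relative to the predator (well defined on the torus as
    long as the detection radius is below L/2).
    """
    if len(candidate_ids) == 0:
        return None
    d = minimum_image(prey_pos[candidate_ids] - predator_pos, L)
    if mode == NP:
        dist = np.linalg.norm(d, axis=1)
    else:
        centre = d.mean(axis=0)
        dist = np.linalg.norm(d - centre, axis=1)
    # argmin returns the first (lowest-id) minimiser since ids are sorted
    return int(candidate_ids[int(np.argmin(dist))])


def strategy_mode(strategy: str, predator_id: int, rng: np.random.Generator) -> int:
    """Per-cycle targeting mode under the configured strategy."""
    if strategy == "purely_NP":
        return NP
    if strategy == "purely_MCP":
        return MCP
    if strategy == "NP_MCP_probabilistic":
        return NP if rng.random() < 0.5 else MCP
    if strategy == "NP_MCP_deterministic":
        return NP if predator_id % 2 == 0 else MCP
    raise ValueError(f"unknown strategy {strategy!r}")


def predator_propulsion_force(v: np.ndarray, heading: np.ndarray, mode: int,
                              pos: np.ndarray, target_pos: np.ndarray | None,
                              params: ModelParams) -> np.ndarray:
    """Three-state Rayleigh-capped propulsion.

    Pursuit accelerates (beta_pd_h) along the minimum-image direction to the
    target ("pure pursuit"); satisfied/refocus/search cruise along the current
    velocity with the lower beta_pd_sr.
    """
    speed2 = float(v @ v)
    if mode == PURSUIT and target_pos is not None:
        dx = minimum_image(np.asarray(target_pos) - np.asarray(pos), params.L)
        r = math.hypot(dx[0], dx[1])
        direction = dx / r if r > 0 else heading
        beta = params.beta_pd_h
    else:
        speed = math.sqrt(speed2)
        direction = v / speed if speed > 0 else heading
        beta = params.beta_pd_sr
    return params.m_pd * (beta - params.gamma * speed2) * np.asarray(direction)


def total_predator_force(world: WorldState, params: ModelParams, k: int,
                         pred_v: np.ndarray | None = None) -> np.ndarray:
    """Separation (vs all agents) + quadratic drag + propulsion for predator k."""
    v = world.pred_v[k] if pred_v is None else pred_v[k]
    n = world.n_prey
    all_x = np.vstack([world.prey_x, world.pred_x])
    pair_radii = np.empty(len(all_x))
    pair_radii[:n] = 0.5 * (params.d_pr + params.d_pd)
    pair_radii[n:] = params.d_pd
    sep = separation_force(n + k, all_x, pair_radii, params.k_n, params.L)
    fric = friction_force(v, params.drag_coeff_predator())
    tgt = int(world.pred_target[k])
    target_pos = world.prey_x[tgt] if tgt != NO_TARGET else None
    prop = predator_propulsion_force(v, world.pred_heading[k],
                                     int(world.pred_mode[k]), world.pred_x[k],
                                     target_pos, params)
    return sep + fric + prop


def _close_pursuit(world: WorldState, k: int, outcome: str, reason: str,
                   params: ModelParams) -> None:
    tgt = int(world.pred_target[k])
    world.events.append(PursuitEvent(
        t_start=float(world.open_pursuit_start[k]),
        t_end=world.t,
        predator_id=k,
        target_id=tgt,
        target_group_size_phi=float(world.open_pursuit_phi[k]),
        outcome=outcome,
        strategy_mode=_MODE_NAMES[int(world.pred_strategy_mode[k])],
        reason=reason,
    ))
    world.pred_target[k] = NO_TARGET
    if outcome == "success":
        world.pred_mode[k] = SATISFIED
        world.pred_timer[k] = params.tau_S
    else:
        world.pred_mode[k] = REFOCUS
        world.pred_timer[k] = params.tau_R


def predation_step(world: WorldState, params: ModelParams, strategy: str,
                   rng: np.random.Generator, dt: float,
                   phi_of_target=None, max_cycles: int | None = None) -> None:
    """Advance every predator's hunting-cycle state machine by one step.

    Processed in predator id order after the kinematic update. ``phi_of_target``
    maps a prey id to the size fraction of its cluster at selection time (used
    for the pursuit event log); when omitted, events record phi = nan.

    Transitions: a pursuit ends in capture when the target enters the capture
    zone R_c (target's mu set to 0), in failure when tau_P expires, or in
    failure with reason ``target_lost`` when the other predator captured the
    target first. Satisfied/refocus count down their timers and fall back to
    search; a searching predator with a non-empty candidate set draws its
    per-cycle NP/MCP mode and starts a fresh pursuit with timer tau_P.
    """
    for k in range(world.n_predators):
        mode = int(world.pred_mode[k])
        if mode == PURSUIT:
            tgt = int(world.pred_target[k])
            if not world.mu[tgt]:
                _close_pursuit(world, k, "failure", "target_lost", params)
                continue
            dx = minimum_image(world.prey_x[tgt] - world.pred_x[k], params.L)
            if math.hypot(dx[0], dx[1]) <= params.R_c:
                world.mu[tgt] = 0
                _close_pursuit(world, k, "success", "capture", params)
                continue
            if params.opportunistic_capture:
                d_all = minimum_image(world.prey_x - world.pred_x[k], params.L)
                near = (np.linalg.norm(d_all, axis=1) <= params.R_c) & \
                    world.mu.astype(bool)
                world.mu[near] = 0
            world.pred_timer[k] -= dt
            if world.pred_timer[k] <= 0:
                _close_pursuit(world, k, "failure", "timeout", params)
        elif mode in (SATISFIED, REFOCUS):
            world.pred_timer[k] -= dt
            if world.pred_timer[k] <= 0:
                world.pred_mode[k] = SEARCH
                world.pred_timer[k] = 0.0
        if int(world.pred_mode[k]) == SEARCH:
            if max_cycles is not None:
                closed = sum(e.predator_id == k for e in world.events)
                if closed >= max_cycles:
                    continue  # hunting budget spent: keep cruising
            cand = candidate_set(world, k, params)
            if len(cand) == 0:
                continue
            smode = strategy_mode(strategy, k, rng)
            tgt = select_target(world.pred_x[k], world.prey_x, cand, smode,
                                params.L)
            world.pred_strategy_mode[k] = smode
            world.pred_target[k] = tgt
            world.pred_mode[k] = PURSUIT
            world.pred_timer[k] = params.tau_P
            world.open_pursuit_start[k] = world.t
            world.open_pursuit_phi[k] = (
                float("nan") if phi_of_target is None else phi_of_target(tgt))
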