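"""Prey force laws: separation, two-state propulsion, alignment, attraction, drag.

This module is the readable reference implementation of the equation of motion

    m_pr x'' = F_sep + F_fric + mu * (F_prop + F_align + F_attr),

where ``mu`` gates the behavioural forces: captured prey (mu = 0) remain in
the domain as passive bodies experiencing only contact separation and drag.

Zones are metric and centred on each agent: separation acts for
``0 < r <= r_sep``, alignment for ``r_sep < r <= r_alg`` and attraction for
``r_alg < r <= r_atr``; a predator is detected anywhere within ``r_d`` outside
the blind cone of total width ``theta_b`` behind the heading.

The production integrator uses a numba kernel (:mod:`preyflock._kernels`)
that reproduces these formulas term by term; tests assert agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import minimum_image
from .params import ModelParams
from .state import CRUISING, ESCAPE, WorldState

__all__ = [
    "ForceBreakdown",
    "coincident_unit_vector",
    "visible_mask",
    "separation_force",
    "prey_mode_update",
    "propulsion_force",
    "alignment_force",
    "attraction_force",
    "friction_force",
    "total_prey_force",
    "prey_force_breakdown",
]


@dataclass
class ForceBreakdown:
    """Per-agent force terms (each (N, 2)) and their gated sum."""

    separation: np.ndarray
    propulsion: np.ndarray
    alignment: np.ndarray
    attraction: np.ndarray
    friction: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return (self.separation + self.propulsion + self.alignment
                + self.attraction + self.friction)


def coincident_unit_vector(id_a: int, id_b: int) -> np.ndarray:
    """Deterministic pseudo-random repulsion direction for coincident agents.

    Derived from a hash of the ordered id pair so that both agents agree on
    the axis; the lower id is pushed along +u, the higher along -u.
    """
    a, b = (id_a, id_b) if id_a < id_b else (id_b, id_a)
    h = (1103515245 * ((a * 73856093) ^ (b * 19349663)) + 12345) % 2147483648
    ang = 2.0 * math.pi * h / 2147483648.0
    return np.array([math.cos(ang), math.sin(ang)])


def visible_mask(pos: np.ndarray, heading: np.ndarray, others: np.ndarray,
                 radius: float, theta_b: float, L: float) -> np.ndarray:
    """Boolean mask of ``others`` within ``radius`` and outside the blind cone.

    The blind cone has half-angle ``theta_b / 2`` about the direction opposite
    the heading. Points at zero distance are considered visible.
    """
    d = minimum_image(np.atleast_2d(others) - pos, L)
    r = np.linalg.norm(d, axis=1)
    inside = r <= radius
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_back = np.where(r > 0, -(d @ heading) / r, -1.0)
    # blind iff strictly inside the rear cone
    blind = cos_back > math.cos(theta_b / 2.0) if theta_b > 0 else np.zeros_like(inside)
    return inside & ~blind


def separation_force(i: int, positions: np.ndarray, pair_radii: np.ndarray,
                     k_n: float, L: float, ids: np.ndarray | None = None) -> np.ndarray:
    """Hertzian-style contact repulsion on agent ``i`` from all overlapping agents.

    ``pair_radii[j]`` is the contact distance (d_i + d_j)/2 for the pair (i, j);
    the force is -k_n * delta * x_hat_ij for overlap delta = r - pair_radius < 0.
    """
    if ids is None:
        ids = np.arange(len(positions))
    f = np.zeros(2)
    for j in range(len(positions)):
        if j == i:
            continue
        dx = minimum_image(positions[j] - positions[i], L)
        r = math.hypot(dx[0], dx[1])
        delta = r - pair_radii[j]
        if delta >= 0:
            continue
        if r > 0:
            away = -dx / r  # unit vector from j toward i
        else:
            u = coincident_unit_vector(int(ids[i]), int(ids[j]))
            away = u if ids[i] < ids[j] else -u
        f += -k_n * delta * away
    return f


def prey_mode_update(world: WorldState, params: ModelParams) -> None:
    """Set cruising/escape mode and flee direction from current positions.

    A live prey escapes iff at least one predator lies in its detection zone
    (radius ``r_d``, blind cone excluded); the flee direction points away from
    the nearest detected predator (or away from their mean direction when the
    ``escape_from_nearest`` switch is off).
    """
    L = params.L
    for i in range(world.n_prey):
        if not world.mu[i]:
            world.prey_mode[i] = CRUISING
            continue
        mask = visible_mask(world.prey_x[i], world.prey_heading[i],
                            world.pred_x, params.r_d, params.theta_b, L)
        if not mask.any():
            world.prey_mode[i] = CRUISING
            continue
        d = minimum_image(world.pred_x[mask] - world.prey_x[i], L)
        r = np.linalg.norm(d, axis=1)
        if params.escape_from_nearest:
            away = -d[np.argmin(r)]
        else:
            with np.errstate(invalid="ignore"):
                away = -(d / np.where(r[:, None] > 0, r[:, None], 1.0)).sum(axis=0)
        nrm = np.linalg.norm(away)
        world.prey_mode[i] = ESCAPE
        world.escape_dir[i] = away / nrm if nrm > 0 else world.prey_heading[i]


def propulsion_force(v: np.ndarray, heading: np.ndarray, mode: int,
                     escape_dir: np.ndarray, params: ModelParams) -> np.ndarray:
    """Two-state Rayleigh-capped self-propulsion.

    Cruising drives along the current heading with acceleration beta_pr_c;
    escape drives away from the detected predator with beta_pr_e. The
    gamma*|v|^2 term caps the attainable speed.
    """
    speed2 = float(v @ v)
    if mode == ESCAPE:
        direction = escape_dir
        beta = params.beta_pr_e
    else:
        speed = math.sqrt(speed2)
        direction = v / speed if speed > 0 else heading
        beta = params.beta_pr_c
    return params.m_pr * (beta - params.gamma * speed2) * np.asarray(direction)


def alignment_force(v: np.ndarray, neighbour_v: np.ndarray, neighbour_dist: np.ndarray,
                    neighbour_mass: np.ndarray, params: ModelParams,
                    zeta: float = 0.0) -> np.ndarray:
    """Mass- and distance-weighted velocity alignment with orientational noise.

    F = C_v * d_pr * (phi * v_surr - v) where phi is the neighbour mass
    fraction against the entrained fluid mass and v_surr the Gaussian-weighted
    mean neighbour velocity; the force direction is then rotated by ``zeta``
    preserving magnitude. With no live neighbours phi*v_surr == 0, leaving the
    social drag -C_v*d_pr*v.
    """
    m_sum = float(np.sum(neighbour_mass))
    if m_sum > 0:
        w = neighbour_mass * np.exp(-neighbour_dist ** 2 / (2.0 * params.w_rms ** 2))
        v_surr = (w[:, None] * neighbour_v).sum(axis=0) / w.sum()
        phi = m_sum / (m_sum + params.m_fluid)
        f = params.C_v * params.d_pr * (phi * v_surr - np.asarray(v))
    else:
        f = -params.C_v * params.d_pr * np.asarray(v)
    if zeta != 0.0:
        c, s = math.cos(zeta), math.sin(zeta)
        f = np.array([c * f[0] - s * f[1], s * f[0] + c * f[1]])
    return f


def attraction_force(pos: np.ndarray, neighbour_pos: np.ndarray,
                     params: ModelParams, L: float | None = None) -> np.ndarray:
    """Long-range cohesion toward live conspecifics in the attraction shell.

    The per-pair magnitude upsilon_a * sqrt(1 - (1 - r/r_atr)^2) grows with
    distance (strongest at the shell edge); each contribution is directed
    toward the neighbour.
    """
    L = params.L if L is None else L
    f = np.zeros(2)
    for xj in np.atleast_2d(neighbour_pos):
        dx = minimum_image(xj - pos, L)
        r = math.hypot(dx[0], dx[1])
        if r <= 0:
            continue
        arg = 1.0 - (1.0 - r / params.r_atr) ** 2
        f += params.upsilon_a * math.sqrt(max(arg, 0.0)) * dx / r
    return f


def friction_force(v: np.ndarray, drag_coeff: float) -> np.ndarray:
    """Quadratic medium drag -0.5*rho*c_f*A*|v|*v (prefactor precomputed)."""
    v = np.asarray(v, dtype=float)
    return -drag_coeff * math.hypot(v[0], v[1]) * v


def prey_force_breakdown(world: WorldState, params: ModelParams,
                         zeta: np.ndarray | None = None,
                         prey_v: np.ndarray | None = None,
                         pred_v: np.ndarray | None = None) -> ForceBreakdown:
    """Assemble every force term for every prey agent (reference path).

    ``prey_v`` may override the stored velocities (the integrator evaluates
    forces at half-updated velocities). Dead prey get exactly zero for the
    mu-gated block.
    """
    n = world.n_prey
    if zeta is None:
        zeta = np.zeros(n)
    v_pr = world.prey_v if prey_v is None else prey_v
    L = params.L
    sep = np.zeros((n, 2))
    prop = np.zeros((n, 2))
    alg = np.zeros((n, 2))
    atr = np.zeros((n, 2))
    fric = np.zeros((n, 2))
    all_x = np.vstack([world.prey_x, world.pred_x])
    drag_pr = params.drag_coeff_prey()
    for i in range(n):
        pair_radii = np.empty(len(all_x))
        pair_radii[:n] = params.d_pr
        pair_radii[n:] = 0.5 * (params.d_pr + params.d_pd)
        sep[i] = separation_force(i, all_x, pair_radii, params.k_n, L)
        fric[i] = friction_force(v_pr[i], drag_pr)
        if not world.mu[i]:
            continue
        prop[i] = propulsion_force(v_pr[i], world.prey_heading[i],
                                   int(world.prey_mode[i]), world.escape_dir[i],
                                   params)
        d = minimum_image(world.prey_x - world.prey_x[i], L)
        r = np.linalg.norm(d, axis=1)
        live = world.mu.astype(bool).copy()
        live[i] = False
        if params.blind_angle_social:
            vis = visible_mask(world.prey_x[i], world.prey_heading[i],
                               world.prey_x, params.r_atr, params.theta_b, L)
        else:
            vis = r <= params.r_atr
        social = live & vis
        in_alg = social & (r > params.r_sep) & (r <= params.r_alg)
        in_atr = social & (r > params.r_alg) & (r <= params.r_atr)
        alg[i] = alignment_force(v_pr[i], v_pr[in_alg], r[in_alg],
                                 np.full(in_alg.sum(), params.m_pr), params,
                                 float(zeta[i]))
        if in_atr.any():
            atr[i] = attraction_force(world.prey_x[i], world.prey_x[in_atr],
                                      params)
    return ForceBreakdown(sep, prop, alg, atr, fric)


def total_prey_force(world: WorldState, params: ModelParams,
                     zeta: np.ndarray | None = None) -> np.ndarray:
    """Total per-prey force (N, 2); see :func:`prey_force_breakdown`."""
    return prey_force_breakdown(world, params, zeta).total
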