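"""Initial conditions: a cohesive prey aggregate and predator placement.

The study starts every realisation from a single connected, polarised prey
aggregate; the predators are then placed on a circle about the aggregate
centroid at a relative angle Omega_P, aimed at the centroid.
"""

from __future__ import annotations

import math

import numpy as np

from .metrics import cluster_prey, default_min_pts
from .params import ConfigError, ModelParams, terminal_speed
from .state import SEARCH, WorldState, empty_world

__all__ = ["init_prey_aggregate", "place_predators", "default_R0", "build_world"]

_LATTICE_SPACING = 1.1  # in prey diameters; slightly above contact
_HEADING_JITTER = 0.02  # rad, std of per-agent heading perturbation


def _disc_lattice(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """First n sites of a jittered triangular lattice, nearest-to-centre first."""
    rows = int(math.ceil(math.sqrt(n))) + 3
    pts = []
    for iy in range(-rows, rows + 1):
        for ix in range(-rows, rows + 1):
            x = (ix + 0.5 * (iy % 2)) * spacing
            y = iy * spacing * math.sqrt(3) / 2
            pts.append((x, y))
    pts = np.array(pts)
    pts = pts[np.argsort(np.linalg.norm(pts, axis=1), kind="stable")][:n]
    return pts + rng.uniform(-0.03, 0.03, size=pts.shape) * spacing


def init_prey_aggregate(params: ModelParams, rng: np.random.Generator,
                        max_retries: int = 5) -> WorldState:
    """Build a world with a single cohesive prey aggregate and no predators.

    Prey are placed on a jittered triangular lattice (spacing 1.1 d_pr) in a
    disc at the domain centre, all with a common random heading (small
    angular jitter) at the lone-agent cruising terminal speed. The
    postcondition that DBSCAN(eps=r_alg, min_pts=1% N) finds exactly one
    cluster is verified; the placement is retried on failure.
    """
    spacing = _LATTICE_SPACING * params.d_pr
    for _ in range(max_retries):
        offsets = _disc_lattice(params.N, spacing, rng)
        radius = np.linalg.norm(offsets, axis=1).max() if params.N > 1 else 0.0
        if 2 * radius > 0.8 * params.L:
            raise ConfigError(
                f"prey aggregate (diameter ~{2 * radius:.1f}) does not fit "
                f"in the domain (L={params.L})")
        world = empty_world(params)
        world.pred_x = np.zeros((0, 2))
        world.pred_v = np.zeros((0, 2))
        world.pred_heading = np.zeros((0, 2))
        world.pred_mode = np.zeros(0, dtype=np.int8)
        world.pred_target = np.zeros(0, dtype=np.int64)
        world.pred_timer = np.zeros(0)
        world.pred_strategy_mode = np.zeros(0, dtype=np.int8)
        world.open_pursuit_start = np.zeros(0)
        world.open_pursuit_phi = np.zeros(0)
        centre = np.array([params.L / 2, params.L / 2])
        world.prey_x = (centre + offsets) % params.L
        theta0 = rng.uniform(0.0, 2 * math.pi)
        angles = theta0 + rng.normal(0.0, _HEADING_JITTER, params.N)
        v_c = terminal_speed(params.m_pr, params.beta_pr_c, params.gamma,
                             params.drag_coeff_prey())
        world.prey_v = v_c * np.column_stack([np.cos(angles), np.sin(angles)])
        world.prey_heading = np.column_stack([np.cos(angles), np.sin(angles)])
        res = cluster_prey(world.prey_x, params.r_alg,
                           default_min_pts(params.N), params.L, params.N)
        if params.N < default_min_pts(params.N) or (
                res.n_clusters == 1 and res.n_noise == 0):
            return world
    raise ConfigError("failed to build a single connected prey aggregate")


def default_R0(params: ModelParams) -> float:
    """Default initial predator distance: just outside the prey detection zone."""
    return params.r_d * 1.1


def place_predators(world: WorldState, params: ModelParams,
                    group_centroid: np.ndarray, Omega_P: float,
                    R0: float | None, rng: np.random.Generator) -> WorldState:
    """Place N_p predators on a circle of radius R0 about the prey centroid.

    For two predators the angle subtended at the centroid equals Omega_P; the
    common bisector direction is drawn uniformly so ensembles average over
    the group heading. Initial velocities point at the centroid at the
    satisfied-state terminal speed; predators start searching for a target.
    """
    if not 0.0 <= Omega_P <= math.pi:
        raise ConfigError(f"Omega_P={Omega_P} outside [0, pi]")
    if R0 is None:
        R0 = default_R0(params)
    if R0 <= 0:
        raise ConfigError(f"R0 must be > 0, got {R0}")
    base = rng.uniform(0.0, 2 * math.pi)
    if params.N_p == 2:
        angles = np.array([base - Omega_P / 2, base + Omega_P / 2])
    else:
        angles = np.array([base])
    offsets = R0 * np.column_stack([np.cos(angles), np.sin(angles)])
    pos = (np.asarray(group_centroid) + offsets) % params.L
    inward = -offsets / np.linalg.norm(offsets, axis=1, keepdims=True)
    v_sr = terminal_speed(params.m_pd, params.beta_pd_sr, params.gamma,
                          params.drag_coeff_predator())
    world.pred_x = pos
    world.pred_v = v_sr * inward
    world.pred_heading = inward.copy()
    world.pred_mode = np.full(params.N_p, SEARCH, dtype=np.int8)
    world.pred_target = np.full(params.N_p, -1, dtype=np.int64)
    world.pred_timer = np.zeros(params.N_p)
    world.pred_strategy_mode = np.zeros(params.N_p, dtype=np.int8)
    world.open_pursuit_start = np.zeros(params.N_p)
    world.open_pursuit_phi = np.zeros(params.N_p)
    world.pred_acc = None  # force re-initialisation of cached accelerations
    world.prey_acc = None
    return world


def live_centroid(world: WorldState, L: float) -> np.ndarray:
    """Centroid of live prey on the torus (circular-mean per coordinate)."""
    live = world.mu.astype(bool)
    x = world.prey_x[live]
    ang = 2 * math.pi * x / L
    mean = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
    return (mean % (2 * math.pi)) * L / (2 * math.pi)


def build_world(params: ModelParams, rng: np.random.Generator,
                Omega_P: float = math.pi, R0: float | None = None,
                equilibration_time: float = 20.0,
                engine: str = "numba") -> WorldState:
    """Aggregate + equilibration + predator placement, ready to simulate."""
    from .engine import initialise, run  # local import to avoid a cycle

    world = init_prey_aggregate(params, rng)
    if equilibration_time > 0:
        initialise(world, params, rng, engine=engine)
        run(world, params, rng, T_max=equilibration_time, engine=engine)
    place_predators(world, params, live_centroid(world, params.L), Omega_P,
                    R0, rng)
    initialise(world, params, rng, engine=engine)
    return world
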