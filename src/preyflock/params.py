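"""Model parameters, derived scales and configuration validation.

The simulation is natively non-dimensional: the prey diameter ``d_pr`` is the
length unit and the escape acceleration ``beta_pr_e`` sets the time unit
``t0 = sqrt(d_pr / beta_pr_e)`` and speed unit ``v0 = sqrt(d_pr * beta_pr_e)``.
With the shipped defaults (``d_pr = beta_pr_e = m_pr = 1``) all outputs are
already in these units.

The prey coordination strength is the dimensionless ratio of the alignment
force to the escape self-propulsion force,

    chi = (C_v * d_pr / m_pr) * sqrt(d_pr / beta_pr_e),

and a configuration may request ``chi_target`` instead of ``C_v``; the
alignment strength is then solved from the definition above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Any

from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "DerivedScales",
    "ExperimentConfig",
    "ConfigError",
    "build_config",
    "default_params",
    "terminal_speed",
    "DEFAULT_PARAM_VALUES",
]


class ConfigError(ValueError):
    """Raised when a configuration violates a model constraint."""


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the force laws and the predation cycle.

    All lengths are in units of the prey diameter, all times in units of
    ``t0`` under the default normalisation.
    """

    # prey
    m_pr: float = 1.0          # prey mass
    d_pr: float = 1.0          # prey diameter (system length unit)
    beta_pr_c: float = 0.25    # cruising acceleration
    beta_pr_e: float = 1.0     # escape acceleration
    gamma: float = 0.05        # Rayleigh friction factor (1/length)
    k_n: float = 60.0          # Hertzian contact stiffness
    C_v: float = 17.0          # alignment strength
    sigma_zeta: float = 0.15   # orientational noise std (rad, per step)
    upsilon_a: float = 0.003   # attraction strength (force per neighbour)
    m_fluid: float = 1.0       # fluid mass in the alignment shell
    w_rms: float = 1.0         # RMS width of the Gaussian alignment weight
    r_sep: float = 1.0         # separation zone radius (= d_pr, monodisperse)
    r_alg: float = 3.5         # alignment zone radius
    r_atr: float = 15.0        # attraction zone radius (= r_d for prey)
    r_d: float = 15.0          # prey detection radius
    theta_b: float = math.pi / 3  # total blind-angle width behind the heading
    # medium (quadratic drag constants, shared functional form)
    rho: float = 1.0           # medium density
    c_f: float = 1.9           # drag coefficient
    A: float = 1.0             # wetted area of a prey agent
    # predator
    m_pd: float = 16.0         # predator mass (~16x prey)
    d_pd: float = 2.0          # predator diameter
    beta_pd_sr: float = 0.11   # satisfied / refocus acceleration
    beta_pd_h: float = 0.175   # pursuit acceleration
    R_c: float = 1.4           # capture radius
    R_d: float = 20.0          # predator detection radius
    tau_P: float = 20.0        # maximum pursuit duration
    tau_S: float = 15.0        # satisfaction duration
    tau_R: float = 10.0        # refocus duration
    # world
    L: float = 200.0           # periodic domain side
    dt: float = 0.025          # integration timestep
    N: int = 506               # prey count
    N_p: int = 2               # predator count (1 or 2)
    # behavioural switches (model variants; defaults documented in docs)
    blind_angle_social: bool = True   # apply theta_b to alignment/attraction
    escape_from_nearest: bool = True  # flee nearest detected predator
    opportunistic_capture: bool = False  # capture non-target prey in R_c

    def drag_coeff_prey(self) -> float:
        """Quadratic drag prefactor 0.5*rho*c_f*A for a prey agent."""
        return 0.5 * self.rho * self.c_f * self.A

    def drag_coeff_predator(self) -> float:
        """Predator drag prefactor; wetted area scales with the diameter."""
        return 0.5 * self.rho * self.c_f * self.A * (self.d_pd / self.d_pr)


@dataclass(frozen=True)
class DerivedScales:
    """Characteristic scales derived from :class:`ModelParams`."""

    v0: float    # speed scale sqrt(d_pr * beta_pr_e)
    t0: float    # time scale sqrt(d_pr / beta_pr_e)
    chi: float   # coordination strength (C_v d_pr / m_pr) * t0

    @classmethod
    def from_params(cls, p: ModelParams) -> "DerivedScales":
        t0 = math.sqrt(p.d_pr / p.beta_pr_e)
        return cls(
            v0=math.sqrt(p.d_pr * p.beta_pr_e),
            t0=t0,
            chi=p.C_v * p.d_pr / p.m_pr * t0,
        )


def c_v_for_chi(chi: float, p: ModelParams) -> float:
    """Invert the chi definition to obtain the alignment strength C_v."""
    t0 = math.sqrt(p.d_pr / p.beta_pr_e)
    return chi * p.m_pr / (p.d_pr * t0)


STRATEGIES = ("purely_NP", "purely_MCP", "NP_MCP_probabilistic", "NP_MCP_deterministic")


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings of one experiment: strategy, geometry, replication, seed."""

    strategy: str = "purely_NP"
    Omega_P: float = math.pi     # relative predator attack angle (rad)
    chi_target: float | None = None
    n_realisations: int = 50
    seed: int = 0
    T_max: float = 100.0         # total simulated time (t0 units)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if not (0.0 <= self.Omega_P <= math.pi):
            raise ConfigError(
                f"Omega_P={self.Omega_P} violates 0 <= Omega_P <= pi")
        if self.n_realisations < 1:
            raise ConfigError("n_realisations must be >= 1")


def terminal_speed(mass: float, beta: float, gamma: float, drag_coeff: float) -> float:
    """Steady speed solving m*(beta - gamma*v^2) = drag_coeff*v^2.

    Solved by bracketed root finding on the force balance; the propulsion
    (Rayleigh-capped) exactly offsets the quadratic medium drag.
    """
    if beta <= 0:
        return 0.0

    def residual(v: float) -> float:
        return mass * (beta - gamma * v * v) - drag_coeff * v * v

    hi = math.sqrt(beta / gamma) if gamma > 0 else 1.0
    while residual(hi) > 0:
        hi *= 2.0
    return float(brentq(residual, 0.0, hi, xtol=1e-12, rtol=1e-15))


_POSITIVE = (
    "m_pr", "d_pr", "beta_pr_c", "beta_pr_e", "gamma", "k_n", "m_fluid",
    "w_rms", "r_sep", "r_alg", "r_atr", "r_d", "rho", "c_f", "A", "m_pd",
    "d_pd", "beta_pd_sr", "beta_pd_h", "R_c", "R_d", "tau_P", "tau_S",
    "tau_R", "L", "dt",
)

MIN_MASS_RATIO = 8.0  # "much higher (around 16x)" predator-to-prey mass


def validate_params(p: ModelParams) -> None:
    """Check every structural constraint; raise ConfigError naming the first
    violated inequality."""
    for name in _POSITIVE:
        if getattr(p, name) <= 0:
            raise ConfigError(f"{name} must be > 0, got {getattr(p, name)}")
    if not p.r_sep < p.r_alg < p.r_atr:
        raise ConfigError(
            f"zone ordering violated: require r_sep < r_alg < r_atr, got "
            f"{p.r_sep} / {p.r_alg} / {p.r_atr}")
    if p.r_atr != p.r_d:
        raise ConfigError(f"require r_atr = r_d for prey, got {p.r_atr} != {p.r_d}")
    if not p.R_c < p.R_d:
        raise ConfigError(f"require R_c < R_d, got {p.R_c} >= {p.R_d}")
    if not 0.0 <= p.theta_b < 2 * math.pi:
        raise ConfigError(f"require 0 <= theta_b < 2*pi, got {p.theta_b}")
    ratio = p.m_pd / p.m_pr
    if ratio < MIN_MASS_RATIO:
        raise ConfigError(
            f"mass-ratio constraint violated: m_pd/m_pr = {ratio:.3g} < "
            f"{MIN_MASS_RATIO} (predators must be much heavier than prey)")
    if p.N < 1:
        raise ConfigError(f"N must be >= 1, got {p.N}")
    if p.N_p not in (1, 2):
        raise ConfigError(f"N_p must be 1 or 2, got {p.N_p}")
    if not max(p.r_d, p.R_d) < p.L / 2:
        raise ConfigError(
            f"detection radii must satisfy max(r_d, R_d) < L/2 for the "
            f"minimum-image convention, got {max(p.r_d, p.R_d)} >= {p.L / 2}")
    # Overshoot stability: the propulsion's Rayleigh term -gamma*|v|^2 points
    # along the drive direction, not along -v; when an agent overshoots its
    # drive direction above terminal speed the term feeds energy back unless
    # the true medium drag dominates it.
    if p.gamma * p.m_pr >= p.drag_coeff_prey():
        raise ConfigError(
            f"stability constraint violated: gamma*m_pr = {p.gamma * p.m_pr:.3g}"
            f" must be < prey drag prefactor {p.drag_coeff_prey():.3g}")
    if p.gamma * p.m_pd >= p.drag_coeff_predator():
        raise ConfigError(
            f"stability constraint violated: gamma*m_pd = {p.gamma * p.m_pd:.3g}"
            f" must be < predator drag prefactor {p.drag_coeff_predator():.3g}")
    v_prey = terminal_speed(p.m_pr, p.beta_pr_e, p.gamma, p.drag_coeff_prey())
    v_pred = terminal_speed(p.m_pd, p.beta_pd_h, p.gamma, p.drag_coeff_predator())
    if not v_pred > v_prey:
        raise ConfigError(
            f"speed constraint violated: predator terminal pursuit speed "
            f"{v_pred:.4g} must exceed prey terminal escape speed {v_prey:.4g}")


_MODEL_FIELDS = {f.name for f in fields(ModelParams)}
_EXP_FIELDS = {f.name for f in fields(ExperimentConfig)}


def build_config(raw: dict[str, Any]) -> tuple[ModelParams, DerivedScales]:
    """Build validated model parameters from a flat key-value map.

    ``chi_target`` may be given instead of (or in addition to) ``C_v``; the
    alignment strength is then computed by inverting the chi definition.
    Unknown keys are rejected.
    """
    raw = dict(raw)
    chi_target = raw.pop("chi_target", None)
    unknown = set(raw) - _MODEL_FIELDS - _EXP_FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    model_kwargs = {k: v for k, v in raw.items() if k in _MODEL_FIELDS}
    p = ModelParams(**model_kwargs)
    if chi_target is not None:
        p = replace(p, C_v=c_v_for_chi(float(chi_target), p))
    validate_params(p)
    return p, DerivedScales.from_params(p)


def default_params(chi: float | None = None, **overrides: Any) -> ModelParams:
    """The documented default parameter set, optionally at a requested chi."""
    p = ModelParams(**overrides)
    if chi is not None:
        p = replace(p, C_v=c_v_for_chi(chi, p))
    validate_params(p)
    return p


DEFAULT_PARAM_VALUES: dict[str, Any] = {
    f.name: getattr(ModelParams(), f.name) for f in fields(ModelParams)
}
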