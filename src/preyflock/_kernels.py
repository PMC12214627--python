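"""Numba-compiled force kernel used by the production integrator.

Implements exactly the same force laws as :mod:`preyflock.forces` and
:mod:`preyflock.predator` with explicit O(N^2) pair loops; tests assert
agreement with the reference path to floating summation tolerance.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

PURSUIT = 0  # must match state.PURSUIT

__all__ = ["compute_forces", "prey_detection"]


@njit(cache=True)
def _min_image(d: float, L: float) -> float:
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True)
def _coincident_angle(a: int, b: int) -> float:
    if a > b:
        a, b = b, a
    h = (1103515245 * ((a * 73856093) ^ (b * 19349663)) + 12345) % 2147483648
    return 2.0 * math.pi * h / 2147483648.0


@njit(cache=True, fastmath=True)
def compute_forces(prey_x, prey_v, prey_heading, mu, prey_mode, escape_dir,
                   pred_x, pred_v, pred_heading, pred_mode, pred_target,
                   zeta,
                   # scalar parameters
                   L, m_pr, d_pr, beta_c, beta_e, gamma, k_n, C_v,
                   upsilon_a, m_fluid, w_rms, r_sep, r_alg, r_atr,
                   cos_half_blind, blind_social,
                   drag_pr, m_pd, d_pd, beta_sr, beta_h, drag_pd):
    """Total forces on all prey and all predators.

    Velocities are whatever the integrator passes (half-kick velocities for
    the velocity-Verlet force evaluation). ``cos_half_blind`` is
    cos(theta_b/2); a neighbour is inside the blind cone when the unit
    displacement's projection on -heading exceeds it.
    """
    n = prey_x.shape[0]
    npd = pred_x.shape[0]
    f_prey = np.zeros((n, 2))
    f_pred = np.zeros((npd, 2))
    inv2w2 = 1.0 / (2.0 * w_rms * w_rms)
    half_L = 0.5 * L
    r_atr2 = r_atr * r_atr

    for i in range(n):
        fx = 0.0
        fy = 0.0
        # alignment accumulators
        sw_vx = 0.0
        sw_vy = 0.0
        sw = 0.0
        sm = 0.0
        # attraction accumulator
        ax = 0.0
        ay = 0.0
        hx = prey_heading[i, 0]
        hy = prey_heading[i, 1]
        alive_i = mu[i] != 0
        xi = prey_x[i, 0]
        yi = prey_x[i, 1]
        for j in range(n):
            if j == i:
                continue
            # positions live in [0, L): one branch wraps the displacement
            dx = prey_x[j, 0] - xi
            if dx >= half_L:
                dx -= L
            elif dx < -half_L:
                dx += L
            if dx > r_atr or dx < -r_atr:
                continue  # beyond every prey-prey interaction zone
            dy = prey_x[j, 1] - yi
            if dy >= half_L:
                dy -= L
            elif dy < -half_L:
                dy += L
            if dy > r_atr or dy < -r_atr:
                continue
            r2 = dx * dx + dy * dy
            if r2 > r_atr2:
                continue
            r = math.sqrt(r2)
            inv_r = 1.0 / r if r > 0.0 else 0.0
            # contact separation (pair radius d_pr, monodisperse prey)
            if r < d_pr:
                delta = r - d_pr
                if r > 0.0:
                    ux = -dx * inv_r
                    uy = -dy * inv_r
                else:
                    ang = _coincident_angle(i, j)
                    sgn = 1.0 if i < j else -1.0
                    ux = sgn * math.cos(ang)
                    uy = sgn * math.sin(ang)
                fx += -k_n * delta * ux
                fy += -k_n * delta * uy
            if not alive_i or mu[j] == 0 or r <= r_sep:
                continue
            if blind_social and r > 0.0:
                # blind iff -(d . h)/r > cos(theta_b/2); compare squares to
                # avoid the division (cos_half_blind may be negative for
                # blind angles wider than pi)
                back = -(dx * hx + dy * hy)
                if cos_half_blind >= 0.0:
                    if back > 0.0 and back * back > cos_half_blind * cos_half_blind * r2:
                        continue
                else:
                    if back > 0.0 or back * back < cos_half_blind * cos_half_blind * r2:
                        continue
            if r <= r_alg:
                w = m_pr * math.exp(-r2 * inv2w2)
                sw_vx += w * prey_v[j, 0]
                sw_vy += w * prey_v[j, 1]
                sw += w
                sm += m_pr
            else:
                t = 1.0 - r / r_atr
                mag = upsilon_a * math.sqrt(max(1.0 - t * t, 0.0)) * inv_r
                ax += mag * dx
                ay += mag * dy
        # separation from predators
        for k in range(npd):
            dx = _min_image(pred_x[k, 0] - prey_x[i, 0], L)
            dy = _min_image(pred_x[k, 1] - prey_x[i, 1], L)
            r = math.sqrt(dx * dx + dy * dy)
            pr = 0.5 * (d_pr + d_pd)
            if r < pr:
                delta = r - pr
                if r > 0.0:
                    ux = -dx / r
                    uy = -dy / r
                else:
                    ang = _coincident_angle(i, n + k)
                    ux = math.cos(ang)
                    uy = math.sin(ang)
                fx += -k_n * delta * ux
                fy += -k_n * delta * uy
        vx = prey_v[i, 0]
        vy = prey_v[i, 1]
        speed2 = vx * vx + vy * vy
        speed = math.sqrt(speed2)
        # quadratic drag
        fx += -drag_pr * speed * vx
        fy += -drag_pr * speed * vy
        if alive_i:
            # propulsion
            if prey_mode[i] == 1:  # escape
                dirx = escape_dir[i, 0]
                diry = escape_dir[i, 1]
                beta = beta_e
            else:
                if speed > 0.0:
                    dirx = vx / speed
                    diry = vy / speed
                else:
                    dirx = hx
                    diry = hy
                beta = beta_c
            amp = m_pr * (beta - gamma * speed2)
            fx += amp * dirx
            fy += amp * diry
            # alignment with orientational noise
            if sm > 0.0:
                phi = sm / (sm + m_fluid)
                cx = C_v * d_pr * (phi * sw_vx / sw - vx)
                cy = C_v * d_pr * (phi * sw_vy / sw - vy)
            else:
                cx = -C_v * d_pr * vx
                cy = -C_v * d_pr * vy
            z = zeta[i]
            if z != 0.0:
                cz = math.cos(z)
                sz = math.sin(z)
                tx = cz * cx - sz * cy
                cy = sz * cx + cz * cy
                cx = tx
            fx += cx + ax
            fy += cy + ay
        f_prey[i, 0] = fx
        f_prey[i, 1] = fy

    for k in range(npd):
        fx = 0.0
        fy = 0.0
        for j in range(n):
            dx = _min_image(prey_x[j, 0] - pred_x[k, 0], L)
            dy = _min_image(prey_x[j, 1] - pred_x[k, 1], L)
            r = math.sqrt(dx * dx + dy * dy)
            pr = 0.5 * (d_pr + d_pd)
            if r < pr:
                delta = r - pr
                if r > 0.0:
                    ux = -dx / r
                    uy = -dy / r
                else:
                    ang = _coincident_angle(j, n + k)
                    ux = -math.cos(ang)
                    uy = -math.sin(ang)
                fx += -k_n * delta * ux
                fy += -k_n * delta * uy
        for k2 in range(npd):
            if k2 == k:
                continue
            dx = _min_image(pred_x[k2, 0] - pred_x[k, 0], L)
            dy = _min_image(pred_x[k2, 1] - pred_x[k, 1], L)
            r = math.sqrt(dx * dx + dy * dy)
            if r < d_pd:
                delta = r - d_pd
                if r > 0.0:
                    ux = -dx / r
                    uy = -dy / r
                else:
                    ang = _coincident_angle(n + min(k, k2), n + max(k, k2))
                    sgn = 1.0 if k < k2 else -1.0
                    ux = sgn * math.cos(ang)
                    uy = sgn * math.sin(ang)
                fx += -k_n * delta * ux
                fy += -k_n * delta * uy
        vx = pred_v[k, 0]
        vy = pred_v[k, 1]
        speed2 = vx * vx + vy * vy
        speed = math.sqrt(speed2)
        fx += -drag_pd * speed * vx
        fy += -drag_pd * speed * vy
        if pred_mode[k] == PURSUIT and pred_target[k] >= 0:
            tgt = pred_target[k]
            dx = _min_image(prey_x[tgt, 0] - pred_x[k, 0], L)
            dy = _min_image(prey_x[tgt, 1] - pred_x[k, 1], L)
            r = math.sqrt(dx * dx + dy * dy)
            if r > 0.0:
                dirx = dx / r
                diry = dy / r
            else:
                dirx = pred_heading[k, 0]
                diry = pred_heading[k, 1]
            beta = beta_h
        else:
            if speed > 0.0:
                dirx = vx / speed
                diry = vy / speed
            else:
                dirx = pred_heading[k, 0]
                diry = pred_heading[k, 1]
            beta = beta_sr
        amp = m_pd * (beta - gamma * speed2)
        fx += amp * dirx
        fy += amp * diry
        f_pred[k, 0] = fx
        f_pred[k, 1] = fy

    return f_prey, f_pred


@njit(cache=True)
def prey_detection(prey_x, prey_heading, mu, pred_x, r_d, cos_half_blind,
                   L, escape_from_nearest):
    """Cruise/escape mode and flee direction for every prey.

    Returns (mode array, escape-direction array). Escape iff a predator is
    within r_d outside the blind cone; the flee direction points away from
    the nearest detected predator (or the averaged repulsion when
    ``escape_from_nearest`` is false).
    """
    n = prey_x.shape[0]
    npd = pred_x.shape[0]
    mode = np.zeros(n, dtype=np.int8)
    edir = np.zeros((n, 2))
    for i in range(n):
        if mu[i] == 0:
            continue
        best_r = 1e300
        bx = 0.0
        by = 0.0
        sx = 0.0
        sy = 0.0
        found = False
        for k in range(npd):
            dx = _min_image(pred_x[k, 0] - prey_x[i, 0], L)
            dy = _min_image(pred_x[k, 1] - prey_x[i, 1], L)
            r = math.sqrt(dx * dx + dy * dy)
            if r > r_d:
                continue
            if r > 0.0:
                proj = -(dx * prey_heading[i, 0] + dy * prey_heading[i, 1]) / r
                if proj > cos_half_blind:
                    continue
            found = True
            if r > 0.0:
                sx += -dx / r
                sy += -dy / r
            if r < best_r:
                best_r = r
                bx = -dx
                by = -dy
        if not found:
            continue
        mode[i] = 1
        if escape_from_nearest:
            ex, ey = bx, by
        else:
            ex, ey = sx, sy
        nrm = math.sqrt(ex * ex + ey * ey)
        if nrm > 0.0:
            edir[i, 0] = ex / nrm
            edir[i, 1] = ey / nrm
        else:
            edir[i, 0] = prey_heading[i, 0]
            edir[i, 1] = prey_heading[i, 1]
    return mode, edir
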