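"""Experiment runners for the three studies.

1. Attack-angle sweep: two predators approach a cohesive aggregate at a
   relative angle Omega_P; after one attack the largest-group fraction l_c
   and the group-size distribution p(phi) are measured over realisations.
2. Long-term repeated attacks: predators hunt until prey exhaustion or the
   horizon, recording the live fraction N_l(tau), capture rate alpha_K and
   the pursuit-outcome statistics f_eps.
3. One-vs-two-predator comparison: matched ensembles with N_p=1 and N_p=2
   yield the non-additivity ratio kappa(N_d).

Each realisation derives its own seed from the master seed through
``numpy.random.SeedSequence([master_seed, study_tag, index])`` so ensembles
are reproducible and individually resumable.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .engine import run
from .initial import build_world, default_R0
from .metrics import (MetricRecorder, cluster_prey, default_min_pts,
                      events_to_frame, first_passage_times,
                      group_size_distribution, kappa)
from .params import ModelParams, c_v_for_chi, default_params

__all__ = [
    "realisation_rng", "single_attack_realisation", "run_attack_angle_sweep",
    "run_long_term", "run_predator_count_comparison",
]

# study tags for seed derivation
_TAG_SWEEP, _TAG_LONG, _TAG_KAPPA = 1, 2, 3

EQUILIBRATION_TIME = 10.0  # t0 units of predator-free settling
SETTLE_TIME = 50.0         # continue this long after both first cycles close


def realisation_rng(master_seed: int, tag: int, index: int) -> np.random.Generator:
    """Independent generator for one realisation of one study."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag, index]))


def single_attack_realisation(params: ModelParams, strategy: str,
                              Omega_P: float, rng: np.random.Generator,
                              T_attack: float = 120.0,
                              R0: float | None = None,
                              settle_time: float | None = None,
                              engine: str = "numba") -> dict:
    """One equilibrated aggregate, one simultaneous attack, one clustering.

    The run ends once every predator has closed its first hunting cycle and a
    further settling window has elapsed (so split groups separate beyond
    r_atr), or at the fixed horizon ``T_attack`` past predator insertion.
    Returns l_c, the cluster sizes, the event log and the final world.
    """
    world = build_world(params, rng, Omega_P=Omega_P,
                        R0=default_R0(params) if R0 is None else R0,
                        equilibration_time=EQUILIBRATION_TIME, engine=engine)
    t_insert = world.t
    settle = SETTLE_TIME if settle_time is None else settle_time
    state = {"t_resolved": None}

    def settled(w) -> bool:
        if state["t_resolved"] is None:
            closed = {e.predator_id for e in w.events}
            if len(closed) == w.n_predators:
                state["t_resolved"] = w.t
            return False
        return w.t >= state["t_resolved"] + settle

    run(world, params, rng, T_max=t_insert + T_attack, strategy=strategy,
        engine=engine, stop_condition=settled, max_cycles=1)
    live = world.mu.astype(bool)
    res = cluster_prey(world.prey_x[live], params.r_alg,
                       default_min_pts(params.N), params.L, params.N)
    return {
        "l_c": res.l_c,
        "cluster_sizes": res.sizes,
        "n_clusters": res.n_clusters,
        "n_noise": res.n_noise,
        "events": world.events,
        "world": world,
        "settled": state["t_resolved"] is not None,
    }


def run_attack_angle_sweep(Omega_P_values, chi_values=(17.0,),
                           n_realisations: int = 50, seed: int = 0,
                           params: ModelParams | None = None,
                           strategy: str = "purely_NP",
                           T_attack: float = 120.0,
                           engine: str = "numba") -> dict:
    """Mean largest-group fraction and p(phi) across attack angles and chi.

    Returns {"table": per-realisation DataFrame, "summary": mean l_c per
    (chi, Omega_P), "phi_pool": pooled cluster sizes keyed by (chi, Omega_P)}.
    """
    rows = []
    phi_pool: dict[tuple[float, float], list[np.ndarray]] = {}
    counter = 0
    for chi in chi_values:
        if params is None:
            base = default_params(chi=chi)
        else:
            base = replace(params, C_v=c_v_for_chi(chi, params))
        for om in Omega_P_values:
            sizes_here: list[np.ndarray] = []
            for r in range(n_realisations):
                rng = realisation_rng(seed, _TAG_SWEEP, counter)
                counter += 1
                out = single_attack_realisation(base, strategy, om, rng,
                                                T_attack=T_attack,
                                                engine=engine)
                rows.append({
                    "chi": chi, "Omega_P": om, "realisation": r,
                    "l_c": out["l_c"], "n_clusters": out["n_clusters"],
                    "n_noise": out["n_noise"], "settled": out["settled"],
                })
                sizes_here.append(out["cluster_sizes"])
            phi_pool[(chi, om)] = sizes_here
    table = pd.DataFrame(rows)
    summary = table.groupby(["chi", "Omega_P"], as_index=False)["l_c"] \
        .agg(["mean", "std", "count"])
    return {"table": table, "summary": summary, "phi_pool": phi_pool}


def top_bin_mass(phi_pool_entry, N: int, threshold: float = 0.95) -> float:
    """Probability mass of the group-size distribution above ``threshold``."""
    edges = np.array([0.0, threshold, 1.0 + 1e-9])
    _, p = group_size_distribution(phi_pool_entry, N, bins=edges)
    return float(p[-1])


def run_long_term(strategy: str, chi: float, n_realisations: int = 3,
                  T_max: float = 500.0, seed: int = 0,
                  params: ModelParams | None = None, sample_stride: int = 50,
                  engine: str = "numba") -> dict:
    """Repeated-attack ensembles: N_l(tau) series and pursuit event logs."""
    if params is None:
        params = default_params(chi=chi)
    series = []
    all_events = []
    for r in range(n_realisations):
        rng = realisation_rng(seed, _TAG_LONG, r)
        world = build_world(params, rng, Omega_P=math.pi,
                            equilibration_time=EQUILIBRATION_TIME,
                            engine=engine)
        rec = MetricRecorder(params.r_alg, params.L,
                             math.sqrt(params.d_pr * params.beta_pr_e),
                             default_min_pts(params.N), params.N)
        run(world, params, rng, T_max=world.t + T_max, strategy=strategy,
            engine=engine, observers=[(sample_stride, rec)])
        frame = rec.to_frame()
        frame["realisation"] = r
        series.append(frame)
        ev = events_to_frame(world.events)
        ev["realisation"] = r
        all_events.append(ev)
    return {
        "series": pd.concat(series, ignore_index=True),
        "events": pd.concat(all_events, ignore_index=True),
        "strategy": strategy, "chi": chi,
    }


def run_predator_count_comparison(chi: float, n_realisations: int = 3,
                                  T_max: float = 800.0, seed: int = 0,
                                  Nd_grid=None, strategy: str = "purely_NP",
                                  sample_stride: int = 50,
                                  engine: str = "numba") -> dict:
    """kappa(N_d): matched single-predator and duo ensembles (NP strategy)."""
    if Nd_grid is None:
        Nd_grid = np.array([0.01, 0.02, 0.03, 0.05])
    Nd_grid = np.asarray(Nd_grid, dtype=float)
    fpt = {}
    for n_p in (1, 2):
        params = replace(default_params(chi=chi), N_p=n_p)
        times = np.full((n_realisations, len(Nd_grid)), np.nan)
        for r in range(n_realisations):
            rng = realisation_rng(seed, _TAG_KAPPA, 10 * r + n_p)
            world = build_world(params, rng, Omega_P=math.pi,
                                equilibration_time=EQUILIBRATION_TIME,
                                engine=engine)
            rec = MetricRecorder(params.r_alg, params.L,
                                 math.sqrt(params.d_pr * params.beta_pr_e),
                                 default_min_pts(params.N), params.N)
            t_insert = world.t
            target = float(Nd_grid[-1])

            def reached(w) -> bool:
                return 1.0 - w.n_live() / params.N >= target

            run(world, params, rng, T_max=t_insert + T_max, strategy=strategy,
                engine=engine, observers=[(sample_stride, rec)],
                stop_condition=reached)
            tau = np.asarray(rec.tau) - t_insert
            n_d = 1.0 - np.asarray(rec.n_l)
            times[r] = first_passage_times(tau, n_d, Nd_grid)
        fpt[n_p] = times
    return {
        "Nd_grid": Nd_grid,
        "fpt_single": fpt[1],
        "fpt_duo": fpt[2],
        "kappa": kappa(fpt[1], fpt[2]),
    }
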