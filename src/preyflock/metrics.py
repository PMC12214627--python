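"""Analysis metrics: local order, group statistics, capture rates, kappa.

The quantities here mirror the observables used to characterise collective
escape: the local order parameter Psi_L (mean pairwise heading cosine over
neighbouring live prey), DBSCAN group decomposition with periodic distances
(largest-group fraction l_c, group-size distribution p(phi)), the live
fraction N_l and its smoothed decay rate alpha_K, pursuit outcome tables
f_eps, and the predator-count non-additivity ratio kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import pairwise_displacements

__all__ = [
    "ClusterResult", "MetricRecorder",
    "local_order", "group_speed", "dbscan_periodic", "cluster_prey",
    "default_min_pts", "group_size_distribution", "live_fraction",
    "captured_fraction", "capture_rate", "pursuit_outcome_stats",
    "first_passage_times", "kappa", "events_to_frame",
]

NOISE = -1


def local_order(velocities: np.ndarray, positions: np.ndarray, r_alg: float,
                L: float) -> float:
    """Mean pairwise cosine of velocity directions over neighbouring pairs.

    Pairs are unordered pairs of (live) agents with minimum-image distance
    <= r_alg. Returns nan when no such pair exists (undefined order).
    Psi_L is 1 for a perfectly polarised group and ~0 for isotropic headings.
    """
    n = len(positions)
    if n < 2:
        return float("nan")
    d = pairwise_displacements(positions, positions, L)
    dist = np.linalg.norm(d, axis=2)
    iu, ju = np.triu_indices(n, k=1)
    near = dist[iu, ju] <= r_alg
    if not near.any():
        return float("nan")
    vi = velocities[iu[near]]
    vj = velocities[ju[near]]
    ni = np.linalg.norm(vi, axis=1)
    nj = np.linalg.norm(vj, axis=1)
    ok = (ni > 0) & (nj > 0)
    if not ok.any():
        return float("nan")
    cosang = np.einsum("ij,ij->i", vi[ok], vj[ok]) / (ni[ok] * nj[ok])
    return float(np.sum(cosang) / near.sum())


def group_speed(velocities: np.ndarray, v0: float) -> float:
    """Norm of the mean group velocity, normalised by the speed scale v0."""
    velocities = np.atleast_2d(velocities)
    if len(velocities) == 0:
        raise ValueError("group_speed of an empty group is undefined")
    return float(np.linalg.norm(velocities.mean(axis=0)) / v0)


def dbscan_periodic(positions: np.ndarray, eps: float, min_pts: int,
                    L: float) -> np.ndarray:
    """Deterministic DBSCAN with minimum-image distances.

    Classic DBSCAN semantics (a point's eps-neighbourhood includes itself, as
    in scikit-learn's ``min_samples``). Clusters are grown from core points in
    ascending id order; border points join the first cluster that reaches
    them, which makes the labelling permutation-stable for sorted inputs.
    Returns labels with -1 for noise.
    """
    n = len(positions)
    labels = np.full(n, NOISE, dtype=np.int64)
    if n == 0:
        return labels
    d = pairwise_displacements(positions, positions, L)
    dist = np.linalg.norm(d, axis=2)
    adj = dist <= eps
    counts = adj.sum(axis=1)  # includes self
    core = counts >= min_pts
    visited = np.zeros(n, dtype=bool)
    next_label = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        # breadth-first expansion of a new cluster from core point i
        labels[i] = next_label
        visited[i] = True
        queue = [i]
        while queue:
            p = queue.pop(0)
            for q in np.flatnonzero(adj[p]):
                if labels[q] == NOISE:
                    labels[q] = next_label
                if core[q] and not visited[q]:
                    visited[q] = True
                    queue.append(q)
        next_label += 1
    return labels


def default_min_pts(N: int) -> int:
    """Cluster membership threshold: 1% of the initial prey count, floored."""
    return max(1, int(np.floor(0.01 * N)))


@dataclass
class ClusterResult:
    """DBSCAN decomposition of the live prey."""

    labels: np.ndarray       # per live-prey labels, -1 = noise
    sizes: np.ndarray        # member count per cluster, descending
    l_c: float               # largest-cluster fraction of the initial N

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))


def cluster_prey(live_positions: np.ndarray, r_alg: float, min_pts: int,
                 L: float, N: int) -> ClusterResult:
    """Group live prey with DBSCAN(eps=r_alg, min_pts) on the torus.

    ``l_c`` is the largest cluster's size normalised by the *initial* prey
    count N (0 when everything is noise or no prey remain alive).
    """
    labels = dbscan_periodic(np.atleast_2d(live_positions)
                             if len(live_positions) else np.empty((0, 2)),
                             r_alg, min_pts, L)
    if labels.size and (labels >= 0).any():
        sizes = np.sort(np.bincount(labels[labels >= 0]))[::-1]
    else:
        sizes = np.array([], dtype=np.int64)
    l_c = float(sizes[0] / N) if len(sizes) else 0.0
    return ClusterResult(labels=labels, sizes=sizes, l_c=l_c)


def group_size_distribution(cluster_sizes: list[np.ndarray] | np.ndarray,
                            N: int, bins: np.ndarray | int = 20
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram p(phi) of cluster sizes phi = size/N pooled over realisations.

    Noise points never appear (they carry no cluster). Returns (bin_edges,
    probabilities) with the probabilities summing to 1 over all pooled
    clusters.
    """
    if isinstance(cluster_sizes, np.ndarray):
        pooled = cluster_sizes.astype(float)
    else:
        pooled = np.concatenate([np.asarray(s, dtype=float) for s in cluster_sizes]) \
            if cluster_sizes else np.array([])
    if pooled.size == 0:
        raise ValueError("no clusters to histogram")
    phi = pooled / N
    if np.isscalar(bins):
        edges = np.linspace(0.0, 1.0, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(np.clip(phi, edges[0], edges[-1]), bins=edges)
    return edges, counts / counts.sum()


def live_fraction(mu: np.ndarray) -> float:
    """Fraction N_l of the initial prey still alive."""
    mu = np.asarray(mu)
    return float(mu.sum() / len(mu))


def captured_fraction(mu: np.ndarray) -> float:
    """Fraction N_d = 1 - N_l of the initial prey captured."""
    return 1.0 - live_fraction(mu)


def capture_rate(tau: np.ndarray, n_l: np.ndarray, window: int = 5
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed prey capture rate alpha_K.

    Consecutive-pair slopes of N_l (reported as positive decay magnitudes)
    averaged with a centred moving window; edge samples use truncated
    windows. Returns (midpoint times, alpha_K).
    """
    tau = np.asarray(tau, dtype=float)
    n_l = np.asarray(n_l, dtype=float)
    if len(tau) < 2:
        raise ValueError("capture_rate needs at least two samples")
    slopes = -(np.diff(n_l) / np.diff(tau))
    mid = 0.5 * (tau[:-1] + tau[1:])
    if window <= 1:
        return mid, slopes
    half = window // 2
    out = np.empty_like(slopes)
    for k in range(len(slopes)):
        lo = max(0, k - half)
        hi = min(len(slopes), k + half + 1)
        out[k] = slopes[lo:hi].mean()
    return mid, out


def events_to_frame(events) -> pd.DataFrame:
    """Flatten a list of PursuitEvent records into a DataFrame."""
    return pd.DataFrame([{
        "t_start": e.t_start, "t_end": e.t_end, "predator_id": e.predator_id,
        "target_id": e.target_id, "phi": e.target_group_size_phi,
        "outcome": e.outcome, "strategy_mode": e.strategy_mode,
        "reason": e.reason,
    } for e in events])


def pursuit_outcome_stats(events: pd.DataFrame | list,
                          phi_bins: np.ndarray | int = 10) -> pd.DataFrame:
    """Fractions f_eps of all pursuits by outcome and target group size.

    Rows are ("success", "failure"), columns are phi bins; the table sums
    to 1 over all pursuits pooled across realisations.
    """
    if not isinstance(events, pd.DataFrame):
        events = events_to_frame(events)
    if len(events) == 0:
        raise ValueError("empty pursuit event log")
    if np.isscalar(phi_bins):
        edges = np.linspace(0.0, 1.0, int(phi_bins) + 1)
    else:
        edges = np.asarray(phi_bins, dtype=float)
    total = len(events)
    rows = {}
    for outcome in ("success", "failure"):
        phi = events.loc[events["outcome"] == outcome, "phi"].to_numpy(float)
        counts, _ = np.histogram(np.clip(phi, edges[0], edges[-1]), bins=edges)
        rows[outcome] = counts / total
    cols = [f"({edges[i]:.3g},{edges[i + 1]:.3g}]" for i in range(len(edges) - 1)]
    return pd.DataFrame(rows, index=cols).T


def first_passage_times(tau: np.ndarray, n_d: np.ndarray,
                        grid: np.ndarray) -> np.ndarray:
    """First time each captured-fraction level in ``grid`` is reached.

    Linearly interpolated between the bracketing samples of the N_d series;
    nan for levels never reached.
    """
    tau = np.asarray(tau, dtype=float)
    n_d = np.asarray(n_d, dtype=float)
    out = np.full(len(grid), np.nan)
    for g, level in enumerate(np.asarray(grid, dtype=float)):
        idx = np.flatnonzero(n_d >= level)
        if len(idx) == 0:
            continue
        k = idx[0]
        if k == 0 or n_d[k] == n_d[k - 1]:
            out[g] = tau[k]
        else:
            frac = (level - n_d[k - 1]) / (n_d[k] - n_d[k - 1])
            out[g] = tau[k - 1] + frac * (tau[k] - tau[k - 1])
    return out


def kappa(fpt_single: np.ndarray, fpt_duo: np.ndarray) -> np.ndarray:
    """Non-additivity ratio kappa(N_d).

    Ratio of the realisation-mean first-passage time of a lone predator to
    that of a non-coordinating duo, per captured-fraction level. A value
    above 2 means two predators are more than twice as fast per capita.
    """
    fpt_single = np.atleast_2d(np.asarray(fpt_single, dtype=float))
    fpt_duo = np.atleast_2d(np.asarray(fpt_duo, dtype=float))
    if fpt_single.size == 0 or fpt_duo.size == 0:
        raise ValueError("both ensembles must be nonempty")
    mean_single = np.nanmean(fpt_single, axis=0)
    mean_duo = np.nanmean(fpt_duo, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mean_single / mean_duo


@dataclass
class MetricRecorder:
    """Observer sampling Psi_L, N_l, l_c and group speed during a run.

    Attach through :func:`preyflock.engine.run` with a sampling stride; one
    clustering pass per sample.
    """

    r_alg: float
    L: float
    v0: float
    min_pts: int
    N: int
    tau: list = field(default_factory=list)
    psi_l: list = field(default_factory=list)
    n_l: list = field(default_factory=list)
    l_c: list = field(default_factory=list)
    n_clusters: list = field(default_factory=list)
    v_f: list = field(default_factory=list)

    def __call__(self, world, step_index: int) -> None:
        live = world.mu.astype(bool)
        x = world.prey_x[live]
        v = world.prey_v[live]
        self.tau.append(world.t)
        self.n_l.append(live_fraction(world.mu))
        self.psi_l.append(local_order(v, x, self.r_alg, self.L)
                          if live.sum() >= 2 else float("nan"))
        res = cluster_prey(x, self.r_alg, self.min_pts, self.L, self.N)
        self.l_c.append(res.l_c)
        self.n_clusters.append(res.n_clusters)
        if res.n_clusters and (res.labels >= 0).any():
            largest = np.argmax(np.bincount(res.labels[res.labels >= 0]))
            self.v_f.append(group_speed(v[res.labels == largest], self.v0))
        else:
            self.v_f.append(float("nan"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tau": self.tau, "Psi_L": self.psi_l, "N_l": self.n_l,
            "l_c": self.l_c, "n_clusters": self.n_clusters, "v_f": self.v_f,
        })
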