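"""World state containers: prey and predator arrays plus the event log.

The engine works on struct-of-arrays storage (positions, velocities, flags)
for speed; the per-agent dataclass views exist for inspection and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "CRUISING", "ESCAPE",
    "PURSUIT", "SATISFIED", "REFOCUS", "SEARCH",
    "PREY_MODE_NAMES", "PREDATOR_MODE_NAMES",
    "PursuitEvent", "PreyView", "PredatorView", "WorldState",
]

# prey behavioural modes
CRUISING, ESCAPE = 0, 1
PREY_MODE_NAMES = {CRUISING: "cruising", ESCAPE: "escape"}

# predator hunting-cycle modes; SEARCH is the detection stage between cycles
PURSUIT, SATISFIED, REFOCUS, SEARCH = 0, 1, 2, 3
PREDATOR_MODE_NAMES = {PURSUIT: "pursuit", SATISFIED: "satisfied",
                       REFOCUS: "refocus", SEARCH: "search"}

NO_TARGET = -1


@dataclass
class PursuitEvent:
    """One completed hunting cycle of one predator."""

    t_start: float
    t_end: float
    predator_id: int
    target_id: int
    target_group_size_phi: float  # cluster size of the target at selection, / N
    outcome: str                  # "success" | "failure"
    strategy_mode: str            # "NP" | "MCP"
    reason: str = ""              # e.g. "timeout", "target_lost"


@dataclass
class PreyView:
    id: int
    x: np.ndarray
    v: np.ndarray
    mu: int
    mode: str


@dataclass
class PredatorView:
    id: int
    x: np.ndarray
    v: np.ndarray
    mode: str
    target_id: int | None
    timer: float
    strategy_mode_this_cycle: str | None


@dataclass
class WorldState:
    """Full simulation state at one instant."""

    t: float
    prey_x: np.ndarray        # (N, 2) positions in [0, L)
    prey_v: np.ndarray        # (N, 2)
    prey_heading: np.ndarray  # (N, 2) unit last-nonzero-velocity direction
    mu: np.ndarray            # (N,) alive flag, int8
    prey_mode: np.ndarray     # (N,) CRUISING/ESCAPE, int8
    escape_dir: np.ndarray    # (N, 2) unit flee direction (valid when ESCAPE)
    pred_x: np.ndarray        # (N_p, 2)
    pred_v: np.ndarray        # (N_p, 2)
    pred_heading: np.ndarray  # (N_p, 2)
    pred_mode: np.ndarray     # (N_p,) int8
    pred_target: np.ndarray   # (N_p,) prey id or NO_TARGET
    pred_timer: np.ndarray    # (N_p,) remaining mode time
    pred_strategy_mode: np.ndarray  # (N_p,) 0=NP, 1=MCP for current cycle
    events: list[PursuitEvent] = field(default_factory=list)
    open_pursuit_start: np.ndarray | None = None  # (N_p,) t at pursuit entry
    open_pursuit_phi: np.ndarray | None = None    # (N_p,) phi at selection

    # cached accelerations for the velocity-Verlet step
    prey_acc: np.ndarray | None = None
    pred_acc: np.ndarray | None = None

    @property
    def n_prey(self) -> int:
        return len(self.prey_x)

    @property
    def n_predators(self) -> int:
        return len(self.pred_x)

    def n_live(self) -> int:
        return int(self.mu.sum())

    def prey_view(self, i: int) -> PreyView:
        return PreyView(i, self.prey_x[i].copy(), self.prey_v[i].copy(),
                        int(self.mu[i]), PREY_MODE_NAMES[int(self.prey_mode[i])])

    def predator_view(self, k: int) -> PredatorView:
        tgt = int(self.pred_target[k])
        return PredatorView(
            k, self.pred_x[k].copy(), self.pred_v[k].copy(),
            PREDATOR_MODE_NAMES[int(self.pred_mode[k])],
            None if tgt == NO_TARGET else tgt,
            float(self.pred_timer[k]),
            ("NP", "MCP")[int(self.pred_strategy_mode[k])],
        )

    def copy(self) -> "WorldState":
        return WorldState(
            t=self.t,
            prey_x=self.prey_x.copy(), prey_v=self.prey_v.copy(),
            prey_heading=self.prey_heading.copy(), mu=self.mu.copy(),
            prey_mode=self.prey_mode.copy(), escape_dir=self.escape_dir.copy(),
            pred_x=self.pred_x.copy(), pred_v=self.pred_v.copy(),
            pred_heading=self.pred_heading.copy(), pred_mode=self.pred_mode.copy(),
            pred_target=self.pred_target.copy(), pred_timer=self.pred_timer.copy(),
            pred_strategy_mode=self.pred_strategy_mode.copy(),
            events=list(self.events),
            open_pursuit_start=None if self.open_pursuit_start is None
            else self.open_pursuit_start.copy(),
            open_pursuit_phi=None if self.open_pursuit_phi is None
            else self.open_pursuit_phi.copy(),
            prey_acc=None if self.prey_acc is None else self.prey_acc.copy(),
            pred_acc=None if self.pred_acc is None else self.pred_acc.copy(),
        )


def empty_world(params: ModelParams) -> WorldState:
    """Allocate a zeroed world of the configured sizes."""
    n, npd = params.N, params.N_p
    return WorldState(
        t=0.0,
        prey_x=np.zeros((n, 2)), prey_v=np.zeros((n, 2)),
        prey_heading=np.tile([1.0, 0.0], (n, 1)),
        mu=np.ones(n, dtype=np.int8),
        prey_mode=np.full(n, CRUISING, dtype=np.int8),
        escape_dir=np.zeros((n, 2)),
        pred_x=np.zeros((npd, 2)), pred_v=np.zeros((npd, 2)),
        pred_heading=np.tile([1.0, 0.0], (npd, 1)),
        pred_mode=np.full(npd, SEARCH, dtype=np.int8),
        pred_target=np.full(npd, NO_TARGET, dtype=np.int64),
        pred_timer=np.zeros(npd),
        pred_strategy_mode=np.zeros(npd, dtype=np.int8),
        open_pursuit_start=np.zeros(npd),
        open_pursuit_phi=np.zeros(npd),
    )
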