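"""Grid-world state containers for the foraging ABM.

The world is a ``height x width`` grid whose columns wrap (torus
left-right).  Hunters bounce off the top and bottom edges; prey march one
row per tick toward the bottom edge, which absorbs them.  Agent state is
held in flat structure-of-arrays form (one slot per agent ever born; dead
slots are never reused), which the per-tick kernels operate on directly.
Dataclass views (:class:`AgentState`, :class:`PairState`,
:class:`PreyItem`) are provided for inspection and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from staghunt.core import EnergyParams, PayoffScheme, Phenotype
from staghunt.rng import RngStreams

__all__ = [
    "WorldConfig",
    "World",
    "AgentState",
    "PairState",
    "PreyItem",
    "COUNTER_NAMES",
    "EV_BIRTH",
    "EV_DEATH",
    "EV_CAPTURE",
    "EV_PAIR_FORM",
    "EV_PAIR_DISSOLVE",
    "EV_QUERY",
    "EVENT_NAMES",
]

# Event type codes shared with the kernels.
EV_BIRTH = 0          # a = child, b = parent
EV_DEATH = 1          # a = agent
EV_CAPTURE = 2        # a = agent, b = prey kind (0 stag / 1 hare), amount = energy credited
EV_PAIR_FORM = 3      # a, b = members; amount = 0.0 for SS, 1.0 for SH
EV_PAIR_DISSOLVE = 4  # a, b = members
EV_QUERY = 5          # a = stag-hunter who walked away, b = hare-hunter queried

EVENT_NAMES = {
    EV_BIRTH: "birth",
    EV_DEATH: "death",
    EV_CAPTURE: "capture",
    EV_PAIR_FORM: "pair_form",
    EV_PAIR_DISSOLVE: "pair_dissolve",
    EV_QUERY: "query",
}

COUNTER_NAMES = (
    "captures_stag",
    "captures_hare",
    "deaths",
    "births",
    "pairs_ss_formed",
    "pairs_sh_formed",
    "pair_dissolutions",
    "queries",
    "hare_hare_meetings",
    "prey_exited_stag",
    "prey_exited_hare",
)


@dataclass(frozen=True)
class WorldConfig:
    """Full parameterisation of one simulation run.

    Defaults are the reference conditions: 100 hunters of each phenotype,
    100 prey of each kind, unit prey inflow, natal energy 20 with a
    storage cap of 20, reproduction every 1000 ticks.
    """

    width: int = 50
    height: int = 50
    n_stag_hunters: int = 100
    n_hare_hunters: int = 100
    n_stags: int = 100
    n_hares: int = 100
    prey_intro_rate: float = 1.0
    energy: EnergyParams = field(default_factory=EnergyParams)
    payoff: PayoffScheme = field(default_factory=PayoffScheme)
    reproduction_interval: int = 1000
    communication: bool = False
    t_end: int = 50_000
    #: Whether a stag capture ends the SS partnership.  The game's rules
    #: state an end condition only for Stag-Hare pairs (hare catch or
    #: death), so by default SS pairs persist and keep hunting together;
    #: setting this True matches the ODE model's resolve-on-catch
    #: assumption instead.
    ss_pairs_dissolve_on_capture: bool = False

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError(
                f"grid must be at least 2x2, got {self.height}x{self.width}"
            )
        for name in ("n_stag_hunters", "n_hare_hunters", "n_stags", "n_hares"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.prey_intro_rate < 0:
            raise ValueError(f"prey_intro_rate must be >= 0, got {self.prey_intro_rate}")
        if self.reproduction_interval <= 0:
            raise ValueError(
                f"reproduction_interval must be > 0, got {self.reproduction_interval}"
            )
        if self.t_end < 0:
            raise ValueError(f"t_end must be >= 0, got {self.t_end}")


@dataclass(frozen=True)
class AgentState:
    """Read-only view of one agent slot."""

    id: int
    phenotype: Phenotype
    energy: float
    position: tuple[int, int]
    pair_id: int | None
    birth_tick: int
    last_reproduction_tick: int
    alive: bool


@dataclass(frozen=True)
class PairState:
    """Read-only view of one standing pair (identified by its lead member)."""

    pair_id: int
    kind: str                   # "SS" or "SH"
    members: tuple[int, int]


@dataclass(frozen=True)
class PreyItem:
    """Read-only view of one prey animal on the grid."""

    id: int
    kind: str                   # "stag" or "hare"
    position: tuple[int, int]


class World:
    """Mutable simulation state in structure-of-arrays form."""

    def __init__(self, config: WorldConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        self.rng = RngStreams(seed)
        self.tick = 0

        n0 = config.n_stag_hunters + config.n_hare_hunters
        cap = max(2 * n0 + 64, 256)
        self._cap = cap
        self.n_slots = 0  # slots in use; also the next agent id

        self.alive = np.zeros(cap, dtype=np.bool_)
        self.phen = np.zeros(cap, dtype=np.int8)
        self.energy = np.zeros(cap, dtype=np.float64)
        self.row = np.zeros(cap, dtype=np.int32)
        self.col = np.zeros(cap, dtype=np.int32)
        self.pair_with = np.full(cap, -1, dtype=np.int32)
        self.birth_tick = np.zeros(cap, dtype=np.int64)
        self.last_repro = np.zeros(cap, dtype=np.int64)

        # prey: compact arrays rebuilt each tick
        self.prey_kind = np.zeros(0, dtype=np.int8)   # 0 stag, 1 hare
        self.prey_row = np.zeros(0, dtype=np.int32)
        self.prey_col = np.zeros(0, dtype=np.int32)
        self.prey_id = np.zeros(0, dtype=np.int64)
        self.next_prey_id = 0
        self.prey_acc_stag = 0.0
        self.prey_acc_hare = 0.0

        self.counters = np.zeros(len(COUNTER_NAMES), dtype=np.int64)

        self.log_events = False
        self._events: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []

        # scratch buffers for the kernels (occupancy grid)
        self._head = np.empty(config.height * config.width, dtype=np.int32)

    # -- slot management ---------------------------------------------------

    def _grow(self, extra: int) -> None:
        need = self.n_slots + extra
        if need <= self._cap:
            return
        new_cap = max(need, 2 * self._cap)
        for name in ("alive", "phen", "energy", "row", "col", "pair_with",
                     "birth_tick", "last_repro"):
            old = getattr(self, name)
            arr = np.zeros(new_cap, dtype=old.dtype)
            if name == "pair_with":
                arr[:] = -1
            arr[: self._cap] = old
            setattr(self, name, arr)
        self._cap = new_cap

    def spawn_agents(
        self,
        phen: np.ndarray,
        rows: np.ndarray,
        cols: np.ndarray,
        energy: float,
        tick: int,
    ) -> np.ndarray:
        """Append new agents; returns their slot ids."""
        k = len(phen)
        self._grow(k)
        sl = np.arange(self.n_slots, self.n_slots + k)
        self.alive[sl] = True
        self.phen[sl] = phen
        self.energy[sl] = energy
        self.row[sl] = rows
        self.col[sl] = cols
        self.pair_with[sl] = -1
        self.birth_tick[sl] = tick
        self.last_repro[sl] = tick
        self.n_slots += k
        return sl

    # -- event log ---------------------------------------------------------

    def record_events(
        self,
        etype: np.ndarray,
        a: np.ndarray,
        b: np.ndarray,
        amount: np.ndarray,
    ) -> None:
        if not self.log_events or len(etype) == 0:
            return
        tick = np.full(len(etype), self.tick, dtype=np.int64)
        self._events.append(
            (tick, np.asarray(etype, dtype=np.int16), np.asarray(a, dtype=np.int32),
             np.asarray(b, dtype=np.int32), np.asarray(amount, dtype=np.float64))
        )

    def event_log_frame(self) -> "pd.DataFrame":
        """All logged events as a tidy frame (tick, event, agent, other, amount)."""
        import pandas as pd

        if not self._events:
            return pd.DataFrame(
                columns=["tick", "event", "agent", "other", "amount"]
            ).astype({"tick": np.int64, "agent": np.int32, "other": np.int32,
                      "amount": np.float64})
        tick = np.concatenate([e[0] for e in self._events])
        et = np.concatenate([e[1] for e in self._events])
        a = np.concatenate([e[2] for e in self._events])
        b = np.concatenate([e[3] for e in self._events])
        amt = np.concatenate([e[4] for e in self._events])
        return pd.DataFrame(
            {"tick": tick, "event": [EVENT_NAMES[int(t)] for t in et],
             "agent": a, "other": b, "amount": amt}
        )

    # -- views -------------------------------------------------------------

    def agent(self, i: int) -> AgentState:
        if not 0 <= i < self.n_slots:
            raise IndexError(f"no agent slot {i}")
        paired = int(self.pair_with[i])
        return AgentState(
            id=i,
            phenotype=Phenotype(int(self.phen[i])),
            energy=float(self.energy[i]),
            position=(int(self.row[i]), int(self.col[i])),
            pair_id=None if paired < 0 else min(i, paired),
            birth_tick=int(self.birth_tick[i]),
            last_reproduction_tick=int(self.last_repro[i]),
            alive=bool(self.alive[i]),
        )

    def pairs(self) -> Iterator[PairState]:
        for i in range(self.n_slots):
            j = int(self.pair_with[i])
            if self.alive[i] and 0 <= i < j:
                kind = "SS" if (self.phen[i] == 0 and self.phen[j] == 0) else "SH"
                yield PairState(pair_id=i, kind=kind, members=(i, j))

    def prey_items(self) -> Iterator[PreyItem]:
        for t in range(len(self.prey_kind)):
            yield PreyItem(
                id=int(self.prey_id[t]),
                kind="stag" if self.prey_kind[t] == 0 else "hare",
                position=(int(self.prey_row[t]), int(self.prey_col[t])),
            )

    # -- counts ------------------------------------------------------------

    def population_counts(self) -> dict[str, int]:
        n = self.n_slots
        alive, phen, pw = self.alive[:n], self.phen[:n], self.pair_with[:n]
        stag_h = int(np.count_nonzero(alive & (phen == 0)))
        hare_h = int(np.count_nonzero(alive & (phen == 1)))
        paired = np.nonzero(alive & (pw >= 0))[0]
        ss = int(np.count_nonzero(
            (phen[paired] == 0) & (self.phen[pw[paired]] == 0))) // 2
        sh = (len(paired) // 2) - ss
        return {
            "stag_hunters": stag_h,
            "hare_hunters": hare_h,
            "stags": int(np.count_nonzero(self.prey_kind == 0)),
            "hares": int(np.count_nonzero(self.prey_kind == 1)),
            "pairs_ss": ss,
            "pairs_sh": sh,
        }

    def counter(self, name: str) -> int:
        return int(self.counters[COUNTER_NAMES.index(name)])
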