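"""Per-tick operations and the simulation driver for the grid ABM.

A tick applies, in fixed order: prey advance -> agent movement -> pair
formation -> capture resolution -> metabolism & mortality ->
reproduction.  Each phase draws only from its own named random stream,
so identical ``(config, seed)`` replays are bit-identical and any phase
can be exercised in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from staghunt import _kernels
from staghunt.core import STARVATION_EPS
from staghunt.world import (
    COUNTER_NAMES,
    EV_BIRTH,
    EV_DEATH,
    World,
    WorldConfig,
)

__all__ = [
    "init_world",
    "advance_prey",
    "move_agents",
    "form_pairs",
    "resolve_captures",
    "apply_metabolism_and_mortality",
    "reproduce",
    "step",
    "run_simulation",
    "survival_outcome",
    "SimulationResult",
    "replay_energy_audit",
]

# Moore neighbourhood directions (8 moves, no standing still)
_DR = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int32)
_DC = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int32)

_C = {name: i for i, name in enumerate(COUNTER_NAMES)}


def _reflect_rows(r: np.ndarray, height: int) -> np.ndarray:
    r = np.where(r < 0, -r, r)
    return np.where(r >= height, 2 * (height - 1) - r, r)


def init_world(config: WorldConfig, seed: int) -> World:
    """Populate a fresh grid: hunters at uniform cells with natal energy
    ``E_s``, initial prey at uniform cells, tick 0."""
    w = World(config, seed)
    g = w.rng["movement"]
    n0 = config.n_stag_hunters + config.n_hare_hunters
    phen = np.concatenate(
        [np.zeros(config.n_stag_hunters, dtype=np.int8),
         np.ones(config.n_hare_hunters, dtype=np.int8)]
    )
    rows = g.integers(0, config.height, n0).astype(np.int32)
    cols = g.integers(0, config.width, n0).astype(np.int32)
    w.spawn_agents(phen, rows, cols, config.energy.e_start, tick=0)
    w.counters[_C["births"]] = 0  # natal placement is not a birth event

    gp = w.rng["prey"]
    n_prey = config.n_stags + config.n_hares
    w.prey_kind = np.concatenate(
        [np.zeros(config.n_stags, dtype=np.int8),
         np.ones(config.n_hares, dtype=np.int8)]
    )
    w.prey_row = gp.integers(0, config.height, n_prey).astype(np.int32)
    w.prey_col = gp.integers(0, config.width, n_prey).astype(np.int32)
    w.prey_id = np.arange(n_prey, dtype=np.int64)
    w.next_prey_id = n_prey
    return w


def advance_prey(w: World) -> None:
    """March prey one row toward the absorbing bottom edge and deposit the
    per-tick inflow ``F`` of each kind at random top-row columns
    (fractional rates accumulate)."""
    cfg = w.config
    if len(w.prey_kind):
        w.prey_row += 1
        exited = w.prey_row >= cfg.height
        if exited.any():
            w.counters[_C["prey_exited_stag"]] += int(
                np.count_nonzero(exited & (w.prey_kind == 0)))
            w.counters[_C["prey_exited_hare"]] += int(
                np.count_nonzero(exited & (w.prey_kind == 1)))
            keep = ~exited
            w.prey_kind = w.prey_kind[keep]
            w.prey_row = w.prey_row[keep]
            w.prey_col = w.prey_col[keep]
            w.prey_id = w.prey_id[keep]

    w.prey_acc_stag += cfg.prey_intro_rate
    w.prey_acc_hare += cfg.prey_intro_rate
    k_s = int(w.prey_acc_stag)
    k_h = int(w.prey_acc_hare)
    w.prey_acc_stag -= k_s
    w.prey_acc_hare -= k_h
    k = k_s + k_h
    if k:
        g = w.rng["prey"]
        cols = g.integers(0, cfg.width, k).astype(np.int32)
        kind = np.concatenate([np.zeros(k_s, dtype=np.int8),
                               np.ones(k_h, dtype=np.int8)])
        w.prey_kind = np.concatenate([w.prey_kind, kind])
        w.prey_row = np.concatenate([w.prey_row, np.zeros(k, dtype=np.int32)])
        w.prey_col = np.concatenate([w.prey_col, cols])
        w.prey_id = np.concatenate(
            [w.prey_id, np.arange(w.next_prey_id, w.next_prey_id + k, dtype=np.int64)])
        w.next_prey_id += k


def move_agents(w: World) -> None:
    """Random Moore-step for every unpaired agent; each pair moves as a
    unit (one shared direction).  Columns wrap, rows reflect."""
    n = w.n_slots
    idx = np.nonzero(w.alive[:n])[0]
    if len(idx) == 0:
        return
    g = w.rng["movement"]
    d = g.integers(0, 8, len(idx))
    dr = _DR[d].copy()
    dc = _DC[d].copy()
    pw = w.pair_with[idx]
    follower = (pw >= 0) & (pw < idx)
    if follower.any():
        pos = np.empty(n, dtype=np.int64)
        pos[idx] = np.arange(len(idx))
        lead = pos[pw[follower]]
        dr[follower] = dr[lead]
        dc[follower] = dc[lead]
    w.row[idx] = _reflect_rows(w.row[idx] + dr, w.config.height).astype(np.int32)
    w.col[idx] = (w.col[idx] + dc) % w.config.width


def form_pairs(w: World) -> None:
    """Let unpaired agents with an unpaired Moore-neighbour interact, in
    random order with uniform tie-breaks (see the kernel docstring for
    the phenotype/communication outcome table)."""
    n = w.n_slots
    unpaired = np.nonzero(w.alive[:n] & (w.pair_with[:n] < 0))[0]
    m = len(unpaired)
    if m < 2:
        return
    g = w.rng["pairing"]
    perm = g.permutation(m)
    u = g.random(m)
    ev_type = np.empty(m, dtype=np.int16)
    ev_a = np.empty(m, dtype=np.int32)
    ev_b = np.empty(m, dtype=np.int32)
    ev_amount = np.empty(m, dtype=np.float64)
    n_ev = _kernels.form_pairs_kernel(
        unpaired, perm, u,
        w.row, w.col, w.phen, w.pair_with,
        w._head, np.empty(m, dtype=np.int32),
        w.config.height, w.config.width, w.config.communication,
        ev_type, ev_a, ev_b, ev_amount, w.counters,
    )
    if n_ev:
        w.record_events(ev_type[:n_ev], ev_a[:n_ev], ev_b[:n_ev], ev_amount[:n_ev])


def resolve_captures(w: World) -> None:
    """Hunting units (SS pairs and hare-hunters) take adjacent prey in
    random order; captured prey are removed at once.  Solo stag-hunters
    and the stag member of an SH pair never capture."""
    n = w.n_slots
    n_prey = len(w.prey_kind)
    if n_prey == 0:
        return
    alive = w.alive[:n]
    phen = w.phen[:n]
    pw = w.pair_with[:n]
    paired_stag = np.nonzero(alive & (phen == 0) & (pw >= 0))[0]
    leaders = paired_stag[
        (pw[paired_stag] > paired_stag) & (w.phen[pw[paired_stag]] == 0)
    ]
    hare_units = np.nonzero(alive & (phen == 1))[0]
    n_units = len(leaders) + len(hare_units)
    if n_units == 0:
        return
    unit_idx = np.concatenate([leaders, hare_units])
    unit_type = np.concatenate(
        [np.zeros(len(leaders), dtype=np.int8), np.ones(len(hare_units), dtype=np.int8)]
    )
    g = w.rng["capture"]
    perm = g.permutation(n_units)
    u = g.random(n_units)
    prey_alive = np.ones(n_prey, dtype=np.bool_)
    cap = 3 * n_units + 4
    ev_type = np.empty(cap, dtype=np.int16)
    ev_a = np.empty(cap, dtype=np.int32)
    ev_b = np.empty(cap, dtype=np.int32)
    ev_amount = np.empty(cap, dtype=np.float64)
    n_ev = _kernels.resolve_captures_kernel(
        unit_idx, unit_type, perm, u,
        w.row, w.col, w.phen, w.pair_with, w.energy,
        w.prey_kind, w.prey_row, w.prey_col, prey_alive,
        w._head, np.empty(n_prey, dtype=np.int32),
        w.config.height, w.config.width,
        w.config.payoff.stag_reward, w.config.payoff.hare_reward,
        w.config.energy.e_max, w.config.ss_pairs_dissolve_on_capture,
        ev_type, ev_a, ev_b, ev_amount, w.counters,
    )
    if n_ev:
        w.record_events(ev_type[:n_ev], ev_a[:n_ev], ev_b[:n_ev], ev_amount[:n_ev])
    if not prey_alive.all():
        w.prey_kind = w.prey_kind[prey_alive]
        w.prey_row = w.prey_row[prey_alive]
        w.prey_col = w.prey_col[prey_alive]
        w.prey_id = w.prey_id[prey_alive]


def apply_metabolism_and_mortality(w: World) -> None:
    """Charge every agent the per-tick cost ``E_r``; remove starved agents
    (energy below :data:`~staghunt.core.STARVATION_EPS`) synchronously and
    free their surviving partners, who keep their current energy."""
    n = w.n_slots
    alive = w.alive[:n]
    if not alive.any():
        return
    w.energy[:n][alive] -= w.config.energy.e_rate
    dead = np.nonzero(alive & (w.energy[:n] < STARVATION_EPS))[0]
    if len(dead) == 0:
        return
    partners = w.pair_with[dead]
    widowed = partners[partners >= 0]
    if len(widowed):
        both = np.isin(widowed, dead)
        w.counters[_C["pair_dissolutions"]] += int(both.sum()) // 2 + int((~both).sum())
        w.pair_with[widowed] = -1
    w.alive[dead] = False
    w.pair_with[dead] = -1
    w.counters[_C["deaths"]] += len(dead)
    w.record_events(
        np.full(len(dead), EV_DEATH, dtype=np.int16),
        dead.astype(np.int32),
        np.full(len(dead), -1, dtype=np.int32),
        np.zeros(len(dead)),
    )


def reproduce(w: World) -> None:
    """Every agent whose last reproduction lies >= R ticks back produces
    one unpaired offspring of its own phenotype with natal energy ``E_s``
    in a random Moore-neighbour cell."""
    n = w.n_slots
    cfg = w.config
    eligible = np.nonzero(
        w.alive[:n] & (w.tick - w.last_repro[:n] >= cfg.reproduction_interval)
    )[0]
    k = len(eligible)
    if k == 0:
        return
    g = w.rng["reproduction"]
    d = g.integers(0, 8, k)
    rows = _reflect_rows(w.row[eligible] + _DR[d], cfg.height).astype(np.int32)
    cols = ((w.col[eligible] + _DC[d]) % cfg.width).astype(np.int32)
    children = w.spawn_agents(
        w.phen[eligible].copy(), rows, cols, cfg.energy.e_start, tick=w.tick
    )
    w.last_repro[eligible] = w.tick
    w.counters[_C["births"]] += k
    w.record_events(
        np.full(k, EV_BIRTH, dtype=np.int16),
        children.astype(np.int32),
        eligible.astype(np.int32),
        np.zeros(k),
    )


def step(w: World) -> World:
    """Advance the world one tick (phases in fixed order); returns ``w``."""
    w.tick += 1
    advance_prey(w)
    move_agents(w)
    form_pairs(w)
    resolve_captures(w)
    apply_metabolism_and_mortality(w)
    reproduce(w)
    return w


def _tick_counts(w: World) -> tuple[int, int, int, int, int, int]:
    n = w.n_slots
    alive = w.alive[:n]
    phen = w.phen[:n]
    pw = w.pair_with[:n]
    stag_h = int(np.count_nonzero(alive & (phen == 0)))
    hare_h = int(np.count_nonzero(alive & (phen == 1)))
    paired = np.nonzero(alive & (pw >= 0))[0]
    ss = int(np.count_nonzero(
        (phen[paired] == 0) & (w.phen[pw[paired]] == 0))) // 2
    sh = len(paired) // 2 - ss
    stags = int(np.count_nonzero(w.prey_kind == 0))
    hares = len(w.prey_kind) - stags
    return stag_h, hare_h, stags, hares, ss, sh


@dataclass
class SimulationResult:
    """Outcome of one run: strided population series plus final summary."""

    config: WorldConfig
    seed: int
    ticks: np.ndarray
    stag_hunters: np.ndarray
    hare_hunters: np.ndarray
    stags: np.ndarray
    hares: np.ndarray
    pairs_ss: np.ndarray
    pairs_sh: np.ndarray
    completed_ticks: int
    counters: dict[str, int]
    world: World

    def counts_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {"tick": self.ticks,
             "stag_hunters": self.stag_hunters,
             "hare_hunters": self.hare_hunters,
             "stags": self.stags,
             "hares": self.hares,
             "pairs_ss": self.pairs_ss,
             "pairs_sh": self.pairs_sh}
        )

    @property
    def final_counts(self) -> dict[str, int]:
        return {
            "stag_hunters": int(self.stag_hunters[-1]),
            "hare_hunters": int(self.hare_hunters[-1]),
            "stags": int(self.stags[-1]),
            "hares": int(self.hares[-1]),
            "pairs_ss": int(self.pairs_ss[-1]),
            "pairs_sh": int(self.pairs_sh[-1]),
        }


def run_simulation(
    config: WorldConfig,
    seed: int,
    record_stride: int = 1,
    log_events: bool = False,
    world: Optional[World] = None,
) -> SimulationResult:
    """Run for ``t_end`` ticks or until both phenotypes are extinct.

    ``record_stride`` thins the stored population series (the final tick
    is always recorded); ``log_events`` keeps the full per-event audit
    trail (births, deaths, captures with credited energy, pair events).
    """
    if config.t_end < 1:
        raise ValueError("t_end must be >= 1 to run")
    w = world if world is not None else init_world(config, seed)
    w.log_events = log_events

    rec_t = [0]
    rec = [_tick_counts(w)]
    t = 0
    for t in range(1, config.t_end + 1):
        step(w)
        extinct = not w.alive[: w.n_slots].any()
        if t % record_stride == 0 or t == config.t_end or extinct:
            rec_t.append(t)
            rec.append(_tick_counts(w))
        if extinct:
            break
    arr = np.array(rec, dtype=np.int64).T
    return SimulationResult(
        config=config,
        seed=int(seed),
        ticks=np.array(rec_t, dtype=np.int64),
        stag_hunters=arr[0],
        hare_hunters=arr[1],
        stags=arr[2],
        hares=arr[3],
        pairs_ss=arr[4],
        pairs_sh=arr[5],
        completed_ticks=t,
        counters={name: int(v) for name, v in zip(COUNTER_NAMES, w.counters)},
        world=w,
    )


def survival_outcome(result: SimulationResult) -> tuple[int, int]:
    """Per-phenotype survival indicator: 1 iff at least one agent of that
    phenotype is alive at the end of the run (stag, hare)."""
    return (
        1 if result.stag_hunters[-1] > 0 else 0,
        1 if result.hare_hunters[-1] > 0 else 0,
    )


def replay_energy_audit(result: SimulationResult) -> None:
    """Replay the event log and assert it reproduces every agent exactly.

    For each agent: energy is re-derived as the natal deposit minus
    ``E_r`` per tick of age plus the logged capture credits (already
    capped at ``E_max`` when logged), applied in tick order with captures
    before decay — mirroring the phase order.  Alive agents must match
    their current energy bit-for-bit; dead agents must starve on exactly
    the tick of their logged death.  Raises ``AssertionError`` otherwise.
    """
    w = result.world
    ev = w.event_log_frame()
    if not w.log_events:
        raise ValueError("run_simulation(..., log_events=True) is required for audit")
    e_start = w.config.energy.e_start
    e_rate = w.config.energy.e_rate
    final_tick = result.completed_ticks

    captures: dict[int, list[tuple[int, float]]] = {}
    for row in ev[ev.event == "capture"].itertuples():
        captures.setdefault(int(row.agent), []).append((int(row.tick), float(row.amount)))
    death_tick = {
        int(r.agent): int(r.tick) for r in ev[ev.event == "death"].itertuples()
    }

    for a in range(w.n_slots):
        energy = e_start
        born = int(w.birth_tick[a])
        died_at = None
        caps = captures.get(a, [])
        ci = 0
        for t in range(born + 1, final_tick + 1):
            while ci < len(caps) and caps[ci][0] == t:
                energy += caps[ci][1]
                ci += 1
            energy -= e_rate
            if energy < STARVATION_EPS:
                died_at = t
                break
        if w.alive[a]:
            assert died_at is None, f"agent {a}: replay starves at {died_at} but is alive"
            assert energy == w.energy[a], (
                f"agent {a}: replayed energy {energy!r} != recorded {w.energy[a]!r}"
            )
        else:
            assert a in death_tick, f"agent {a} dead without a death event"
            assert died_at == death_tick[a], (
                f"agent {a}: replay death {died_at} != logged {death_tick[a]}"
            )
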