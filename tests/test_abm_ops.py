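"""Unit tests for the individual ABM tick phases."""

import numpy as np
import pytest

from staghunt import EnergyParams, PayoffScheme, WorldConfig
from staghunt.core import STARVATION_EPS
from staghunt.engine import (
    advance_prey,
    apply_metabolism_and_mortality,
    form_pairs,
    init_world,
    move_agents,
    reproduce,
    resolve_captures,
    step,
)


def bare_world(width=20, height=20, ratio=3.0, communication=False, **kw):
    """Empty world to be populated by hand."""
    cfg = WorldConfig(
        width=width, height=height,
        n_stag_hunters=0, n_hare_hunters=0, n_stags=0, n_hares=0,
        payoff=PayoffScheme(stag_ratio=ratio),
        communication=communication, t_end=10, **kw,
    )
    return init_world(cfg, 1)


def put_agents(w, spec):
    """spec: list of (phenotype 0/1, row, col); returns slot ids."""
    phen = np.array([s[0] for s in spec], dtype=np.int8)
    rows = np.array([s[1] for s in spec], dtype=np.int32)
    cols = np.array([s[2] for s in spec], dtype=np.int32)
    return w.spawn_agents(phen, rows, cols, w.config.energy.e_start, tick=0)


def put_prey(w, spec):
    """spec: list of (kind 0/1, row, col)."""
    w.prey_kind = np.array([s[0] for s in spec], dtype=np.int8)
    w.prey_row = np.array([s[1] for s in spec], dtype=np.int32)
    w.prey_col = np.array([s[2] for s in spec], dtype=np.int32)
    w.prey_id = np.arange(len(spec), dtype=np.int64)
    w.next_prey_id = len(spec)


# ------------------------------------------------------------- init_world

def test_init_world_reference_defaults():
    w = init_world(WorldConfig(), seed=1)
    counts = w.population_counts()
    assert counts["stag_hunters"] == 100 and counts["hare_hunters"] == 100
    assert counts["stags"] == 100 and counts["hares"] == 100
    assert np.all(w.energy[: w.n_slots] == 20.0)
    assert w.tick == 0


def test_init_world_empty_is_valid(empty_config):
    w = init_world(empty_config, seed=3)
    assert w.n_slots == 0
    assert w.population_counts()["stags"] == 0


def test_init_world_seeded_determinism(small_config):
    a = init_world(small_config, seed=11)
    b = init_world(small_config, seed=11)
    for name in ("row", "col", "phen", "energy"):
        assert np.array_equal(getattr(a, name), getattr(b, name))
    assert np.array_equal(a.prey_row, b.prey_row)


def test_too_small_grid_rejected():
    with pytest.raises(ValueError):
        WorldConfig(width=1, height=50)


# ------------------------------------------------------------ advance_prey

def test_prey_marches_down_and_exits():
    w = bare_world(prey_intro_rate=0.0)
    put_prey(w, [(0, 19, 4), (1, 10, 4)])  # one stag at the bottom row
    advance_prey(w)
    assert len(w.prey_kind) == 1  # bottom-row stag absorbed
    assert w.prey_row[0] == 11
    assert w.counter("prey_exited_stag") == 1


def test_prey_inflow_at_unit_rate():
    w = bare_world()  # F = 1.0
    for _ in range(10):
        advance_prey(w)
    assert np.count_nonzero(w.prey_kind == 0) == 10
    assert np.count_nonzero(w.prey_kind == 1) == 10
    assert np.all(w.prey_row[w.prey_row == 0] == 0) and w.prey_row.max() == 9


def test_fractional_inflow_accumulates():
    w = bare_world(prey_intro_rate=0.25)
    for _ in range(8):
        advance_prey(w)
    assert np.count_nonzero(w.prey_kind == 0) == 2  # floor(8 * 0.25)


def test_zero_inflow_monotone_nonincreasing():
    w = bare_world(prey_intro_rate=0.0)
    put_prey(w, [(0, 0, 0), (1, 5, 5)])
    sizes = []
    for _ in range(25):
        advance_prey(w)
        sizes.append(len(w.prey_kind))
    assert all(b <= a for a, b in zip(sizes, sizes[1:]))
    assert sizes[-1] == 0


# ------------------------------------------------------------- move_agents

def test_unpaired_move_is_one_moore_step():
    w = bare_world()
    put_agents(w, [(0, 10, 10)])
    for _ in range(20):
        r0, c0 = int(w.row[0]), int(w.col[0])
        move_agents(w)
        assert abs(int(w.row[0]) - r0) <= 1
        dc = abs(int(w.col[0]) - c0)
        assert min(dc, w.config.width - dc) <= 1
        assert (int(w.row[0]), int(w.col[0])) != (r0, c0)


def test_paired_agents_stay_adjacent():
    w = bare_world()
    i, j = put_agents(w, [(0, 0, 0), (0, 0, 1)])  # at the reflecting edge
    w.pair_with[i], w.pair_with[j] = j, i
    for _ in range(200):
        move_agents(w)
        dr = abs(int(w.row[i]) - int(w.row[j]))
        dc = abs(int(w.col[i]) - int(w.col[j]))
        dc = min(dc, w.config.width - dc)
        assert max(dr, dc) <= 1


def test_movement_is_seed_deterministic(small_config):
    a = init_world(small_config, seed=5)
    b = init_world(small_config, seed=5)
    for _ in range(30):
        move_agents(a)
        move_agents(b)
    assert np.array_equal(a.row, b.row) and np.array_equal(a.col, b.col)


# -------------------------------------------------------------- form_pairs

def test_adjacent_stag_hunters_pair_in_both_modes():
    for comm in (False, True):
        w = bare_world(communication=comm)
        i, j = put_agents(w, [(0, 5, 5), (0, 5, 6)])
        form_pairs(w)
        assert w.pair_with[i] == j and w.pair_with[j] == i
        assert w.counter("pairs_ss_formed") == 1


def test_mixed_encounter_without_communication_locks_sh_pair():
    w = bare_world(communication=False)
    i, j = put_agents(w, [(0, 5, 5), (1, 6, 6)])
    form_pairs(w)
    assert w.pair_with[i] == j
    assert w.counter("pairs_sh_formed") == 1


def test_mixed_encounter_with_communication_walks_away():
    w = bare_world(communication=True)
    i, j = put_agents(w, [(0, 5, 5), (1, 6, 6)])
    form_pairs(w)
    assert w.pair_with[i] == -1 and w.pair_with[j] == -1
    assert w.counter("queries") == 1


def test_hare_hunters_go_separate_ways():
    w = bare_world()
    i, j = put_agents(w, [(1, 5, 5), (1, 5, 6)])
    form_pairs(w)
    assert w.pair_with[i] == -1 and w.pair_with[j] == -1
    assert w.counter("hare_hare_meetings") == 1


def test_each_agent_interacts_at_most_once_per_tick():
    # three stag-hunters in a row can yield only one pair per tick
    w = bare_world()
    ids = put_agents(w, [(0, 5, 4), (0, 5, 5), (0, 5, 6)])
    form_pairs(w)
    assert np.count_nonzero(w.pair_with[ids] >= 0) == 2
    assert w.counter("pairs_ss_formed") == 1


def test_pairing_wraps_across_columns():
    w = bare_world()
    i, j = put_agents(w, [(0, 5, 0), (0, 5, 19)])  # adjacent on the torus
    form_pairs(w)
    assert w.pair_with[i] == j


# -------------------------------------------------------- resolve_captures

def test_ss_pair_captures_adjacent_stag():
    w = bare_world(ratio=3.0)
    i, j = put_agents(w, [(0, 10, 10), (0, 10, 11)])
    w.pair_with[i], w.pair_with[j] = j, i
    w.energy[[i, j]] = 10.0
    put_prey(w, [(0, 11, 11)])
    resolve_captures(w)
    assert w.energy[i] == 13.0 and w.energy[j] == 13.0
    assert len(w.prey_kind) == 0
    assert w.counter("captures_stag") == 1
    assert w.pair_with[i] == j  # partnership persists by default


def test_ss_pair_dissolves_on_capture_when_configured():
    w = bare_world(ratio=3.0, ss_pairs_dissolve_on_capture=True)
    i, j = put_agents(w, [(0, 10, 10), (0, 10, 11)])
    w.pair_with[i], w.pair_with[j] = j, i
    put_prey(w, [(0, 11, 11)])
    resolve_captures(w)
    assert w.pair_with[i] == -1 and w.pair_with[j] == -1
    assert w.counter("pair_dissolutions") == 1


def test_capture_reward_capped_at_e_max():
    w = bare_world(ratio=3.0)
    i, j = put_agents(w, [(0, 10, 10), (0, 10, 11)])
    w.pair_with[i], w.pair_with[j] = j, i
    w.energy[i] = 19.5
    w.energy[j] = 10.0
    put_prey(w, [(0, 10, 12)])
    resolve_captures(w)
    assert w.energy[i] == 20.0 and w.energy[j] == 13.0


def test_solo_stag_hunter_cannot_capture():
    w = bare_world(ratio=3.0)
    (i,) = put_agents(w, [(0, 10, 10)])
    w.energy[i] = 10.0
    put_prey(w, [(0, 10, 11)])
    resolve_captures(w)
    assert w.energy[i] == 10.0
    assert len(w.prey_kind) == 1


def test_sh_pair_hare_member_captures_and_pair_ends():
    w = bare_world()
    i, j = put_agents(w, [(0, 10, 10), (1, 10, 11)])
    w.pair_with[i], w.pair_with[j] = j, i
    w.energy[[i, j]] = 10.0
    put_prey(w, [(1, 11, 11)])
    resolve_captures(w)
    assert w.energy[j] == 11.0     # hare member eats
    assert w.energy[i] == 10.0     # locked stag member gets nothing
    assert w.pair_with[i] == -1 and w.pair_with[j] == -1
    assert w.counter("captures_hare") == 1


def test_sh_stag_member_cannot_take_stag_prey():
    w = bare_world(ratio=3.0)
    i, j = put_agents(w, [(0, 10, 10), (1, 10, 11)])
    w.pair_with[i], w.pair_with[j] = j, i
    w.energy[[i, j]] = 10.0
    put_prey(w, [(0, 10, 9)])
    resolve_captures(w)
    assert w.energy[i] == 10.0
    assert len(w.prey_kind) == 1


def test_single_prey_goes_to_exactly_one_unit():
    w = bare_world()
    ids = put_agents(w, [(1, 10, 10), (1, 10, 12)])
    w.energy[ids] = 10.0
    put_prey(w, [(1, 10, 11)])
    resolve_captures(w)
    assert sorted(w.energy[ids]) == [10.0, 11.0]
    assert w.counter("captures_hare") == 1


# --------------------------------------------- metabolism / mortality

def test_metabolism_decrements_and_starves():
    w = bare_world(energy=EnergyParams(20, 20, 0.02))
    i, j = put_agents(w, [(0, 5, 5), (1, 9, 9)])
    w.energy[i] = 0.01   # below one tick's upkeep
    apply_metabolism_and_mortality(w)
    assert not w.alive[i]
    assert w.alive[j] and w.energy[j] == pytest.approx(19.98)
    assert w.counter("deaths") == 1


def test_widowed_partner_decouples_and_keeps_energy():
    w = bare_world(energy=EnergyParams(20, 20, 0.02))
    i, j = put_agents(w, [(0, 5, 5), (1, 5, 6)])
    w.pair_with[i], w.pair_with[j] = j, i
    w.energy[j] = 0.001
    w.energy[i] = 15.0
    apply_metabolism_and_mortality(w)
    assert not w.alive[j] and w.alive[i]
    assert w.pair_with[i] == -1
    assert w.energy[i] == pytest.approx(14.98)


def test_zero_decay_never_starves():
    w = bare_world(energy=EnergyParams(20, 20, 0.0))
    put_agents(w, [(0, 5, 5), (1, 9, 9)])
    for _ in range(50):
        apply_metabolism_and_mortality(w)
    assert w.alive[:2].all()


# ----------------------------------------------------------- reproduce

def test_reproduction_at_interval():
    w = bare_world(reproduction_interval=200)
    (i,) = put_agents(w, [(0, 5, 5)])
    w.tick = 200
    reproduce(w)
    assert w.n_slots == 2
    child = 1
    assert w.phen[child] == w.phen[i]
    assert w.energy[child] == 20.0
    assert w.pair_with[child] == -1
    assert w.birth_tick[child] == 200
    assert w.last_repro[i] == 200
    # child within parent's Moore neighbourhood
    assert abs(int(w.row[child]) - 5) <= 1 and abs(int(w.col[child]) - 5) <= 1


def test_no_reproduction_before_interval():
    w = bare_world(reproduction_interval=200)
    put_agents(w, [(0, 5, 5)])
    w.tick = 199
    reproduce(w)
    assert w.n_slots == 1


def test_offspring_of_paired_parent_is_unpaired():
    w = bare_world(reproduction_interval=100)
    i, j = put_agents(w, [(0, 5, 5), (0, 5, 6)])
    w.pair_with[i], w.pair_with[j] = j, i
    w.tick = 100
    reproduce(w)
    assert w.n_slots == 4
    assert np.all(w.pair_with[2:4] == -1)
    assert w.pair_with[i] == j  # parents stay paired


# ---------------------------------------------------------------- step

def test_step_on_empty_world_advances_tick_and_prey(empty_config):
    w = init_world(empty_config, seed=2)
    step(w)
    assert w.tick == 1
    assert len(w.prey_kind) == 2  # one stag + one hare from the inflow
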