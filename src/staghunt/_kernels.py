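"""Numba kernels for the two sequential phases of a tick.

Pair formation and capture resolution process candidates one at a time in
a random order with uniform tie-breaking, which does not vectorise; both
are implemented here as jitted loops over the world's flat arrays.  The
kernels are RNG-free: permutations and uniform variates are drawn in the
caller from named streams and consumed sequentially, so runs are
bit-reproducible and independent of numba internals.

Grid conventions: columns wrap (torus), rows do not; "adjacent" means
Chebyshev distance <= 1 under the wrapped column metric, including
sharing a cell (multiple occupancy is allowed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# counter indices (must match world.COUNTER_NAMES order)
C_CAPTURES_STAG = 0
C_CAPTURES_HARE = 1
C_DEATHS = 2
C_BIRTHS = 3
C_PAIRS_SS = 4
C_PAIRS_SH = 5
C_DISSOLUTIONS = 6
C_QUERIES = 7
C_HH_MEET = 8

# event codes (must match world.EV_*)
EV_CAPTURE = 2
EV_PAIR_FORM = 3
EV_PAIR_DISSOLVE = 4
EV_QUERY = 5


@njit(cache=False)
def build_occupancy(head, nxt, rows, cols, members, W):
    """Chain ``members`` (array of indices into rows/cols) into per-cell
    linked lists: head[cell] -> position in ``members``; nxt chains."""
    head[:] = -1
    for t in range(len(members)):
        i = members[t]
        c = rows[i] * W + cols[i]
        nxt[t] = head[c]
        head[c] = t


@njit(cache=False)
def form_pairs_kernel(
    unpaired, perm, u,
    row, col, phen, pair_with,
    head, nxt, H, W, communication,
    ev_type, ev_a, ev_b, ev_amount, counters,
):
    """One pairing round.

    Unpaired agents are visited in the random order ``perm``; each still-
    available agent picks one uniformly random available neighbour
    (Moore, wrapped columns) and the encounter is settled by phenotype:
    Stag+Stag pair up; Stag+Hare pair up (no communication) or the
    stag-hunter walks away (communication), costing both their pairing
    opportunity this tick; Hare+Hare separate immediately.  Every agent
    interacts at most once per tick.

    Returns the number of events written.
    """
    m = len(unpaired)
    n_ev = 0
    if m < 2:
        return 0
    build_occupancy(head, nxt, row, col, unpaired, W)
    avail = np.ones(m, dtype=np.bool_)
    cand = np.empty(m, dtype=np.int64)

    for q in range(m):
        t = perm[q]
        if not avail[t]:
            continue
        i = unpaired[t]
        ri = row[i]
        ci = col[i]
        ncand = 0
        for dr in range(-1, 2):
            rr = ri + dr
            if rr < 0 or rr >= H:
                continue
            for dc in range(-1, 2):
                cc = (ci + dc) % W
                s = head[rr * W + cc]
                while s >= 0:
                    if s != t and avail[s]:
                        cand[ncand] = s
                        ncand += 1
                    s = nxt[s]
        if ncand == 0:
            continue
        pick = int(u[q] * ncand)
        if pick >= ncand:
            pick = ncand - 1
        s = cand[pick]
        j = unpaired[s]
        avail[t] = False
        avail[s] = False

        pi = phen[i]
        pj = phen[j]
        if pi == 0 and pj == 0:  # Stag + Stag -> SS pair
            pair_with[i] = j
            pair_with[j] = i
            counters[C_PAIRS_SS] += 1
            ev_type[n_ev] = EV_PAIR_FORM
            ev_a[n_ev] = i
            ev_b[n_ev] = j
            ev_amount[n_ev] = 0.0
            n_ev += 1
        elif pi == 1 and pj == 1:  # Hare + Hare -> go separate ways
            counters[C_HH_MEET] += 1
        else:  # mixed
            a_stag = i if pi == 0 else j
            a_hare = j if pi == 0 else i
            if communication:
                counters[C_QUERIES] += 1
                ev_type[n_ev] = EV_QUERY
                ev_a[n_ev] = a_stag
                ev_b[n_ev] = a_hare
                ev_amount[n_ev] = 0.0
                n_ev += 1
            else:
                pair_with[i] = j
                pair_with[j] = i
                counters[C_PAIRS_SH] += 1
                ev_type[n_ev] = EV_PAIR_FORM
                ev_a[n_ev] = a_stag
                ev_b[n_ev] = a_hare
                ev_amount[n_ev] = 1.0
                n_ev += 1
    return n_ev


@njit(cache=False)
def _col_dist(c1, c2, W):
    d = c1 - c2
    if d < 0:
        d = -d
    if W - d < d:
        d = W - d
    return d


@njit(cache=False)
def _scan_prey(cand, ncand, head, nxt, prey_kind, prey_alive, want_kind,
               r0, c0, H, W):
    """Append alive prey of ``want_kind`` within the Moore neighbourhood of
    (r0, c0) to cand; returns the new count."""
    for dr in range(-1, 2):
        rr = r0 + dr
        if rr < 0 or rr >= H:
            continue
        for dc in range(-1, 2):
            cc = (c0 + dc) % W
            t = head[rr * W + cc]
            while t >= 0:
                if prey_alive[t] and prey_kind[t] == want_kind:
                    cand[ncand] = t
                    ncand += 1
                t = nxt[t]
    return ncand


@njit(cache=False)
def resolve_captures_kernel(
    unit_idx, unit_type, perm, u,
    row, col, phen, pair_with, energy,
    prey_kind, prey_row, prey_col, prey_alive,
    prey_head, prey_nxt, H, W,
    stag_reward, hare_reward, e_max, dissolve_ss,
    ev_type, ev_a, ev_b, ev_amount, counters,
):
    """One capture round over hunting units in random order.

    A unit is either an SS pair (unit_type 0, unit_idx = lead member) that
    may take a stag from the Moore neighbourhood of either member, or a
    hare-hunter (unit_type 1, solo or SH-paired) that may take a hare from
    its own neighbourhood.  A captured prey is removed immediately, so
    later units cannot take it.  Both SS members are credited the stag
    reward (capped at ``e_max``); the pair dissolves on capture only when
    ``dissolve_ss`` is set, otherwise it keeps hunting together.  SH
    pairs always dissolve when their hare member captures.  Solo
    stag-hunters and the stag member of an SH pair never capture.

    Returns the number of events written.
    """
    n_units = len(unit_idx)
    n_ev = 0
    if n_units == 0:
        return 0
    build_occupancy(prey_head, prey_nxt, prey_row, prey_col,
                    np.arange(len(prey_kind)), W)
    cand = np.empty(max(len(prey_kind), 1), dtype=np.int64)

    for q in range(n_units):
        k = perm[q]
        i = unit_idx[k]
        if unit_type[k] == 0:
            # SS pair: neighbourhood of either member, without double counting
            j = pair_with[i]
            ncand = _scan_prey(cand, 0, prey_head, prey_nxt, prey_kind,
                               prey_alive, 0, row[i], col[i], H, W)
            n_first = ncand
            ncand = _scan_prey(cand, ncand, prey_head, prey_nxt, prey_kind,
                               prey_alive, 0, row[j], col[j], H, W)
            # drop second-scan entries already adjacent to member i
            w = n_first
            for z in range(n_first, ncand):
                p = cand[z]
                dr = prey_row[p] - row[i]
                if dr < 0:
                    dr = -dr
                if dr > 1 or _col_dist(prey_col[p], col[i], W) > 1:
                    cand[w] = p
                    w += 1
            ncand = w
            if ncand == 0:
                continue
            pick = int(u[q] * ncand)
            if pick >= ncand:
                pick = ncand - 1
            p = cand[pick]
            prey_alive[p] = False
            counters[C_CAPTURES_STAG] += 1
            for z in range(2):
                member = i if z == 0 else j
                d = stag_reward
                if energy[member] + d > e_max:
                    d = e_max - energy[member]
                energy[member] += d
                ev_type[n_ev] = EV_CAPTURE
                ev_a[n_ev] = member
                ev_b[n_ev] = 0
                ev_amount[n_ev] = d
                n_ev += 1
            if dissolve_ss:
                pair_with[i] = -1
                pair_with[j] = -1
                counters[C_DISSOLUTIONS] += 1
                ev_type[n_ev] = EV_PAIR_DISSOLVE
                ev_a[n_ev] = i
                ev_b[n_ev] = j
                ev_amount[n_ev] = 0.0
                n_ev += 1
        else:
            # hare-hunter (solo or SH pair member)
            ncand = _scan_prey(cand, 0, prey_head, prey_nxt, prey_kind,
                               prey_alive, 1, row[i], col[i], H, W)
            if ncand == 0:
                continue
            pick = int(u[q] * ncand)
            if pick >= ncand:
                pick = ncand - 1
            p = cand[pick]
            prey_alive[p] = False
            counters[C_CAPTURES_HARE] += 1
            d = hare_reward
            if energy[i] + d > e_max:
                d = e_max - energy[i]
            energy[i] += d
            ev_type[n_ev] = EV_CAPTURE
            ev_a[n_ev] = i
            ev_b[n_ev] = 1
            ev_amount[n_ev] = d
            n_ev += 1
            j = pair_with[i]
            if j >= 0:  # SH pair ends when the hare member catches
                pair_with[i] = -1
                pair_with[j] = -1
                counters[C_DISSOLUTIONS] += 1
                ev_type[n_ev] = EV_PAIR_DISSOLVE
                ev_a[n_ev] = i
                ev_b[n_ev] = j
                ev_amount[n_ev] = 0.0
                n_ev += 1
    return n_ev
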