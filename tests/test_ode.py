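"""ODE model: transcription checks, closed forms, steady states.

The derivative function is cross-checked against an independent
reaction-stoichiometry construction of the same model: every process is
written as (rate law, stoichiometry vector) and summed.  Agreement at
random states guards against transcription slips in either version.
"""

import dataclasses

import numpy as np
import pytest

from staghunt.ode import (
    STATE_NAMES,
    OdeParams,
    OdeState,
    critical_ke,
    default_initial_state,
    derivatives,
    derivatives_vector,
    hare_only_initial_state,
    hare_steady_state_closed_form,
    integrate,
    ke_sweep,
    steady_state,
)

IX = {n: i for i, n in enumerate(STATE_NAMES)}


def reaction_derivatives(y, p):
    """Independent re-derivation: processes as (rate, stoichiometry)."""
    s = dict(zip(STATE_NAMES, y))
    F, R, k, a, l1, l2, l3, ke = p.F, p.R, p.k, p.alpha, p.l1, p.l2, p.l3, p.ke
    out = np.zeros(13)

    def add(rate, **delta):
        for name, d in delta.items():
            out[IX[name]] += rate * d

    # food supply and departure
    add(F, Fs=+1)
    add(F, Fh=+1)
    add(l3 * s["Fs"], Fs=-1)
    add(l3 * s["Fh"], Fh=-1)
    # pair formation (homotypic 1/2 factor; hare-hunters never pair together)
    add(k * s["Sp"] ** 2 / 2, Sp=-2, S2pp=+1)
    add(k * s["Sp"] * s["Sm"], Sp=-1, Sm=-1, S2pm=+1)
    add(k * s["Sm"] ** 2 / 2, Sm=-2, S2mm=+1)
    add(k * s["Sp"] * s["Hp"], Sp=-1, Hp=-1, Bpp=+1)
    add(k * s["Sp"] * s["Hm"], Sp=-1, Hm=-1, Bpm=+1)
    add(k * s["Sm"] * s["Hp"], Sm=-1, Hp=-1, Bmp=+1)
    add(k * s["Sm"] * s["Hm"], Sm=-1, Hm=-1, Bmm=+1)
    # S2 pairs catch stags at 2*ke*Fs each, resolving to two well-fed singles
    for pair in ("S2pp", "S2pm", "S2mm"):
        add(2 * ke * s[pair] * s["Fs"], **{pair: -1, "Fs": -1, "Sp": +2})
    # hare members (paired or free) catch hares at ke*Fh
    add(ke * s["Bpp"] * s["Fh"], Bpp=-1, Fh=-1, Sp=+1, Hp=+1)
    add(ke * s["Bpm"] * s["Fh"], Bpm=-1, Fh=-1, Sp=+1, Hp=+1)
    add(ke * s["Bmp"] * s["Fh"], Bmp=-1, Fh=-1, Sm=+1, Hp=+1)
    add(ke * s["Bmm"] * s["Fh"], Bmm=-1, Fh=-1, Sm=+1, Hp=+1)
    add(ke * s["Hp"] * s["Fh"], Fh=-1)                 # stays well-fed
    add(ke * s["Hm"] * s["Fh"], Fh=-1, Hm=-1, Hp=+1)
    # fed-status transitions (stag slowed by alpha)
    add(a * l1 * s["Sp"], Sp=-1, Sm=+1)
    add(l2 * s["Hp"], Hp=-1, Hm=+1)
    add(2 * a * l1 * s["S2pp"], S2pp=-1, S2pm=+1)
    add(a * l1 * s["S2pm"], S2pm=-1, S2mm=+1)
    add(a * l1 * s["Bpp"], Bpp=-1, Bmp=+1)
    add(a * l1 * s["Bpm"], Bpm=-1, Bmm=+1)
    add(l2 * s["Bpp"], Bpp=-1, Bpm=+1)
    add(l2 * s["Bmp"], Bmp=-1, Bmm=+1)
    # deaths of poorly-fed individuals (survivor keeps status)
    add(l1 * s["Sm"], Sm=-1)
    add(l2 * s["Hm"], Hm=-1)
    add(l1 * s["S2pm"], S2pm=-1, Sp=+1)
    add(2 * l1 * s["S2mm"], S2mm=-1, Sm=+1)
    add(l2 * s["Bpm"], Bpm=-1, Sp=+1)
    add(l2 * s["Bmm"], Bmm=-1, Sm=+1)
    add(l1 * s["Bmp"], Bmp=-1, Hp=+1)
    add(l1 * s["Bmm"], Bmm=-1, Hm=+1)
    # reproduction at 1/R per individual: frees paired parents, offspring
    # is a well-fed unpaired copy of the reproducing parent
    add(s["Sp"] / R, Sp=+1)
    add(s["Sm"] / R, Sp=+1)
    add(s["Hp"] / R, Hp=+1)
    add(s["Hm"] / R, Hp=+1)
    add(2 * s["S2pp"] / R, S2pp=-1, Sp=+3)
    add(s["S2pm"] / R, S2pm=-1, Sp=+2, Sm=+1)          # + member reproduces
    add(s["S2pm"] / R, S2pm=-1, Sp=+2, Sm=+1)          # - member reproduces
    add(2 * s["S2mm"] / R, S2mm=-1, Sm=+2, Sp=+1)
    add(s["Bpp"] / R, Bpp=-1, Sp=+2, Hp=+1)            # stag member
    add(s["Bpp"] / R, Bpp=-1, Sp=+1, Hp=+2)            # hare member
    add(s["Bpm"] / R, Bpm=-1, Sp=+2, Hm=+1)
    add(s["Bpm"] / R, Bpm=-1, Sp=+1, Hm=+1, Hp=+1)
    add(s["Bmp"] / R, Bmp=-1, Sm=+1, Sp=+1, Hp=+1)
    add(s["Bmp"] / R, Bmp=-1, Sm=+1, Hp=+2)
    add(s["Bmm"] / R, Bmm=-1, Sm=+1, Sp=+1, Hm=+1)
    add(s["Bmm"] / R, Bmm=-1, Sm=+1, Hm=+1, Hp=+1)
    return out


def test_all_zero_state_only_food_flows():
    d = derivatives(OdeState(), OdeParams())
    assert d.Fs == 10.0 and d.Fh == 10.0
    assert all(getattr(d, n) == 0.0 for n in STATE_NAMES[2:])


def test_hare_only_state_is_closed():
    # no stag-hunters anywhere: every stag compartment stays exactly zero
    d = derivatives(OdeState(Fs=3.0, Fh=5.0, Hp=7.0, Hm=2.0), OdeParams())
    for n in ("Sp", "Sm", "S2pp", "S2pm", "S2mm", "Bpp", "Bpm", "Bmp", "Bmm"):
        assert getattr(d, n) == 0.0


def test_negative_state_rejected():
    with pytest.raises(ValueError):
        derivatives(OdeState(Fs=-1.0), OdeParams())


def test_derivatives_match_independent_reaction_transcription(rng):
    p = OdeParams()
    for _ in range(200):
        y = rng.uniform(0, 20, 13)
        a = derivatives_vector(y, p)
        b = reaction_derivatives(y, p)
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-10)
    # and across a few random parameter sets
    for _ in range(20):
        q = OdeParams(F=rng.uniform(1, 20), R=rng.uniform(1.95, 5),
                      k=rng.uniform(0, 2), alpha=rng.uniform(0.1, 1),
                      l1=rng.uniform(0.5, 2), l2=rng.uniform(0.5, 2),
                      l3=rng.uniform(1, 40), ke=rng.uniform(0.05, 3))
        y = rng.uniform(0, 15, 13)
        np.testing.assert_allclose(
            derivatives_vector(y, q), reaction_derivatives(y, q),
            rtol=1e-10, atol=1e-10)


# ------------------------------------------------------------ closed forms

def test_critical_ke_reference_value():
    # l3*l2*(l2*R - 2)/F = 30 * 1.05 * 0.1 / 10
    assert critical_ke(OdeParams()) == pytest.approx(0.315, rel=1e-12)


def test_doubling_food_halves_threshold():
    p = OdeParams()
    assert critical_ke(dataclasses.replace(p, F=20.0)) == pytest.approx(
        critical_ke(p) / 2)


def test_closed_form_reference_values():
    p = OdeParams()
    # favourable limit: F/(l2*(l2*R-2)) = 10/0.105
    assert hare_steady_state_closed_form(
        dataclasses.replace(p, ke=1e15)) == pytest.approx(95.238, abs=1e-3)
    assert hare_steady_state_closed_form(
        dataclasses.replace(p, ke=0.63)) == pytest.approx(47.62, abs=1e-2)
    assert hare_steady_state_closed_form(
        dataclasses.replace(p, ke=critical_ke(p))) == pytest.approx(0.0, abs=1e-9)
    assert hare_steady_state_closed_form(
        dataclasses.replace(p, ke=0.2)) == 0.0   # below threshold: extinction


def test_explosion_regime_flagged():
    p = dataclasses.replace(OdeParams(), R=1.5)  # l2*R = 1.575 < 2
    with pytest.raises(ValueError, match="explosion"):
        hare_steady_state_closed_form(p)
    with pytest.raises(ValueError, match="explosion"):
        critical_ke(p)


# -------------------------------------------------------------- integrate

def test_trajectory_stays_nonnegative():
    traj = integrate(OdeParams(), default_initial_state(), t_end=50.0)
    assert traj.y.min() >= 0.0


def test_zero_input_zero_state_stays_zero():
    p = dataclasses.replace(OdeParams(), F=0.0)
    traj = integrate(p, OdeState(), t_end=10.0)
    assert np.all(traj.y == 0.0)


def test_tolerance_halving_changes_h_total_little():
    p = OdeParams()
    init = hare_only_initial_state()
    h1 = integrate(p, init, t_end=100.0, tol=1e-6).h_total[-1]
    h2 = integrate(p, init, t_end=100.0, tol=5e-7).h_total[-1]
    assert abs(h1 - h2) / max(h2, 1.0) < 1e-3


# ----------------------------------------------------------- steady state

def test_hare_only_steady_state_matches_closed_form():
    p = OdeParams()  # ke = 0.63 = 2x critical
    rep = steady_state(p, hare_only_initial_state(), horizon=2000.0)
    assert rep.converged
    want = hare_steady_state_closed_form(p)
    assert rep.h_tot == pytest.approx(want, rel=1e-2)
    assert rep.s_tot == 0.0


def test_hare_extinction_below_threshold():
    p = dataclasses.replace(OdeParams(), ke=0.2)
    rep = steady_state(p, hare_only_initial_state(), horizon=5000.0)
    assert rep.h_tot < 1e-3


def test_explosion_grows_beyond_any_bound():
    p = dataclasses.replace(OdeParams(), R=1.5)
    traj = integrate(p, hare_only_initial_state(), t_end=150.0, tol=1e-7)
    assert traj.h_total[-1] > 1e6


def test_hare_totals_independent_of_stag_hunters():
    p = OdeParams()
    t_eval = np.linspace(0, 60, 121)
    with_stags = integrate(p, default_initial_state(), 60.0, t_eval=t_eval)
    without = integrate(p, hare_only_initial_state(), 60.0, t_eval=t_eval)
    np.testing.assert_allclose(
        with_stags.h_total, without.h_total, rtol=1e-6, atol=1e-6)


def test_harsh_environment_favours_stag_hunters():
    rep = steady_state(dataclasses.replace(OdeParams(), ke=0.2),
                       default_initial_state(), horizon=3000.0)
    assert rep.s_tot > 1.0
    assert rep.h_tot < 1e-6


def test_favourable_environment_favours_hare_hunters():
    rep = steady_state(dataclasses.replace(OdeParams(), ke=1.0),
                       default_initial_state(), horizon=2000.0)
    assert rep.h_tot > 1.0


def test_stag_hunters_reemerge_when_environment_very_favourable():
    rep = steady_state(dataclasses.replace(OdeParams(), ke=5.0),
                       default_initial_state(), horizon=2000.0)
    assert rep.s_tot > 1.0 and rep.h_tot > 1.0


def test_lower_alpha_never_hurts_stag_hunters():
    # alpha is the well-fed -> poorly-fed slowdown; smaller alpha means
    # stags are more nourishing, so steady stag totals cannot drop
    totals = []
    for alpha in (0.9, 0.75, 0.6):
        rep = steady_state(
            dataclasses.replace(OdeParams(), ke=0.2, alpha=alpha),
            default_initial_state(), horizon=3000.0)
        totals.append(rep.s_tot)
    assert totals[0] <= totals[1] + 1e-6 <= totals[2] + 2e-6


def test_ke_sweep_brackets_analytic_threshold():
    p = OdeParams()
    crit = critical_ke(p)
    kes = np.linspace(0.8 * crit, 1.3 * crit, 6)
    table = ke_sweep(p, kes, init=hare_only_initial_state(), horizon=4000.0)
    alive = table.H_tot.to_numpy() > 0.05
    # extinct strictly below, persistent strictly above, one crossing
    assert not alive[0] and alive[-1]
    assert np.count_nonzero(np.diff(alive.astype(int)) != 0) == 1
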