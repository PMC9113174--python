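"""Well-fed/poorly-fed pair-formation ODE model of stag- and hare-hunters.

The population is split into 13 compartments: stag food ``Fs`` and hare
food ``Fh``; free stag-hunters ``S+``/``S-`` and free hare-hunters
``H+``/``H-`` by nutritional state; homotypic stag-hunter pairs
``S2++``/``S2+-``/``S2--`` by the members' fed status; and heterotypic
(stag-with-hare, "nuisance") pairs ``B++``/``B+-``/``B-+``/``B--`` keyed
as (stag member, hare member).

Mechanics, all mass-action:

* food of each kind is provided at rate ``F`` and leaves at rate ``l3``
  times its level; it is consumed at rate ``ke`` (the food-catching rate:
  small ``ke`` = harsh environment) times hunter x food;
* free hunters pair at rate ``k`` (with the 1/2 symmetry factor for
  homotypic pairing); hare-hunters never pair with each other;
* every individual reproduces at rate ``1/R``; a reproduction event frees
  a paired parent, and the offspring is a well-fed, unpaired copy of the
  reproducing parent's phenotype;
* well-fed hunters slide to poorly-fed at rate ``alpha*l1`` (stag) or
  ``l2`` (hare); poorly-fed hunters die at ``l1``/``l2``; ``alpha < 1``
  encodes the higher nutritional value of a stag;
* an S2 pair catches a stag at rate ``2*ke*Fs`` and resolves into two
  well-fed free stag-hunters; the hare member of a B pair catches a hare
  at rate ``ke*Fh``, resolving the pair into a well-fed free hare-hunter
  plus a free stag-hunter that keeps its fed status; a death in a pair
  frees the survivor with its status intact.

The hare-hunter subsystem closes on itself (pairing with stag-hunters
changes neither a hare-hunter's feeding nor its mortality), which yields
the closed-form steady state and extinction threshold implemented in
:func:`hare_steady_state_closed_form` and :func:`critical_ke`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "OdeParams",
    "OdeState",
    "SteadyStateReport",
    "STATE_NAMES",
    "derivatives",
    "derivatives_vector",
    "integrate",
    "hare_steady_state_closed_form",
    "critical_ke",
    "steady_state",
    "ke_sweep",
    "default_initial_state",
    "hare_only_initial_state",
    "s_total",
    "h_total",
]

#: Canonical ordering of the 13 compartments in vector form.
STATE_NAMES: tuple[str, ...] = (
    "Fs", "Fh",
    "Sp", "Sm", "Hp", "Hm",
    "S2pp", "S2pm", "S2mm",
    "Bpp", "Bpm", "Bmp", "Bmm",
)


@dataclass(frozen=True)
class OdeParams:
    """Model rates.  Defaults are the reference parameter set.

    ``ke`` has no single reference value — it is the harshness dial the
    steady-state sweeps vary; the default here is the worked-example value
    of twice the critical threshold for the other defaults.
    """

    F: float = 10.0       # food provision rate (each kind)
    R: float = 2.0        # reproduction interval; individuals reproduce at 1/R
    k: float = 0.6        # pair-formation rate
    alpha: float = 0.75   # stag-hunter well-fed -> poorly-fed slowdown (< 1)
    l1: float = 1.2       # poorly-fed stag-hunter death rate
    l2: float = 1.05      # poorly-fed hare-hunter death rate
    l3: float = 30.0      # food departure rate
    ke: float = 0.63      # food-catching rate; small = harsh environment

    def __post_init__(self) -> None:
        for name in ("F", "R", "k", "alpha", "l1", "l2", "l3", "ke"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class OdeState:
    """One point in the 13-dimensional compartment space."""

    Fs: float = 0.0
    Fh: float = 0.0
    Sp: float = 0.0
    Sm: float = 0.0
    Hp: float = 0.0
    Hm: float = 0.0
    S2pp: float = 0.0
    S2pm: float = 0.0
    S2mm: float = 0.0
    Bpp: float = 0.0
    Bpm: float = 0.0
    Bmp: float = 0.0
    Bmm: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "OdeState":
        y = np.asarray(y, dtype=float)
        if y.shape != (13,):
            raise ValueError(f"state vector must have shape (13,), got {y.shape}")
        return cls(**dict(zip(STATE_NAMES, map(float, y))))


def default_initial_state() -> OdeState:
    """Reference initial conditions: Fs = Fh = S+ = H+ = 10, rest 0."""
    return OdeState(Fs=10.0, Fh=10.0, Sp=10.0, Hp=10.0)


def hare_only_initial_state() -> OdeState:
    """Hare-hunter subsystem start: Fh = H+ = 10, every stag compartment 0."""
    return OdeState(Fh=10.0, Hp=10.0)


def derivatives_vector(y: np.ndarray, p: OdeParams) -> np.ndarray:
    """Time derivatives of the 13 compartments at state vector ``y``."""
    (Fs, Fh, Sp, Sm, Hp, Hm, S2pp, S2pm, S2mm, Bpp, Bpm, Bmp, Bmm) = y
    F, R, k, a, l1, l2, l3, ke = p.F, p.R, p.k, p.alpha, p.l1, p.l2, p.l3, p.ke

    S2 = S2pp + S2pm + S2mm
    Bh = Bpp + Bpm + Bmp + Bmm          # hare members of heterotypic pairs
    Sfree = Sp + Sm
    Hfree = Hp + Hm

    dFs = F - 2.0 * ke * S2 * Fs - l3 * Fs
    dFh = F - ke * (Bh + Hfree) * Fh - l3 * Fh

    dSp = (
        (6.0 * S2pp + 4.0 * S2pm + 2.0 * S2mm + 3.0 * Bpp + 3.0 * Bpm + Bmp + Bmm
         + Sp + Sm) / R
        + 4.0 * ke * S2 * Fs
        + ke * (Bpp + Bpm) * Fh
        - a * l1 * Sp
        - k * Sp * Sfree
        - k * Sp * Hfree
        + l1 * S2pm
        + l2 * Bpm
    )
    dSm = (
        (2.0 * S2pm + 4.0 * S2mm + 2.0 * Bmp + 2.0 * Bmm) / R
        + ke * (Bmp + Bmm) * Fh
        + a * l1 * Sp
        - l1 * Sm
        - k * Sm * Sfree
        - k * Sm * Hfree
        + 2.0 * l1 * S2mm
        + l2 * Bmm
    )
    dHp = (
        (3.0 * Bpp + 3.0 * Bmp + Bpm + Bmm + Hp + Hm) / R
        + ke * (Bpp + Bpm + Bmp + Bmm + Hm) * Fh
        - l2 * Hp
        - k * Hp * Sfree
        + l1 * Bmp
    )
    dHm = (
        (2.0 * Bpm + 2.0 * Bmm) / R
        + l2 * Hp
        - ke * Hm * Fh
        - l2 * Hm
        - k * Hm * Sfree
        + l1 * Bmm
    )
    dS2pp = k * Sp * Sp / 2.0 - 2.0 * S2pp / R - 2.0 * ke * S2pp * Fs - 2.0 * a * l1 * S2pp
    dS2pm = (
        k * Sp * Sm
        - 2.0 * S2pm / R
        - 2.0 * ke * S2pm * Fs
        - (1.0 + a) * l1 * S2pm
        + 2.0 * a * l1 * S2pp
    )
    dS2mm = (
        k * Sm * Sm / 2.0
        - 2.0 * S2mm / R
        - 2.0 * ke * S2mm * Fs
        - 2.0 * l1 * S2mm
        + a * l1 * S2pm
    )
    dBpp = k * Sp * Hp - 2.0 * Bpp / R - ke * Bpp * Fh - (l2 + a * l1) * Bpp
    dBpm = (
        k * Sp * Hm - 2.0 * Bpm / R - ke * Bpm * Fh - (l2 + a * l1) * Bpm + l2 * Bpp
    )
    dBmp = (
        k * Sm * Hp - 2.0 * Bmp / R - ke * Bmp * Fh - (l2 + l1) * Bmp + a * l1 * Bpp
    )
    dBmm = (
        k * Sm * Hm
        - 2.0 * Bmm / R
        - ke * Bmm * Fh
        - (l2 + l1) * Bmm
        + a * l1 * Bpm
        + l2 * Bmp
    )

    return np.array(
        [dFs, dFh, dSp, dSm, dHp, dHm, dS2pp, dS2pm, dS2mm, dBpp, dBpm, dBmp, dBmm]
    )


def derivatives(state: OdeState, params: OdeParams) -> OdeState:
    """Typed wrapper over :func:`derivatives_vector`; rejects negative states."""
    y = state.to_array()
    if np.any(y < 0):
        bad = [n for n, v in zip(STATE_NAMES, y) if v < 0]
        raise ValueError(f"state components must be >= 0; negative: {bad}")
    return OdeState.from_array(derivatives_vector(y, params))


@dataclass(frozen=True)
class Trajectory:
    """Integration output: times and the 13 x n_times state matrix."""

    t: np.ndarray
    y: np.ndarray
    params: OdeParams
    success: bool
    message: str = ""

    def component(self, name: str) -> np.ndarray:
        return self.y[STATE_NAMES.index(name)]

    @property
    def s_total(self) -> np.ndarray:
        return s_total(self.y)

    @property
    def h_total(self) -> np.ndarray:
        return h_total(self.y)

    def final_state(self) -> OdeState:
        return OdeState.from_array(self.y[:, -1])


def s_total(y: np.ndarray) -> np.ndarray:
    """Total stag-hunters: free + 2 per S2 pair + the stag member of each B."""
    names = STATE_NAMES
    ix = {n: names.index(n) for n in names}
    return (
        y[ix["Sp"]] + y[ix["Sm"]]
        + 2.0 * (y[ix["S2pp"]] + y[ix["S2pm"]] + y[ix["S2mm"]])
        + y[ix["Bpp"]] + y[ix["Bpm"]] + y[ix["Bmp"]] + y[ix["Bmm"]]
    )


def h_total(y: np.ndarray) -> np.ndarray:
    """Total hare-hunters: free + the hare member of each B pair."""
    names = STATE_NAMES
    ix = {n: names.index(n) for n in names}
    return (
        y[ix["Hp"]] + y[ix["Hm"]]
        + y[ix["Bpp"]] + y[ix["Bpm"]] + y[ix["Bmp"]] + y[ix["Bmm"]]
    )


def integrate(
    params: OdeParams,
    init: OdeState,
    t_end: float,
    tol: float = 1e-8,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from ``init`` to ``t_end``.

    Uses an adaptive stiff/non-stiff solver.  Trajectories from
    non-negative initial conditions stay non-negative up to integrator
    error; components are clipped at zero only when within ``-100*tol``
    (a genuine negative excursion beyond that raises).
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    y0 = init.to_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")

    sol = solve_ivp(
        lambda t, y: derivatives_vector(y, params),
        (0.0, float(t_end)),
        y0,
        method=method,
        rtol=tol,
        atol=tol * 1e-2,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y
    floor = -100.0 * max(tol, 1e-12) * max(1.0, float(np.max(np.abs(y))))
    if np.min(y) < floor:
        raise RuntimeError(
            f"negative excursion {np.min(y):.3e} exceeds tolerance floor {floor:.3e}"
        )
    return Trajectory(t=sol.t, y=np.clip(y, 0.0, None), params=params,
                      success=True, message=sol.message)


def hare_steady_state_closed_form(params: OdeParams) -> float:
    """Closed-form steady-state total of hare-hunters in isolation.

    ``H_TOT = F / (l2*(l2*R - 2)) - l3/ke`` when positive, else 0
    (extinction).  Requires ``l2*R > 2``; below that the population grows
    without bound and no finite steady state exists.
    """
    l2R = params.l2 * params.R
    if l2R <= 2:
        raise ValueError(
            f"no finite steady state: l2*R = {l2R} <= 2 (explosion regime)"
        )
    if params.ke <= 0:
        return 0.0
    level = params.F / (params.l2 * (l2R - 2.0)) - params.l3 / params.ke
    return max(level, 0.0)


def critical_ke(params: OdeParams) -> float:
    """Food-catching-rate threshold below which hare-hunters go extinct.

    ``ke* = l3*l2*(l2*R - 2)/F``; above it hare-hunters converge to the
    closed-form steady state, below it to zero.
    """
    l2R = params.l2 * params.R
    if l2R <= 2:
        raise ValueError(
            f"critical ke undefined: l2*R = {l2R} <= 2 (explosion regime)"
        )
    return params.l3 * params.l2 * (l2R - 2.0) / params.F


@dataclass(frozen=True)
class SteadyStateReport:
    """Outcome of integrating to (near) equilibrium."""

    converged: bool
    state: OdeState
    s_tot: float
    h_tot: float
    residual: float       # inf-norm of the derivative at the final state
    t_final: float


def steady_state(
    params: OdeParams,
    init: OdeState | None = None,
    horizon: float = 500.0,
    tol: float = 1e-8,
    chunk: float = 50.0,
) -> SteadyStateReport:
    """Integrate until the derivative inf-norm drops below ``tol``.

    Proceeds in chunks of ``chunk`` time units up to ``horizon``;
    non-convergence is reported (``converged=False``), never raised.
    """
    if init is None:
        init = default_initial_state()
    y = init.to_array()
    t = 0.0
    residual = float(np.max(np.abs(derivatives_vector(y, params))))
    while residual >= tol and t < horizon:
        span = min(chunk, horizon - t)
        sol = solve_ivp(
            lambda _t, _y: derivatives_vector(_y, params),
            (0.0, span),
            y,
            method="LSODA",
            rtol=1e-8,
            atol=1e-11,
        )
        if not sol.success:
            break
        y = np.clip(sol.y[:, -1], 0.0, None)
        t += span
        residual = float(np.max(np.abs(derivatives_vector(y, params))))
    state = OdeState.from_array(y)
    return SteadyStateReport(
        converged=residual < tol,
        state=state,
        s_tot=float(s_total(y[:, None])[0]),
        h_tot=float(h_total(y[:, None])[0]),
        residual=residual,
        t_final=t,
    )


def ke_sweep(
    params: OdeParams,
    ke_values: Sequence[float],
    init: OdeState | None = None,
    horizon: float = 500.0,
    tol: float = 1e-8,
) -> "pd.DataFrame":
    """Steady-state totals across a grid of food-catching rates.

    Returns a tidy frame with columns ``ke, S_tot, H_tot, converged,
    residual`` sorted by ``ke``, suitable for harshness-curve plots.
    """
    import pandas as pd

    ke_values = sorted(float(v) for v in ke_values)
    if any(v <= 0 for v in ke_values):
        raise ValueError("all ke values must be > 0")
    rows = []
    for ke in ke_values:
        rep = steady_state(replace(params, ke=ke), init=init, horizon=horizon, tol=tol)
        rows.append(
            dict(ke=ke, S_tot=rep.s_tot, H_tot=rep.h_tot,
                 converged=rep.converged, residual=rep.residual)
        )
    return pd.DataFrame(rows)
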