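"""Decision lab: the avatar hunting game and the switch-decision analysis.

Reproduces the rules of the online Stag Hunt game — an energy bar
draining at a per-trial decay rate, a certain 1-unit reward for hunting
hare versus a coin-flip 2-unit reward for hunting stag — for
policy-driven agents, and provides the binomial logistic regression of
switch direction (hare-to-stag vs stag-to-hare) on current energy that
is the game's headline analysis.  The logistic fit is a from-scratch
iteratively-reweighted-least-squares (IRLS) maximum-likelihood
implementation reporting the likelihood-ratio test against the
intercept-only model, Wald confidence intervals on the odds-ratio scale,
and Cox & Snell / Nagelkerke pseudo-R².

Trials are partitioned by decay rate into "good times" (0.02, 0.025) and
"hard times" (0.03, 0.035, 0.04).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from staghunt.core import STARVATION_EPS
from staghunt.rng import stream_generator

__all__ = [
    "Condition",
    "SwitchDirection",
    "LabConfig",
    "SwitchPolicy",
    "DecisionRecord",
    "LogisticFit",
    "SeparationError",
    "simulate_session",
    "generate_decisions",
    "partition_conditions",
    "condition_for_decay",
    "fit_switch_logit",
    "fit_intercept_only",
    "lr_chi_square",
    "records_to_frame",
]

GOOD_TIMES_DECAYS = (0.02, 0.025)
HARD_TIMES_DECAYS = (0.03, 0.035, 0.04)


class Condition(enum.Enum):
    GOOD_TIMES = "good_times"
    HARD_TIMES = "hard_times"


class SwitchDirection(enum.Enum):
    HARE_TO_STAG = "hare_to_stag"
    STAG_TO_HARE = "stag_to_hare"


class SeparationError(RuntimeError):
    """The logistic likelihood has no finite maximiser (perfect or
    quasi-perfect separation, or a single outcome class)."""


@dataclass(frozen=True)
class LabConfig:
    """Rules of the avatar game.

    Rewards follow the 100-calories-per-unit mapping: a hare is 1 unit
    with certainty, a stag 2 units with probability 1/2.  ``decay_rates``
    are the per-tick energy losses assigned to trials.  The capture
    opportunity and decision rates are free parameters of the lab (the
    original game does not publish them); defaults are set so a median
    trial produces a handful of switches, matching the order of ~4
    recorded decisions per trial.
    """

    decay_rates: tuple[float, ...] = (0.02, 0.025, 0.03, 0.035, 0.04)
    hare_reward: float = 1.0
    stag_reward: float = 2.0
    stag_success_p: float = 0.5
    trials_per_participant: int = 6
    bar_max: float = 20.0
    t_limit: int = 1000
    capture_rate: float = 0.03     # per-tick probability of a capture opportunity
    decision_rate: float = 0.06    # per-tick probability of a switch-decision point

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.decay_rates):
            raise ValueError("decay rates must be > 0")
        if not math.isclose(self.stag_reward, 2 * self.hare_reward):
            raise ValueError("the game fixes a 2:1 stag:hare reward ratio")
        for name in ("stag_success_p", "capture_rate", "decision_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass(frozen=True)
class SwitchPolicy:
    """Logistic preference for hunting stag as a function of energy.

    ``sigmoid(beta0 + beta1 * energy)`` is the probability of adopting
    (or sticking with) the Stag strategy at a decision point; negative
    ``beta1`` makes low-energy avatars gamble on the stag.
    """

    beta0: float = 0.0
    beta1: float = -0.19

    def p_stag(self, energy: float | np.ndarray) -> float | np.ndarray:
        return _sigmoid(self.beta0 + self.beta1 * np.asarray(energy, dtype=float))


@dataclass(frozen=True)
class DecisionRecord:
    """One strategy switch with its context."""

    participant: int
    trial: int
    decay_rate: float
    energy: float
    direction: SwitchDirection
    condition: Condition


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def condition_for_decay(decay_rate: float) -> Condition:
    """Map a trial decay rate to its harshness condition."""
    for d in GOOD_TIMES_DECAYS:
        if math.isclose(decay_rate, d, rel_tol=1e-9, abs_tol=1e-12):
            return Condition.GOOD_TIMES
    for d in HARD_TIMES_DECAYS:
        if math.isclose(decay_rate, d, rel_tol=1e-9, abs_tol=1e-12):
            return Condition.HARD_TIMES
    raise ValueError(f"unknown decay rate {decay_rate!r}; expected one of "
                     f"{GOOD_TIMES_DECAYS + HARD_TIMES_DECAYS}")


def partition_conditions(
    records: Iterable[DecisionRecord],
) -> tuple[list[DecisionRecord], list[DecisionRecord]]:
    """Split records into (good_times, hard_times) by trial decay rate."""
    good: list[DecisionRecord] = []
    hard: list[DecisionRecord] = []
    for r in records:
        if condition_for_decay(r.decay_rate) is Condition.GOOD_TIMES:
            good.append(r)
        else:
            hard.append(r)
    return good, hard


def simulate_session(
    config: LabConfig,
    policy: SwitchPolicy,
    seed: int,
    participant: int = 0,
) -> list[DecisionRecord]:
    """Play one participant's trials and emit every strategy switch.

    Each trial: the energy bar starts full and drains at the trial's
    decay rate; capture opportunities arrive as a Bernoulli process and
    pay by the current strategy (hare certain, stag a coin flip for
    double); at decision points the policy's logistic probability of
    preferring Stag, evaluated at current energy, sets the strategy, and
    any change is recorded.  A trial ends at starvation or the time
    limit.
    """
    g = stream_generator(seed, "lab")
    rates = list(config.decay_rates)
    order = list(g.permutation(len(rates)))
    trial_rates = [rates[i] for i in order]
    while len(trial_rates) < config.trials_per_participant:
        trial_rates.append(rates[int(g.integers(0, len(rates)))])
    trial_rates = trial_rates[: config.trials_per_participant]

    records: list[DecisionRecord] = []
    for trial, decay in enumerate(trial_rates):
        condition = condition_for_decay(decay)
        energy = config.bar_max
        hunting_stag = False  # everyone starts on the safe Hare strategy
        for _t in range(config.t_limit):
            # decision point
            if g.random() < config.decision_rate:
                want_stag = g.random() < policy.p_stag(energy)
                if want_stag != hunting_stag:
                    records.append(DecisionRecord(
                        participant=participant,
                        trial=trial,
                        decay_rate=decay,
                        energy=float(energy),
                        direction=(SwitchDirection.HARE_TO_STAG if want_stag
                                   else SwitchDirection.STAG_TO_HARE),
                        condition=condition,
                    ))
                    hunting_stag = want_stag
            # capture opportunity
            if g.random() < config.capture_rate:
                if hunting_stag:
                    if g.random() < config.stag_success_p:
                        energy = min(energy + config.stag_reward, config.bar_max)
                else:
                    energy = min(energy + config.hare_reward, config.bar_max)
            energy -= decay
            if energy < STARVATION_EPS:
                break
    return records


def generate_decisions(
    beta0: float,
    beta1: float,
    n: int,
    energy_dist: tuple = ("uniform", 0.0, 20.0),
    seed: int = 0,
    decay_rates: Sequence[float] = HARD_TIMES_DECAYS,
) -> list[DecisionRecord]:
    """Synthetic switch records with a known logistic law.

    Energies are drawn from ``energy_dist`` (``("uniform", lo, hi)`` or
    ``("normal", mu, sd)``, clipped to [0, 20]); the direction is
    hare-to-stag with probability ``sigmoid(beta0 + beta1*energy)``.
    Decay rates cycle through ``decay_rates`` and set the condition tag.
    Used as the ground-truth surface for parameter-recovery tests of the
    logistic fit.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    g = stream_generator(seed, "lab")
    kind = energy_dist[0]
    if kind == "uniform":
        lo, hi = float(energy_dist[1]), float(energy_dist[2])
        energy = g.uniform(lo, hi, n)
    elif kind == "normal":
        mu, sd = float(energy_dist[1]), float(energy_dist[2])
        energy = np.clip(g.normal(mu, sd, n), 0.0, 20.0)
    else:
        raise ValueError(f"unknown energy distribution {kind!r}")
    p = _sigmoid(beta0 + beta1 * energy)
    to_stag = g.random(n) < p
    records = []
    for i in range(n):
        decay = float(decay_rates[i % len(decay_rates)])
        records.append(DecisionRecord(
            participant=i // 24,          # ~4 decisions x 6 trials per participant
            trial=i % 6,
            decay_rate=decay,
            energy=float(energy[i]),
            direction=(SwitchDirection.HARE_TO_STAG if to_stag[i]
                       else SwitchDirection.STAG_TO_HARE),
            condition=condition_for_decay(decay),
        ))
    return records


def records_to_frame(records: Iterable[DecisionRecord]) -> "pd.DataFrame":
    """Records as a tidy frame with the interchange CSV schema."""
    import pandas as pd

    return pd.DataFrame(
        [{"participant": r.participant, "trial": r.trial,
          "decay_rate": r.decay_rate, "energy": r.energy,
          "direction": r.direction.value, "condition": r.condition.value}
         for r in records],
        columns=["participant", "trial", "decay_rate", "energy",
                 "direction", "condition"],
    )


@dataclass(frozen=True)
class LogisticFit:
    """ML logistic fit of switch direction (1 = hare-to-stag) on energy."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    or_ci_low: float          # 95% Wald CI for exp(beta1)
    or_ci_high: float
    loglik: float
    loglik_null: float
    lr_chi2: float            # vs intercept-only, df = 1
    lr_df: int
    p_value: float
    cox_snell: float
    nagelkerke: float
    n: int
    n_params: int
    n_iter: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _irls(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
          tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Newton/IRLS maximiser of the Bernoulli log-likelihood.

    Returns (beta, covariance, loglik, iterations); raises
    :class:`SeparationError` when the likelihood keeps improving toward
    an infinite coefficient.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        if np.max(w) < 1e-12 or np.max(np.abs(eta)) > 40.0:
            raise SeparationError(
                "logistic fit diverged (perfect or quasi-perfect separation)")
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol * (1.0 + np.max(np.abs(beta))):
            break
    else:
        raise SeparationError(f"IRLS failed to converge in {max_iter} iterations")
    eta = X @ beta
    mu = _sigmoid(eta)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, ll, it


def fit_switch_logit(records) -> LogisticFit:
    """Fit direction ~ energy by maximum likelihood (IRLS).

    ``records`` may be an iterable of :class:`DecisionRecord` or a frame
    with ``energy`` and ``direction`` columns.  Requires both outcome
    classes and n >= 20; perfect separation raises
    :class:`SeparationError`.
    """
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        energy = records["energy"].to_numpy(dtype=float)
        direction = records["direction"].astype(str).to_numpy()
    else:
        records = list(records)
        energy = np.array([r.energy for r in records], dtype=float)
        direction = np.array([r.direction.value for r in records])
    y = (direction == SwitchDirection.HARE_TO_STAG.value).astype(float)
    n = len(y)
    if n < 20:
        raise ValueError(f"need at least 20 records to fit, got {n}")
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise SeparationError(
            f"single outcome class ({n1}/{n} hare-to-stag); no slope is identifiable")

    X = np.column_stack([np.ones(n), energy])
    beta, cov, ll, n_iter = _irls(X, y)

    pbar = n1 / n
    ll0 = n1 * math.log(pbar) + (n - n1) * math.log(1.0 - pbar)
    lr = max(0.0, 2.0 * (ll - ll0))
    from scipy.stats import chi2, norm

    p = float(chi2.sf(lr, df=1))
    z = float(norm.ppf(0.975))
    se = np.sqrt(np.diag(cov))
    cs = 1.0 - math.exp(2.0 * (ll0 - ll) / n)
    cs_max = 1.0 - math.exp(2.0 * ll0 / n)
    return LogisticFit(
        beta0=float(beta[0]), beta1=float(beta[1]),
        se_beta0=float(se[0]), se_beta1=float(se[1]),
        or_ci_low=float(np.exp(beta[1] - z * se[1])),
        or_ci_high=float(np.exp(beta[1] + z * se[1])),
        loglik=ll, loglik_null=float(ll0),
        lr_chi2=lr, lr_df=1, p_value=p,
        cox_snell=cs, nagelkerke=cs / cs_max if cs_max > 0 else 0.0,
        n=n, n_params=2, n_iter=n_iter,
    )


def fit_intercept_only(records) -> LogisticFit:
    """Intercept-only (null) fit of the switch direction, for LR testing."""
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        direction = records["direction"].astype(str).to_numpy()
    else:
        direction = np.array([r.direction.value for r in records])
    y = (direction == SwitchDirection.HARE_TO_STAG.value).astype(float)
    n = len(y)
    if n < 1:
        raise ValueError("need at least one record")
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise SeparationError(f"single outcome class ({n1}/{n} hare-to-stag)")
    pbar = n1 / n
    ll0 = n1 * math.log(pbar) + (n - n1) * math.log(1.0 - pbar)
    b0 = math.log(pbar / (1.0 - pbar))
    se0 = 1.0 / math.sqrt(n * pbar * (1.0 - pbar))
    nan = float("nan")
    return LogisticFit(
        beta0=b0, beta1=0.0, se_beta0=se0, se_beta1=nan,
        or_ci_low=nan, or_ci_high=nan,
        loglik=float(ll0), loglik_null=float(ll0),
        lr_chi2=0.0, lr_df=0, p_value=1.0,
        cox_snell=0.0, nagelkerke=0.0, n=n, n_params=1, n_iter=0,
    )


def lr_chi_square(full: LogisticFit, null: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio statistic between nested fits on the same data.

    Returns ``(statistic, df, p_value)`` with
    ``statistic = 2*(loglik_full - loglik_null)`` and ``df`` the
    difference in parameter counts.
    """
    if full.n != null.n:
        raise ValueError(f"fits are not on the same records (n {full.n} != {null.n})")
    if full.n_params < null.n_params:
        raise ValueError("'full' model has fewer parameters than 'null'")
    df = full.n_params - null.n_params
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    if df == 0:
        return 0.0, 0, 1.0
    from scipy.stats import chi2

    return stat, df, float(chi2.sf(stat, df=df))
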