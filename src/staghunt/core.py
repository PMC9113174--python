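"""Shared domain types: payoff arithmetic, energy accounting, phenotypes.

The classic two-player Stag Hunt payoff matrix used throughout::

                 j: Stag      j: Hare
    i: Stag      (r, r)       (0, 1)
    i: Hare      (1, 0)       (1, 1)

with ``r = stag_ratio * hare_reward`` the payoff-dominant joint reward and
the off-diagonal zero the miscoordination penalty paid by a stag chooser
whose partner hunts hare.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "HuntChoice",
    "Phenotype",
    "PayoffScheme",
    "EnergyParams",
    "STARVATION_EPS",
    "payoff",
    "gain_energy",
]

#: Starvation threshold: an agent dies when energy < STARVATION_EPS.  The
#: nominal rule is "energy account = 0"; the epsilon absorbs float rounding
#: from repeated subtraction of the per-tick decay (e.g. 20 - 200*0.1 must
#: read as exactly dead).
STARVATION_EPS = 1e-9


class HuntChoice(enum.Enum):
    """What a hunter commits to in an encounter."""

    STAG = "stag"
    HARE = "hare"


class Phenotype(enum.IntEnum):
    """Heritable, fixed foraging strategy.

    Grid-world agents are STAG_HUNTER or HARE_HUNTER for life; FLEXIBLE
    exists only for decision-lab avatars, which may switch strategy at
    run time.
    """

    STAG_HUNTER = 0
    HARE_HUNTER = 1
    FLEXIBLE = 2


@dataclass(frozen=True)
class PayoffScheme:
    """Stag:Hare reward structure with a zero miscoordination payoff.

    Parameters
    ----------
    stag_ratio:
        Dimensionless ratio r of the Stag reward to the Hare reward,
        >= 1.  The survival sweeps use 1:1 through 5:1.
    hare_reward:
        Energy units for a solitary hare catch; normalised to 1.0.
    miscoordination_reward:
        Energy for a stag chooser facing a hare chooser; fixed at 0 — this
        is what makes Stag the risky, payoff-dominant strategy.
    """

    stag_ratio: float = 2.0
    hare_reward: float = 1.0
    miscoordination_reward: float = 0.0

    def __post_init__(self) -> None:
        if self.hare_reward <= 0:
            raise ValueError(f"hare_reward must be > 0, got {self.hare_reward}")
        if self.stag_ratio < 1:
            raise ValueError(f"stag_ratio must be >= 1, got {self.stag_ratio}")
        if self.miscoordination_reward != 0:
            raise ValueError("miscoordination_reward is fixed at 0 in the Stag Hunt")

    @property
    def stag_reward(self) -> float:
        """Per-member energy from a coordinated stag capture."""
        return self.stag_ratio * self.hare_reward


@dataclass(frozen=True)
class EnergyParams:
    """Energy budget of a hunter.

    ``e_start`` (E_s) is the natal energy deposit, ``e_max`` (E_max) the
    metabolic storage ceiling, and ``e_rate`` (E_r) the constant per-tick
    expenditure — the environmental-harshness dial.
    """

    e_start: float = 20.0
    e_max: float = 20.0
    e_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.e_start <= self.e_max:
            raise ValueError(
                f"need 0 < e_start <= e_max, got e_start={self.e_start}, e_max={self.e_max}"
            )
        if self.e_rate < 0:
            raise ValueError(f"e_rate must be >= 0, got {self.e_rate}")


def payoff(
    choice_i: HuntChoice, choice_j: HuntChoice, scheme: PayoffScheme
) -> tuple[float, float]:
    """Energy payoffs for one encounter under the Stag Hunt matrix.

    Returns ``(energy_i, energy_j)``; symmetric under swapping players.
    """
    if not isinstance(choice_i, HuntChoice) or not isinstance(choice_j, HuntChoice):
        raise ValueError(f"invalid hunt choice: {choice_i!r}, {choice_j!r}")

    def _one(mine: HuntChoice, theirs: HuntChoice) -> float:
        if mine is HuntChoice.STAG:
            if theirs is HuntChoice.STAG:
                return scheme.stag_reward
            return scheme.miscoordination_reward
        return scheme.hare_reward

    return _one(choice_i, choice_j), _one(choice_j, choice_i)


def gain_energy(current: float, amount: float, e_max: float) -> float:
    """Credit ``amount`` to an energy account capped at ``e_max``.

    Gains beyond the storage ceiling are lost, so the operation is
    idempotent at ``e_max``.
    """
    if amount < 0:
        raise ValueError(f"energy gain must be >= 0, got {amount}")
    if not 0 <= current <= e_max:
        raise ValueError(f"current energy {current} outside [0, {e_max}]")
    return min(current + amount, e_max)
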