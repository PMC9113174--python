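"""Survival-probability sweeps over harshness x payoff ratio x communication.

Replicates the survival-grid experimental design: for every cell
``(e_rate, stag_ratio, communication)`` the ABM is run ``runs`` times
with independently derived seeds and the per-phenotype survival
probability is the mean of the binary per-run outcomes (alive at the
horizon or not).  Cell seeds are derived as a hash of (master seed, cell
indices, run index), so any cell can be recomputed in isolation — or in
parallel — without changing results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from staghunt.core import EnergyParams, PayoffScheme
from staghunt.engine import run_simulation, survival_outcome
from staghunt.rng import derive_seed
from staghunt.world import WorldConfig

__all__ = ["SweepSpec", "SweepResult", "run_sweep", "survival_difference",
           "DESK_PRESET", "FULL_PRESET"]

#: Reference full-scale protocol: the complete harshness and ratio grids,
#: both communication modes, 100 runs per cell to the 50 000-tick horizon.
FULL_PRESET = dict(
    e_rates=(0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.11, 0.12),
    ratios=(1.0, 2.0, 3.0, 4.0, 5.0),
    runs=100,
    t_end=50_000,
)

#: Desk-scale preset: corner-and-centre grid, 20 runs, 5 000-tick horizon.
#: Same qualitative structure at a small fraction of the cost.
DESK_PRESET = dict(
    e_rates=(0.02, 0.07, 0.12),
    ratios=(1.0, 3.0, 5.0),
    runs=20,
    t_end=5_000,
)


@dataclass(frozen=True)
class SweepSpec:
    """Grid of conditions to sweep plus the shared base configuration."""

    e_rates: tuple[float, ...] = DESK_PRESET["e_rates"]
    ratios: tuple[float, ...] = DESK_PRESET["ratios"]
    modes: tuple[bool, ...] = (False, True)     # communication off/on
    runs: int = DESK_PRESET["runs"]
    t_end: int = DESK_PRESET["t_end"]
    base_config: WorldConfig = field(default_factory=WorldConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.e_rates or not self.ratios or not self.modes:
            raise ValueError("e_rates, ratios and modes must be non-empty")
        if self.runs < 1:
            raise ValueError(f"runs must be >= 1, got {self.runs}")

    @classmethod
    def from_preset(cls, preset: str, base_config: WorldConfig | None = None,
                    master_seed: int = 0) -> "SweepSpec":
        p = {"desk": DESK_PRESET, "full": FULL_PRESET}[preset]
        return cls(
            e_rates=tuple(p["e_rates"]), ratios=tuple(p["ratios"]),
            runs=p["runs"], t_end=p["t_end"],
            base_config=base_config or WorldConfig(),
            master_seed=master_seed,
        )

    def cell_config(self, e_rate: float, ratio: float, communication: bool) -> WorldConfig:
        base = self.base_config
        return dataclasses.replace(
            base,
            energy=EnergyParams(base.energy.e_start, base.energy.e_max, e_rate),
            payoff=PayoffScheme(stag_ratio=ratio,
                                hare_reward=base.payoff.hare_reward),
            communication=communication,
            t_end=self.t_end,
        )


@dataclass
class SweepResult:
    """Per-cell survival probabilities and the raw per-run outcomes.

    ``stag_p`` and ``hare_p`` are arrays of shape
    ``(n_e_rates, n_ratios, n_modes)``; ``outcomes`` has an extra
    ``(runs, 2)`` trailing block holding each run's (stag, hare) binary
    outcome, so ``p * runs`` is always an integer count of surviving runs.
    """

    spec: SweepSpec
    stag_p: np.ndarray
    hare_p: np.ndarray
    outcomes: np.ndarray

    def to_frame(self) -> "pd.DataFrame":
        """Tidy form: e_rate, ratio, mode, phenotype, survival_p, runs."""
        import pandas as pd

        rows = []
        for ie, er in enumerate(self.spec.e_rates):
            for ir, ratio in enumerate(self.spec.ratios):
                for im, mode in enumerate(self.spec.modes):
                    for phname, p in (("stag", self.stag_p), ("hare", self.hare_p)):
                        rows.append(dict(
                            e_rate=er, ratio=ratio,
                            mode="comm" if mode else "no_comm",
                            phenotype=phname,
                            survival_p=float(p[ie, ir, im]),
                            runs=self.spec.runs,
                        ))
        return pd.DataFrame(rows)


def run_cell(spec: SweepSpec, ie: int, ir: int, im: int) -> np.ndarray:
    """Per-run (stag, hare) outcomes for one sweep cell, shape (runs, 2)."""
    cfg = spec.cell_config(spec.e_rates[ie], spec.ratios[ir], spec.modes[im])
    out = np.zeros((spec.runs, 2), dtype=np.int8)
    for run in range(spec.runs):
        seed = derive_seed(spec.master_seed, ie, ir, im, run)
        res = run_simulation(cfg, seed, record_stride=max(1, cfg.t_end // 50))
        out[run] = survival_outcome(res)
    return out


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Execute the full sweep serially, cell by cell."""
    shape = (len(spec.e_rates), len(spec.ratios), len(spec.modes))
    outcomes = np.zeros(shape + (spec.runs, 2), dtype=np.int8)
    cells = [(ie, ir, im) for ie in range(shape[0])
             for ir in range(shape[1]) for im in range(shape[2])]
    it = cells
    if progress:  # pragma: no cover
        from tqdm import tqdm  # type: ignore

        it = tqdm(cells, desc="sweep cells")
    for ie, ir, im in it:
        outcomes[ie, ir, im] = run_cell(spec, ie, ir, im)
    stag_p = outcomes[..., 0].mean(axis=-1)
    hare_p = outcomes[..., 1].mean(axis=-1)
    return SweepResult(spec=spec, stag_p=stag_p, hare_p=hare_p, outcomes=outcomes)


def plot_survival_heatmaps(result: SweepResult, path: str | None = None):
    """Three-column heatmap figure per mode: stag survival, hare survival,
    and their difference over the (harshness, ratio) grid.  Requires
    matplotlib; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = result.spec
    diff = survival_difference(result)
    fig, axes = plt.subplots(
        len(spec.modes), 3, figsize=(11, 3.2 * len(spec.modes)), squeeze=False
    )
    panels = (("stag survival", result.stag_p, "Blues", 0, 1),
              ("hare survival", result.hare_p, "Reds", 0, 1),
              ("stag - hare", diff, "RdBu", -1, 1))
    for im, mode in enumerate(spec.modes):
        for j, (title, data, cmap, vmin, vmax) in enumerate(panels):
            ax = axes[im][j]
            img = ax.imshow(data[:, :, im], cmap=cmap, vmin=vmin, vmax=vmax,
                            aspect="auto", origin="lower")
            ax.set_xticks(range(len(spec.ratios)),
                          [f"{r:g}:1" for r in spec.ratios])
            ax.set_yticks(range(len(spec.e_rates)),
                          [f"{e:g}" for e in spec.e_rates])
            ax.set_xlabel("stag:hare payoff ratio")
            ax.set_ylabel("energy expenditure $E_r$")
            ax.set_title(f"{title} ({'comm' if mode else 'no comm'})")
            fig.colorbar(img, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def survival_difference(result: SweepResult) -> np.ndarray:
    """Element-wise stag minus hare survival probability, in [-1, 1];
    positive values mean a stag-hunting advantage."""
    if result.stag_p.shape != result.hare_p.shape:
        raise ValueError("mismatched survival grids")
    return result.stag_p - result.hare_p
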