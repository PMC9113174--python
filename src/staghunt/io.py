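"""Configuration files, result persistence, and run manifests.

Configs are YAML mirroring the dataclass field names exactly, with a
top-level ``kind`` selecting the schema (``abm``, ``sweep``, ``ode`` or
``lab``).  Unknown keys are rejected with the offending field named.
Results are written as headered CSV (tabular) and JSON (nested), plus a
``manifest.json`` listing every output file with its SHA-256 hash so any
run can be verified or regenerated from (config, seed, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Union

import numpy as np
import yaml

from staghunt.core import EnergyParams, PayoffScheme
from staghunt.engine import SimulationResult
from staghunt.lab import LabConfig, LogisticFit
from staghunt.ode import OdeParams
from staghunt.sweep import SweepResult, SweepSpec, survival_difference
from staghunt.world import WorldConfig

__all__ = ["SCHEMA_VERSION", "RunManifest", "load_config", "save_config",
           "write_outputs", "file_sha256"]

SCHEMA_VERSION = 1

AnyConfig = Union[WorldConfig, SweepSpec, OdeParams, LabConfig]

_KINDS: dict[str, type] = {
    "abm": WorldConfig,
    "sweep": SweepSpec,
    "ode": OdeParams,
    "lab": LabConfig,
}
_NESTED = {
    "energy": EnergyParams,
    "payoff": PayoffScheme,
    "base_config": WorldConfig,
}


def _build_dataclass(cls: type, data: dict[str, Any], context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in names:
            raise ValueError(
                f"unknown field {context}{key!r}; valid fields: {sorted(names)}")
        if key in _NESTED and isinstance(value, dict):
            value = _build_dataclass(_NESTED[key], value, context=f"{context}{key}.")
        ftypes = {f.name: f.type for f in dataclasses.fields(cls)}
        if isinstance(value, list) and "tuple" in str(ftypes.get(key, "")):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration for {context or cls.__name__}: {exc}") from exc


def load_config(path: str | Path) -> AnyConfig:
    """Load and validate a YAML config file.

    The file must carry ``kind: abm | sweep | ode | lab``; all other keys
    must match the corresponding dataclass fields.  An empty body (just
    ``kind``) yields the reference defaults.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    kind = data.pop("kind", None)
    if kind not in _KINDS:
        raise ValueError(
            f"{path}: config needs a 'kind' of one of {sorted(_KINDS)}, got {kind!r}")
    return _build_dataclass(_KINDS[kind], data, context="")


def _as_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_config(config: AnyConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    kind = {v: k for k, v in _KINDS.items()}[type(config)]
    data = {"kind": kind, **_as_plain(config)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Inventory of a run's outputs with content hashes."""

    schema_version: int
    command: str
    config: dict
    seed: int | None
    software_version: str
    timestamp: str
    files: dict[str, str]          # relative path -> sha256

    def verify(self, out_dir: str | Path) -> None:
        """Recompute hashes of the listed files; raise on any mismatch."""
        out_dir = Path(out_dir)
        for rel, digest in self.files.items():
            actual = file_sha256(out_dir / rel)
            if actual != digest:
                raise ValueError(f"{rel}: hash mismatch ({actual} != {digest})")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_as_plain(payload), indent=2, sort_keys=True) + "\n")


def write_outputs(result: Any, out_dir: str | Path, command: str = "",
                  seed: int | None = None) -> RunManifest:
    """Persist a result object and return the manifest.

    Supported results: :class:`SimulationResult` (per-tick counts CSV,
    summary JSON, event CSV when logged), :class:`SweepResult` (tidy
    survival CSV plus stag-hare difference CSV), a DataFrame (plain CSV),
    a list of decision records (decision CSV), or :class:`LogisticFit`
    (JSON).  Data files are byte-deterministic for deterministic runs;
    only the manifest carries a timestamp.
    """
    import pandas as pd
    from staghunt import __version__
    from staghunt.lab import records_to_frame, DecisionRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    config_echo: dict = {}

    if isinstance(result, SimulationResult):
        config_echo = _as_plain(result.config)
        seed = result.seed if seed is None else seed
        counts = out_dir / "counts.csv"
        result.counts_frame().to_csv(counts, index=False)
        files.append(counts)
        summary = out_dir / "summary.json"
        _write_json(summary, {
            "schema_version": SCHEMA_VERSION,
            "config": config_echo,
            "seed": result.seed,
            "completed_ticks": result.completed_ticks,
            "final_counts": result.final_counts,
            "counters": result.counters,
            "survival": {"stag": int(result.stag_hunters[-1] > 0),
                         "hare": int(result.hare_hunters[-1] > 0)},
        })
        files.append(summary)
        if result.world.log_events:
            events = out_dir / "events.csv"
            result.world.event_log_frame().to_csv(events, index=False)
            files.append(events)
    elif isinstance(result, SweepResult):
        config_echo = _as_plain(result.spec)
        seed = result.spec.master_seed if seed is None else seed
        tidy = out_dir / "survival.csv"
        result.to_frame().to_csv(tidy, index=False)
        files.append(tidy)
        diff = survival_difference(result)
        rows = []
        for ie, er in enumerate(result.spec.e_rates):
            for ir, ratio in enumerate(result.spec.ratios):
                for im, mode in enumerate(result.spec.modes):
                    rows.append(dict(e_rate=er, ratio=ratio,
                                     mode="comm" if mode else "no_comm",
                                     stag_minus_hare=float(diff[ie, ir, im])))
        dpath = out_dir / "difference.csv"
        pd.DataFrame(rows).to_csv(dpath, index=False)
        files.append(dpath)
    elif isinstance(result, LogisticFit):
        fpath = out_dir / "fit.json"
        _write_json(fpath, {"schema_version": SCHEMA_VERSION, **result.as_dict()})
        files.append(fpath)
    elif isinstance(result, pd.DataFrame):
        fpath = out_dir / "table.csv"
        result.to_csv(fpath, index=False)
        files.append(fpath)
    elif isinstance(result, list) and (not result or isinstance(result[0], DecisionRecord)):
        fpath = out_dir / "decisions.csv"
        records_to_frame(result).to_csv(fpath, index=False)
        files.append(fpath)
    else:
        raise TypeError(f"don't know how to persist {type(result).__name__}")

    manifest = RunManifest(
        schema_version=SCHEMA_VERSION,
        command=command,
        config=config_echo,
        seed=seed,
        software_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        files={f.name: file_sha256(f) for f in files},
    )
    _write_json(out_dir / "manifest.json", dataclasses.asdict(manifest))
    return manifest
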