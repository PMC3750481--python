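"""Strict YAML configuration for simulation runs.

The schema has three sections — ``population``, ``phases``, ``output`` —
plus a top-level ``name``.  Parsing is strict: unknown keys are fatal
and all missing required keys are reported at once, each error
path-qualified (e.g. ``phases[1].efficacy.sigma``), so a silently
misconfigured rate or efficacy cannot slip through.

Example::

    name: noisy_uptake
    population:
      n_init: 1000.0
      division_rate: 0.1     # per day
      death_rate: 0.1        # per day
      truncation_order: 20
    phases:
      - duration_d: 10.0
        efficacy: {variant: normal, mu: 1.0, sigma: 0.2}
      - duration_d: 10.0
        efficacy: {variant: dirac, mu: 0.0}
    output:
      eval_times_d: [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]
      grid: {x_min: -0.5, x_max: 1.5, n_points: 2001}
      sample_size: 10000
      thresholds: [0.1]
      seed: 1

Efficacy variants: ``dirac`` (mu), ``normal`` (mu, sigma),
``mixture`` (weights, means, sigma — a common within-component sigma),
``gridded`` (x, density — explicit lists).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .label_content import Efficacy, Grid, heterogeneous_efficacy
from .scenarios import ScenarioConfig

__all__ = ["ConfigError", "parse_config", "config_to_yaml", "write_config"]


class ConfigError(ValueError):
    """Raised with one path-qualified message per problem found."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


_EFFICACY_KEYS = {
    "dirac": {"mu"},
    "normal": {"mu", "sigma"},
    "mixture": {"weights", "means", "sigma"},
    "gridded": {"x", "density"},
}


def _require(mapping: dict, keys: set[str], path: str, problems: list[str]) -> bool:
    missing = sorted(k for k in keys if k not in mapping)
    for k in missing:
        problems.append(f"{path}.{k}: missing required key")
    unknown = sorted(k for k in mapping if k not in keys)
    for k in unknown:
        problems.append(f"{path}.{k}: unknown key")
    return not missing and not unknown


def _efficacy(raw: Any, path: str, problems: list[str]) -> Efficacy | None:
    if not isinstance(raw, dict):
        problems.append(f"{path}: expected a mapping")
        return None
    variant = raw.get("variant")
    if variant not in _EFFICACY_KEYS:
        problems.append(
            f"{path}.variant: expected one of {sorted(_EFFICACY_KEYS)}, got {variant!r}"
        )
        return None
    if not _require(raw, _EFFICACY_KEYS[variant] | {"variant"}, path, problems):
        return None
    try:
        if variant == "dirac":
            return Efficacy.dirac(float(raw["mu"]))
        if variant == "normal":
            return Efficacy.normal(float(raw["mu"]), float(raw["sigma"]))
        if variant == "mixture":
            return heterogeneous_efficacy(
                [float(w) for w in raw["weights"]],
                [float(m) for m in raw["means"]],
                float(raw["sigma"]),
            )
        return Efficacy.gridded(
            np.asarray(raw["x"], dtype=float), np.asarray(raw["density"], dtype=float)
        )
    except (ValueError, TypeError) as exc:
        problems.append(f"{path}: {exc}")
        return None


def parse_config(path: str | Path) -> ScenarioConfig:
    """Load and fully validate a simulation configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["top level: expected a mapping"])

    problems: list[str] = []
    _require(raw, {"name", "population", "phases", "output"}, "top level", problems)

    pop = raw.get("population")
    if isinstance(pop, dict):
        _require(
            pop,
            {"n_init", "division_rate", "death_rate", "truncation_order"},
            "population",
            problems,
        )
    elif pop is not None:
        problems.append("population: expected a mapping")

    durations: list[float] = []
    efficacies: list[Efficacy] = []
    phases = raw.get("phases")
    if isinstance(phases, list) and phases:
        for j, ph in enumerate(phases):
            ppath = f"phases[{j}]"
            if not isinstance(ph, dict):
                problems.append(f"{ppath}: expected a mapping")
                continue
            if not _require(ph, {"duration_d", "efficacy"}, ppath, problems):
                continue
            try:
                d = float(ph["duration_d"])
                if d <= 0:
                    raise ValueError("must be positive")
                durations.append(d)
            except (TypeError, ValueError) as exc:
                problems.append(f"{ppath}.duration_d: {exc}")
            eff = _efficacy(ph["efficacy"], f"{ppath}.efficacy", problems)
            if eff is not None:
                efficacies.append(eff)
    elif phases is not None:
        problems.append("phases: expected a non-empty list")

    out = raw.get("output")
    grid = Grid()
    if isinstance(out, dict):
        _require(
            out,
            {"eval_times_d", "grid", "sample_size", "thresholds", "seed"},
            "output",
            problems,
        )
        g = out.get("grid")
        if isinstance(g, dict) and _require(
            g, {"x_min", "x_max", "n_points"}, "output.grid", problems
        ):
            try:
                grid = Grid(float(g["x_min"]), float(g["x_max"]), int(g["n_points"]))
            except (TypeError, ValueError) as exc:
                problems.append(f"output.grid: {exc}")
        elif g is not None and not isinstance(g, dict):
            problems.append("output.grid: expected a mapping")
    elif out is not None:
        problems.append("output: expected a mapping")

    if problems:
        raise ConfigError(problems)

    try:
        return ScenarioConfig(
            name=str(raw["name"]),
            n_init=float(pop["n_init"]),
            division_rate=float(pop["division_rate"]),
            death_rate=float(pop["death_rate"]),
            truncation_order=int(pop["truncation_order"]),
            phase_durations=tuple(durations),
            efficacies=tuple(efficacies),
            eval_times=tuple(float(t) for t in out["eval_times_d"]),
            grid=grid,
            sample_size=int(out["sample_size"]),
            thresholds=tuple(float(t) for t in out["thresholds"]),
            seed=int(out["seed"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError([str(exc)]) from exc


def _efficacy_to_raw(eff: Efficacy) -> dict:
    if eff.kind == "dirac":
        return {"variant": "dirac", "mu": float(eff.means[0])}
    if eff.kind == "normal":
        return {"variant": "normal", "mu": float(eff.means[0]), "sigma": float(eff.sds[0])}
    if eff.kind == "mixture":
        sig = set(float(s) for s in eff.sds)
        if len(sig) != 1:
            raise ValueError("config mixtures use a common sigma per phase")
        return {
            "variant": "mixture",
            "weights": [float(w) for w in eff.weights],
            "means": [float(m) for m in eff.means],
            "sigma": float(eff.sds[0]),
        }
    return {
        "variant": "gridded",
        "x": [float(v) for v in eff.grid_x],
        "density": [float(v) for v in eff.grid_f],
    }


def config_to_yaml(config: ScenarioConfig) -> str:
    """Canonical YAML serialization (round-trips through parse_config)."""
    raw = {
        "name": config.name,
        "population": {
            "n_init": float(config.n_init),
            "division_rate": float(config.division_rate),
            "death_rate": float(config.death_rate),
            "truncation_order": int(config.truncation_order),
        },
        "phases": [
            {"duration_d": float(d), "efficacy": _efficacy_to_raw(e)}
            for d, e in zip(config.phase_durations, config.efficacies)
        ],
        "output": {
            "eval_times_d": [float(t) for t in config.eval_times],
            "grid": {
                "x_min": float(config.grid.x_min),
                "x_max": float(config.grid.x_max),
                "n_points": int(config.grid.n),
            },
            "sample_size": int(config.sample_size),
            "thresholds": [float(t) for t in config.thresholds],
            "seed": int(config.seed),
        },
    }
    return yaml.safe_dump(raw, sort_keys=False)


def write_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(config_to_yaml(config))
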