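"""Built-in labeling scenarios and small test fixtures.

Two Results-style experiments are packaged: a noisy-uptake scenario
(normal labeling efficacy during uplabeling, pure dilution afterwards)
and a spatially heterogeneous scenario (two-compartment mixture
efficacy).  Both simulate a hypothetical population of 1000 cells with
equal division and death rates of 0.1 per day and a 10-day uplabeling
phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .label_content import (
    Efficacy,
    Grid,
    closed_form_normal,
    conditional_label_density,
    heterogeneous_efficacy,
)
from .population import RateModel, TimePartition, analytic_population_constant_rates

__all__ = [
    "ScenarioConfig",
    "scenario_noisy_uptake",
    "scenario_spatial_heterogeneity",
    "named_scenario",
    "SCENARIO_NAMES",
    "generate_fixture",
    "heterogeneity_division_densities",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, validated description of one simulation run."""

    name: str
    n_init: float
    division_rate: float
    death_rate: float
    truncation_order: int
    phase_durations: tuple[float, ...]
    efficacies: tuple[Efficacy, ...]
    eval_times: tuple[float, ...]
    grid: Grid
    sample_size: int
    thresholds: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.n_init <= 0:
            raise ValueError("n_init must be positive")
        if self.division_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.truncation_order < 1:
            raise ValueError("truncation order must be at least 1")
        if len(self.phase_durations) != len(self.efficacies):
            raise ValueError("one efficacy per phase required")
        self.partition()  # validates durations
        end = sum(self.phase_durations)
        if any(t < 0 or t > end for t in self.eval_times):
            raise ValueError(f"eval times must lie in [0, {end}]")
        if any(t2 <= t1 for t1, t2 in zip(self.eval_times, self.eval_times[1:])):
            raise ValueError("eval times must be strictly increasing")
        if self.sample_size < 1:
            raise ValueError("sample size must be at least 1")

    def partition(self) -> TimePartition:
        return TimePartition.from_durations(self.phase_durations)

    def rates(self) -> RateModel:
        return RateModel.constant(self.division_rate, self.death_rate)


def scenario_noisy_uptake() -> ScenarioConfig:
    """Noise in label uptake: normal efficacy (mu=1, sigma=0.2) for 10 days
    of uplabeling, then 10 days of delabeling (zero efficacy), sampled
    every 2 days."""
    return ScenarioConfig(
        name="noisy_uptake",
        n_init=1000.0,
        division_rate=0.1,
        death_rate=0.1,
        truncation_order=20,
        phase_durations=(10.0, 10.0),
        efficacies=(Efficacy.normal(1.0, 0.2), Efficacy.dirac(0.0)),
        eval_times=(2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0),
        grid=Grid(-0.5, 1.5, 2001),
        sample_size=10000,
        thresholds=(0.1,),
        seed=1,
    )


def scenario_spatial_heterogeneity() -> ScenarioConfig:
    """Two-compartment heterogeneous uptake: one third of divisions see half
    the labeling efficacy, (1/3) N(0.5, sigma^2) + (2/3) N(1, sigma^2)
    with sigma = 0.05, over 10 days of uplabeling."""
    return ScenarioConfig(
        name="spatial_heterogeneity",
        n_init=1000.0,
        division_rate=0.1,
        death_rate=0.1,
        truncation_order=20,
        phase_durations=(10.0,),
        efficacies=(heterogeneous_efficacy((1.0 / 3.0, 2.0 / 3.0), (0.5, 1.0), 0.05),),
        eval_times=(2.0, 4.0, 6.0, 8.0, 10.0),
        grid=Grid(-0.5, 1.5, 2001),
        sample_size=10000,
        thresholds=(0.1,),
        seed=1,
    )


SCENARIO_NAMES = ("noisy_uptake", "spatial_heterogeneity")


def named_scenario(name: str) -> ScenarioConfig:
    if name == "noisy_uptake":
        return scenario_noisy_uptake()
    if name == "spatial_heterogeneity":
        return scenario_spatial_heterogeneity()
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def heterogeneity_division_densities(
    config: ScenarioConfig | None = None, i_max: int = 7
):
    """Per-division-number content densities p(x|i_1) for the heterogeneous
    scenario's uplabeling phase, i_1 = 1..i_max."""
    config = config or scenario_spatial_heterogeneity()
    eff = config.efficacies[0]
    return {
        i: conditional_label_density((i,) + (0,) * (len(config.efficacies) - 1), config.efficacies)
        for i in range(1, i_max + 1)
    }


def generate_fixture(kind: str, seed: int = 0) -> tuple[ScenarioConfig, dict]:
    """Tiny scenario plus oracle-computed expectations for fast tests.

    kinds: ``dirac_toy`` (uniform uptake value — atom positions and
    scaled-Poisson weights), ``normal_toy`` (closed-form moments),
    ``mixture_toy`` (two-compartment moments).
    """
    if kind not in ("dirac_toy", "normal_toy", "mixture_toy"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    alpha = beta = 0.1
    n_init = 100.0
    S = 5
    eval_times = (1.0, 2.0, 3.0)
    if kind == "dirac_toy":
        eff = Efficacy.dirac(1.0)
    elif kind == "normal_toy":
        eff = Efficacy.normal(1.0, 0.2)
    else:
        eff = heterogeneous_efficacy((1.0 / 3.0, 2.0 / 3.0), (0.5, 1.0), 0.05)
    config = ScenarioConfig(
        name=kind,
        n_init=n_init,
        division_rate=alpha,
        death_rate=beta,
        truncation_order=S,
        phase_durations=(3.0,),
        efficacies=(eff,),
        eval_times=eval_times,
        grid=Grid(-0.5, 1.5, 2001),
        sample_size=1000,
        thresholds=(0.1,),
        seed=int(seed),
    )
    expected: dict = {"counts": {}, "atoms": {}, "moments": {}}
    for t in eval_times:
        expected["counts"][t] = {
            i: analytic_population_constant_rates(n_init, alpha, beta, t, i)
            for i in range(S + 1)
        }
    if kind == "dirac_toy":
        # uniform uptake: after i divisions the content is the exact value
        # (1 - 2^{-i}) * mu, a pure atom
        expected["atoms"] = {i: (1.0 - 2.0 ** (-i)) * 1.0 for i in range(S + 1)}
    if kind == "normal_toy":
        expected["moments"] = {i: closed_form_normal(i, 0, 1.0, 0.2) for i in range(S + 1)}
    if kind == "mixture_toy":
        mu_mix = eff.mean()  # 5/6
        expected["moments"] = {
            i: ((1.0 - 2.0 ** (-i)) * mu_mix, None) for i in range(S + 1)
        }
    return config, expected
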