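"""Reduced-size oracle self-checks, callable from the CLI.

Each check compares the production path against an independent oracle:
the constant-rate closed form for the population ODEs, the closed-form
normal moments for the dilution recursion, mass conservation with equal
division and death rates, and (unless skipped) the transport-equation
solver against the decomposed construction.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .assembly import overall_distribution, pde_reference_solver
from .label_content import (
    Efficacy,
    Grid,
    closed_form_normal,
    conditional_density_table,
    conditional_label_density,
)
from .population import (
    RateModel,
    TimePartition,
    analytic_population_constant_rates,
    solve_population,
)

__all__ = ["run_all"]


def run_all(fast: bool = False, echo: Callable[[str], None] = print) -> int:
    """Run all checks; returns the number of failures."""
    failures = 0

    def report(name: str, ok: bool, detail: str) -> None:
        nonlocal failures
        echo(f"[{'ok' if ok else 'FAIL'}] {name}: {detail}")
        if not ok:
            failures += 1

    # population solver vs constant-rate closed form
    design = TimePartition((0.0, 5.0))
    alpha = beta = 0.1
    S = 15
    state = solve_population(design, RateModel.constant(alpha, beta), 1000.0, S, [5.0])[0]
    errs = []
    for i in range(S):  # top bin differs by truncation design
        exact = analytic_population_constant_rates(1000.0, alpha, beta, 5.0, i)
        if exact > 1e-7 * 1000.0:
            errs.append(abs(state.count((i,)) - exact) / exact)
    worst = max(errs)
    report("ode-vs-closed-form", worst < 1e-6, f"max rel err {worst:.2e}")

    # conservation with alpha == beta
    tot = state.total()
    report("mass-conservation", abs(tot - 1000.0) < 1e-4 * 1000.0, f"total {tot:.6f}")

    # dilution recursion vs closed-form normal moments
    effs = (Efficacy.normal(1.0, 0.2), Efficacy.dirac(0.0))
    worst = 0.0
    for i1 in range(7):
        for i2 in range(4):
            d = conditional_label_density((i1, i2), effs)
            m, v = closed_form_normal(i1, i2, 1.0, 0.2)
            worst = max(worst, abs(d.mean() - m), abs(d.variance() - v))
    report("recursion-vs-closed-form", worst < 1e-10, f"max moment err {worst:.2e}")

    if not fast:
        # transport-equation solver vs decomposed construction
        design1 = TimePartition((0.0, 2.0))
        rates = RateModel.constant(0.1, 0.1)
        eff = (Efficacy.normal(1.0, 0.2),)
        grid = Grid(-0.5, 1.5, 301)
        S_pde = 3
        pde = pde_reference_solver(design1, rates, 1000.0, eff, S_pde, grid, [2.0])[0]
        states = solve_population(design1, rates, 1000.0, S_pde, [2.0])
        table = conditional_density_table(S_pde, eff)
        dec = overall_distribution(states[0], table, grid)
        sup = float(np.max(np.abs(pde.density - dec.density)))
        peak = float(dec.density.max())
        report("transport-vs-decomposed", sup < 1e-2 * peak, f"sup err {sup:.3g} vs peak {peak:.3g}")

    return failures
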