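"""Population-level label distribution and cytometry-style readouts.

The number density of cells with history i at label content x is the
product of the cell count and the conditional content density,

    n(x, i|t) = N(i|t) * p(x|i),

and summing over all (truncated) histories gives the overall label
distribution m(x|t) — the model's measurable output, in cells per unit
label content.  From it the classical summaries are computed exactly
(threshold fraction of labeled cells, mean fluorescence intensity),
per-cell intensity samples are drawn, and modes are counted.

A direct method-of-lines solver for the transport form of the same
dynamics (a PDE in t and x per history) is included purely as a
cross-validation oracle for the decomposed construction; the decomposed
ODE-plus-convolution route is the production path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks
from scipy.special import ndtr

from .label_content import (
    Efficacy,
    Grid,
    LabelDensity,
    _eval_gaussians,
    _merge_atoms,
)
from .population import PopulationState, RateModel, TimePartition, _index_vectors, _RateTable

__all__ = [
    "WeightedDensity",
    "OverallDistribution",
    "IntensitySample",
    "number_density",
    "overall_distribution",
    "pde_reference_solver",
    "fraction_labeled",
    "mean_intensity",
    "sample_intensities",
    "count_peaks",
    "find_modes",
]

_MASS_EPS = 1e-12


class WeightedDensity(NamedTuple):
    """A conditional density scaled to carry N(i|t) cells."""

    weight: float
    density: LabelDensity


@dataclass
class OverallDistribution:
    """m(x|t): cells per unit label content, gridded continuous part + atoms.

    When assembled from analytic conditional densities the aggregated
    Gaussian components are retained (comp_*), so summaries and samples
    are exact rather than grid-quadrature approximations.
    """

    time: float
    grid_x: np.ndarray
    density: np.ndarray
    atom_w: np.ndarray
    atom_x: np.ndarray
    comp_w: np.ndarray | None = None
    comp_mu: np.ndarray | None = None
    comp_sd: np.ndarray | None = None
    components: dict[tuple[int, ...], WeightedDensity] | None = None

    @property
    def analytic(self) -> bool:
        return self.comp_w is not None

    def total_mass(self) -> float:
        if self.analytic:
            cont = float(self.comp_w.sum())
        else:
            cont = float(np.trapezoid(self.density, self.grid_x))
        return cont + float(self.atom_w.sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_d": self.time, "x": self.grid_x, "density": self.density})

    def atom_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_d": self.time, "x": self.atom_x, "weight": self.atom_w})


@dataclass
class IntensitySample:
    """Simulated per-cell label intensities, mimicking a cytometry listmode."""

    intensities: np.ndarray
    threshold: float | None = None

    def fraction_above_threshold(self) -> float:
        if self.threshold is None:
            raise ValueError("no threshold set")
        return float(np.mean(self.intensities >= self.threshold))


def number_density(
    pop: PopulationState,
    densities: Mapping[tuple[int, ...], LabelDensity],
) -> dict[tuple[int, ...], WeightedDensity]:
    """n(x, i|t) = N(i|t) * p(x|i) for every populated history i."""
    out: dict[tuple[int, ...], WeightedDensity] = {}
    for i, count in pop.counts.items():
        if count <= _MASS_EPS:
            continue
        if i not in densities:
            raise ValueError(f"missing conditional label density for populated history i={i}")
        out[i] = WeightedDensity(count, densities[i])
    return out


def overall_distribution(
    pop: PopulationState,
    densities: Mapping[tuple[int, ...], LabelDensity],
    grid: Grid | None = None,
    keep_components: bool = False,
) -> OverallDistribution:
    """Assemble m(x|t) = sum_i N(i|t) p(x|i) over the truncated index set."""
    grid = grid or Grid()
    parts = number_density(pop, densities)
    all_analytic = all(wd.density.backend == "analytic" for wd in parts.values())

    aw_list: list[np.ndarray] = []
    ax_list: list[np.ndarray] = []
    if all_analytic:
        cw_list, cmu_list, csd_list = [], [], []
        for wd in parts.values():
            d = wd.density
            cw_list.append(wd.weight * d.gauss_w)
            cmu_list.append(d.gauss_mu)
            csd_list.append(d.gauss_sd)
            aw_list.append(wd.weight * d.atom_w)
            ax_list.append(d.atom_x)
        comp_w = np.concatenate(cw_list) if cw_list else np.empty(0)
        comp_mu = np.concatenate(cmu_list) if cmu_list else np.empty(0)
        comp_sd = np.concatenate(csd_list) if csd_list else np.empty(0)
        aw, axx = _merge_atoms(
            np.concatenate(aw_list) if aw_list else np.empty(0),
            np.concatenate(ax_list) if ax_list else np.empty(0),
        )
        density = _eval_gaussians(grid.x, comp_w, comp_mu, comp_sd)
        return OverallDistribution(
            time=pop.time,
            grid_x=grid.x,
            density=density,
            atom_w=aw,
            atom_x=axx,
            comp_w=comp_w,
            comp_mu=comp_mu,
            comp_sd=comp_sd,
            components=parts if keep_components else None,
        )

    density = np.zeros_like(grid.x)
    for wd in parts.values():
        g = wd.density if wd.density.backend == "gridded" else wd.density.to_gridded(grid)
        if not np.array_equal(g.grid_x, grid.x):
            g = g.to_gridded(grid)
        density += wd.weight * g.grid_f
        aw_list.append(wd.weight * g.atom_w)
        ax_list.append(g.atom_x)
    aw, axx = _merge_atoms(
        np.concatenate(aw_list) if aw_list else np.empty(0),
        np.concatenate(ax_list) if ax_list else np.empty(0),
    )
    return OverallDistribution(
        time=pop.time,
        grid_x=grid.x,
        density=density,
        atom_w=aw,
        atom_x=axx,
        components=parts if keep_components else None,
    )


def fraction_labeled(dist: OverallDistribution, l_theta: float) -> float:
    """Mass fraction at label content x >= l_theta (atoms treated exactly)."""
    if not math.isfinite(l_theta):
        raise ValueError("threshold must be finite")
    total = dist.total_mass()
    if total <= 0:
        raise ValueError("distribution carries no mass")
    tail = float(dist.atom_w[dist.atom_x >= l_theta].sum())
    if dist.analytic:
        if len(dist.comp_w):
            tail += float(
                np.sum(dist.comp_w * ndtr((dist.comp_mu - l_theta) / dist.comp_sd))
            )
    else:
        x, f = dist.grid_x, dist.density
        if l_theta <= x[0]:
            tail += float(np.trapezoid(f, x))
        elif l_theta < x[-1]:
            fl = float(np.interp(l_theta, x, f))
            mask = x > l_theta
            xs = np.concatenate([[l_theta], x[mask]])
            fs = np.concatenate([[fl], f[mask]])
            tail += float(np.trapezoid(fs, xs))
    return tail / total


def mean_intensity(dist: OverallDistribution) -> float:
    """Mean label content of the population (the MFI-style summary)."""
    total = dist.total_mass()
    if total <= 0:
        raise ValueError("distribution carries no mass")
    first = float(np.sum(dist.atom_w * dist.atom_x))
    if dist.analytic:
        first += float(np.sum(dist.comp_w * dist.comp_mu))
    else:
        first += float(np.trapezoid(dist.grid_x * dist.density, dist.grid_x))
    return first / total


def sample_intensities(
    dist: OverallDistribution,
    M: int,
    seed: int | np.random.Generator,
    threshold: float | None = None,
) -> IntensitySample:
    """M i.i.d. per-cell intensities from the normalized distribution.

    Component-wise mixture sampling (pick a Gaussian component or atom
    by weight, then draw), so analytic-backend samples are exact.
    """
    if M < 1:
        raise ValueError("sample size must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist.analytic:
        w = np.concatenate([dist.comp_w, dist.atom_w])
        idx = rng.choice(len(w), size=M, p=w / w.sum())
        vals = np.empty(M)
        ncomp = len(dist.comp_w)
        is_comp = idx < ncomp
        if is_comp.any():
            j = idx[is_comp]
            vals[is_comp] = dist.comp_mu[j] + dist.comp_sd[j] * rng.standard_normal(is_comp.sum())
        if (~is_comp).any():
            vals[~is_comp] = dist.atom_x[idx[~is_comp] - ncomp]
        return IntensitySample(vals, threshold)
    x, f = dist.grid_x, dist.density
    cont_mass = float(np.trapezoid(f, x))
    atom_mass = float(dist.atom_w.sum())
    total = cont_mass + atom_mass
    vals = np.empty(M)
    from_atom = rng.random(M) < (atom_mass / total if total > 0 else 0.0)
    n_atom = int(from_atom.sum())
    if n_atom:
        j = rng.choice(len(dist.atom_w), size=n_atom, p=dist.atom_w / atom_mass)
        vals[from_atom] = dist.atom_x[j]
    n_cont = M - n_atom
    if n_cont:
        cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2.0 * np.diff(x))])
        cdf /= cdf[-1]
        vals[~from_atom] = np.interp(rng.random(n_cont), cdf, x)
    return IntensitySample(vals, threshold)


def count_peaks(
    dist: OverallDistribution,
    min_prominence: float = 0.02,
    include_atoms: bool = True,
) -> int:
    """Number of modes of m(x|t).

    Strict local maxima of the continuous part whose prominence exceeds
    ``min_prominence`` times the global continuous maximum; atoms at
    distinct locations count as one mode each when ``include_atoms``.
    The undivided pool is a point mass at x = 0, so cytometry-style
    "peaks of the labeled distribution" are obtained with
    ``include_atoms=False``.
    """
    if min_prominence < 0:
        raise ValueError("min_prominence must be non-negative")
    n = len(find_modes(dist, min_prominence))
    total = dist.total_mass()
    if include_atoms:
        aw, _ = _merge_atoms(dist.atom_w, dist.atom_x)
        n += int(np.sum(aw > _MASS_EPS * max(total, 1.0)))
    if n == 0 and float(dist.density.max(initial=0.0)) == 0.0 and not len(dist.atom_w):
        raise ValueError("distribution is identically zero")
    return n


def find_modes(dist: OverallDistribution, min_prominence: float = 0.02) -> np.ndarray:
    """Label-axis locations of the continuous modes (same rule as count_peaks)."""
    f = dist.density
    peak = float(f.max(initial=0.0))
    if peak <= 0:
        if not len(dist.atom_w):
            raise ValueError("distribution is identically zero")
        return np.empty(0)
    idx, _ = find_peaks(f, prominence=min_prominence * peak)
    return dist.grid_x[idx]


# ---------------------------------------------------------------------------
# PDE cross-validation oracle
# ---------------------------------------------------------------------------


def pde_reference_solver(
    design: TimePartition,
    rates: RateModel,
    n_init: float,
    efficacies: Sequence[Efficacy],
    S: int,
    grid: Grid,
    eval_times: Sequence[float],
) -> list[OverallDistribution]:
    """Method-of-lines solver for the transport form of the number densities.

    Integrates, per history i on the label grid,

        dn(x,i)/dt = -(alpha_i + beta_i) n(x,i) + 4 alpha_{i-e_k} (p_eff^(k) * n(.,i-e_k))(2x)

    where * is ordinary convolution; the prefactor 4 combines the
    factor 2 from the change of variables (support halving) with the
    doubling of cells at division.  The overall distribution is
    assembled by summing over histories.  The undivided pool stays an
    exact point mass at x = 0 whose count follows its own scalar ODE;
    its influx into the first divided state is the closed form
    4 alpha N0(t) p_eff(2x).

    This is a verification oracle: smooth (non-atomic) efficacies only,
    small S, coarse grids.  Accuracy is O(dx^2) from the quadrature.
    """
    for e in efficacies:
        if e.is_atomic:
            raise ValueError("PDE oracle supports smooth (non-atomic) efficacies only")
    if len(efficacies) != design.n_phases:
        raise ValueError("one efficacy per phase required")
    if S < 1:
        raise ValueError("S must be at least 1")
    eval_times = [float(t) for t in eval_times]
    if any(t2 <= t1 for t1, t2 in zip(eval_times, eval_times[1:])):
        raise ValueError("eval_times must be strictly increasing")

    K = design.n_phases
    index = _index_vectors(S, K)
    nz_index = [i for i in index if any(i)]
    pos = {i: j for j, i in enumerate(nz_index)}
    table = _RateTable(rates, index)
    rate_pos = {i: j for j, i in enumerate(index)}

    x, dx, n = grid.x, grid.dx, grid.n
    conv_x = 2.0 * x[0] + dx * np.arange(2 * n - 1)
    eff_grid = []
    eff_at_2x = []
    for e in efficacies:
        eff_grid.append(_efficacy_pdf(e, x))
        eff_at_2x.append(_efficacy_pdf(e, 2.0 * x))

    n_states = len(nz_index)
    y0 = np.zeros(1 + n_states * n)
    y0[0] = float(n_init)

    results: list[OverallDistribution] = []

    def assemble(t: float, y: np.ndarray) -> OverallDistribution:
        dens = y[1:].reshape(n_states, n).sum(axis=0)
        return OverallDistribution(
            time=t,
            grid_x=x,
            density=np.clip(dens, 0.0, None),
            atom_w=np.array([max(y[0], 0.0)]),
            atom_x=np.array([0.0]),
        )

    if eval_times and eval_times[0] == 0.0:
        results.append(assemble(0.0, y0))

    zero = (0,) * K
    y = y0
    for k in range(1, K + 1):
        a, b = design.boundaries[k - 1], design.boundaries[k]
        ax = k - 1
        targets = [t for t in eval_times if a < t <= b]
        peffg = eff_grid[ax]
        peff2x = eff_at_2x[ax]

        def rhs(t: float, yv: np.ndarray) -> np.ndarray:
            alpha, beta = table.arrays(t)
            dy = np.empty_like(yv)
            N0 = yv[0]
            a0, b0 = alpha[rate_pos[zero]], beta[rate_pos[zero]]
            dy[0] = -(a0 + b0) * N0
            nd = yv[1:].reshape(n_states, n)
            out = np.empty_like(nd)
            for i, j in pos.items():
                ai = alpha[rate_pos[i]]
                bi = beta[rate_pos[i]]
                loss = (ai + bi) if i[ax] < S else bi  # top bin: no division outflux
                d = -loss * nd[j]
                if i[ax] >= 1:
                    prev = list(i)
                    prev[ax] -= 1
                    prev_t = tuple(prev)
                    a_prev = alpha[rate_pos[prev_t]]
                    if prev_t == zero:
                        d = d + 4.0 * a_prev * N0 * peff2x
                    else:
                        full = np.convolve(peffg, nd[pos[prev_t]]) * dx
                        d = d + 4.0 * a_prev * np.interp(2.0 * x, conv_x, full, left=0.0, right=0.0)
                out[j] = d
            dy[1:] = out.ravel()
            return dy

        t_eval = sorted(set(targets) | {b})
        sol = solve_ivp(rhs, (a, b), y, method="RK45", t_eval=t_eval, rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"PDE integration failed in phase {k}: {sol.message}")
        for col, t in zip(sol.y.T, sol.t):
            if t in targets:
                results.append(assemble(float(t), col))
        y = sol.y[:, -1].copy()

    return results


def _efficacy_pdf(eff: Efficacy, pts: np.ndarray) -> np.ndarray:
    if eff.kind == "gridded":
        return np.interp(pts, eff.grid_x, eff.grid_f, left=0.0, right=0.0)
    return _eval_gaussians(pts, eff.weights, eff.means, eff.sds)
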