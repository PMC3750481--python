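"""Label content of a cell conditional on its division history.

At each division a daughter cell keeps half of its mother's label (old
DNA strands split roughly evenly across daughters) and gains half of a
fresh uptake ``U`` drawn from the phase's labeling-efficacy
distribution:

    X(i+1) = U/2 + X(i)/2,     X(0) = 0.

During delabeling the efficacy is a point mass at zero, so the content
simply halves per division.  This module represents efficacy
distributions (point mass, normal, normal mixture, gridded), applies
the one-division update by support-halving plus convolution, and
provides the closed form for the normal-uplabeling / delabeling case:

    X(i1, i2) ~ Normal( (1 - 2^{-i1}) 2^{-i2} mu,
                        2^{-2 i2} sigma^2 * sum_{j=1..i1} 2^{-2j} ).

Two backends are available.  The analytic backend carries densities as
weighted Gaussian components plus symbolic point masses (atoms), closed
under the update; mixtures are kept tractable by merging components
whose means nearly coincide.  The gridded backend works on a fixed
label axis and convolves numerically; atoms stay symbolic there too, so
delabeling never needs grid refinement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Grid",
    "Efficacy",
    "LabelDensity",
    "one_division_update",
    "conditional_label_density",
    "conditional_density_table",
    "closed_form_normal",
    "heterogeneous_efficacy",
    "simulate_label_content",
    "l1_distance",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)
_WEIGHT_FLOOR = 1e-12
_DEFAULT_MERGE_TOL = 2.5e-4
_ATOM_TOL = 1e-12


@dataclass(frozen=True)
class Grid:
    """Uniform label axis for gridded densities (fluorescence-equivalent units)."""

    x_min: float = -0.5
    x_max: float = 1.5
    n: int = 2001

    def __post_init__(self) -> None:
        if self.n < 3 or self.x_max <= self.x_min:
            raise ValueError("grid needs x_max > x_min and at least 3 points")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / (self.n - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n)


def _as_prob_weights(weights: Sequence[float], tol: float = 1e-9) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    return w


class Efficacy:
    """Labeling-efficacy distribution of the per-division uptake U.

    Units are normalized so that full expected uptake is mu = 1.
    Analytic variants are mixtures of Gaussian components; sd = 0 marks
    a point mass.  A gridded variant carries an arbitrary density
    sampled on a label axis.
    """

    def __init__(
        self,
        kind: str,
        weights: Sequence[float] = (),
        means: Sequence[float] = (),
        sds: Sequence[float] = (),
        grid_x: np.ndarray | None = None,
        grid_f: np.ndarray | None = None,
    ):
        self.kind = kind
        self.weights = np.asarray(weights, dtype=float)
        self.means = np.asarray(means, dtype=float)
        self.sds = np.asarray(sds, dtype=float)
        self.grid_x = None if grid_x is None else np.asarray(grid_x, dtype=float)
        self.grid_f = None if grid_f is None else np.asarray(grid_f, dtype=float)
        if kind != "gridded":
            self.weights = _as_prob_weights(self.weights)
            if np.any(self.sds < 0):
                raise ValueError("sigma must be non-negative")
            if not (len(self.weights) == len(self.means) == len(self.sds)):
                raise ValueError("weights, means, sds must have equal length")
        else:
            if self.grid_x is None or self.grid_f is None:
                raise ValueError("gridded efficacy needs grid_x and grid_f")
            if np.any(self.grid_f < 0):
                raise ValueError("gridded density must be non-negative")
            mass = float(np.trapezoid(self.grid_f, self.grid_x))
            if abs(mass - 1.0) > 1e-6:
                raise ValueError(f"gridded density must integrate to 1 (got {mass!r})")

    # -- constructors ----------------------------------------------------
    @classmethod
    def dirac(cls, mu: float) -> "Efficacy":
        """Uniform labeling value (the classical single-uptake-value model)."""
        return cls("dirac", (1.0,), (float(mu),), (0.0,))

    @classmethod
    def normal(cls, mu: float, sigma: float) -> "Efficacy":
        return cls("normal", (1.0,), (float(mu),), (float(sigma),))

    @classmethod
    def mixture(
        cls, weights: Sequence[float], means: Sequence[float], sds: Sequence[float]
    ) -> "Efficacy":
        return cls("mixture", tuple(weights), tuple(means), tuple(sds))

    @classmethod
    def gridded(cls, x: Sequence[float], density: Sequence[float]) -> "Efficacy":
        return cls("gridded", grid_x=np.asarray(x), grid_f=np.asarray(density))

    # -- properties ------------------------------------------------------
    @property
    def is_atomic(self) -> bool:
        """True if any probability mass sits in a point component."""
        return self.kind != "gridded" and bool(np.any(self.sds == 0))

    def mean(self) -> float:
        if self.kind == "gridded":
            return float(np.trapezoid(self.grid_x * self.grid_f, self.grid_x))
        return float(np.sum(self.weights * self.means))

    def variance(self) -> float:
        if self.kind == "gridded":
            m = self.mean()
            return float(np.trapezoid((self.grid_x - m) ** 2 * self.grid_f, self.grid_x))
        m = self.mean()
        second = np.sum(self.weights * (self.means**2 + self.sds**2))
        return float(second - m**2)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "gridded":
            cdf = np.concatenate(
                [[0.0], np.cumsum((self.grid_f[1:] + self.grid_f[:-1]) / 2.0 * np.diff(self.grid_x))]
            )
            cdf /= cdf[-1]
            return np.interp(rng.random(size), cdf, self.grid_x)
        idx = rng.choice(len(self.weights), size=size, p=self.weights / self.weights.sum())
        return self.means[idx] + self.sds[idx] * rng.standard_normal(size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Efficacy):
            return NotImplemented
        if self.kind != other.kind:
            return False
        if self.kind == "gridded":
            return np.array_equal(self.grid_x, other.grid_x) and np.array_equal(
                self.grid_f, other.grid_f
            )
        return (
            np.array_equal(self.weights, other.weights)
            and np.array_equal(self.means, other.means)
            and np.array_equal(self.sds, other.sds)
        )

    def __repr__(self) -> str:
        if self.kind == "gridded":
            return f"Efficacy(gridded, {len(self.grid_x)} pts)"
        parts = ", ".join(
            f"{w:.3g}*N({m:.3g},{s:.3g}^2)" if s > 0 else f"{w:.3g}*d({m:.3g})"
            for w, m, s in zip(self.weights, self.means, self.sds)
        )
        return f"Efficacy({self.kind}: {parts})"


def heterogeneous_efficacy(
    weights: Sequence[float], means: Sequence[float], sigma: float
) -> Efficacy:
    """Spatial-compartment mixture: sum_j w_j Normal(mean_j, sigma^2).

    Models cell divisions occurring in compartments (organs, tissues)
    with different local label concentration but a common within-
    compartment spread sigma.
    """
    w = _as_prob_weights(weights)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return Efficacy.mixture(tuple(w), tuple(float(m) for m in means), (float(sigma),) * len(w))


class LabelDensity:
    """Probability density of label content X(i) given a division history.

    Either analytic — weighted Gaussian components plus point masses
    (atoms) — or gridded — values on a label axis plus atoms.  Atoms are
    always symbolic: (weight, location) pairs that are never smeared
    onto the grid.
    """

    def __init__(
        self,
        *,
        gauss_w: Sequence[float] = (),
        gauss_mu: Sequence[float] = (),
        gauss_sd: Sequence[float] = (),
        atom_w: Sequence[float] = (),
        atom_x: Sequence[float] = (),
        grid_x: np.ndarray | None = None,
        grid_f: np.ndarray | None = None,
        condition: tuple[int, ...] | None = None,
    ):
        self.gauss_w = np.asarray(gauss_w, dtype=float)
        self.gauss_mu = np.asarray(gauss_mu, dtype=float)
        self.gauss_sd = np.asarray(gauss_sd, dtype=float)
        self.atom_w = np.asarray(atom_w, dtype=float)
        self.atom_x = np.asarray(atom_x, dtype=float)
        self.grid_x = None if grid_x is None else np.asarray(grid_x, dtype=float)
        self.grid_f = None if grid_f is None else np.asarray(grid_f, dtype=float)
        self.condition = None if condition is None else tuple(int(v) for v in condition)
        if np.any(self.gauss_sd <= 0):
            raise ValueError("gaussian components need sd > 0 (use atoms for sd = 0)")

    @property
    def backend(self) -> str:
        return "gridded" if self.grid_x is not None else "analytic"

    @classmethod
    def delta(cls, loc: float = 0.0, condition: tuple[int, ...] | None = None) -> "LabelDensity":
        """Pure point mass — the undivided cell's zero label content for loc=0."""
        return cls(atom_w=(1.0,), atom_x=(float(loc),), condition=condition)

    # -- scalar summaries ------------------------------------------------
    def total_mass(self) -> float:
        cont = 0.0
        if self.backend == "gridded":
            cont = float(np.trapezoid(self.grid_f, self.grid_x))
        else:
            cont = float(self.gauss_w.sum())
        return cont + float(self.atom_w.sum())

    def mean(self) -> float:
        if self.backend == "gridded":
            cont = float(np.trapezoid(self.grid_x * self.grid_f, self.grid_x))
        else:
            cont = float(np.sum(self.gauss_w * self.gauss_mu))
        return (cont + float(np.sum(self.atom_w * self.atom_x))) / self.total_mass()

    def variance(self) -> float:
        if self.backend == "gridded":
            second = float(np.trapezoid(self.grid_x**2 * self.grid_f, self.grid_x))
        else:
            second = float(np.sum(self.gauss_w * (self.gauss_mu**2 + self.gauss_sd**2)))
        second += float(np.sum(self.atom_w * self.atom_x**2))
        m = self.mean()
        return second / self.total_mass() - m**2

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Continuous part of the density evaluated at x (atoms excluded)."""
        x = np.asarray(x, dtype=float)
        if self.backend == "gridded":
            return np.interp(x, self.grid_x, self.grid_f, left=0.0, right=0.0)
        return _eval_gaussians(x, self.gauss_w, self.gauss_mu, self.gauss_sd)

    def to_gridded(self, grid: Grid) -> "LabelDensity":
        """Sample the continuous part on a grid; atoms stay symbolic."""
        if self.backend == "gridded":
            f = np.interp(grid.x, self.grid_x, self.grid_f, left=0.0, right=0.0)
            return LabelDensity(
                grid_x=grid.x, grid_f=f, atom_w=self.atom_w, atom_x=self.atom_x,
                condition=self.condition,
            )
        _check_grid_resolution(self.gauss_sd, grid)
        f = _eval_gaussians(grid.x, self.gauss_w, self.gauss_mu, self.gauss_sd)
        return LabelDensity(
            grid_x=grid.x, grid_f=f, atom_w=self.atom_w, atom_x=self.atom_x,
            condition=self.condition,
        )

    def truncated_at_zero(self, grid: Grid | None = None) -> "LabelDensity":
        """Optional non-negativity clamp: drop mass at x < 0 and renormalize.

        The model itself keeps untruncated normals (a small negative-x
        mass is part of the closed forms); this helper is for users who
        want a physical non-negative readout.
        """
        g = self if self.backend == "gridded" else self.to_gridded(grid or Grid())
        f = np.where(g.grid_x < 0, 0.0, g.grid_f)
        keep = g.atom_x >= 0
        mass = float(np.trapezoid(f, g.grid_x)) + float(g.atom_w[keep].sum())
        if mass <= 0:
            raise ValueError("no mass at x >= 0")
        return LabelDensity(
            grid_x=g.grid_x, grid_f=f / mass,
            atom_w=g.atom_w[keep] / mass, atom_x=g.atom_x[keep],
            condition=self.condition,
        )

    def __repr__(self) -> str:
        if self.backend == "gridded":
            body = f"gridded[{len(self.grid_x)}]"
        else:
            body = f"{len(self.gauss_w)} gaussians"
        return f"LabelDensity({body}, {len(self.atom_w)} atoms, i={self.condition})"


def _eval_gaussians(
    x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray, chunk: int = 256
) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for s in range(0, len(w), chunk):
        wc, mc, sc = w[s : s + chunk], mu[s : s + chunk], sd[s : s + chunk]
        z = (x[:, None] - mc[None, :]) / sc[None, :]
        out += np.sum(wc[None, :] / (sc[None, :] * _SQRT2PI) * np.exp(-0.5 * z**2), axis=1)
    return out


def _check_grid_resolution(sds: np.ndarray, grid: Grid) -> None:
    if len(sds) and float(np.min(sds)) < 2.0 * grid.dx:
        raise ValueError(
            f"grid too coarse: component sd {float(np.min(sds)):.3g} < 2*dx = "
            f"{2 * grid.dx:.3g}; refine the grid (smaller dx) or use the analytic backend"
        )


def _merge_gaussians(
    w: np.ndarray, mu: np.ndarray, sd: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coalesce components with (numerically) equal sd and nearby means.

    Keeps total mass and the first moment exact; the second moment is
    perturbed by at most tol^2 per merge, far below grid resolution.
    """
    keep = w > _WEIGHT_FLOOR
    if not np.all(keep):
        lost = float(w[~keep].sum())
        w, mu, sd = w[keep], mu[keep], sd[keep]
        if len(w):
            w = w * (1.0 + lost / w.sum())  # return dropped dust to preserve mass
    if tol <= 0 or len(w) < 2:
        return w, mu, sd
    order = np.lexsort((mu, np.round(sd, 12)))
    w, mu, sd = w[order], mu[order], sd[order]
    out_w: list[float] = []
    out_mu: list[float] = []
    out_sd: list[float] = []
    cw, cm, cs, c0 = w[0], mu[0], sd[0], mu[0]
    for j in range(1, len(w)):
        same_sd = abs(sd[j] - cs) <= 1e-12 + 1e-9 * cs
        if same_sd and mu[j] - c0 <= tol:
            tot = cw + w[j]
            cm = (cw * cm + w[j] * mu[j]) / tot
            cw = tot
        else:
            out_w.append(cw), out_mu.append(cm), out_sd.append(cs)
            cw, cm, cs, c0 = w[j], mu[j], sd[j], mu[j]
    out_w.append(cw), out_mu.append(cm), out_sd.append(cs)
    return np.asarray(out_w), np.asarray(out_mu), np.asarray(out_sd)


def _merge_atoms(w: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(w) < 2:
        return w, x
    order = np.argsort(x)
    w, x = w[order], x[order]
    out_w, out_x = [w[0]], [x[0]]
    for j in range(1, len(w)):
        if abs(x[j] - out_x[-1]) <= _ATOM_TOL:
            out_w[-1] += w[j]
        else:
            out_w.append(w[j])
            out_x.append(x[j])
    return np.asarray(out_w), np.asarray(out_x)


def one_division_update(
    prior: LabelDensity,
    eff: Efficacy,
    *,
    merge_tol: float = _DEFAULT_MERGE_TOL,
    grid: Grid | None = None,
) -> LabelDensity:
    """Density of X' = U/2 + X/2 with U ~ eff independent of X ~ prior.

    Both supports are halved (Gaussian components: mean and sd halved;
    atoms: location halved) and the results convolved — in closed form
    for the analytic backend, numerically for the gridded one.
    """
    if prior.backend == "analytic" and eff.kind != "gridded":
        return _analytic_update(prior, eff, merge_tol)
    return _gridded_update(prior, eff, grid)


def _analytic_update(prior: LabelDensity, eff: Efficacy, merge_tol: float) -> LabelDensity:
    # prior components: gaussians followed by atoms (sd = 0)
    pw = np.concatenate([prior.gauss_w, prior.atom_w])
    pm = np.concatenate([prior.gauss_mu, prior.atom_x])
    ps = np.concatenate([prior.gauss_sd, np.zeros_like(prior.atom_w)])
    uw, um, us = eff.weights, eff.means, eff.sds

    w = (uw[:, None] * pw[None, :]).ravel()
    mu = 0.5 * (um[:, None] + pm[None, :]).ravel()
    sd = 0.5 * np.hypot(us[:, None], ps[None, :]).ravel()

    is_atom = sd == 0.0
    aw, axx = _merge_atoms(w[is_atom], mu[is_atom])
    gw, gmu, gsd = _merge_gaussians(w[~is_atom], mu[~is_atom], sd[~is_atom], merge_tol)
    return LabelDensity(gauss_w=gw, gauss_mu=gmu, gauss_sd=gsd, atom_w=aw, atom_x=axx)


def _halve_support(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Density of X/2 sampled on the same grid: 2 f(2x)."""
    return 2.0 * np.interp(2.0 * x, x, f, left=0.0, right=0.0)


def _shift(x: np.ndarray, f: np.ndarray, loc: float) -> np.ndarray:
    return np.interp(x - loc, x, f, left=0.0, right=0.0)


def _halved_efficacy_on_grid(
    eff: Efficacy, grid: Grid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(density of U/2 on grid, atom weights, halved atom locations).

    The halved continuous part 2 p_eff(2x) is evaluated from the
    efficacy's own representation, so efficacy mass beyond the grid's
    doubled span is not clipped.
    """
    if eff.kind == "gridded":
        f = 2.0 * np.interp(2.0 * grid.x, eff.grid_x, eff.grid_f, left=0.0, right=0.0)
        return f, np.empty(0), np.empty(0)
    cont = eff.sds > 0
    _check_grid_resolution(eff.sds[cont] / 2.0, grid)
    f = 2.0 * _eval_gaussians(2.0 * grid.x, eff.weights[cont], eff.means[cont], eff.sds[cont])
    return f, eff.weights[~cont], 0.5 * eff.means[~cont]


def _gridded_update(prior: LabelDensity, eff: Efficacy, grid: Grid | None) -> LabelDensity:
    if grid is None:
        if prior.backend == "gridded":
            x = prior.grid_x
            grid = Grid(float(x[0]), float(x[-1]), len(x))
        else:
            grid = Grid()
    gp = prior if prior.backend == "gridded" else prior.to_gridded(grid)
    if not np.array_equal(gp.grid_x, grid.x):
        gp = gp.to_gridded(grid)

    x, dx = grid.x, grid.dx
    # halve every support first (exact re-grid), then plain convolution
    pc = _halve_support(x, gp.grid_f)
    ec, eaw2, eax2 = _halved_efficacy_on_grid(eff, grid)
    paw, pax = gp.atom_w, 0.5 * gp.atom_x

    cont = np.zeros_like(x)
    if pc.any() and ec.any():
        full = np.convolve(ec, pc) * dx
        conv_x = 2.0 * x[0] + dx * np.arange(len(full))
        cont += np.interp(x, conv_x, full, left=0.0, right=0.0)
    for wgt, loc in zip(eaw2, eax2):
        if pc.any():
            cont += wgt * _shift(x, pc, loc)
    for wgt, loc in zip(paw, pax):
        if ec.any():
            cont += wgt * _shift(x, ec, loc)
    aw = (eaw2[:, None] * paw[None, :]).ravel()
    axx = (eax2[:, None] + pax[None, :]).ravel()
    aw, axx = _merge_atoms(aw, axx)
    return LabelDensity(grid_x=x, grid_f=cont, atom_w=aw, atom_x=axx)


def conditional_label_density(
    i: Sequence[int],
    efficacies: Sequence[Efficacy],
    *,
    backend: str = "analytic",
    grid: Grid | None = None,
    merge_tol: float = _DEFAULT_MERGE_TOL,
) -> LabelDensity:
    """p(x|i): label-content density after the division history i.

    Applies the one-division update i_1 times with the phase-1 efficacy,
    then i_2 times with the phase-2 efficacy, and so on, in
    chronological order starting from a point mass at zero.
    """
    i = tuple(int(v) for v in i)
    if len(efficacies) == 0:
        raise ValueError("need at least one phase efficacy")
    if len(i) != len(efficacies):
        raise ValueError(f"division vector length {len(i)} != number of phases {len(efficacies)}")
    if any(v < 0 for v in i):
        raise ValueError("division counts must be non-negative")
    dens = LabelDensity.delta(0.0)
    if backend == "gridded":
        dens = dens.to_gridded(grid or Grid())
    elif backend != "analytic":
        raise ValueError(f"unknown backend {backend!r}")
    for eff, ik in zip(efficacies, i):
        for _ in range(ik):
            dens = one_division_update(dens, eff, merge_tol=merge_tol, grid=grid)
    dens.condition = i
    return dens


def conditional_density_table(
    S: int,
    efficacies: Sequence[Efficacy],
    *,
    backend: str = "analytic",
    grid: Grid | None = None,
    merge_tol: float = _DEFAULT_MERGE_TOL,
) -> dict[tuple[int, ...], LabelDensity]:
    """p(x|i) for every i in {0..S}^K, built incrementally along the lattice.

    Exploits that appending one division to history i applies a single
    update to p(x|i), so the whole table costs one update per entry.
    """
    K = len(efficacies)
    if K == 0:
        raise ValueError("need at least one phase efficacy")
    table: dict[tuple[int, ...], LabelDensity] = {}
    base = LabelDensity.delta(0.0, condition=(0,) * K)
    if backend == "gridded":
        base = base.to_gridded(grid or Grid())
    table[(0,) * K] = base

    for i in itertools.product(range(S + 1), repeat=K):
        if i in table:
            continue
        # last chronologically-applied division: highest phase with i_k > 0
        k = max(j for j in range(K) if i[j] > 0)
        prev = list(i)
        prev[k] -= 1
        dens = one_division_update(
            table[tuple(prev)], efficacies[k], merge_tol=merge_tol, grid=grid
        )
        dens.condition = i
        table[i] = dens
    return table


def closed_form_normal(i1: int, i2: int, mu: float, sigma: float) -> tuple[float, float]:
    """Mean and variance of X after i1 normal-efficacy uplabeling divisions
    followed by i2 delabeling divisions.

    mean = (1 - 2^{-i1}) 2^{-i2} mu;
    variance = 2^{-2 i2} sigma^2 sum_{j=1..i1} 2^{-2j}.  The delabeling
    scaling enters the variance as 2^{-2 i2}: halving a random variable
    i2 times scales its variance by 4^{-i2}.
    """
    if i1 < 0 or i2 < 0:
        raise ValueError("division counts must be non-negative")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    mean = (1.0 - 2.0 ** (-i1)) * 2.0 ** (-i2) * mu
    # sum_{j=1..i1} 4^{-j} = (1 - 4^{-i1}) / 3
    var = 4.0 ** (-i2) * sigma**2 * (1.0 - 4.0 ** (-i1)) / 3.0
    return mean, var


def simulate_label_content(
    i: Sequence[int],
    efficacies: Sequence[Efficacy],
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo draws of X(i) straight from the recursion X <- U/2 + X/2.

    Independent of the density machinery; used as a cross-check oracle.
    """
    i = tuple(int(v) for v in i)
    if len(i) != len(efficacies):
        raise ValueError("division vector and efficacy list length mismatch")
    x = np.zeros(size)
    for eff, ik in zip(efficacies, i):
        for _ in range(ik):
            x = 0.5 * eff.sample(rng, size) + 0.5 * x
    return x


def l1_distance(a: LabelDensity, b: LabelDensity, grid: Grid | None = None) -> float:
    """Integral of |a - b| over the label axis (continuous parts + atoms)."""
    grid = grid or Grid()
    ga, gb = a.to_gridded(grid), b.to_gridded(grid)
    d = float(np.trapezoid(np.abs(ga.grid_f - gb.grid_f), grid.x))
    locs = np.unique(np.concatenate([ga.atom_x, gb.atom_x]))
    for loc in locs:
        wa = float(ga.atom_w[np.abs(ga.atom_x - loc) <= _ATOM_TOL].sum())
        wb = float(gb.atom_w[np.abs(gb.atom_x - loc) <= _ATOM_TOL].sum())
        d += abs(wa - wb)
    return d
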