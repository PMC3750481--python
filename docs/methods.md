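# Methods

## Model

`brdusim` composes two sub-models and a product rule.

**Division-structured population.**  Cell counts `N(i|t)` are indexed by
the vector `i = (i_1, …, i_K)` of divisions undergone during each of K
experimental phases `(T_{k-1}, T_k]` (phase 1 contains t = 0).  During
phase k only `i_k` can change; divisions at rate `α_i(t)` double the
cells and advance `i_k`, deaths at rate `β_i(t)` remove them:

    dN(i|t)/dt = −(α_i + β_i) N(i|t) + 2 α_{i−e_k} N(i−e_k|t).

The system is linear; with constant rates and one phase the solution is
a scaled Poisson ladder `N(i|t) = n_init (2αt)^i/i! · e^{−(α+β)t}`,
which the package carries as an independent test oracle.

**Label content.**  At division, a daughter keeps half of the mother's
label (old DNA strands split almost evenly across daughters given the
dozens of chromosomes involved) and gains half of a fresh uptake `U`
drawn from the phase's labeling-efficacy distribution `p_eff^(k)`:

    X(i+1) = U/2 + X(i)/2,  X(0) = 0.

Delabeling is the special case `p_eff = δ(0)` (pure halving); a point
mass `δ(x−μ)` recovers the classical uniform-uptake models.  The
conditional density `p(x|i)` is built by applying the one-division
update — halve both supports, then convolve — for all phase-1 divisions,
then phase-2, and so on, in chronological order.  Order matters *across*
phases (later divisions multiply earlier uptakes by extra ½ factors) but
not within a phase, where the uptakes are i.i.d.  For a normal
uplabeling efficacy `N(μ, σ²)` followed by delabeling the result is a
single Gaussian with

    mean = (1 − 2^{−i1}) 2^{−i2} μ,
    var  = 2^{−2 i2} σ² Σ_{j=1..i1} 2^{−2j}.

The delabeling factor in the variance is `2^{−2 i2}`: scaling a random
variable by `2^{−i2}` scales its variance by `4^{−i2}`.  This is
verified both against composed one-division updates (agreement to
1e-10) and against direct Monte-Carlo simulation of the recursion.

**Assembly.**  The number density is `n(x, i|t) = N(i|t) p(x|i)`, and
the overall label distribution is the truncated sum
`m(x|t) = Σ_{i∈{0..S}^K} N(i|t) p(x|i)`, in cells per unit label
content.  Summaries: fraction of cells at `x ≥ l_θ` (computed exactly
from Gaussian tail functions and atom weights, never by smearing atoms
onto the grid), mean intensity (first moment), mode counts, and i.i.d.
per-cell intensity samples drawn by mixture sampling (component by
weight, then component draw — exact for the analytic backend).

## Tunable parameters

| parameter | units | default | why |
|---|---|---|---|
| `n_init` | cells | 1000 | built-in scenario population size |
| `α`, `β` | 1/day | 0.1 each | balanced turnover; total count constant |
| `S` (truncation) | divisions/phase | 20 | tail mass beyond S is < 1e-6 at day 10 under the defaults (measured by `truncation_error`) |
| efficacy `μ` | normalized label | 1 | full expected uptake defines the unit |
| efficacy `σ` | same | 0.2 (noisy) / 0.05 (heterogeneous) | scenario noise levels |
| mixture weights/means | — | (1/3, 2/3) at (0.5, 1) | one third of divisions in a half-efficacy compartment |
| label grid | — | x ∈ [−0.5, 1.5], 2001 points | efficacy means ≤ 1 and dilution shrinks support; dx = 1e-3 |
| uplabeling / delabeling duration | days | 10 / 10 | delabeling length and 2-day sampling chosen symmetric with uplabeling, which covers the qualitative claims |
| peak prominence | fraction of max | 0.02 | see below |

## Numerical choices

- **ODE integration**: interval-by-interval LSODA with rtol 1e-8,
  atol 1e-10; the terminal state of one phase seeds the next with no
  re-indexing.  Outputs are clipped at zero after a magnitude check
  (any count below −10·atol aborts).  States below ~1e-7 of the initial
  population carry absolute integrator error comparable to their size;
  oracle comparisons therefore apply a mass floor.
- **Truncation semantics**: the top bin `i_k = S` keeps dying but its
  division outflux is dropped, so the truncated system slightly
  undercounts rather than distorts; consequently the top bin itself is
  not comparable to the untruncated closed form, while all bins below it
  are exact (the coupling is strictly one-directional up the ladder).
- **Atoms are symbolic** everywhere: (weight, location) pairs convolve
  by shift-and-scale and are never discretized, so delabeling and
  uniform-uptake scenarios need no grid refinement.
- **Analytic backend growth control**: a K-phase history with an
  m-component mixture efficacy has up to m^Σi Gaussian components.
  After each update, components with (numerically) equal sd whose means
  lie within 2.5e-4 (a quarter grid step) are coalesced by
  weight-averaging; mass and first moment are preserved exactly, the
  second moment to O(tol²).  Dirac/normal chains produce single
  components, so the closed-form equivalence checks are unaffected.
  The day-10 heterogeneous scenario stays near ~1.2e4 components.
- **Gridded backend**: supports are halved by exact re-gridding (the
  halved efficacy `2 p_eff(2x)` is evaluated from its analytic form, so
  no tail is clipped at the grid edge), then convolved discretely with
  dx scaling.  Densities whose halved component sd falls below two grid
  steps are rejected with guidance to refine the grid.
- **Negative support**: untruncated normal efficacies put a small mass
  at negative label content; the model keeps them untruncated (faithful
  to the closed forms).  `LabelDensity.truncated_at_zero()` is an
  optional clamp, off by default.
- **Transport (PDE) oracle**: method of lines on the label grid with

      ∂n(x,i)/∂t = −(α_i+β_i) n + 4 α_{i−e_k} (p_eff^(k) ⊛ n(·, i−e_k))(2x),

  where the prefactor 4 combines the change-of-variables factor with
  the doubling at division (the equivalence test, not typography, fixes
  it).  The undivided pool is a point mass that cannot live on a grid;
  it is carried as an exact scalar ODE whose influx into the first
  divided state is `4 α N_0(t) p_eff(2x)`.  Trapezoid-level quadrature
  makes the oracle O(dx²) accurate, which sets the 1e-2·peak
  equivalence tolerance; it accepts smooth efficacies only and is never
  the production path.

## Peak counting and its sensitivity

Modes of the continuous part of m(x|t) are strict local maxima with
prominence above a floor expressed as a fraction of the global
continuous maximum (default 0.02); point masses count separately, and
`include_atoms=False` gives the cytometry-style count of the *labeled*
structure, excluding the undivided zero-label spike.

For the noisy scenario (σ = 0.2) the counts are 1, 1, 2, 2, 2 at days
2, 4, 6, 8, 10.  Sensitivity (measured): the second mode is genuinely
shallow at its first appearance — prominence ≈ 2.4% of the maximum at
day 6, growing to ≈ 17% at day 8 — so the day-6 "two peaks" result
holds for floors below ≈ 0.024 and merges to one peak above that, while
days 8 and 10 are robust through a floor of 0.05.  The day-2/4 single
mode and the separated delabeling ladder (mode locations halving per
division, at intensities below ~0.1 by day 16) are insensitive over
floors 0.005–0.1.

## Heterogeneous-uptake scenario

With the two-compartment efficacy `(1/3) N(0.5, 0.05²) + (2/3)
N(1, 0.05²)`, the content density after one division has two clearly
separated modes (0.25 and 0.5), while densities for three and seven
divisions nearly coincide: on the default grid, `L1(p(x|3), p(x|7)) ≈
0.70` versus `L1(p(x|1), p(x|7)) ≈ 1.91` (the maximum possible L1
distance between two densities is 2).  The distance between the 3- and
7-division densities is moderate rather than tiny because at σ = 0.05
p(x|3) is a partially resolved 8-component comb while p(x|7) is smooth;
the tests assert the qualitative ordering (multimodal at one division;
3-vs-7 far closer than 1-vs-7) and this note records the measured
values rather than enforcing a threshold.

## What the generator emulates — and what it does not

The scenario machinery produces *model-exact* populations: a
deterministic ODE mass (not a stochastic birth–death realization),
label content with no detection noise, no background fluorescence, no
instrument compensation, and no label degradation other than dilution
by division.  Passing tests therefore demonstrate internal consistency
of the model chain (counts × content → distribution → summaries) and
its closed forms, not agreement with any experimental dataset; fitting
the predicted m(x|t) to measured histograms is out of scope.

## Known limitations

- Rates may depend on the full division-history vector, but all
  packaged scenarios use constants; time-varying rates are integrated
  but only lightly exercised.
- State space is dense over `{0..S}^K`: fine for K ≤ 3 (the solver
  warns beyond that), not designed for many-phase protocols.
- The PDE oracle is restricted to smooth efficacies and small S by
  construction.
- Unequal strand segregation between daughters is not modeled (the
  even-split approximation rests on the large chromosome number).
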