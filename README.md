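# brdusim

Simulation of the **full label-intensity distribution** of a proliferating
cell population in division-linked labeling experiments (BrdU-style DNA
labels, which are incorporated at cell division during an "uplabeling"
phase and diluted by halving per division once the label is withdrawn).

Classical analyses collapse cytometry readouts into the fraction of
labeled cells or a mean fluorescence intensity, and classical models
assume every division incorporates the same amount of label — which would
predict sharp, division-number-indexed peaks that real data do not show.
`brdusim` instead treats the per-division label uptake as a random
variable with an arbitrary *labeling-efficacy distribution*, and predicts
the whole population-level label distribution, so noisy or spatially
heterogeneous uptake can be studied quantitatively.

## Model

Cells are classified by the vector `i = (i_1, …, i_K)` of divisions
undergone during each experimental phase `(T_{k-1}, T_k]`.  Counts obey a
linear division-structured ODE system (division rate `α_i(t)`, death rate
`β_i(t)`; each division doubles the cells moving up one step in the
active coordinate):

```
dN(i|t)/dt = −(α_i(t) + β_i(t)) N(i|t) + 2 α_{i−e_k}(t) N(i−e_k|t)
```

with all `n_init` cells undivided at t = 0, truncated at a finite order
`S` per coordinate.  A cell's label content follows the dilution/uptake
recursion `X(i+1) = U/2 + X(i)/2`, `X(0) = 0`, where `U ~ p_eff^(k)` is
the phase's labeling efficacy; the conditional content density `p(x|i)`
is obtained by support-halving and convolution, in closed form for
normal / point-mass / mixture efficacies.  The measurable output is the
overall label distribution

```
m(x|t) = Σ_i N(i|t) · p(x|i)
```

from which threshold label fractions, mean intensities, mode counts and
per-cell intensity samples are computed.  An independent transport-form
(PDE) solver of the same dynamics is included purely as a
cross-validation oracle for the decomposed ODE × convolution route.

## Worked example

Run the built-in noisy-uptake scenario — 1000 cells, α = β = 0.1/d,
10 days of uplabeling with efficacy N(1, 0.2²) followed by 10 days of
delabeling — from the shell:

```
brdusim scenario --name noisy_uptake --outdir out/
```

or from Python:

```python
from brdusim import scenario_noisy_uptake, count_peaks, mean_intensity
from brdusim.run import simulate_distributions

dists = simulate_distributions(scenario_noisy_uptake())
for d in dists[:5]:
    print(d.time, round(d.total_mass(), 4), round(mean_intensity(d), 4),
          count_peaks(d, 0.02, include_atoms=False))
```

which prints

```
2.0  1000.0  0.1813  1
4.0  1000.0  0.3297  1
6.0  1000.0  0.4512  2
8.0  1000.0  0.5507  2
10.0 1000.0  0.6321  2
```

Total mass stays at 1000 cells because division and death balance; the
mean label content climbs as `1 − e^{−αt·…}`-style saturation of the
dilution ladder; and the distribution shows a single mode at days 2–4
but only two strongly overlapping modes at days 6–10 even though many
division numbers coexist — noisy uptake blurs the division-number
readout.  During delabeling the modes halve per division, producing
separated peaks only at very low intensities.

The CLI writes `population.csv` (counts per division vector),
`distribution.csv` / `atoms.csv` (continuous part and point masses of
m(x|t)), `samples.csv` (simulated per-cell intensities), `summaries.json`
and a `manifest.json` with checksums.  `brdusim simulate --config FILE`
runs user-written YAML configurations (schema in `brdusim/config.py`,
shipped examples in `brdusim/configs/`), and `brdusim check` runs the
oracle self-tests.

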