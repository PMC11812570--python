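# smolsensor

Quantitative analysis for single-molecule imaging of membrane lipid
signalling: when a fluorescent biosensor (or an endogenously tagged kinase)
is expressed at a handful of copies per cell, its plasma-membrane
recruitment appears in TIRF microscopy as discrete diffraction-limited
spots.  This package implements the full analysis chain for that regime:

* **Spot counting** — detection of diffraction-limited spots in TIRF
  frames (difference-of-Gaussians band-pass, local maxima, sub-pixel 2-D
  Gaussian fits) and conversion to densities per 100 µm² of membrane.
* **Multimer deconvolution** — the intensity distribution of *N* puncta is
  modelled as ρ(x) = (1/N) Σ_c A_c ρ_c(x), where ρ_c is the intensity
  distribution of a c-mer.  ρ_1 comes from a monomeric calibration
  construct; ρ_c is derived by axis scaling (ρ_c(x) = ρ_1(x/c)/c) or c-fold
  self-convolution.  The weights A_c/N are estimated by reduced-χ²
  minimisation on the simplex, answering "are these spots single
  molecules?"
* **Recruitment kinetics** — the rise-and-fall of membrane recruitment
  after stimulation is fitted with a two-phase cooperative (Hill) model

      F(t) = F_max · [ tⁿˢ/(tⁿˢ + τ_synⁿˢ) − tⁿᵈ/(tⁿᵈ + τ_degⁿᵈ) ],  t ≥ 0

  with rate constants k_syn = 1/τ_syn and k_deg = 1/τ_deg (min⁻¹) and
  residual-bootstrap confidence intervals.
* **Immunofluorescence gating** — Huang-threshold, watershed and
  label-Voronoi single-cell segmentation with a mean + 3 SD
  transfection-positivity gate, for checking that a tag or biosensor does
  not perturb downstream signalling.
* **Copy-number arithmetic** — densities → per-cell copies → ploidy-scaled
  totals → proteome fractions, and the optical crowding limit from the
  Airy disc area.
* **Synthetic data** — seeded generators for every input (lognormal
  monomer intensities and c-mer mixtures, rendered TIRF movies with
  Poisson/read noise and photobleaching, two-phase traces, multichannel IF
  fields) with ground truth, so every stage is testable end to end.

The two fitted models follow a statsmodels-style surface: build a model
object from data, call `.fit()`, get a results object with estimates,
uncertainties and a `summary()`.

## Worked example

```python
import numpy as np
from smolsensor import simulate, MultimerMixtureModel, TwoPhaseHillModel
from smolsensor.kinetics import KineticParams, TimeCourse
from smolsensor.copynumber import copy_number_report

# --- are the spots single molecules? ---------------------------------
mix = simulate.gen_multimer_mixture(5000, [0.981, 0.019, 0.0], seed=1)
calib = simulate.gen_monomer_intensities(50000, seed=2)
fit = MultimerMixtureModel.from_samples(
    mix["intensity"].to_numpy(), calib, M=3, mode="scale").fit(seed=3)
print(fit.summary())

# --- how fast is the lipid made and degraded? ------------------------
true = KineticParams(F_max=1.0, n_syn=2, tau_syn=1/1.09, n_deg=2, tau_deg=1/0.13)
tc = simulate.gen_timecourse(true, np.arange(-2, 15.25, 0.5), noise_sd=0.05, seed=7)
res = TwoPhaseHillModel(tc).fit()
print(res.summary())

# --- what do the densities mean per cell? ----------------------------
rep = copy_number_report(25.0)
print(rep["molecules_per_cell"], rep["ploidy_scaled_copies"],
      round(rep["proteome_fraction_pct"], 2))
```

Output:

```
Multimer mixture deconvolution
==============================
basis: M = 3 (scale mode), n_total = 5000
reduced chi2 = 1.383  (dof = 30)
  1-mer fraction = 0.9939  (99.4%)
  2-mer fraction = 0.0000  (0.0%)
  3-mer fraction = 0.0061  (0.6%)
Monte-Carlo draws = 100000, seed = 3

Two-phase Hill recruitment kinetics
===================================
observations: 31   RSS: 0.0479425   converged: True
F_max   = 0.9909
n_syn   = 2.42    tau_syn = 0.9127 min    k_syn = 1.096 1/min
n_deg   = 1.977    tau_deg = 7.059 min    k_deg = 0.1417 1/min
F0 (pre-stimulus, fixed) = -0.01081

375.0 1125.0 4.89
```

The deconvolution reads this 5,000-spot sample as 99.4% monomeric with a
reduced χ² near 1 (the model explains the histogram to within counting
noise; recovered fractions scatter ~±1 pp around the generating 98.1%
from sample to sample).  The kinetic fit on one noisy trace recovers the
generating rates to within single-trace scatter — individual rate
estimates carry ~15% spread at this noise level, and medians over many
traces are unbiased (see `smolsensor.protocols`).  The copy-number chain
turns 25 spots per 100 µm² into 375 molecules per cell, 1,125 after
triploid scaling, about 5% of a 23,000-copy proteome estimate.

## Command line

```sh
smolsensor simulate spots --n 5000 --fractions 0.981,0.019,0 --seed 1 --out mix.csv
smolsensor deconvolve --calib calib.csv --expt mix.csv --max-order 3
smolsensor spots detect --in movie.tif --pixel-size 0.0867 --snr 5 --out spots.csv
smolsensor kinetics --in trace.csv --boot 1000 --seed 1
smolsensor report --density 25 --area 1500 --ploidy 3 --total 23000
smolsensor run --seed 1 --out rundir/
```

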