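# Methods

This note documents the models implemented in `smolsensor`, their
assumptions, the default parameters and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## Multimer deconvolution

**Model.** The intensity distribution of N fluorescent puncta of unknown
polydispersity is a finite mixture

    ρ(x) = (1/N) · Σ_{c=1..M} A_c · ρ_c(x),

where A_c is the number of puncta containing c fluorophores and ρ_c the
intensity distribution of a pure c-mer population.  M defaults to 3
(monomer/dimer/trimer); orders above 5 are out of scope.

**Basis construction.** ρ_1 is the normalized histogram of a monomeric
calibration construct.  Two transforms to higher orders are provided as
first-class modes because they encode different physics:

* `scale` (default): ρ_c(x) = ρ_1(x/c)/c — a pure change of variables.
  A c-mer is c times as bright with the same *relative* spread
  (mean and SD both scale by c).  This is the deterministic reading of
  "transforming" the monomer histogram.
* `convolve`: ρ_c is the c-fold self-convolution of ρ_1 — a c-mer is the
  sum of c independent emitters, so means add and *variances* add
  (relative spread shrinks as 1/√c).  This is the standard assumption in
  intensity-deconvolution work on independent fluorophores.

The two agree exactly at c = 1 and diverge in variance for c ≥ 2; the
surface exposes the choice rather than silently resolving it.  Both are
implemented by exact mass redistribution on a common extended grid (bin
width preserved, upper edge extended to M× the calibration range), so no
sampling is involved in the basis itself.

**Fitting.** The model histogram for weights f is
n_total · Σ_c f_c ρ̃_c, where ρ̃_c is basis component c smoothed by
n_draws = 20 × n_total inverse-CDF Monte-Carlo draws and rebinned onto the
experimental grid plus one overflow bin (no model mass is lost above the
experimental range).  The smoothing draw is made once per fit from the
stored seed, so the objective is deterministic and the optimiser is not
chasing noise.  The objective is the reduced χ²; minimisation is
Nelder–Mead over an unconstrained vector mapped onto the simplex by
v ↦ |v|/Σ|v|, with 10 restarts (uniform, monomer-heavy, and Dirichlet(1)
starting points) tie-broken by the lowest objective.

**Reduced χ².** Pearson's statistic with adjacent bins pooled until every
pooled bin has expected count ≥ 5, divided by
dof = pooled bins − (M − 1) − 1 (simplex-constrained weights contribute
M − 1 free parameters).  Under a correctly specified model the statistic
is ≈ 1 with sampling SD √(2/dof) (~0.25 at the default binning), so
single-fit values up to ~2 are ordinary tail behaviour; calibration
checks therefore assert on medians across seeds.

**Binning.** Default 50 equal-width bins from 0 to the sample maximum, so
counts always sum to the sample size.  A quantile range policy (samples
above the cut clipped into the top bin) is available for heavy-tailed
data.  Halving the bin width moves the recovered monomer fraction by
< 0.02 in the standard recovery study.

**Calibration size.** The basis is itself estimated from a finite
calibration sample, which inflates the χ² statistic by roughly
1 + n_expt/n_calib.  The standard study conditions therefore use a
50,000-sample calibration against 5,000-spot experiments (inflation
≤ 1.1), reflecting that a calibration construct can be imaged for as many
frames as needed; with a 10,000-sample calibration, fits remain accurate
but χ² centres near 1.5.

## Two-phase recruitment kinetics

**Model.** Membrane recruitment after stimulation at t = 0:

    F(t) = F0                                                   t < 0
    F(t) = F_max · [ t^n_syn/(t^n_syn + τ_syn^n_syn)
                   − t^n_deg/(t^n_deg + τ_deg^n_deg) ]          t ≥ 0

Both phases are sigmoidal (cooperative) because pathway activation
involves multiplicative adapter/enzyme interactions.  F_max multiplies the
*difference* of the two Hill terms, so F → 0 as t → ∞, matching traces
that decay back to baseline; the alternative reading (F_max scaling only
the synthesis term) would plateau at F_max(1 − 1) = 0 anyway at large t
but changes the fitted amplitude — the difference form is used
throughout.  Rate constants are k_syn = 1/τ_syn, k_deg = 1/τ_deg in
min⁻¹.  F0 is fixed to the pre-stimulus mean (0 after ΔF normalisation)
rather than fitted, matching the piecewise-constant branch.

**Estimation.** Bounded trust-region least squares (analytic Jacobian) on
the post-stimulus points, bounds τ ∈ [0.05, 100] min, n ∈ [0.5, 8],
F_max ∈ [0, 10]; five multiplicative-lognormal-jittered restarts (first
start unjittered, data-driven: τ_syn from the observed peak time),
tie-broken by lowest RSS.  On noiseless data the generator is recovered
to better than 1e-4 relative from ±20%-perturbed starts.  On noisy data
individual fits scatter along the (n, τ) ridge — the Hill exponent and
half-time trade off over a narrow data window — so single-trace rates
carry ~15% scatter at 5% noise while medians across traces are unbiased
to ~1%.  Hill coefficients default to n = 2 in the generator; they are
freely fitted but recovery targets key on the rates, which are the
identifiable quantities.

**Uncertainty.** Residual-resampling bootstrap: refit to
fitted + resampled residuals, percentile 95% intervals (widened, if
needed, to include the point estimate, which matters only for
near-noiseless data).  Default 1,000 resamples; the coverage study uses
199 resamples × 200 simulated experiments, which keeps the full study
under ten minutes on one CPU and measures 92% empirical coverage for
k_syn at nominal 95%.  Bootstrap refits start from the point estimate
with slightly relaxed tolerances (1e-8); the point fit keeps 1e-12.

**Normalisations.** `normalize_to_baseline` divides by the pre-stimulus
mean (F/F0, requires positive baseline after background subtraction);
`normalize_to_max` maps to ΔF/ΔF_max (baseline 0, peak exactly 1,
idempotent); `fold_change_over_baseline` reports
100·(peak − baseline)/baseline.

## Spot detection and densities

Detection is a standard localization pipeline: difference-of-Gaussians
band-pass (σ and 2σ of the PSF), 8-connected local maxima above
median + min_snr × robust-MAD noise of the filtered image, then a 2-D
Gaussian least-squares refinement in a ±max(3, 3σ) pixel window (image
reflect-padded so edge spots keep full windows).  Fits are rejected if the
amplitude is non-positive, the centre moves more than 2 px, or the fitted
σ leaves [0.3σ, 3σ]; surviving maxima closer than 2·psf_sigma are merged
keeping the brighter.  Coordinates are reported in µm with pixel (r, c)
centred at ((c + 0.5), (r + 0.5))·pixel_size; integrated intensity is
A·2πσ_fit².  It is a stand-in for dedicated localization software, not a
re-implementation of any particular tool.

At the default scene (0.0867 µm pixels, 0.09 µm PSF σ, SNR 10,
threshold 5) the detector measures ~98–99% recall, zero-to-rare false
positives per 100 µm² blank, and ~0.2 px RMS localization error.

Densities are count/area × 100 (per 100 µm²), pooled or per frame; the
rolling mean is a centred boxcar with shrunken edge windows; modal
background subtraction uses the histogram mode at 1-ADU bin width (most
pixels in a TIRF field lie outside cells).

## Immunofluorescence quantification

Huang's fuzzy-entropy threshold is implemented from its definition: over
a 256-bin histogram, each candidate threshold assigns fuzzy memberships
u = 1/(1 + |g − μ_class|/C) and the Shannon entropy of u, accumulated over
the histogram, is minimised by exhaustive scan.  The threshold is
shift-equivariant at equal binning.  Degenerate guard: if the threshold
labels > 45% of pixels as foreground (as happens when an essentially
empty, unimodal field is split through its noise), the field is treated
as containing no nuclei.

Segmentation: Huang-thresholded DAPI → fill holes → drop objects below
4 µm² → distance-transform watershed with h-maxima seeds (h = 2 px) to
split touching nuclei.  Cell territories: Huang-thresholded cell-body
mask, each pixel assigned to the nearest labelled nucleus (the label-image
analogue of a Voronoi partition, computed with an exact Euclidean
distance transform).  ROIs are filtered by area strictly greater than
10 µm² and border exclusion.  Positivity gating: cutoff = control mean +
3 × control SD (the upper cutoff is the operative one for a
transfection-positive gate), manual override supported; staining
background from a no-primary-antibody control is subtracted without
clipping.  The pipeline has no stochastic steps: identical inputs give
identical tables.

## Synthetic data: what it emulates, and what it does not

* **Monomer intensities**: lognormal, log-mean ln(1000), log-SD 0.4 —
  single-molecule spot intensities are mono-modal and lognormal on a
  plausible camera-ADU scale.  The calibration distribution's true
  parameters are a declared default, not an inferred value; everything
  downstream treats them as configurable.
* **Mixtures**: order labels drawn from the simplex weights; c-mer
  intensities by c× scaling (default) or c-fold summation, matching the
  two basis modes.
* **TIRF frames**: background + Gaussian PSF spots (integral equals the
  true intensity) + Poisson shot noise on photoelectrons + Gaussian read
  noise; defaults (0.0867 µm pixels, PSF σ 0.09 µm, background 100 ADU,
  0.5 ADU/e⁻, read noise 2 ADU) describe a binned sCMOS at high
  magnification.  Photobleaching is per-frame Bernoulli disappearance.
  Spot-recall fixtures place spots with a minimum separation of 3×PSF σ:
  the resolvable single-molecule regime that spot counting presumes —
  unresolvable pairs are an optical limit, not a detector defect.
* **Recruitment movies**: per-frame spot populations at a prescribed
  density profile (low-duty-cycle imaging of arrivals), or a bleaching
  population with no arrivals.
* **Kinetic traces**: model + i.i.d. Gaussian noise (SD as a fraction of
  F_max), sampled every 0.5 min from −2 to 15 min — one image per 30 s.
* **IF fields**: cells as concentric disks (graded radial nucleus and
  soft-edged cell-body profiles — flat plateaus produce degenerate
  histograms no real stain has), non-overlapping, clear of the border;
  nucleus radius 6 µm and cell radius 11 µm at 0.65 µm pixels (20×
  scale); untransfected reporter levels Gaussian(50, 15) ADU in a 12-bit
  convention, transfected cells offset by +300.

Not emulated: lipid diffusion and binding chemistry, cell morphology,
spatial clustering, drift, multi-emitter overlap, uneven illumination,
chromatic offsets.  Passing tests therefore demonstrate the correctness
of the *analysis logic* under the stated noise models, not robustness to
every artefact of real microscopy.

## Standard study conditions (sizes chosen once, used everywhere)

* Deconvolution recovery: 20 replicates × 5,000-spot mixtures at
  (98.1%, 1.9%, 0%) with 50,000-sample calibrations; asserts mean
  recovered monomer percentage (±2 pp) and median χ² ∈ [0.5, 1.5].
* Kinetics recovery: 100 traces at 5% noise; asserts medians of k_syn and
  k_deg within 5%.
* Bootstrap coverage: 200 experiments × 199 resamples; asserts coverage
  ∈ [90%, 99%].
* Spot detection: 20 SNR-10 frames (25 spots each) + 20 blanks; density
  linearity over 5–35 per 100 µm², 8 frames per density.
* Gating: 10,000 simulated untransfected cells (expected upper-tail rate
  0.135%); segmentation on 20 fields cycling 5–50 cells.

## Known limitations

* The mixture optimiser explores the open simplex through an absolute-
  value map; exact zeros are reachable but weights below ~1e-6 should be
  read as "absent".
* χ² pooling (expected ≥ 5) makes the dof depend weakly on the fitted
  weights; the reported dof is evaluated at the optimum.
* Rate constants from a single noisy trace carry ~15% scatter at 5%
  noise; always aggregate replicates.
* Huang thresholding needs a minimally bimodal histogram; extremely
  sparse fields (foreground ≪ 1% of pixels) can defeat any
  histogram-shape threshold, which is why the field generator uses
  realistic cell sizes for its magnification.
* The detector is single-emitter: overlapping spots within ~2 PSF σ are
  merged by design.
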