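# Methods

This package quantifies how high-density lipoprotein (HDL) particles
interact with model lipid membranes, from five fluorescence readouts:
phase partition coefficients in supported bilayers, Laurdan generalized
polarization, time-dependent fluorescence shift (TDFS), single-particle
tracking (SPT), and fluorescence correlation spectroscopy (FCS).  Because
no raw experimental data are deposited for this class of experiment, every
analysis operation is paired with a synthetic-data generator that records
its ground truth; the test suite is built on parameter recovery from those
generators.  This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what a green recovery test does and
does not establish.

## Synthetic data: the stated world

Generator defaults encode the experimental conditions the analyses are
designed for; they are fixed once and the recovery suite is run against
them.

**TDFS decay sets** (`synthetic.gen_tdfs_dataset`).  The emission model is
a Gaussian band in wavenumber (FWHM 3000 cm^-1, typical of Laurdan in a
phosphatidylcholine bilayer) whose maximum relaxes mono-exponentially,
`nu(t) = nu_inf + (nu0 - nu_inf) exp(-t/tau_shift)`, while the total
intensity decays with a 4 ns fluorescence lifetime.  Defaults: nu0 =
23,800 cm^-1, nu_inf = 21,800 cm^-1 (a 2000 cm^-1 total shift, the order
observed for fluid PC bilayers), tau_shift = 2 ns.  Decays are recorded on
a 400-550 nm grid in 10 nm steps, convolved with a Gaussian IRF of 78 ps
FWHM, scaled so the peak bin holds 5000 expected counts (emulating
acquisition-to-target-peak), with 5 counts/bin dark background, and Poisson
sampled.  4096 bins of 12.5 ps cover a 51.2 ns window.  Wavelength/
wavenumber densities carry the lambda^2 Jacobian symmetrically in the
generator and the reconstruction; the correction can be disabled in both.

**GP spectrum pairs** (`gen_gp_spectra`).  Two excitation spectra (Em 440
and 490 nm) over 320-420 nm whose pointwise ratio encodes a known GP:
`I440/I490 = (1+GP)/(1-GP)`; multiplicative Gaussian noise (default 2%)
models shot and lamp noise.

**Trajectory mixtures** (`gen_trajectory_mixture`).  Immobile particles
are static points; confined particles perform a reflected Brownian walk in
a disc (default R = 150 nm, D = 0.1 um^2/s, sub-stepped so each sub-step
is small against R); free particles are unbounded walks.  All positions
get isotropic localization noise (default sigma_xy = 30 nm, the middle of
the 20-40 nm single-molecule precision band).  Frame timing is
`t_lag = n (t_ill + t_delay)` with defaults t_ill = 5 ms, t_delay = 15 ms
(the short ends of the instrument's ranges, keeping tests fast).

**FCS traces** (`gen_fcs_trace`).  Point particles diffuse in a periodic
box of side 10 w0; the detected rate is a sum of Gaussian-focus weights
`exp(-2 r^2/w0^2)` times a per-particle brightness (30 kcounts/s at focus),
Poisson-sampled per bin.  The particle density is set so the correlation
amplitude is exactly 1/N for the requested in-focus number N.  Defaults:
w0 = 0.25 um (typical for a 40x/1.2 water objective at 639 nm — the beam
waist is a required calibration input that the study does not print),
10 s duration, 50 us bins.  Triplet blinking is available as per-particle
exponential-dwell telegraph processes; its cost scales with
duration/tau_triplet, so it is off by default and exercised on short,
finely-binned traces.  D-recovery runs omit it: tau_D ~ 1.6 ms is three
orders above a ~5 us triplet and the two are spectrally separated.

**Two-phase bilayer images** (`gen_two_phase_image`).  A marker channel
(bright in the liquid-disordered phase) and a signal channel at chosen
per-phase densities, either as uniform intensity or as countable
diffraction-limited emitters (PSF FWHM 300 nm, pixel 100 nm), with Poisson
shot noise, Gaussian read noise (sd 2), and a constant offset (100) —
camera statistics are not specified by the source protocol, so a standard
sCMOS-like model is used.  Spot-count recoveries use <= 0.3 spots/um^2:
spots closer than one PSF are not countable and the detector drops them,
which would otherwise bias the count ratio toward 1.

**GUV z-stacks** (`gen_guv_image`).  A spherical-shell vesicle imaged as a
Gaussian annulus per slice (radius sqrt(R^2 - z^2)), 500 nm z-steps, with
the same camera model.  Neighbouring slices near the equator differ by
<1% in circumference, so the "equatorial slice" is only defined to within
a slice or two under shot noise; tests allow that.

## TDFS analysis

Decays are fitted by iterative reconvolution with the measured IRF:
`background + (shifted IRF) * sum_i a_i exp(-t/tau_i)`.  The fit uses
variable projection — amplitudes and background are linear and solved by
weighted least squares inside the nonlinear optimisation over lifetimes
and sub-bin IRF shift — which is decisively more robust than a fully
nonlinear fit on decays where the band sweeps through the detection
wavelength.  Amplitudes may be negative: red-edge decays rise before they
decay as population relaxes into the window, and forbidding rise terms
makes those fits fail outright.  Weighting is Poisson; a second pass uses
Pearson weights (variance from the fitted model) because Neyman weighting
(variance from counts) biases the fitted background low and the reduced
chi-square high in low-count bins.  The reported chi-square is the Pearson
statistic of the final model.  Component count is chosen automatically:
1-3 exponentials, warm-started from the previous order, a component kept
only if it improves reduced chi-square by >5%; nearly degenerate
same-sign lifetime pairs trigger a refit with one component fewer.

TRES reconstruction follows the standard recipe: each fitted (IRF-free)
decay is normalised to unit time integral and scaled by the steady-state
intensity at its wavelength; intensities are converted to wavenumber
densities (lambda^2 Jacobian, toggleable since the convention is often
left implicit); the band maximum nu(t) and FWHM(t) are extracted per time
slice on a logarithmic 1 ps - 50 ns grid.  The slice fit is a symmetric
Gaussian by default: on a 16-point spectral grid with a partially covered
blue wing, the extra asymmetry parameter of a log-normal line is poorly
constrained and roughly doubles the systematic error of the extracted
maximum (log-normal remains available; a parabolic log-intensity fit is
the fallback).

Two decisions matter for the scalar readouts and were made after
quantifying failure of simpler rules:

* **Support window.**  With a 4 ns lifetime and 5000 peak counts, the
  fitted decays have no photon support beyond ~15-20 ns and the
  reconstructed nu(t) drifts by 100-250 cm^-1 there.  All nu(t) analysis
  is therefore restricted to times where the emitting population is at
  least 10% of its maximum.
* **nu(inf) estimation.**  A late-window mean retains part of the
  relaxation tail (~+25 cm^-1 for a 2 ns shift).  The default estimator is
  instead the asymptote of a mono-exponential fit to the tail part of
  nu(t) (t >= a quarter of the support window, where the slowest component
  dominates, keeping multi-exponential relaxations unbiased).  A
  flat-window scan and a late-mean (flagged `no_plateau`, lower bound) are
  fallbacks.

`delta_nu = nu0 - nu_inf` uses nu0 = 23,800 cm^-1 as a calibration
constant (its independent estimation from absorption/emission spectra is
out of scope).  `tau_r` integrates the normalised shift correlation
trapezoidally up to the point where it falls below 1% and adds an
exponential-tail extrapolation; a tail above 20% of the total flags the
result.  Recovery at the default stated world: |delta_nu error| < 25
cm^-1 and |tau_r error| < 0.015 ns across seeds — inside the intrinsic
uncertainties of 50 cm^-1 and 0.05 ns.

## Laurdan GP

`GP_EX = (I440 - I490)/(I440 + I490)` pointwise over excitation
wavelength.  Points whose denominator falls below 1% of its maximum are
masked (they otherwise produce +-1 artifacts in the band tails).  The
scalar summary is the unweighted mean over 340-400 nm (the summary window
is not standardised; it is configurable).

## Single-particle tracking

Spot detection smooths with a PSF-matched Gaussian, takes local maxima
above a robust threshold (median + k * MAD), excludes a border margin
(filter-padding artifacts), and refines each candidate with a symmetric
2-d Gaussian fit; precision comes from the fit covariance.  Candidates
closer than one PSF FWHM are dropped (default) or merged.  Linking is
greedy nearest-neighbour frame-to-frame with a hard displacement gate and
no gap closing; ambiguous links (multiple candidates in range) are dropped
rather than guessed.

MSD uses non-overlapping index windows by default (pairs i = 1, 1+n,
1+2n, ... for lag n), which keeps the squared displacements entering one
lag independent; overlapping windows are available and are used internally
for per-trajectory curves where variance matters more than independence.
The free-diffusion fit `msd = 4 D t + 4 sigma^2` uses the first 4 lags
(bias/variance compromise).  The bimodal square-displacement CDF fit
shares one mixture weight alpha across lags with per-lag msd1 < msd2;
components closer than 2x collapse to a monomodal fit.  The confined
model `msd = R^2 (1 - exp(-4 D t/R^2))` optionally adds a noise-floor
offset (the source formula has none, but with sigma_xy = 30 nm the floor
is 16% of a 150 nm corral's plateau and ignoring it biases R).

Per-trajectory classification: immobile if the early MSD stays within 1.5x
of the known noise floor 4 sigma^2; otherwise confined vs free by
corrected AIC on the per-trajectory MSD with both models anchored at the
known noise floor.  Because the confined model nests the free one
(R -> inf), plain AIC calls about half of genuinely free trajectories
confined; two guards are added — a decision margin of 6 on the AICc
difference, and the requirement that the fitted plateau be below a third
of the lag-1 free extrapolation.  At the default stated world this yields
mixture fractions within +-0.02 of truth and a residual 5-10% spurious-
confinement rate on pure free ensembles: single-trajectory time-averaged
MSD values at late lags have ~46% relative noise for 50-frame tracks, so
per-trajectory free/confined discrimination is intrinsically noisy.  A
green mixture-recovery test establishes ensemble fractions, not the
correctness of any single trajectory's label.

## FCS

The correlator is multi-tau (16 lags per level, pairwise coarsening),
with the symmetric normalisation, applied independently to 10 contiguous
blocks of the trace; the curve is the block mean and the SE the block
scatter.  Lags longer than a tenth of a block are discarded.  The fit is
the standard one-component 2-d diffusion + triplet model
`G = (1/N)(1 + tau/tau_D)^-1 (1 + T/(1-T) exp(-tau/tau_T)) + G_inf`
with inverse-SE weights over 10 us - 1 s; a triplet time within 10x of
the diffusion time disables the triplet term (unidentifiable) with a
warning.  `D = w0^2/(4 tau_D)` by construction, so absolute D inherits
the calibration of w0.  Sample aggregation mirrors the measurement design:
traces are averaged per vesicle first, then mean +- SE across vesicles and
replicates.

## Partitioning

The phase mask comes from Otsu thresholding of the marker channel (label
1 = marker-rich liquid-disordered phase), with speck/hole cleanup and a
degeneracy check (either phase <1% of the field, or marker class
separation <3 pooled SDs, i.e. a unimodal marker).  `K_p = (I1/I2)(A2/A1)`.
Two measurement-bias corrections proved decisive at extreme ratios
(K_p ~ 0.006, where the dim phase holds ~1 count/pixel):

* a 3-pixel band around the phase boundary is excluded from sums and
  areas — PSF blur leaks bright-phase signal across the boundary and
  roughly doubled the recovered K_p without it;
* background correction for summed intensities keeps negative residuals
  (`clip=False`): clipping rectifies read noise and biased the dim-phase
  sum by +36%.  The default `background_correct` still clips, as a
  displayable image should.

Background is estimated as the intensity-histogram mode when signal-free
pixels exist; for full-field membrane images the calibrated detector
offset must be passed explicitly.  Spot-count K_p replaces intensities by
localization counts with Poisson errors.  Boundary enrichment is reported
against the geometric null (the area fraction of the boundary band).  GUV
segmentation picks the slice with maximal above-threshold ring signal,
fits a circle (Kasa) to the thresholded rim, and reports per-channel
densities on the dilated ring and in an interior region that stands off
1.5 ring-thicknesses from the rim (membrane PSF tails).

## Statistics

`compare_groups` runs the full protocol: Shapiro-Wilk normality per group,
Levene variance homogeneity, Kruskal-Wallis omnibus at alpha = 5%, and
Dunn's all-pairs post-hoc z-test on pooled ranks with tie correction and
Bonferroni adjustment (m = number of pairs).  Percent changes are reported
rounded to the nearest integer with the unrounded value retained; SEs
propagate by the delta method (cross-checked against Monte Carlo in the
tests).

## Known limitations

* nu(0) is a constant, not estimated; TRES-extrapolated time-zero maxima
  carry a ~+40 cm^-1 systematic at these photon budgets and are not used
  for delta_nu.
* Per-trajectory confined/free labels are noisy (see above); only ensemble
  fractions are validated.
* Spot-count K_p is only unbiased while spots are countable (< ~0.3/um^2
  at a 300 nm PSF); the intensity mode has no such limit.
* The FCS model is one-component 2-d + triplet only; no anomalous or 3-d
  variants.
* Synthetic images contain no drift, flat-field structure, or chromatic
  offset, so green recovery tests do not establish robustness to those.
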