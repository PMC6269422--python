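# Methods

`ccakit` implements a comprehensive correlation analysis for single-point
fluctuation data recorded on a 32-element hexagonal detector array
(~50 nm element pitch projected to the sample plane, microsecond
sampling).  One acquisition yields, simultaneously: analog-corrected FCS
with number & brightness at four nested virtual pinholes, the
spot-variation diffusion and number laws with an intercept-plot
classification, 2D pair correlation at the four detector radii, and an
amplitude-derived iMSD along the three hexagonal axes.  A Brownian/photon
simulator provides ground truth for every stage.

## Detector model

The array is modeled as 32 Gaussian collection volumes centered on the
hexagonal element positions (1 center + 6 + 12 + 13 across rings 0-3;
spiral numbering, counter-clockwise from +x).  Each element has a lateral
1/e^2 waist `w_i = w0 + slope * |r_i|` (defaults `w0 = 144 nm`,
`slope = 0.2408`) and an axial waist `A * w_i` with `A = 2.97`.

Virtual pinholes are the nested subsets {center}, {+ring 1},
{+inner ring 2}, {+ring 2}.  Two calibrated quantities describe each
configuration:

* **Effective waist** — the waist a free-diffusion FCS measurement sees:
  the standard single-component model is fitted to the *exact* noiseless
  correlation of the summed profile (closed-form pairwise Gaussian
  overlaps), and `tau_D` is converted back to a waist.  The result is
  independent of the reference diffusion coefficient and equals the
  member waist for a single-element configuration.  With the default
  slope the four waists span 144-196 nm.
* **Effective volume** — the exact `(int W)^2 / int W^2` of the summed
  profile.  This matters: a single-Gaussian formula evaluated at the
  fitted waist overestimates the volume of the flat-topped sums by up to
  ~23%, which would bend the free-diffusion number law into a spurious
  negative x-intercept (an apparent "aggregation" signature) and tilt the
  diffusion law.  Calibrating both laws on the exact profile physics is
  the software equivalent of the bead calibration an instrument would
  use.

The closed form `V_eff = pi^(3/2) w^3 A` remains available for scalar
waists (e.g. `effective_volume(0.196, 2.97) = 0.1245 um^3`).

## Correlator and analog correction

All estimators share one convention, `G(tau) = <dI dI>/<I>^2`, estimated
with symmetric normalization (windowed means on both sides of each lag);
the `<I I>/(<I><I>) - 1` form of the pair-correlation literature is the
same quantity.  Numerators are accumulated on mean-subtracted
fluctuations, which keeps the large-`<I>^2` cancellation out of floating
point so a constant gain cancels to ~1e-13 relative.

The multi-tau grid uses 16 linear lags then repeated 2x rebinning
(averaged bins), capped at min(1 s, T/8 samples).  Cascade 0 is exactly
the linear estimator, which `autocorrelate_direct` implements as an
independent oracle.  Per-lag standard errors come from splitting the
trace into 8 segments; lags beyond the segment-supported range inherit
the last available estimate.

An analog detector adds an offset process `I0` (electronic offset, dark
noise, cross-talk) to the photon signal.  Assuming `I0` independent of
the signal, the corrected correlation is

    G1(tau) = (num(tau) - num_dark(tau)) / ((<I> - <I0_a>)(<I> - <I0_b>)),

with dark means and (auto or per-pair cross) numerators measured once on
an excitation-off acquisition and reused across every curve of the
analysis.  Pair numerators are evaluated lazily with caching; of the 528
possible pairs an analysis touches only a handful.

## FCS, number and brightness

Corrected curves are fitted with the single-component 3D diffusion model
`G0 (1+tau/tau_D)^-1 (1+tau/(A^2 tau_D))^-1/2` plus a free additive
baseline, by weighted least squares (weights `1/stderr^2`, floored at
1e-6; default window `[2 t_sample, 0.8 * max lag]`).  The baseline is
standard FCS practice for slow drifts, and here it also absorbs an exact
finite-system effect: with N molecules conserved in a volume V the
correlation is `C (f(tau) - V_eff/V)` — a constant negative offset that
grows with the observation volume and, left in, biases `tau_D` low by
10-19% across the four pinholes (it does not shrink with trace length,
which rules out finite-trace estimator bias).  `G0` reports the
amplitude of the decaying part.  Derived quantities: `<N> = gamma/G0`
with `gamma = 2^-3/2` (3D Gaussian shape factor),
`B_analog = <I1> G0 / t_sample`, and `B_app = B_analog / S_detector` with
the gain calibrated from a Poisson reference
(`S = (var - var_dark)/(mean - mean_dark)`).

Note the occupancy that `gamma/G0` measures: since `G0 = 1/(c V_eff)`
exactly for Gaussian volumes, `N = gamma c V_eff` is the concentration
times the *detection-weighted* volume `(pi/2)^(3/2) w^3 A`.  The
simulator tests use this internally consistent pairing.

## Spot variation

FCS runs at the four nested volumes; two weighted straight lines follow:
`tau_D` vs `w^2` (intercept `tau_D(0)`: + microdomain, - meshwork,
0 free) and `N` vs `V_eff` (x-intercept `V_eff(0)`: + exclusion,
- aggregation, 0 uniform).  Weights are propagated fit uncertainties;
confidence intervals use the t distribution on n-2 = 2 degrees of
freedom with the covariance scaled by reduced chi-square, floored at 1
(with two residual degrees of freedom a lucky alignment would otherwise
collapse the interval).  An axis whose 95% CI covers zero is read as
neutral; both neutral classifies as free/unstructured.  `S_conf` is
reported as |tau_D(0)| (a proxy: only its monotonicity is used).

A caveat established with exact static integrals and confirmed in
simulation: the x-intercept of the amplitude-derived number law is
nearly blind to geometric exclusion.  Removing detection volume
renormalizes `G0` rather than subtracting molecules — a centered
inaccessible sphere *raises* the effective volume (the profile peak is
clipped, flattening the profile), and peripheral exclusion suppresses
the large volumes relatively more, which moves the intercept the wrong
way.  Across centered/offset spheres, half-spaces and annuli of
realistic size the intercept shift stays below ~0.013 um^3, within
replicate noise.  The positive-exclusion reading of the intercept plot
should therefore be interpreted with care; the package reports what the
estimator actually yields.

## 2D pair correlation

Corrected cross-correlations from the central element to each element of
a distance group (radii `p, sqrt(3) p, 2 p, sqrt(7) p` = 50, 86.6, 100,
132.3 nm).  Per-angle amplitudes are windowed means over one lag decade
centered on the transit time `r^2/(4 D_hat)` (`D_hat` from the
concurrent central-element fit).  The anisotropy index is
`1 - min/max` over angles, clipped to [0, 1].  Connectivity divides each
windowed amplitude, first normalized by the same run's central
autocorrelation amplitude (cancelling concentration differences), by the
matched value from a free-diffusion reference on identical geometry.

Detection limits: all four radii are *below* the single-element waists
(144-160 nm), so the central and target volumes co-detect the same
molecules on either side of any wall.  A 50 nm impermeable wall (the
default barrier: an excluded slab at x = 25 nm, zero permeability)
raises the anisotropy index reliably but depresses blocked-direction
connectivity only to ~0.85 of the free reference — sub-PSF geometry
caps the contrast of amplitude-based connectivity.

## iMSD

Ring 2 (twelve elements of comparable waist — the prerequisite for an
unbiased iMSD) samples nine signed spatial lags {-4..+4} x pitch along
each hexagonal axis.  Only the chi = 0 amplitude row feeds
`sigma^2(tau) = C <G(0)>_Ring / G_theta(0, tau)`; `<G(0)>_Ring` is the
mean fitted member amplitude, `N = 1/<G(0)>_Ring`.  Two refinements:

* the amplitude row is divided by the known axial decay
  `sqrt(1 + tau/(A^2 tau_D))` (`tau_D` from the ring member fits) before
  inversion — otherwise axial escape of the 3D observation volume
  masquerades as lateral spreading and inflates slope-derived D by
  15-30%;
* lags are retained while the amplitude stays above 3x its standard
  error and above 0.25 x `<G(0)>_Ring` (sigma^2 growth <= 4x its
  starting value; beyond that displacements exceed the ROI scale and the
  inversion no longer reflects local transport).

`C` is fixed once on a free-diffusion calibration so the fitted
`tau -> 0` intercept equals the squared ring waist (convention
`G ~ exp(-xi^2/sigma^2)`, so free diffusion gives
`sigma^2 = sigma^2(0) + 4 D tau`).  The all-in-one pipeline
(`run_full_cca`), which has no separate calibration acquisition,
self-calibrates instead: the `tau -> 0` intercept is the PSF width for
free and confined motion alike, so `C` is rescaled until the fitted
intercept equals the ring waist squared (D and L^2 scale linearly with
C; the model choice is scale-invariant).  Free
(`sigma0^2 + 4 D tau`) and confined
(`sigma0^2 + L^2/3 (1 - exp(-tau/tau_c))`) models are fitted with
relative-error weights; "confined" requires a corrected-AIC advantage
greater than 2.  `L_conf` follows from the saturation level,
`sigma^2(inf) - sigma^2(0) = L^2/3`.

## Simulator

Brownian point emitters in a periodic box (per-axis step variance
`2 D t_sample`), detected by the Gaussian element volumes, Poisson
photon statistics, then `I = gain * photons + offset + N(0, dark_sigma)`.
The clean photon trace is always returned next to the analog trace.
Defaults are the study conditions: `D = 30 um^2/s` (GFP-scale mobility),
100 particles in `1 x 1 x 2 um` (50 molecules/um^3, ~2 molecules in the
largest virtual pinhole), `t_sample = 2.46 us`, brightness 0.2 photons
per particle per timepoint at the PSF center (~80 kHz per molecule),
gain 750 counts/photon (a PMT-like pulse height, so a 20-count dark
fluctuation is a small fraction of a photon), offset 200, dark sigma 20.

Environments act per step; disallowed crossings reflect, excluded
regions reject the step:

* **microdomain** — trapping disks (radius 100 nm, square grid 500 nm);
  exits accepted with probability 0.01, entries free;
* **meshwork** — square lateral mesh, crossings accepted with the
  passage probability;
* **barrier** — a finite-thickness excluded slab (50 nm) with optional
  permeability; the barrier axis uses reflecting box walls instead of
  periodic wrap (a single plane cannot separate a periodic box);
* **excluded** — a hard sphere, initial positions rejected inside;
* **confined** — corral cells (side 400 nm, one centered on the ROI)
  with a small hop probability (0.01 per boundary attempt).  The hops
  are essential, not a convenience: a time-averaged correlation
  estimator subtracts the trace mean, so *permanently* trapped occupancy
  patterns are invisible and sigma^2(tau) never saturates; slow
  inter-corral exchange (hop time ~0.1 s: two orders above the corral
  equilibration time, one below the trace length) re-randomizes
  occupancies within the acquisition and produces the saturating iMSD
  the method detects — which is also the physical situation in cells.

What the generator does not emulate: photophysics (blinking, bleaching),
detector afterpulsing and dead time, pixel cross-excitation, non-Gaussian
PSF structure, and flow.  Passing tests therefore validate the estimator
chain against the stated physical model, not against instrument
artifacts beyond the analog offset/dark/gain model.

## Problem sizes and test design

Tests and the acceptance script run the chain at 250k timepoints
(~0.6 s, 2000-3500 transit times) with 20 (tests) or 8 (script)
replicates per stochastic claim; the analog-correction convergence check
uses 2e6 timepoints.  These sizes put the free-null intercept coverage
and the detection-power claims in a regime where residual estimator
systematics (~2% on per-level tau_D and N) are comparable to the
replicate scatter, which is the honest operating point of the method at
these acquisition lengths.

## Known limitations

* Exclusion detection via the number-law x-intercept is physically weak
  (see above); the corresponding claim is asserted as specified and
  fails under the stated conditions.
* Blocked-direction connectivity cannot drop below ~0.5 for sub-PSF
  detector separations; the anisotropy index is the sensitive barrier
  readout at this geometry.
* Ring-1 iMSD is implemented (`ring=1`) but not validated against
  reference behavior; ring 2 is the default and the validated path.
* The confined iMSD model's `tau_c` and `L^2` are correlated at short
  traces; `L_conf` is reliable, `tau_c` only indicative.
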