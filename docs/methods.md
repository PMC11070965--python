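# Methods

This package models how the microstructure of a silicone (PDMS-like,
"SiliGlass") tissue-mimicking phantom — hollow silica microspheres as the
scatterer, a diluted black silicone pigment as the absorber — determines its
bulk optical properties, and solves the inverse problem of recovering the
constituent fractions from a measured diffuse reflectance spectrum.  This
note records the models, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Units and conventions

Wavelengths are nanometres everywhere; absorption and scattering
coefficients are cm^-1; particle geometry (diameters, wall thicknesses) is
micrometres.  The only conversion constant, 1 cm = 10^4 um, lives in
`spectra.py`.  Reflectance and transmittance are dimensionless in [0, 1]
with a configurable overshoot tolerance (default 0.05) for values slightly
above 1 near a white reference.

## Mie scattering of hollow spheres

Solid spheres use the Lorenz–Mie series with the relative-index convention
for a non-absorbing host: size parameter x = pi d n_host / lambda, relative
index m = n_sphere / n_host.  Numerics follow the standard stable recipe —
downward recurrence for the logarithmic derivative D_n(mx) (valid for
complex m), upward recurrence for the Riccati–Bessel functions of the real
argument x, truncation at n_max = ceil(x + 4 x^(1/3) + 2).  The asymmetry
parameter g = <cos theta> comes from the usual bilinear series in (a_n, b_n).
Size parameters above 5e4 are rejected as out of regime.

Hollow spheres are two-layer (air core, silica shell) particles solved with
the Aden–Kerker coefficients in the Bohren & Huffman formulation.  The naive
upward recurrence for psi is unstable at orders above the core argument, so
psi is generated by a rescaled downward recurrence pinned to psi_0 = sin z,
and chi upward with an overflow cap; once the core chi functions overflow,
the core terms A_n, B_n are set to zero, which is the exact vanishing-core
limit.  Cores with size parameter below 1e-3 are treated as absent
(sub-Rayleigh: their scattering contribution is far below double precision
at the efficiencies of interest).  The solver is exercised with real
indices; strongly absorbing shells at large x are outside its validated
regime.  The coated solver does not produce g; see the surrogate below.

## Population averaging (mixture model)

The diameter distribution enters through volume-fraction weights phi_r.  The
wall thickness is modelled as a box distribution over {0.7, 0.8, 0.9, 1.0,
1.1} um with weight 0.2 each, reflecting focused-ion-beam cross-sections of
a few spheres; both the list and the weights are configurable.  For each
(wall t, diameter d) pair with radius r = d/2:

* r > t: hollow sphere — coated-sphere Qs; anisotropy from the equivalent
  air bubble of radius r − t in the host (silica and the host are close in
  index, so the bubble dominates the angular redistribution);
* r <= t: solid glass sphere — solid Qs and g.

The per-size scattering coefficient of a dilute suspension is number density
times cross-section, mu_s = f_v · 3 Qs / (2 d); non-interacting (independent
scattering) is assumed, so everything is linear in the volume fraction and
is computed once at f_v = 1.  The distribution is linearly interpolated to a
0.1 um step and renormalized before averaging.  The mixture g is
phi-weighted directly by default (`g_weighting="literal"`); the
scattering-weighted alternative (sum phi mu_s g / sum phi mu_s) is available
behind a switch.  Reduced scattering is mu_s' = (1 − g) mu_s.

Mass and volume fractions interconvert through the two-component mixture
formula v = (w/rho_r) / (w/rho_r + 1 − w) with the measured density ratio
rho_r = 1.196 (±2.5%).

## Cuvette absorption

Collimated transmittance of a filled macro cuvette
(air | wall | medium | wall | air) is modelled incoherently: normal-incidence
Fresnel reflectances at the four interfaces, Beer–Lambert attenuation in the
walls and the medium, and the complete geometric series of inter-wall
multiple reflections composed with the two-beam (Stokes) layer-stacking
relations.  Coherent interference is rightly absent — the ~1 mm walls far
exceed the source coherence length.  Inversion is a per-wavelength Brent
root solve bracketed on [0, 1e3] cm^-1 (|Delta T| tolerance 1e-10);
measurements above the lossless prediction clamp to mu_a = 0 with a warning.
Wall absorption is calibrated from an empty (air-filled) cuvette by the same
solve with the content transmittance fixed at 1.

## Photon Monte Carlo transport

Two engines share the same physics (Henyey–Greenstein phase function,
unpolarized Fresnel boundaries with total internal reflection, normal
launch, specular deduction at entry):

1. **Layered weighted-packet kernel** (`simulate_reflectance`): the classic
   multi-layer scheme — exponential step sampling, weight deposition
   w·mu_a/mu_t per interaction, Russian roulette below 1e-4 with survival
   0.1 — for arbitrary layer stacks.  It reproduces the classical
   benchmarks: R = 0.09739 / T = 0.66096 for the optical-depth-2 slab with
   albedo 0.9 and g = 0.75 (van de Hulst tabulation), and the exact
   Chandrasekhar H-function plane albedo 0.41495 for the matched
   semi-infinite isotropic albedo-0.9 medium.

2. **Scaled path engine** (`trace_semi_infinite_paths`,
   `spectral_reflectance`): for the homogeneous semi-infinite medium of the
   reflectance fit, absorption factorizes as exp(−mu_a L) along each path
   and mu_s only rescales lengths, so one scattering-only simulation at
   fixed (g, n) yields R_d for every (mu_a, mu_s) pair — the classic
   scaled/"white" Monte Carlo.  Early termination uses an exponential
   dimensionless absorption budget (rate 1e-3) that the estimator weights
   compensate exactly, so the estimate is unbiased at any evaluated
   mu_a/mu_s.  The two engines are cross-checked against each other within
   Monte Carlo error in the test suite.

Spectral runs derive one substream seed per wavelength from (base seed,
index) via `numpy.random.SeedSequence`.  Re-using the base seed across
optimizer iterations gives common random numbers: the least-squares
objective becomes a smooth deterministic function of the composition, which
is what makes a finite-difference trust-region fit on a stochastic forward
model converge.  Identical inputs and seeds give bit-identical results.

The phase function is Henyey–Greenstein parameterized by the mixture g; the
true hollow-sphere phase function is not sampled (a known approximation of
this modelling chain).  Tallies are spatially integrated because the fit
target is a spatially averaged spectrum.

## Inverse problem

Free parameters are exactly two: the scatterer volume fraction f_scat and
the diluted-pigment fraction f_pig.  The composed medium has

    mu_a = f_pig mu_a_pig + (1 − f_pig − f_scat) mu_a_host,
    mu_s = f_scat mu_s_unit,   g, n independent of composition.

The fit is trust-region-reflective least squares on [0,1]^2
(`scipy.optimize.least_squares`, finite-difference step 1e-3 in fraction
units, default start (0.05, 0.10), optional 3x3 multi-start).  The default
fit grid is 166 uniformly spaced wavelengths on [420, 980] nm; tests and the
acceptance studies use a 20-point reduced grid with 1e5 photons per
wavelength — problem sizes chosen so the full studies run comfortably on a
single CPU.  Goodness-of-fit: global RMSE plus mean and max |Delta R| in the
420–850 and 850–980 nm windows (half-open bins, last window right-closed).
No nuisance amplitude parameter is fitted by default since measured spectra
are white-standard normalized; specular reflection is excluded from the
model for the same reason (both behind config flags).

## Particle sizing

Detection = CLAHE contrast enhancement, Canny edges, then a phase-coded
circular Hough transform: every edge pixel votes along its gradient
direction at all candidate radii with complex weight exp(i phi(r))/r, where
phi encodes log-radius; the accumulator magnitude locates centers and the
phase decodes the radius, refined against the radial gradient profile.
Candidates must show edge response around >= 60% of their perimeter (a
geometric validation that separates faint true circles from chance
alignments better than any accumulator threshold), and near-duplicate
centers are suppressed greedily by accumulator strength.  The `sensitivity`
parameter maps to the accumulator threshold exactly as in the familiar
phase-coded implementations.

Distributions are histograms (default bin 0.5 um): number fractions are
normalized counts; volume fractions weight bins by d^3 — the weighting that
makes the result a volume fraction — and renormalize.  Smoothing is a
centered moving average (default window 11 bins) with shrinking edge
windows.  Undetected-particle bias is accepted as size-independent.

## Synthetic data

Generators are pure functions of (parameters, seed):

* **Size distribution**: an analytic bimodal log-normal number-fraction
  mixture on a 0.1 um grid over [0.5, 60] um; defaults (medians 3.0 and
  10.0 um, sigmas 0.45 and 0.34, weight 0.82 on the small mode) were chosen
  by matching the volume-weighted moments to ~13.5 ± 6 um, the regime of
  the commercial polydisperse microspheres this emulates, and then frozen.
* **Disk images**: anti-aliased bright disks on a dark background with
  Gaussian pixel noise, non-overlapping by rejection sampling.  Real
  electron micrographs add aggregates, partial occlusion and non-uniform
  illumination that these images do not emulate, so detection scores here
  are an upper bound on real-data performance.
* **Cuvette spectra**: the forward transmittance model plus multiplicative
  Gaussian noise, clipped to (0, 1].
* **Reflectance spectra**: the Monte Carlo forward model plus multiplicative
  noise (default 1%), reflecting white-standard normalization.  The
  measurement and any subsequent fit use different Monte Carlo substreams.
* **Pigment and host absorption curves are synthetic stand-ins**: smooth
  curves at realistic magnitudes, the pigment normalized so a 33% stock
  fraction gives mu_a(600 nm) = 0.99 cm^-1.  Recovery results on synthetic
  spectra therefore validate the machinery, not any particular pigment's
  chemistry.

## Identifiability of the inverse problem

The two fitted fractions compensate each other along a ridge (more
scatterer brightens, more pigment darkens, with only mild spectral-shape
differences separating them on a reduced 20-wavelength grid).  The noisy
recovery study in the test suite and acceptance script quantifies the
consequence: with 1% multiplicative spectral noise the per-replicate
recovered fractions scatter by roughly 15–20% relative (noise amplification
~12–15x), while the mean recovered composition over ten replicates stays
within a few percent of truth.  The scatter is statistical, not numerical:
tightening optimizer tolerances or switching to noise-matched relative
residuals changes it by well under one point.  Denser wavelength grids
shrink it roughly with the square root of the point count.

## Known limitations

* Independent scattering only: no packing/dependent-scattering correction,
  so volume fractions well above ~10% overestimate mu_s.
* Henyey–Greenstein is a surrogate for the hollow-sphere phase function;
  anisotropy of hollow spheres is approximated by the equivalent air
  bubble.  Reduced scattering is the quantity most sensitive to this.
* The printed mass-to-volume conversion of the original preparation for the
  7.5% series is not exactly reproducible from the stated density ratio
  (the formula gives 6.35%, not 7.3%); reports surface both numbers rather
  than hard-coding a guess.
* The scaled path engine applies to homogeneous semi-infinite media only;
  layered geometries go through the weighted-packet kernel.
* ENVI support covers the plain header + raw BIL/BSQ/BIP subset, not the
  full format zoo.
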