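# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions that matter when reproducing results.

## Anisotropy → hydrodynamic size

The chain assumes a rigid, globular (spherical-rotor) particle carrying a
fluorophore whose emission depolarises only through overall tumbling.
Under that assumption the steady-state anisotropy `r`, the limit
anisotropy `r0` and the fluorescence lifetime `tau` fix the rotational
correlation time via the Perrin equation, σ = τ / (r0/r − 1), and the
Stokes–Einstein–Debye relation converts σ into a hydrodynamic volume.

The SED relation is often quoted in its molar form σ = ηV/RT, in which V
is a molar volume. This package reports the per-molecule volume
Vh = σRT/(ηN_A); the Avogadro division is what makes a 2.2 ns correlation
time in water at 298 K correspond to ~10 nm³, the scale of a peptide
oligomer. Unit conversions (cP → Pa·s, ns → s, m³ → nm³) are internal;
all public values are ns, nm³ and Å.

Defaults: viscosity 0.89 cP and temperature 298 K (water at 25 °C) and
r0 = 0.260, the literature limit anisotropy of tryptophan excited at
295 nm. All three are plain dataclass fields and overridable per run.
Anisotropies at or above r0 have no finite correlation time and are
rejected rather than clamped. When an uncertainty on `r` is supplied, Vh
and Rh uncertainties are first-order delta-method propagations; second
order terms are negligible at the ±0.001 level typical of polarized
intensity measurements.

Assumptions to keep in mind: no local probe wobble (which would need an
order-parameter correction), no ellipsoidal shape factor, and a single
emitting species. Deviations bias σ, and hence Vh, multiplicatively.

## TCSPC decay fitting

The histogram expectation is B + Σᵢ Aᵢ exp(−t/τᵢ), optionally convolved
with the instrument response on the same channel grid. Fits minimise
chi-square with Poisson weights (variance `max(counts, 1)`; the floor
keeps empty tail channels from acquiring infinite weight). Two modes:

* **tail fitting** (default): the window starts at the count maximum, so
  the IRF-distorted rise is excluded. Adequate when the pulse is much
  shorter than the lifetimes; biased when they are comparable.
* **reconvolution**: the model is IRF ⊗ multi-exponential over the full
  window, using the trace's stored IRF normalised to unit sum.

Initial lifetimes come from a log-linear fit of the tail (longest
component) and a fixed geometric ladder below it; a small fixed set of
perturbed restarts (seeded internally, independent of the data) guards
against local minima, stopping early once the reduced chi-square reaches
the Poisson-expected level (< 1.15). The fit is therefore deterministic
for a given trace and options. Fitted amplitudes are renormalised to
fractions αᵢ and sorted by lifetime; two lifetimes within 5% of each
other flag the fit `ill-conditioned` (the amplitude split between them is
then arbitrary). A fit that converges from no start raises rather than
returning parameters.

The amplitude-weighted mean ⟨τ⟩ = Σαᵢτᵢ is the default summary because it
is the population-weighted mean decay time; the intensity-weighted
alternative Σαᵢτᵢ²/Σαᵢτᵢ weights by emitted photons and is never smaller
(Cauchy–Schwarz). With weights (0.45, 0.41, 0.14) on lifetimes
(1.22, 3.66, 7.40) ns the amplitude mean is 3.09 ns and the intensity mean
≈ 4.5 ns; only the former matches the ~3 ns scale expected for this
tryptophan system, which is why amplitude weighting is the default.

## Pyrene cac assay

The I₁/I₃ ratio uses band maxima within ±2 nm of 372 and 387 nm, making
the extraction insensitive to ≤2 nm calibration shifts and, because it is
a ratio, to the steady quenching of pyrene emission with increasing
peptide concentration.

The cac estimator is the intersection of two straight lines in
(log₁₀ c, ratio) space. The breakpoint search scans every split of the
sorted points with at least three points per side (a two-point side would
fit exactly and overfit), fits each side by ordinary least squares, and
keeps the admissible split with the smallest total squared residual.
A split is admissible when the lines' intersection falls inside the
measured concentration range — with noisy data the intersection can land
one grid step outside its own split's bracket, and demanding otherwise
discards valid fits. No sigmoid alternative is fitted: the two-regime
linear form is the assay's operational definition.

Two degenerate outcomes return `no_breakpoint` instead of a number: no
admissible split at all, and slopes indistinguishable within their joint
standard error. That standard error pools the residual variance over both
segments (n − 4 degrees of freedom); per-segment variances from a 3-point
segment (1 dof) are too noisy to test with. The bootstrap confidence
interval resamples points with replacement (seeded), refits the full
search each time and reports the 2.5–97.5 percentile range of the
estimates.

Exact invariances of the estimator, used as tests: scaling all
concentrations by k scales the cac by k; adding a constant to all ratios
leaves it unchanged; the two reported segments meet at `log10_cac` to
machine precision.

## Coordinate descriptors

Rg is mass-weighted by default (the convention of standard MD
post-processing tools); unweighted mode sets all masses to one. The
Kirkwood hydrodynamic radius Rh = ⟨r_ij⁻¹⟩⁻¹ averages over unordered
pairs of the selected atoms — all carbons by default, matching the usual
coarse estimate for peptides; a Cα-only selection is available for
sensitivity checks. Ordered-pair averaging would give the identical
value. Coincident atoms make the statistic singular and are reported as
an error with the offending pair. For trajectories, Rg and Rh are
computed per frame and summarised as mean ± sd; the volumes Vg and Vh are
spheres of the *mean* radii, and both use the same (4/3)πR³ helper as the
anisotropy chain, so spectroscopic and geometric volumes are directly
comparable.

RMSF is computed over trajectory frames for a named-atom selection
(default Cα), optionally after rigid-body superposition of each frame
onto the selection's mean structure (mean → fit → recompute mean, one
iteration; the rotations come from an SVD-based least-squares fit).
Whether to superpose is left to the caller — without it, overall tumbling
inflates the fluctuations — and both modes are tested.

PDB is the only coordinate format; multi-MODEL files are trajectories.
Elements come from the element column with an atom-name fallback, and
masses from a standard atomic-mass table. Binary trajectory formats are a
documented extension point, not implemented.

## Synthetic data: what it does and does not emulate

* **Decays** reproduce the counting statistics of TCSPC exactly
  (independent Poisson channels) and the pulse shape approximately
  (Gaussian IRF, σ = 0.4 ns by default so the FWHM ≈ 1 ns matches a
  typical diode laser; the true pulse is asymmetric). The convolution is
  linear on the channel grid with a normalised kernel; edge effects are
  ignored because the 50 ns window dwarfs the lifetimes (total expected
  counts are conserved to better than 0.1%). Not emulated: detector
  afterpulsing, pile-up, dark-count drift.
* **Titrations** are exactly piecewise-linear in log-concentration with
  homoscedastic Gaussian ratio noise (sd 0.02 by default — a convention;
  the real assay's scatter is unpublished). Twelve log-spaced points over
  0.2–21 μM with the breakpoint at 4.3 μM mirror the assay's design.
  Real titrations add curvature near the cac from partitioning equilibria;
  recovery results on the synthetic sharp-kink model are therefore an
  upper bound on real-data performance.
* **Geometry fixtures** (regular helices, uniform balls) have analytic or
  brute-force-checkable descriptors; the uniform ball's Rg → R√(3/5) and
  Rh → (5/6)R are asymptotic in the number of points. Unit masses are
  used in fixtures; files read from PDB carry standard masses.

Passing tests on these generators validate the estimators under their own
model assumptions; they do not certify behaviour under model mismatch
(non-exponential decays, curved titrations, flexible aggregates).

## Problem sizes and numerical conventions

The stochastic validation suites use 50 decay traces at 1e4 peak counts,
200 noisy titrations (and 100 titrations × 250 resamples for bootstrap
coverage), and 2×10⁴-point balls for the closed-form geometry checks —
sizes at which the target tolerances (10% per lifetime, 0.05 in log₁₀ cac,
1–2% on the closed forms) are comfortably resolved while the whole suite
runs in a couple of minutes. Pair distances use dense `pdist` arrays
(~1.6 GB at 2×10⁴ atoms; chunking would be the first extension for larger
systems). All randomness flows through seeded `numpy` generators; every
generator is bit-reproducible, and pipeline reports contain no timestamps
so identical config + seed gives byte-identical output.

## Known limitations

* The spherical-rotor assumption has no shape correction; elongated
  aggregates will read as larger spheres.
* Lifetime fits beyond three components are allowed up to four but rarely
  identifiable at 1e4 peak counts; the `ill-conditioned` flag is a
  heuristic, not a rigorous identifiability test.
* The cac estimator assumes exactly one breakpoint; multi-stage
  aggregation (premicellar clusters) would need a multi-breakpoint
  extension.
* Instrument-level observables with no computable procedure here —
  dynamic-light-scattering size distributions, zeta potentials,
  amyloid-type 440 nm emission — are outside the package's scope.
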