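# Methods

This note records the modelling assumptions, numerical conventions and
design choices behind the package, and what the synthetic-data tests do
and do not demonstrate about real measurements.

## Structural parameters

All geometry comes from electron-microscopy measurements of the
transparent wing windows, collected in
`clearwing.wing_models.DEFAULT_REGISTRY` with their reported
uncertainties: membrane layers h_de = 436 ± 20 nm (dorsal exocuticle,
chitin n = 1.56), h_m = 194 ± 7 nm (pigmented mesocuticle, n = 1.74 + ik),
h_ve = 412 ± 10 nm (ventral exocuticle); nipple array h_n = 142 ± 10 nm,
d_n = 135 ± 11 nm, pitch 300 nm; scale interridge microribs
h_mr = 45 ± 2 nm, w_mr = 62 ± 4 nm, gap 58 ± 3 nm over the lower lamina
h_LL = 225 ± 12 nm. The registry is immutable by default and overridable
per run; every report carries the values actually used.

## Pigment optics

The mesocuticle carries melanin. Its extinction coefficient comes from
decadic absorbance via Beer–Lambert, k(λ) = ln(10)·A(λ)·λ/(4πd), where d
is the measured path thickness; the inverse map is exact, and k is linear
in A and ∝ 1/d. Because the measured k(λ) curve is not tabulated here, the
default pigment is a constant k = 0.010 — consistent with the reported
visible-range ceiling of 0.012 — with a tabulated k(λ) accepted wherever a
material is accepted. The membrane's extremum positions are insensitive to
this choice (verified against melanin-like exponentially decaying k(λ)
profiles); the dip depths are the only quantities that move.

## Transfer-matrix solver

Characteristic-matrix (Abelès) formalism at normal incidence, between
lossless semi-infinite media. The public sign convention is n + i·k with
k > 0 absorbing; internally the matrices use the conjugate index because
the implemented r/t expressions correspond to the e^{+iωt} time
orientation (the solver enforces passivity: R + T + A = 1 to machine
precision, asserted at 1e-9 in tests). Only normal incidence is
implemented: the study's simulations use a normally incident plane wave,
and the finite numerical aperture of the microspectrophotometer objective
is deliberately not modelled. The Airy single-slab oracle sums the
multiple-reflection series term by term and shares no code with the matrix
path; both must agree to 1e-10.

## Nipple-array homogenization

The nipple array is a two-dimensional lattice of half-ellipsoids on the
membrane surface. For the transfer-matrix surrogate each height slice z is
replaced by a homogeneous layer at fill fraction

* areal (default): f(z) = π·r(z)²/p², the fill of the actual
  half-ellipsoid lattice (one nipple per p × p cell) — the right
  convention when the homogenized stack stands in for the full 3D
  structure, and the one whose predicted extrema match the measured
  bimodal signature;
* line: f(z) = w(z)/p, the fill of the corrugated 2D cross-section —
  the consistent convention when comparing against this package's own 2D
  FDTD rasters.

Mixing is volume-weighted permittivity by default (Maxwell Garnett
available); 32 slices, converged to < 1e-4 in reflectance against 64.
Nipples sit on **both** membrane faces by default: the dorsal and ventral
exocuticles are the same tissue and both carry the array; a dorsal-only
and a nipple-free variant exist for comparison. Lattice randomness is
ignored in the EMT surrogate.

## 2D FDTD solver

A from-scratch Yee-grid solver in the (x, z) plane: periodic in x (one
300 nm period by default), split-field PML in z (cubic-graded
conductivity, 40 cells by default, ≥ 10 enforced), Courant factor
c·Δt = 0.5·Δx, default Δx = 5 nm with a hard resolution guard
Δx ≤ λ_min/(20·n_max). TM (E out of plane) is the default polarization; TE
(H out of plane, permittivity averaged onto staggered E positions) is
available, and both reproduce the transfer-matrix solution on planar
stacks to < 0.01 absolute (< 0.005 after one grid refinement).

Spectra come from one broadband Gaussian-pulse run with running DFTs of
the x-averaged field at monitor lines, normalized against an empty-domain
reference of identical layout; reflection is the structure-minus-reference
field at the monitor above the source. A run whose field energy has not
decayed below 1e-4 of its peak raises an explicit error rather than
returning truncated spectra. Absorbing media enter through an electrical
conductivity matched to k at the band center (pulsed) or at the run
wavelength (CW); a constant-k material therefore realizes
k_eff(λ) = k·λ/λ₀ across a pulsed band, an error below 1e-3 in absorptance
for the pigment layer and checked exactly in the tests.

Steady-state field maps use a ramped continuous-wave source and per-cell
phasor extraction by DFT over the final cycles, for the structure and the
empty reference; magnitudes are normalized by the reference amplitude at
the reflection monitor. The "reflected-field magnitude above the source"
is the monitor-line average of |total − reference|, which equals √R — the
reading adopted for the printed field values, cross-checked against the
reflectance spectrum to 0.02.

Two genuinely two-dimensional effects deserve note. First, a strictly
periodic single-period corrugated raster of the nipple membrane supports
guided-mode resonances below ~460 nm (first diffracted order propagating
inside chitin) that depress transmittance locally — coherent-grating
physics that the randomly arranged three-dimensional array does not show;
quantitative membrane results therefore use the graded (homogenized)
raster, with the corrugated raster retained for geometry checks. Second,
the interior reflectance minimum of any coherent planar model is a deep
interference null (R ~ 0.001–0.01); a measured or fully 3D simulated dip
sits higher because broadband diffuse backscatter from the random array
fills it. The reflected-field magnitude at the dip is reported as computed
and is expected to undershoot values that include that diffuse floor.

## Spectrum analytics

One canonical extremum rule serves the whole package: detection on a
5-point centered moving average (never applied to stored data), absolute
prominence threshold 0.005, plateau midpoints, endpoints excluded. A
bimodal spectrum is summarized by its two most prominent maxima and the
most prominent interior minimum between them (ties toward the deeper
minimum). Modality is measured by the number of *dominant* maxima —
prominence at least half the strongest — which separates the one-layer
membrane's three equal fringes from the three-layer model's bimodal
envelope, where the interior fringe is suppressed. "Visible" is fixed at
400–700 nm; band means are trapezoid-weighted.

## Membrane-thickness fitting

`fit_membrane_thicknesses` minimizes the RMS reflectance misfit over
(h_de, h_m, h_ve) with a 5³ grid over the bounds (default: the printed
± uncertainties) seeding a bounded trust-region refinement. Deterministic;
the returned residual never exceeds the registry-default residual. On
self-generated spectra it recovers thicknesses to well under 2 nm
(noiseless) and 10 nm (1% multiplicative noise).

## Contact angles

1 µl droplets are small enough that gravity flattening is negligible, so
the silhouette is modelled as a circular cap: algebraic (Kåsa) circle fit
seeding a geometric least-squares refinement on the contour points above
the baseline, excluding a band within 2% of the droplet height above the
contact line (where reflection artifacts live in real goniometry). For a
circle of radius r centered height c above the baseline the angle through
the liquid is θ = 90° + asin(c/r), identical at both contact points by
construction. Fits whose radius diverges past 10³ times the contour span
are rejected as degenerate. The t statistic and degrees of freedom of the
group comparison are computed from the explicit formulas (paired:
d.f. = n−1, the default, matching the reported d.f. = 4 at n = 5;
unpaired pooled: d.f. = n_a + n_b − 2) with p-values from the Student-t
distribution; reproducing the study's exact printed p-values would
require the raw per-droplet angles, which are not bundled.

## Synthetic data

The generators emulate the *structure* of the measurements, not the
instrument: spectra get a per-replicate multiplicative gain
(sd 1%) plus per-point additive noise (sd 0.002), averaged over three
replicates as in the bench protocol — the magnitudes are declared
assumptions; droplet contours are exact circular caps plus isotropic
coordinate noise; structural jitter draws each length from a truncated
normal (± 3 sd, positive) at the printed mean and sd. Every stochastic
call takes a mandatory seed and uses a private generator stream, so
emitted CSVs are byte-reproducible. Passing recovery tests on these
fixtures demonstrates the estimators are correct and well-conditioned at
realistic noise levels; it does not validate the noise model itself, nor
cover instrument wavelength-calibration error, baseline drift, or
non-circular droplet distortion.

## Pipeline and reproducibility

The three analyses (membrane, scale, wettability) write plain CSV/JSON
without timestamps; identical configuration and seed reproduce
byte-identical outputs (tested by digest). Reports embed the registry
values and overrides used. The ridge model's air-gap and lamella
thicknesses are not measured quantities and are required inputs — the
pipeline marks the ridge stage "not run" when absent; the pair
(h_air = 30 nm, lamella = 85 nm), located by scan, is kept as a frozen
regression fixture reproducing the ~410 nm ridge peak. Problem sizes used
throughout (1 nm TMM grids, 2–10 nm FDTD bands, single-period domains,
5-droplet groups) match the study's scales while keeping any single
computation under a minute on one CPU.

## Known limitations

* Normal incidence only; no numerical-aperture averaging, oblique angles
  or polarization-resolved quantities.
* The FDTD solver is 2D; fully 3D nipple lattices (and their random
  arrangement) are represented only through the areal-fill EMT surrogate.
* Constant default pigment k; dispersive melanin must be supplied as a
  table.
* No color-space (CIE/RGB) conversion of spectra.
* Ridge–interridge coupling and the scales' natural ~80° tilt are not
  modelled; scale models are illuminated face-on.
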