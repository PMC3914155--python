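# Methods

## Model and estimator

The package reconstructs volumetric current source density (CSD) from
extracellular potentials under the quasi-static approximation, in which the
potential obeys the Poisson equation
∇·(σ∇φ) = −C with conductivity tensor σ.  Solving the equation for a point
current in a given volume conductor yields a Green's function
G(r_e, r_s); discretizing the sources on a cubic grid of spacing d turns
the forward problem into Φ = G I with I_j = C_j d³.  All geometry is in
micrometers in a local frame (x, y tangential; z = depth below the pia,
positive downward); unit conversion to SI happens only inside the conductor
kernels.

The inverse is the Laplacian-penalized least-squares estimate

  Ĉ = (G′G + λ L′L)⁻¹ G′Φ,   L = (6/d²)(W − E),  W_ij = 1/6 at
  face-adjacent node pairs,

applied independently per time instant.  Boundary rows of W are *not*
renormalized: rows with fewer than six neighbors keep the full −6/d²
diagonal, so the prior additionally pushes the solution toward zero on the
grid boundary.  Around the electrode-covered region the grid carries guard
planes (three per side tangentially, two per side in depth for the
30×30×28 recording grid): their nodes stay in the inverse and absorb
sources from outside the region (a free boundary condition), but they are
excluded from every reported plane and metric.

λ is selected by generalized cross-validation, E(λ) = ‖PΦ‖²/tr(P)² with
P = E − G(G′G + λL′L)⁻¹G′, minimized over 40 log-spaced values spanning
[1e−6, 1e4] × tr(G′G)/tr(L′L) — a scale-aware default; ties break toward
the larger (smoother) λ.  λ = 0 is accepted only when the system is
genuinely overdetermined and well-conditioned; with more sources than
electrodes the normal matrix is rank-deficient by construction and λ = 0 is
rejected with an explicit error.

### Numerical path

With M ≫ N sources, forming the M×M normal matrix is wasteful.  Since L is
nonsingular on a bounded grid, the solver uses the algebraically identical
dual form Ĉ = R⁻¹G′(G R⁻¹G′ + λE)⁻¹Φ with R = L′L, factoring the sparse L
once (LU) and eigendecomposing the N×N kernel G R⁻¹G′ once; every λ and
every time instant then costs a few matrix–vector products, and the GCV
curve comes from the same eigenvalues.  A dense primal Cholesky path exists
for small systems; unit tests verify both against a brute-force dense
transcription to 1e−8.

## Volume conductors

**InfH** — infinite homogeneous isotropic medium, kernel 1/(4πσr); default
σ = 0.3 S/m (generic gray matter).

**SphIh** — concentric spherical regions, each with radial and tangential
conductivity, embedded in an unbounded isotropic outer medium.  The model
is open (potential → 0 at infinity) because a monopolar source has no
steady state inside an insulated sphere.  The kernel is a Legendre series;
within a region the radial solutions are powers r^ν and r^(−ν−1) with
ν(n) = −1/2 + sqrt(1/4 + (σ_t/σ_r) n(n+1)), chained across boundaries by
continuity of φ and σ_r ∂φ/∂r.  Coefficients are propagated in the log
domain, so the chaining is stable to arbitrary degree.  Convergence is
geometric with ratio exp(−∫ sqrt(σ_t/σ_r) dln r) along the radial path
between the two points, which is slow for nearby radii; the summation
therefore subtracts a two-term asymptote (c₀ + c₁/n)·gⁿ fitted to the last
computed terms and restores its closed-form Legendre sums analytically.  In
the homogeneous-isotropic limit the exact term *is* c₀gⁿ, so the sum
collapses to 1/(4πσ|r_e − r_s|) at machine precision regardless of the
truncation depth (verified to 1e−6 over random pairs as an acceptance
check, and per-harmonic against direct ODE integration of the radial
problem).  Defaults: series tolerance 1e−8 (relative-term cutoff),
512 terms, acceleration on.  A conservative tail bound raises a
convergence error only for genuinely near-singular geometry; electrode/node
layouts are additionally guarded by a d/10 exclusion radius.

Registration of the flat grid to the sphere: the region-of-interest axis
passes through the sphere center; a local point (x, y, z) sits at
(x, y, R_pia − z) relative to the center.  A flat plane therefore bulges
slightly relative to the spherical layers, exactly as a flat probe does in
curved cortex.

**Shipped profile.**  The package's default six-layer profile (white-matter
core at 3.0 mm, layer shells up to a 5.0 mm pia radius, saline above) is a
*synthetic, plausible* profile: generic gray-matter conductivities
(0.35–0.45 S/m radial) with mild layer-wise anisotropy (tangential/radial
ratios 0.75–0.95), white matter 0.14 S/m, saline 1.5 S/m.  It is not a
measured dataset, and no published conductivity table is reproduced here.
Every validation experiment is profile-agnostic: the same model generates
and inverts the data, so conclusions do not depend on the specific values.

## Synthetic data

The phantom generators define the study conditions:

* **Charge-balanced**: sin(2π(z−z₀)/T)·exp(−(x²+y²)/(2l²)) for
  |z−z₀| < T/2, else 0 — one axial period of a sinusoid, Gaussian
  tangentially.
* **Charge-unbalanced**: exp(−‖r−r₀‖²/(2l²)).  The width parameter l is
  used as the Gaussian standard-deviation parameter throughout; the term
  "FWHM" attached to it in the source literature conflicts with the
  equations, and the equations win.  The isotropic-blob variant used in the
  noise sweep adopts the same /(2l²) convention for consistency.

Observation noise is i.i.d. Gaussian per channel and time instant with
variance β times the spatial sample variance of the potentials
(β ∈ {0.01, 0.05, 0.1, 0.5} are the standard levels), seeded and
reproducible.

**Mismatch experiment** (matched vs homogeneous inversion): 16×16×28 grid,
d = 50 µm, dense 9×9×15 array at 100 µm pitch, ten trials with phantom
depths uniform over the middle two-thirds of the grid's depth extent;
phantom sizes small (l = 200 µm, T = 600 µm) and large (l = 400 µm,
T = 1200 µm) — the size pair is a package choice, as only "small and
large" sources are described in the source literature.  Potentials are
average-referenced, emulating recording practice.  Simulation grids carry
no guard planes (the reconstruction error sums over all nodes).

**Noise × pitch sweep**: 24×24×24 grid at 50 µm, Gaussian blobs with
l = 400 µm at uniform random centers (inset 200 µm), arrays covering a
fixed 1.2×1.2×1.4 mm volume at 200–600 µm pitch, forward and inverse both
homogeneous so that the comparison isolates noise handling.  Full scale is
50 trials per cell; the test suite runs 5 trials per cell at the two
extreme noise levels and pitches, which reproduces the qualitative
tradeoff (the problem sizes were chosen so the suite completes on one CPU).

**Barrel benchmark**: synthetic layer-4 barrel sinks (cylinder footprint,
radius 150–220 µm, depth band 650–850 µm, smooth taper) on the 30×30×28
recording grid, observed by the 128-site probe through the layered-sphere
conductor at β = 0.1 noise.  The regularized inverse uses the matched lead
field; the interpolation baseline — which by its published construction
assumes a homogeneous medium — observes the 64-site equidistant subset, as
it did in the original comparison.  The synthetic mask stands in for the
histological gold standard (cytochrome-oxidase barrel outlines).  Under
these matched-noise desk conditions both methods are limited by the 400 µm
tangential pitch and their localization errors are close (≈0.7 on the
2-norm metric); the benchmark asserts only the ordering of the medians,
not the absolute real-animal values, which require in-vivo data.

## Barrel localization

The layer-4 plane of interior nodes is sign-flipped so current sinks
(negative CSD) become positive — peak normalization is only meaningful on
the sink-positive representation — then normalized to a maximum of exactly
1.  The functional barrel F(α*) is the super-threshold set whose area best
matches the anatomical mask's; because the area is piecewise constant in
α, the exact argmin is found over the sorted unique plane values, ties
toward the larger threshold.  The localization error is
‖A − F(α*)‖₂/‖A‖₂ on the binary rasters, implemented exactly as printed in
the defining equation.  Note its actual range: a perfect match scores 0,
but two disjoint equal-area barrels score √2, not 1 — the statement that
the worst case is 1.0 is inconsistent with the formula, and no rescaling
is applied here.

## Preprocessing front-end

Butterworth band-passes (LFP 1–500 Hz, unit 500 Hz–8 kHz), order 4,
applied forward–backward for zero phase so ERP and STAP latencies are
preserved; the corners must lie below Nyquist.  ERPs average stimulus-locked
epochs (default window −50 to +100 ms).  Spike detection: negative
crossings of −4× the channel standard deviation (an MAD-based robust
estimate is available by flag), 1.5 ms dead time, spike time at the trough,
20-sample snippets (8 before / 12 after).  Spike-triggered averages are
computed on whichever band the caller supplies; cluster labels (e.g.
pyramidal vs interneuron) are accepted from external spike-sorting tools
and are not produced here.

## Known limitations

* The layered-sphere kernel's accelerated truncation is exact in the
  homogeneous limit but approximate (relative error typically < 1e−4 at
  512 terms) for strongly anisotropic profiles with nearly equal source and
  electrode radii; validation experiments use the same kernel forward and
  inverse, so this does not bias the reported errors.
* The inverse-CSD baseline substitutes step elements and trilinear
  extension for the published spline bases; it is labeled "approximate" in
  outputs and comparisons against it are qualitative.
* The synthetic noise is white across channels and time; real recordings
  carry correlated and 1/f physiological noise, so passing the synthetic
  benchmarks does not guarantee the same error levels in vivo.
* Grids are regular lattices; histology-warped geometries are out of scope.
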