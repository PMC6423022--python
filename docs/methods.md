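# Methods

## Model

A protein is a hard sphere of diameter `D` (7 nm for albumin; the excluded
volume in solution screens the molecule's heart shape, so the spherical
coarse graining is standard for small globular proteins).  The substrate
is a single-valued height field `z = f(x, y)` over a periodic lateral
cell; no overhangs.  Three surface families are supported:

* **flat** — the classical 2D hard-disk RSA benchmark;
* **Gaussian arrays** — axisymmetric features `H exp(−r²/2v)` with
  `v = (W/2)²/(2 ln 2)` (so `W` is the width at half height), truncated
  to zero outside the lateral radius `d_p/2` and tiled with period `d_p`.
  The truncation is part of the definition: when the Gaussian has not
  decayed at `d_p/2` the profile steps discontinuously to zero there, and
  the gradient is defined as zero in the flat region.  Signed `H` gives
  pillars/spikes (`H > 0`) or holes (`H < 0`);
* **height maps** — gridded AFM-like scans, bilinearly interpolated, with
  the gradient from periodic central differences at the nodes (itself
  interpolated).  Tiles wrap periodically, which avoids edge-depletion
  bias and matches the treatment of the parametric surfaces.

Deposition is irreversible RSA: an anchor point is drawn uniformly with
respect to *curved* area (uniform lateral proposals thinned by
`w/w_max`, `w = √(1 + |∇f|²)`); the sphere centre sits at
`anchor + (D/2) n̂` (tangent placement — on a flat substrate this reduces
exactly to 2D hard-disk RSA, which is why we adopt it); the attempt is
rejected if any existing centre is within `D` (3D distance, minimum image
laterally) or, by default, if the sphere would dip below the substrate
anywhere on its lower hemisphere (chord test on a lateral stencil of step
`D/10`, tolerance `10⁻³ D`; exposed as a toggle because the pure
pair-exclusion variant is also of interest).  Coverage is normalised by
the curved area: `θ = N σ / A_s`.

## Engine and determinism

The attempt loop is compiled (numba).  Exclusion uses a 3D cell list
(lateral + vertical cells of edge ≥ D, so only the 3×3×3 neighbourhood is
scanned); a brute-force all-pairs back-end shares the identical code path
and random-stream consumption, and the test suite asserts bit-identical
deposit sequences between the two on batches of random small systems.
Each repeat runs on its own seeded legacy MT19937 stream (`seed + repeat
index`); per anchor candidate the stream yields `u_x, u_y` and, on curved
surfaces, one thinning variate, in that order.  Identical configuration
and seed therefore reproduce byte-identical outputs.

## Stop rule (jamming)

True RSA saturation is approached algebraically, so a finite run always
undershoots `θ∞`.  A run is declared jammed after `stop_after_failures`
consecutive rejections.  The default is 3×10⁶, set by a convergence study
on the flat benchmark: doubling the threshold then moves the mean final
coverage by ≈0.001, comparable to across-repeat noise, and the flat mean
lands at 0.542 against the literature 0.547 ± 0.002.  Much looser rules
bias visibly (2×10⁵ gives ≈0.533).

## Surface area, spacing calibration and problem sizes

`A_s` is a midpoint-rule integral of `w` at resolution `D/10` (0.7 nm);
refining 2× changes Gaussian-array areas by < 0.1%.  The peak spacing
`d_p` is generally not a primary input: reference geometries are stated
as (H, W, A_s/A_f), and `calibrate_dp` recovers `d_p` by bisection of the
same integrator (the ratio is strictly decreasing in `d_p`), making the
round trip self-consistent to 10⁻³.

Default problem sizes are desk-scale: 20 repeats (the reference study
used 1000) on a 500×500 nm flat box (~3500 spheres per run), and one to
two unit cells (~180–360 nm) for Gaussian arrays.  A finite-size check
(1×1 vs 2×2 cells on the sharp spike) moved `θ∞` by 3×10⁻⁴, an order of
magnitude below the across-repeat spread, so the small tiles are used in
the test suite; the acceptance script uses 2×2 cells for the hole
geometry and the full 500 nm box for flat.

## Blocking statistics

Two estimators of `B(θ)` are provided and cross-checked: the pooled
binned ratio (successes over attempts per coverage bin, the `N_succ/N_att`
definition; coverage is piecewise constant between successes, so the
binning is exact) and the reciprocal of the across-repeat mean attempts
per deposit index.  They agree within 2 pooled standard errors up to
θ ≈ 0.5 and diverge systematically in the jamming bin, where the binned
ratio includes the final (censored) failure streak and the
inverse-attempts estimator does not; which definition the reference
analysis used is ambiguous, so both carry estimator tags.  Standard
errors come from across-repeat variation (binomial fallback for a single
run); the default bin width 0.01 resolves the near-jamming tail without
starving bins at 20 repeats.

Cubic fits pin the intercept at `B(0) = 1` and report the free-intercept
fit (with standard errors) as a diagnostic.  Two fit ranges matter:

* restricted to the expansion's validity range (`theta_max ≈ 0.3`) the
  fit recovers the analytic coefficients — the linear term comes out
  −3.9 ± 0.1 against the theoretical −4;
* over the full range the cubic is only an effective parameterisation
  (the measured linear term steepens to ≈ −5.2) because `B` spans five
  decades and vanishes tangentially at jamming.

Note that the *binned* estimate near θ = 0 is the bin average of a
steeply falling function, not `B(0)` itself: with bin width 0.01 the
first bin is centred where the true `B ≈ 0.98`.  Statements about
`B(0) = 1` are therefore made through the extrapolated fit intercept.

## Kinetics

`dθ/dt = k_a n B(θ) − k_d θ` is integrated adaptively (LSODA, rtol 10⁻⁸)
with `B` from either the Langmuir form `θ∞ − θ` (closed-form checks) or a
fitted cubic clamped to `max(poly, 0)` and to 0 at its first positive
root, which defines the kinetic `θ∞`.  The bulk concentration is treated
as constant (no depletion).  Units: `k_a n` is s⁻¹ with `k_a` in
L mol⁻¹ s⁻¹ and `n` in mol/L; Avogadro conversion enters only the
diffusion timescale `τ_D = 1/(n² σ² D_dif)` (with `n` in molecules/m³,
`σ` in m²), which evaluates to 0.77 s at 1.06×10⁻⁵ mol/L and 3.1×10⁻⁴ s
at the blood-plasma 5.3×10⁻⁴ mol/L for albumin.  `τ_a` is reported as
the time to reach 99% of the plateau, since the adsorption timescale is
otherwise not defined numerically.

**Known quantitative caveat.**  The often-quoted statement that the
kinetic plateau coincides with the jamming limit when `k_d ≪ k_a n` is an
artifact of loose cubic fits whose root crosses zero linearly at `θ∞`.
The steady state actually satisfies `B(θss) = k_d θ/(k_a n)` ≈ 6×10⁻⁵ at
the albumin constants and blood concentration, and a faithfully measured
blocking tail (which vanishes tangentially, ∝ (θ∞ − θ)³) reaches that
level 2–3% of coverage below `θ∞`.  Solving the ODE with any honest
representation of `B` therefore plateaus 2–3% below the jamming limit;
the corresponding reproduction test in the acceptance suite asserts the
claimed 1% band and is expected to fail, deliberately, with this analysis
as the explanation.

## Synthetic AFM-like surfaces

The real bSi scan is not distributable, so a generator emulates it:
Poisson-placed spike centres thinned to a minimum separation (generation
fails if the requested density is infeasible for the separation), each
spike a truncated Gaussian with height and width jittered around the bSi
nominal values (H = 500 ± 50 nm, W = 60 ± 6 nm); overlapping solids
combine by pointwise maximum; finally a grayscale dilation with a
spherical structuring element applies the AFM tip-convolution artifact.
Defaults: 35 candidate spikes/μm² (the density matching the calibrated
array spacing of the reference spike geometry), 80 nm separation, 10 nm
tip, 512 pixels per 2.5 μm.

What the generator does and does not emulate: at the default density the
field is convex-dominated (spike caps over an open floor) and jams
*above* the flat limit, like the periodic spike arrays.  Real bSi jams
well below flat because its recorded topography is valley-dominated.
That regime is reached by construction — density high enough that the
spike bases merge (mean gap < base width) and a blunt tip (radius
~40 nm) that leaves sharp creases where sphere centres are excluded; the
corresponding test verifies the qualitative claim (rough field below
flat) in exactly that regime.  Passing it says the engine responds to
concave morphology correctly; it does not certify quantitative agreement
with any particular scan.

## Numerical choices and degenerate inputs

* Rejection-free sampling bound `w_max`: analytic for Gaussian arrays
  (radial slope maximum), node-wise bound for bilinear height fields
  (interpolation is a convex combination, so node maxima bound the field).
* Bisection brackets: `d_p ∈ [W, 50 W]`; calibration outside it raises.
* Cells smaller than 3 diameters per side fall back to the brute-force
  exclusion scan automatically.
* A run that exhausts `max_attempts` before the failure streak is flagged
  budget-limited and excluded from jamming statistics.
* Empty coverage bins are dropped, never interpolated.

## Limitations

Single protein species, spherical and rigid (no Vroman competition, no
conformational change); irreversible placements with no surface diffusion
or relaxation; desorption only through the mean-field ODE, never inside
the Monte Carlo; no coupled diffusion–adsorption transport (the
closed-form `τ_D` estimate only brackets the regime); height-field
substrates cannot represent overhangs; AFM tip artifacts are emulated,
not deconvolved.
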