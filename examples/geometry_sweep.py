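"""How nanostructure shape shifts the jamming limit.

Compares a sharp Gaussian spike (black-silicon-like, H=500 nm, W=40 nm)
against a Gaussian hole (H=-550 nm, W=60 nm), with the peak spacing
calibrated so the curved-to-flat area ratio matches the reference values
(2.8 and 3.8).  Convex features jam above the flat limit, concave ones
below: coverage is not just an area effect.  Reference values: spike
0.597, hole 0.499, flat 0.545.
"""

import nanorsa as nr

flat = nr.jamming_limit(nr.run_repeats(
    nr.make_flat_surface(300.0), nr.HSA,
    nr.AdsorptionConfig(seed=3, repeats=4, stop_after_failures=500_000)))
print(f"flat   : theta_inf = {flat.theta_inf:.4f} +/- {flat.sd:.4f}")

for name, H, W, ratio in [("spike", 500.0, 40.0, 2.8), ("hole", -550.0, 60.0, 3.8)]:
    d_p = nr.calibrate_dp(H, W, ratio)
    surface = nr.make_gaussian_surface(nr.GaussianArraySpec(H, W, d_p))
    config = nr.AdsorptionConfig(seed=5, repeats=4, stop_after_failures=500_000)
    est = nr.jamming_limit(nr.run_repeats(surface, nr.HSA, config), flat)
    print(f"{name:7s}: d_p = {d_p:.1f} nm, A_s/A_f = {est.area_ratio:.2f}, "
          f"theta_inf = {est.theta_inf:.4f} +/- {est.sd:.4f}, "
          f"delta vs flat = {est.delta * 100:+.1f}%, Ns/Nf = {est.ns_over_nf:.2f}")
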