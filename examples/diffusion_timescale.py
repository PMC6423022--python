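"""Diffusion versus adsorption timescales for albumin.

h = 1/(n sigma) is the depth of solution that holds one monolayer's worth
of protein; tau_D = h^2/D_dif estimates how long diffusion needs to
deliver it.  At blood concentration tau_D is sub-millisecond, so the
adsorption step (seconds) limits the kinetics; at 50x dilution tau_D
approaches a second and transport starts to matter.
"""

import nanorsa as nr
from nanorsa.stats import FLAT_BLOCKING_COEFFS

blocking = nr.BlockingPolynomial(FLAT_BLOCKING_COEFFS)

for n in (1.06e-5, 5.3e-4):
    spec = nr.KineticsSpec(n=n)
    est = nr.diffusion_timescale(nr.HSA, n, spec, blocking)
    print(f"n = {n:.2e} mol/L: h = {est.h * 1e6:.2f} um, "
          f"tau_D = {est.tau_D:.2g} s, tau_a (99% of plateau) = {est.tau_a:.2g} s")
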