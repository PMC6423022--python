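"""Coverage versus time and the Langmuir comparison.

Integrates d theta/dt = k_a n B(theta) - k_d theta with the albumin rate
constants (k_a = 1e4 L/mol/s, k_d = 5.78e-4 1/s) using the analytic flat
blocking cubic, at the blood-plasma albumin concentration and a 50x lower
one.  Then compares the exclusion-effect (RSA) steady-state isotherm with
the Langmuir isotherm at matched constants: the RSA curve needs a higher
concentration to approach saturation.
"""

import numpy as np

import nanorsa as nr
from nanorsa.stats import FLAT_BLOCKING_COEFFS

blocking = nr.BlockingPolynomial(FLAT_BLOCKING_COEFFS)

for n, t_end in ((5.3e-4, 20.0), (1.06e-5, 600.0)):
    spec = nr.KineticsSpec(n=n)
    traj = nr.solve_kinetics(spec, blocking, t_end=t_end)
    t63 = traj.t[np.argmax(traj.theta >= 0.63 * traj.plateau)]
    print(f"n = {n:.2e} mol/L: plateau = {traj.plateau:.4f}, "
          f"63% of plateau after {t63:.2g} s")

spec = nr.KineticsSpec(n=1e-4)
n_grid = np.geomspace(1e-9, 1e-4, 40)
th_rsa = nr.rsa_isotherm(spec, blocking, n_grid)
th_lang = nr.langmuir_isotherm(spec, blocking.theta_inf, n_grid)
n90_rsa = n_grid[np.argmax(th_rsa >= 0.9 * th_rsa[-1])]
n90_lang = n_grid[np.argmax(th_lang >= 0.9 * th_lang[-1])]
print(f"concentration for 90% saturation: RSA {n90_rsa:.2e} mol/L, "
      f"Langmuir {n90_lang:.2e} mol/L (RSA saturates later)")
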