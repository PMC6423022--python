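# nanorsa

Random sequential adsorption (RSA) of globular proteins on nanostructured
surfaces: a hard-sphere Monte Carlo deposition engine for parametric
Gaussian nanostructure arrays and AFM-like height maps, with the analyses
that turn raw depositions into adsorption science — blocking functions,
jamming limits, adsorption kinetics and diffusion timescales.

## The problem

How much protein sticks to a nanostructured biomaterial, and how fast?
Surfaces such as black silicon (bSi) or cicada wings carry dense
nanoscale spikes and pillars; protein adsorption on them controls
biocompatibility and antifouling behaviour.  `nanorsa` models a globular
protein (human serum albumin by default) as a hard sphere of diameter
`D = 7 nm` that adsorbs irreversibly at random area-weighted positions on
a substrate `z = f(x, y)`, subject only to steric exclusion:

* coverage `θ = N σ / A_s` with `σ = π D² / 4` and `A_s` the curved area;
* the **blocking function** `B(θ) = N_succ / N_att` is the probability an
  attempt succeeds at coverage `θ`; on a flat substrate it expands as
  `B(θ) = 1 − 4θ + (6√3/π) θ² + (40/(π√3) − 176/(3π²)) θ³ + O(θ⁴)`;
* the **jamming limit** `θ∞` is the final coverage (0.547 ± 0.002 for
  hard disks on a flat plane);
* mean-field kinetics follow `dθ/dt = k_a n B(θ) − k_d θ`, whose Langmuir
  special case `B = θ∞ − θ` has the closed-form isotherm
  `θ = K_eq n / (1 + K_eq n) · θ∞`;
* the closed-form diffusion timescale `τ_D = 1/(n² σ² D_dif)` bounds the
  regime in which adsorption, not transport, limits the kinetics.

Convex features (spikes, pillars) raise `θ∞` above the flat value;
concave ones (holes, valleys) lower it — surface occupancy is a shape
effect, not just an area effect.

## A worked example

```python
import nanorsa as nr

# flat benchmark: classical hard-disk RSA
flat = nr.jamming_limit(nr.run_repeats(
    nr.make_flat_surface(500.0), nr.HSA, nr.AdsorptionConfig(seed=7, repeats=20)))

# black-silicon-like spike, spacing calibrated to the curved/flat area ratio 2.8
d_p = nr.calibrate_dp(H=500.0, W=40.0, target_ratio=2.8)
spike_surface = nr.make_gaussian_surface(nr.GaussianArraySpec(500.0, 40.0, d_p))
spike = nr.jamming_limit(
    nr.run_repeats(spike_surface, nr.HSA, nr.AdsorptionConfig(seed=11, repeats=12)),
    flat_reference=flat)

print(f"flat  theta_inf = {flat.theta_inf:.4f} +/- {flat.sd:.4f}")
print(f"spike theta_inf = {spike.theta_inf:.4f} +/- {spike.sd:.4f} "
      f"(delta vs flat {spike.delta*100:+.1f}%, Ns/Nf = {spike.ns_over_nf:.2f})")
```

prints

```
flat  theta_inf = 0.5425 +/- 0.0022
spike theta_inf = 0.5989 +/- 0.0044 (delta vs flat +10.4%, Ns/Nf = 3.09)
```

i.e. the sharp spike array jams about 10% above the flat limit, and — the
area ratio being 2.8 — binds about 3.1x as much protein per projected
area.  The `examples/` directory holds one short script per capability
(flat jamming, geometry sweep, blocking function, kinetics and isotherms,
diffusion timescales, synthetic AFM-like surfaces), each printing and
explaining its numbers.

A thin CLI covers the same ground for shell use:

```bash
nanorsa timescale -n 1.06e-5 -n 5.3e-4
nanorsa synth-surface --out bsi.dat
nanorsa simulate --config run.yaml --out run
```

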