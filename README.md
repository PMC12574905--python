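# hetasym

Joint reconstruction of **regional effective heterogeneity** and **asymmetric
structural connectivity** from neural activity and a symmetric connectome.

## The problem

Directed interactions between brain regions (effective connectivity) mix two
things that are usually entangled: the anatomical asymmetry of the underlying
projections, and per-region differences in excitability, gain and saturation.
Diffusion imaging only delivers the *symmetric* part of structural
connectivity, `W = (C + Cᵀ)/2`, while activity recordings carry the
directional information. This package implements a two-step framework that
puts the pieces together for anyone modeling large-scale cortical dynamics or
inferring connectivity from multivariate recordings:

1. **Temporal reconstruction.** For activity fluctuating around a stable
   fixed point, the dynamical differential covariance (DDC) estimator

   `Ĵ = ⟨dS/dt, S⟩ ⟨S, S⟩⁻¹`

   is an unbiased estimate of the Jacobian of the linearized dynamics.

2. **Spatial separation.** At a fixed point of the heterogeneous mean-field
   models implemented here, the Jacobian factorizes off the diagonal as
   `J_ij = h_i C_ij`, with effective heterogeneity
   `h_i = γ G (1 − S_i*) H′(x_i*)`. Writing `y_i = 1/h_i`, the symmetric
   constraint gives one linear equation per region pair,
   `Ĵ_ij y_i + Ĵ_ji y_j = 2 W_ij`, solved by least squares; then
   `ĥ_i = 1/ŷ_i` and `Ĉ_ij = ŷ_i Ĵ_ij`.

Around this core the package provides: three validated mean-field models
(heterogeneous `w_i, I_i`; heterogeneous `τ_i, b_i`; and an
excitatory–inhibitory circuit whose hidden inhibition is absorbed by the
Schur complement `J_eff = J_EE − J_EI J_II⁻¹ J_IE`), feedback inhibition
control (FIC) that calibrates regional rates to ~3 Hz, degenerate baselines
(no-asymmetry, no-heterogeneity), detailed parameter recovery, and the
sampling-interval correction `Ĵ_o = ln(T Ĵ_T + I)/T` for activity observed
every `T` seconds. A synthetic connectome generator emulates a macaque-like
tracer matrix (N = 29, density 0.65, heavy-tailed weights, unit row sums,
tunable asymmetry level η).

## Worked example

```python
import numpy as np
from hetasym import connectome as cn, dynamics as dy, simulate as sm
from hetasym import reconstruct as rc, metrics as mt

conn = cn.generate_synthetic_connectome(n=29, density=0.65, target_eta=0.7, seed=1)
print(f"eta = {cn.asymmetry_level(conn.C):.3f}")

params = dy.default_modelA(conn, G=0.8)            # standard constants + gradients
gt = dy.ground_truth(params)                       # fixed point, exact J, true h

traj = sm.simulate(params, duration=5000.0, dt=0.001, seed=7)
J_hat = rc.ddc_estimate(traj)
dec = rc.spatial_separation(J_hat, conn.W)

print(f"RE(J) = {mt.relative_error(gt.J, J_hat):.3f}")
print(f"RE(h) = {mt.relative_error(gt.h, dec.h_hat, 'vector'):.3f}")
print(f"RE(C) = {mt.relative_error(conn.C, dec.C_hat, 'offdiag'):.3f}")
h_sym = rc.baseline_no_asymmetry(J_hat, conn.W)
print(f"RE(h), no-asymmetry baseline = {mt.relative_error(gt.h, h_sym, 'vector'):.3f}")
```

Output:

```
eta = 0.689
RE(J) = 0.009
RE(h) = 0.095
RE(C) = 0.241
RE(h), no-asymmetry baseline = 0.224
```

The estimated Jacobian is essentially exact (relative error below 1%); the
separation recovers the 29 regional heterogeneities to ~10% and the directed
weights to ~24% from 5,000 s of noisy activity, while forcing the connectome
to be symmetric more than doubles the heterogeneity error — the directional
information in the activity is doing real work.

A thin CLI mirrors the library:

```bash
hetasym gen-connectome --n 29 --density 0.65 --eta 0.7 --seed 1 --out sc.csv
hetasym simulate --model A --sc sc.csv --g 0.8 --duration 1000 --out traj.h5
hetasym reconstruct --traj traj.h5 --sc sc.csv --out dec.h5
hetasym sampling-sweep --sc sc.csv --t 0.01,0.1,0.3 --out sweep.csv
hetasym ei-pipeline --n 29 --g 0.1 --fic --out report.json
```

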