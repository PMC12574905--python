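# Methods

## Models

All models describe per-region synaptic gating variables driven by additive
white noise on a directed connectome `C` (`C[i, j]` = weight of the j → i
projection; `G` = global coupling).

**Model A** (heterogeneous recurrent strength and input):

    dS_i/dt = −S_i/τ_s + γ (1 − S_i) H(x_i) + σ ν_i(t)
    H(x)    = (a x − b) / (1 − exp(−d (a x − b)))
    x_i     = w_i S_i + G Σ_j C_ij S_j + I_i

with τ_s = 0.1 s, γ = 0.641, a = 270 nC⁻¹, b = 108 Hz, d = 0.154 s,
σ = 0.01. The heterogeneity gradients follow the anatomical hierarchy:
w_i ascends linearly over [0.0652, 0.1581] nA and I_i descends over
[0.33, 0.30] nA.

**Model B** moves the heterogeneity into per-region time constants τ_i and
firing thresholds b_i while w and I are scalar. Its ground-truth instances
are produced by `map_A_to_B`, which maps a Model A instance onto Model B at
the same state: b_i is chosen so the gains match exactly (this makes the
off-diagonal Jacobians identical), τ_i then matches the diagonal. Steady-state
self-consistency of the mapped model is approximate by construction; in
practice its own fixed point sits within ~5·10⁻³ of the source state and the
stationary functional connectivity correlates at > 0.999.

**Model C** adds a hidden inhibitory population per region (only excitatory
populations project long range):

    dS_Ei/dt = −S_Ei/τ_E + γ (1 − S_Ei) H_E(x_Ei) + σ ν_Ei
    dS_Ii/dt = −S_Ii/τ_I + H_I(x_Ii) + σ ν_Ii
    x_Ei = w_EEi S_Ei + G Σ_j C_ij S_Ej − w_EIi S_Ii + I_E
    x_Ii = w_IEi S_Ei − S_Ii + I_I

with τ_E = 0.1 s, τ_I = 0.01 s, (a, b, d) = (310, 125, 0.16) for E and
(615, 177, 0.087) for I, I_E = 0.382 nA, I_I = 0.2674 nA, w_EE ascending over
[0.126, 0.210] nA, w_IE over [0.090, 0.150] nA, w_EI = 1 before calibration.
The inhibitory gating relaxes linearly (no (1 − S) factor), taken literally
from the model definition. The transfer function's removable singularity at
a x = b is evaluated by a second-order series for |d(ax − b)| < 10⁻⁷; both
tails are computed in overflow-safe form.

## Ground truth and reconstruction

At a stable fixed point S\* (located by noiseless relaxation plus a root
polish; residual < 10⁻¹⁰) the exact Jacobian factorizes off the diagonal as
`J_ij = h_i C_ij` with `h_i = γ G (1 − S_i*) H′(x_i*)` (for Model C, the
excitatory block quantities). Hidden inhibition is absorbed by the Schur
complement `J_eff = J_EE − J_EI J_II⁻¹ J_IE`; because the E↔I blocks are
diagonal this only corrects within-region terms, so the h·C factorization of
the off-diagonal survives. A covariance route
(`J_EE + J_EI COV_IE COV_EE⁻¹` with the exact Lyapunov covariance of the 2N
system) agrees with the Schur form to within ~0.2% on the diagonal at
τ_I = 0.01 ≪ τ_E = 0.1, with the gap shrinking as τ_I → 0. The intermediate
approximation Σ ≈ σ²J⁻¹J⁻ᵀ is kept exposed (`smallnoise_covariance`) but is
*not* the stationary covariance (scalar J = −k: σ²/k² vs the exact σ²/(2k));
only the end result is used.

Reconstruction: DDC with mean-centered activity and a forward difference
paired with the same-time sample (a central-difference option exists); the
separation solves the pair equations `Ĵ_ij y_i + Ĵ_ji y_j = 2 W_ij` (each
unordered pair once — ordered duplicates only rescale the normal equations)
by least squares, reporting cond(M), the residual, and any non-positive ŷ
(surfaced, never clipped). Baselines: no-asymmetry = per-row scalar
regression of Ĵ onto W; no-heterogeneity = alternating exact minimization of
`‖J − hC‖² + ‖C + Cᵀ − 2W‖²` over scalar h and zero-diagonal C, restricted
to off-diagonal entries (the diagonal of J is structurally not h·C), with a
provably non-increasing loss. Parameter recovery inverts the fixed-point
algebra: ŵ from the Jacobian diagonal, x̂\* from the strictly monotone gain
equation (unique root), Î from the input balance; Model B analogously for
τ̂, b̂. Gain inversion is intrinsically ill-conditioned when a region is
fully saturated (the gain is within float precision of its supremum a); such
regions are reported as failures rather than silently extrapolated, and
round-trip accuracy of 10⁻⁶ holds away from total saturation.

## Sampling-interval correction

Observing the linearized system every T seconds exposes
`J_T = (e^{T J_o} − I)/T`; the original Jacobian is recovered through the
principal matrix logarithm `Ĵ_o = ln(T Ĵ_T + I)/T` (scipy `expm`/`logm`).
Eigenvalues of `T Ĵ_T + I` on the closed negative real axis raise a
branch-cut error; the imaginary residue of the log is discarded below 10⁻⁶
relative norm, warned about below 10⁻², and an error above; proximity of any
log-eigenvalue to ±iπ is flagged as a uniqueness diagnostic. The noise-mixing
matrix appearing in the discretized theory is never materialized — it is
uncorrelated with the regressor and cancels from the estimator.

## Synthetic connectome

The generator emulates a retrograde-tracer matrix: a symmetric binary mask at
density 0.65 of ordered pairs; log-normal base weights with σ(ln w) = 2.8
(≈ 1.2 decades — tracer fractional weights span several orders of magnitude);
symmetric Sinkhorn balancing to unit row sums (a single positive diagonal
scaling, so symmetry is preserved — plain row normalization would break it);
then directional multiplicative log-normal jitter whose scale is bisected
against the measured asymmetry level η (correlation of reciprocal pairs,
computed over both orderings of every pair so the statistic is exactly
invariant under node relabeling). At target η = 1 the jitter vanishes and
the output is exactly symmetric with unit row sums. Defaults: N = 29,
density 0.65, η = 0.7.

What it does *not* emulate: unidirectional connections (the mask is
reciprocal by construction), distance- or hierarchy-dependent weight decay,
and the empirical matrix's sub-unit row sums. The last point matters
dynamically: with rows summing exactly to 1 the recurrent input `G Σ C_ij S_j`
is strong, the low-activity branch of Model A disappears near G ≈ 0.25, and
the sweep regime G ≥ 0.3 operates on the single high-activity, gain-saturated
branch. Reconstruction is agnostic to the branch (it only assumes
fluctuations around a stable fixed point), but two consequences should be
kept in mind when comparing to data from weaker-coupling regimes: effective
heterogeneity is more homogeneous at saturation, which lowers the error level
of the no-asymmetry baseline (measured ≈ 0.22 here) relative to
mixed-saturation regimes; and the intrinsic timescales are fast
(|J_ii| ~ 10–140 s⁻¹), so the matrix-log recovery typically fails outright
(branch cut) for sampling intervals T ≳ 0.3 s instead of degrading smoothly —
the sweep records such failures per row and continues.

Feedback inhibition control calibrates per-region w_EI until every excitatory
rate sits at 3 Hz (tolerance 0.01 Hz by default): an analytic seed inverts
the target rate through the steady-state relations (exact at unit row sums),
then damped Newton sweeps with full fixed-point recomputation polish it,
using the local sensitivity −g_Ei S_Ii of the rate to the weight, with
per-sweep step capping. Under unit row sums the calibrated 3 Hz state is
linearly stable only for G ≲ 0.18; at larger G calibration still converges
(the root solve tracks the fixed point) but the state is network-unstable —
the E–I analysis pipeline therefore checks stability explicitly and the
simulated pipeline is exercised in the stable regime.

## Numerical choices

* Euler–Maruyama with σ√dt increments; dt = 0.001 s by default (τ_I = 0.01 s
  demands it for Model C; the one-population models tolerate 0.005 s in test
  profiles), burn-in 50 s, chunked integration (2·10⁵-step blocks) with
  bitwise seed reproducibility; numba-compiled inner loops.
* Fixed points: BDF relaxation for 100 s of model time, then a hybrid-Powell
  root solve; acceptance tolerance max |drift| < 10⁻¹⁰.
* Desk-scale profile: 5,000 s simulations, 3 noise seeds (the package's
  standard sweep size; estimator error at this length is within a factor ~1.5
  of its long-record asymptote, and the error decreases monotonically with
  duration — asserted in tests at 100/1,000/5,000 s).
* Relative errors: ℓ2 for vectors, Frobenius for full matrices, off-diagonal
  Frobenius for connectivity (its diagonal is structurally zero).
* CSV I/O uses round-trip float parsing so write→read is bitwise exact.

## Known limitations

* The separation assumes fluctuations around a *stable* fixed point;
  oscillatory (post-Hopf) regimes and regimes with noise-induced branch
  switching are out of scope (eigenvalue diagnostics are provided).
* Negative ŷ entries can occur in noise-dominated regimes (short records,
  very small G); they are flagged, and downstream parameter recovery treats
  the affected regions as failures.
* Detailed parameter recovery (Î_i especially) degrades near full gain
  saturation, where the operating point is insensitive to the parameters —
  an identifiability limit, not an estimator defect.
* The synthetic generator reproduces summary statistics (density, tail,
  row normalization, η) of tracer connectomes, not their topology; passing
  tests demonstrate correctness of the machinery under those conditions, not
  performance on any empirical matrix.
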