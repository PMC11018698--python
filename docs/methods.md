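# Methods

## The model

A membrane of thickness *L* is crossed by *n* identical single-file
channels whose length equals the membrane thickness. The water column in a
channel is modelled as a one-dimensional fluid of hard rods of diameter
*a*: rods interact only by exclusion, cannot pass one another, and
otherwise diffuse freely with bare diffusion coefficient D₀. The single
state variable is the occupancy fraction φ = *Na/L* ∈ [0, 1).

Both permeabilities are written P = K·D/L, with the same partition
coefficient K = (n·v_w⁰/aA)·φ (ratio of in-membrane to reservoir water
concentration, reservoirs ideally dilute). They differ only through the
diffusivity: tracer exchange proceeds at the self-diffusion coefficient
D\*, whereas gradient-driven (osmotic) flow proceeds at the collective
coefficient D. Their ratio is the thermodynamic factor

    D/D* = 1 + dμ_ex/d ln φ,

and for the 1D hard-rod fluid the excess chemical potential is exactly

    μ_ex(φ) = φ/(1−φ) − ln(1−φ),

so that P_f/P_d = 1/(1−φ)². Because K cancels, the ratio is parameter-free:
one measured ratio determines one occupancy, φ = 1 − (P_f/P_d)^(−1/2).

The individual permeabilities need one extra modelling step: a 1D random
walk whose mean free path shrinks with crowding, l = l₀(1−φ), giving
D\* = D₀(1−φ)² and hence

    P_d = B·φ·(1−φ)²,   P_f = B·φ,   B = D₀·n·v_w⁰/(aAL).

P_d vanishes at φ = 0 (no water to exchange) and at φ = 1 (jammed column),
peaking at φ = 1/3; P_f rises linearly to B. Both formulas are mean-field:
they treat φ as a uniform density and ignore correlations beyond the
contact exclusion, so they should not be trusted as φ → 1.

### Assumptions worth stating

- Athermal hard spheres: no hydrogen bonding, no attractive forces, no
  temperature dependence beyond the k_BT scale absorbed into μ_ex.
- The channel is a featureless hard tube; wall chemistry enters only
  through D₀ and the partition coefficient.
- Osmotic and hydrostatic driving are equivalent and are represented in the
  simulator by a reservoir density difference; no osmolyte species is
  simulated.
- Reservoirs are ideally dilute, so reservoir activity = density.

## Default physical constants

| symbol | value | meaning |
|---|---|---|
| D₀ | 2.30×10⁻⁵ cm²/s | bulk-water self-diffusion, 25 °C |
| a | 2.8×10⁻⁸ cm | effective water diameter |
| v_w⁰ | 2.99×10⁻²³ cm³ | volume per water molecule (18.07 cm³/mol ÷ N_A) |
| L (gramicidin) | 2.5×10⁻⁷ cm | pore length |

These enter only dimensional outputs (B, per-pore pf). With φ = 0.57 they
give pf = (A/n)·P_f = D₀·v_w⁰·φ/(aL) = 5.6×10⁻¹⁴ cm³/s for gramicidin A.
The per-pore value is independent of A and n — they cancel algebraically —
and the package asserts that cancellation. All internal units are CGS; the
CLI converts nm flags.

## Exact hard-rod engine (`tonks`)

Hard walls at 0 and L; rod centres confined to [a/2, L−a/2]; free length
L−Na. The configuration integral is Q_N = (L−Na)^N/N!, evaluated in log
form with exact log-gamma (Stirling appears nowhere in computations).

Finite-N excess chemical potential: several inequivalent finite-N
conventions share the same thermodynamic limit; this package fixes the
insertion form

    μ_ex(N) = −[ln Q_{N+1} − ln Q_N] − ln((N+1)/L),

the work of inserting rod N+1 minus its ideal part. At fixed φ it
converges to μ_ex(φ) with an O(1/N) deficit (measured: ×100 reduction from
N=10² to N=10⁴), which is the convergence rate the oracle-chain test
asserts.

Sampling is exact, not Markov-chain: N uniform points in a box of length
L−Na are sorted and shifted by a/2 + i·a. Consequently every sampled
configuration satisfies the gap invariant by construction, and a neighbour
gap minus a is an exchangeable uniform spacing with survival law
(1 − x/(L−Na))^N — the closed form the Kolmogorov–Smirnov exactness test
uses (one randomly chosen gap per configuration, so the KS sample is iid).

Widom insertion: a test-rod centre is drawn uniformly on [a/2, L−a/2]
(consistent with the wall convention) and acceptance requires distance ≥ a
from every rod. The acceptance fraction p estimates μ_ex through
μ_ex = −ln(p·(L−a)/L); the (L−a)/L factor converts the conditional
acceptance over the drawing window to the full-box average demanded by the
Q_{N+1}/Q_N identity, making the estimator exactly consistent with
`mu_excess_finite` rather than biased by O(a/L). The standard error is the
delta-method binomial error √((1−p)/np). A run that accepts nothing
returns an infinite-estimate flag with advice, not an exception.

## Brownian channel simulator (`channel_sim`)

Dynamics. Each step every rod takes an independent Gaussian step of
variance 2·D₀·dt. Single-file order is enforced by re-sorting positions
while origin labels stay attached to rank order — for identical hard rods
this is an exact elastic-exchange mapping. Sorting alone cannot restore
the finite-diameter gap constraint, so residual neighbour overlaps are
then removed by symmetric pairwise reflection (the exact two-body Brownian
reflection); the construction-time resolution condition
σ = √(2·D₀·dt) < a/4 keeps overlaps shallow and the sweep count small
(default dt = 0.02 a²/D₀, σ = 0.2a). A reject-overlap Metropolis
integrator is retained as a cross-check; the two schemes are required to
share the stationary density profile (they differ in kinetics — rejection
lowers mobility — so only equilibrium properties are compared).

Reservoir coupling. Rods whose centres leave [0, L] are absorbed and
counted. Each reservoir attempts one insertion per step with probability
ρ·√(D₀·dt/π) — the one-way diffusive flux of an ideal gas of density ρ
across the channel mouth in one step — at a uniform position in a boundary
zone of width a, accepted only if no overlap results. This open-boundary
coupling is deliberately simple and is *not* exactly grand-canonical: it
leaves a boundary layer of ~1.5–3a at each end and an O(1) bias between
the nominal reservoir density and the steady channel occupancy. Two
consequences are handled explicitly:

- The hard-rod activity z(φ) = (φ/a)·e^{μ_ex(φ)} is only the initial guess
  for the reservoir density; `calibrate_reservoir_density` refines it with
  short probe runs (fixed-point rescaling by φ_target/φ̂, default
  tolerance 0.015) so a run is performed *at* the stated occupancy.
- Equilibrium flatness of the density profile is asserted over the
  interior excluding 3a at each end, at a run length (t = 2×10⁶ a²/D₀, 20
  bins, block SEs) where the interior is flat to ~0.3%.

By symmetry the coupling is exactly left–right balanced, so zero net flux
at equal densities and flux antisymmetry under reservoir swap hold
regardless of the coupling bias.

Measurements (operational definitions):

- P_d: equal reservoir densities; every rod inserted from the left carries
  a tracer label; P_d = (steady flux of labelled rods out of the right
  boundary) / ρ, since the reservoir tracer densities are ρ and 0.
- P_f: reservoir densities ρ(1±Δ/2) with relative drive Δ ≤ 0.1 (linear
  response; larger drives are flagged); P_f = net flux / (ρΔ), with the
  net flux taken from boundary-event balance
  ½[(ins_L − rem_L) + (rem_R − ins_R)], which is unambiguous under
  insertion/deletion coupling (no midplane-crossing bookkeeping).
- Errors: 20-block averaging; ratio errors propagated in quadrature;
  fewer than 100 relevant crossings raises an insufficient-statistics flag
  (CLI exit code 3).

Burn-in is 5·L²/D₀ (several channel diffusion times) from an empty
channel. Default geometry is desk-scale, L/a = 10, so a full paired
ratio measurement at t_run = 1.6×10⁶ a²/D₀ takes seconds.

Normalising both permeabilities by *reservoir* densities means any entry
efficiency factor cancels in the ratio, and in the dilute limit the two
experiments are literally the same counting, so P_f/P_d → 1 exactly as the
theory requires.

### What the simulator does and does not test

The simulator realises the same microscopic picture as the closed-form
theory (Brownian hard rods in single file) but measures the permeabilities
the way experiments define them. Passing its tests therefore shows the
theory's *qualitative* content is right: equal permeabilities when dilute,
a ratio significantly above 1 when crowded, linear response through the
origin. The *quantitative* mean-field prediction 1/(1−φ̂)² is evaluated at
the measured occupancy and reported with its discrepancy in SE units
(typical finding at φ̂ ≈ 0.3, L/a = 10: measured ratio ≈ 1.7–1.9 vs
predicted ≈ 2.1); whether the exact finite open channel obeys the
mean-field formula is a genuinely open question, so the comparison is a
research output, never a pass/fail assertion. None of this says anything
about real water: hydrogen-bonded chain cooperativity, wall chemistry and
electrostatics are all outside the hard-sphere model.

## Numerical choices

- φ = 1 is singular for μ_ex and the ratio (errors raised); P_d and P_f
  accept it with their finite limits 0 and B.
- `thermodynamic_factor` is computed from the analytic derivative of
  μ_ex, and its algebraic collapse to 1/(1−φ)² is a *tested* identity
  (2000-point grid, 10⁻¹⁰ relative), not an assumption.
- Inversion returns full precision; the CLI adds a 2-decimal field because
  occupancies are conventionally quoted to 2 dp.
- A measured P_f < P_d yields a flagged negative convective component
  rather than an exception (such pairs occur experimentally).
- Small-N configuration integrals are cross-checked against direct nested
  quadrature (N ≤ 3, clamped ordered limits, 10⁻⁸ relative).
- Test problem sizes: Widom 10⁵ samples at N=100; finite-N convergence up
  to N=10⁴; KS exactness with 10⁴ configurations at φ=0.5; MSD from 100
  kernel trajectories of 2×10⁴ steps fitted over the 10 shortest lags
  (short lags pool the most independent increments); linear response at
  drives {0.02, 0.05, 0.1} with t = 2.4×10⁷ a²/D₀ per drive, sized so the
  R² > 0.99 criterion has several-fold noise margin.
- All randomness flows from explicit `numpy.random.Generator` seeds; CLI
  runs log a manifest (parameters, seed, version, output checksum) to
  stderr and are bit-for-bit reproducible given the seed.

## Known limitations

- Mean-field individual permeabilities: the random-walk D\* = D₀(1−φ)² is
  heuristic; only the ratio rests on exact statistical mechanics.
- The open-boundary coupling requires calibration to place the channel at
  a target occupancy, and its boundary layers limit how sharp a profile
  test can be.
- The simulator's ratio estimate at moderate occupancy sits below the
  mean-field curve; resolving whether that gap is a finite-L/a effect, a
  coupling artifact, or a real correction to mean field would need a
  channel-length study outside the default desk-scale geometry.
- No anomalous-diffusion (single-file subdiffusion) study: the unbounded
  tracer MSD check only verifies the diffusive free limit.
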