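# Methods

This note records the model, the algorithms, the conventions that had to be
fixed, and the numerical choices, in enough detail to re-derive every
number the package produces.

## Model and units

Two electronic states couple linearly to one harmonic, mass-weighted
solvent polarization coordinate `Q` (a Brownian oscillator); the residual
Ohmic bath J(ω) = γω acting on `Q` is folded into a Langevin equation,
which is formally equivalent to propagating the full multidimensional bath
for classical nuclei. Reduced units β = ℏ = m = 1 are used everywhere: the
model inputs are the dimensionless groups βΛ (reorganization energy), βε
(driving force), βΔ (diabatic coupling), βℏΩ (oscillator frequency), βℏγ
(friction); times are in βℏ and rates in 1/βℏ.

Diabats: V_r = ½Ω²Q², V_p = ½Ω²(Q−Q₀)² − ε with Q₀ = √(2Λ)/Ω. The diabatic
gap D(Q) = V_r − V_p = a(Q − Q‡) is linear with constant slope a = Ω√(2Λ)
and crossing Q‡ = (Λ−ε)/a. Adiabats: V_± = ½(V_r+V_p) ± ½√(D² + 4Δ²);
the adiabatic gap is bounded below by 2Δ, attained exactly at Q‡. The
derivative coupling d(Q) = Δa/(D² + 4Δ²) is a Lorentzian of unit area π/2,
positive at the crossing by package convention. Forces are the analytic
Hellmann–Feynman gradients of V_±.

The default study point throughout tests and the acceptance script is
βΛ = 12, βℏΩ = 1/4, γ = Ω (underdamped), with Δ and ε varied;
log₁₀(βΔ) = −7/5 is the weak-coupling (golden-rule) reference.

## Electronic propagation and conventions

Amplitudes evolve in the adiabatic representation,

    iℏċ_± = V_± c_± ∓ iℏ Q̇ d c_∓ ,

equivalently rigid precession of the Bloch vector S about
ω = (0, 2Q̇d, (V₊−V₋)/ℏ). The phase convention is fixed once:
S_x = 2Re(c₊*c₋), S_y = 2Im(c₊*c₋), S_z = |c₊|² − |c₋|². Only relative
signs between d and these equations are observable; flipping both leaves
every population and hop time unchanged.

Each step applies the exact exponential of the traceless 2×2 generator for
the field evaluated at the mid-step configuration (mean of the endpoint
positions, mean of the endpoint momenta), dropping the unobservable mean
dynamical phase. Norm conservation is therefore exact to round-off; field
sampling makes the scheme globally second order on smooth trajectories,
verified by a convergence test. One substep per nuclear step suffices at
the default dt (see below).

## Nuclear dynamics

BAOAB splitting of the Langevin equation on the active adiabat: half kick,
half drift, Ornstein–Uhlenbeck momentum update with the exact one-step
coefficients (c₁ = e^{−γdt}, noise variance (1−c₁²)/β), half drift, half
kick. At γ = 0 this is velocity Verlet (energy drift < 10⁻⁶ over 10⁵ steps
at dt = 0.01 in a well); at γ > 0 the Boltzmann distribution is stationary
to O(dt²), verified against equipartition.

## Hopping rules

**MASH.** After each step the active surface must satisfy n = sign(S_z);
when the sign disagrees a hop is attempted at the end of the step (no
bisection refinement of the crossing time — rates at dt = 0.01, 0.005 and
0.0025 agree within statistical error). An exact S_z = 0 keeps the current
surface (measure zero). Hops rescale the momentum along the nonadiabatic
coupling direction — all of P in one dimension — to conserve V_n + P²/2
exactly; an upward attempt with insufficient kinetic energy reflects the
momentum (frustrated hop) and leaves n unchanged. Hop counters count only
executed switches.

**FSSH.** The fewest-switches probability for leaving the active state n
in one step is

    g = dt · (population flux out of n) / ρ_nn ,
    flux out of + = 2 Q̇ d Re(c₊*c₋) ,

clamped to zero when negative (coherence feeding the active state means no
hop) and flagged in the log if it exceeds one. The denominator is the
active population *at the start of the step* (Tully's g = b·dt/a_nn at
time t). This choice matters: normalizing by the post-step population
biases hops toward the early edge of the coupling region and produces a
strong O(dt) error in rates (at the activationless point the FSSH excess
over Marcus read 1.17 at dt = 0.01 versus 1.49 at dt = 0.0025 with
post-step normalization, while pre-step normalization is dt-converged at
0.01 within statistics). Momentum rescaling and frustrated-hop reflection
are identical to MASH — the prescription the MASH derivation fixes
uniquely, which the package also applies to FSSH for comparability;
`frustrated="ignore"` switches reflection off for sensitivity studies (at
the activationless point it raises the FSSH rate excess from ~0.5 to ~0.9,
so the choice is consequential for FSSH).

Accepted hops never alter the wave function, in either method.

## Initial conditions

Positions and active states are drawn jointly from the classical Boltzmann
weight e^{−βV_n(Q)} over both adiabats (not Wigner functions), restricted
to the requested region; momenta are Maxwell–Boltzmann. The restriction
uses the same adiabatic reactant/product partition as the observable:
product = lower adiabat right of Q‡ or upper adiabat left of it, boundary
assigned to reactant. Sampling is exact rejection from diabat-well Gaussian
proposals with the envelope e^{−βV_n} ≤ e^{−βV_diab}·e^{βΔ} (from
V₋ ≥ min(V_r,V_p) − Δ); no burn-in or autocorrelation.

Electronic initialization: FSSH starts in the pure state of the active
surface; MASH draws S from the hemisphere of the active surface with
density ∝ |S_z| (S_z = ±√u, u uniform; azimuth uniform), the sampling that
replaces hop stochasticity. The overall phase is unobservable and is
randomized for MASH, zero for FSSH.

## Decoherence corrections

Mode `gap_triggered`: once per sampling stride (default every 10 steps),
any trajectory whose adiabatic gap exceeds the threshold (default 4 k_BT —
i.e. only in the wells, far from the coupling region where ⟨S_x⟩ = ⟨S_y⟩ ≈ 0)
is corrected: MASH resamples S from the |S_z|-weighted hemisphere of its
active surface (identical in law to the initial sampling, hence idempotent);
FSSH collapses the amplitudes to the pure active state. MASH resampling
while sign(S_z) disagrees with n would change the active state and is
treated as an error; under the large-gap trigger it does not occur.
Results are insensitive to the cadence and to the precise threshold as
long as it separates wells from the crossing region.

## Observables and rate estimators

⟨P_p(t)⟩ is the fraction of trajectories in the product region (adiabatic
definition above). Populations come from active-state counts, never from
wave-function coefficients.

*Plateau-slope rate*: weighted linear regression of ⟨P_p(t)⟩ over
t ∈ [10, 20] βℏ (after the initial transient), divided by the mean
reactant population over the window, which makes the estimator exact for
two-state kinetics. A quadratic-term z-score flags unfinished transients.

*Decay rate*: weighted fit of p(t) = p_eq(1 − e^{−(k_f+k_b)t}); reports
k_f and the half-life ln2/(k_f+k_b) of the reactant-excess decay, and
errors out if the curve spans fewer than two fitted half-lives.

*Marcus benchmark*: the closed form above; an independent numerical route
(2πΔ²/ℏ × quadrature of the thermal density at the crossing) agrees to
1e−10 and guards the formula in the tests.

*Statistical errors*: population errors are binomial. Rate errors use the
scatter of per-chunk slope estimates (the ensemble is propagated in fixed
chunks of 2¹⁵ trajectories, each with its own child random stream), which
captures the time correlation of the ensemble mean that a naive
independent-samples regression error misses by roughly a factor of two.
Fewer than six chunks fall back to the regression error.

*Hop-count decomposition*: ⟨P_p(t)·1[hops=m]⟩ for requested m plus a
remainder stratum, summing exactly to the total — used to isolate the
two-hop pathway that FSSH suppresses.

## Numerical choices and problem sizes

- dt = 0.01 βℏ by default. A startup check rejects dt if dt·gap/ℏ > 0.25
  for the gap at the bottom of the initialization well (≈ |Λ−ε|); the much
  larger gap deep in the opposite well is harmless because the coupling
  there is negligible and the phase propagator is exact for a constant
  field. Rates at dt = 0.01 agree with dt = 0.0025 within statistics for
  both engines with the discretizations above.
- Chunked propagation with one spawned random substream per fixed 2¹⁵-size
  chunk makes every ensemble bitwise reproducible and independent of
  memory batching; the compiled (numba) and vectorized (numpy) cores
  implement identical dynamics and agree bitwise on noise-free runs.
- Plateau-rate studies use 2–6 × 10⁵ trajectories in the test suite and
  0.6–2.4 × 10⁶ in the acceptance script (the ε = 0 rates are rare-event
  quantities; their relative errors scale as ~70/√N with these settings).
  Full-decay studies use 600–1000 trajectories to t = 9000 βℏ.
- Weighted fits guard against zero stderr on exact synthetic curves by
  falling back to unweighted regression.

## What the synthetic conditions do and do not show

All inputs are generated internally (thermal sampling plus the model
Hamiltonian); there is no external data. Passing tests therefore
demonstrate the internal correctness of the dynamics, sampling, and
estimators, and reproduction of the known analytic limits (Marcus theory,
Landau–Zener passage, detailed balance) — not transferability to
anharmonic, multidimensional, or non-Ohmic systems, for which the
one-dimensional rescaling direction and the single Brownian mode are the
obvious limitations.

## Known limitations

- Two electronic states only; the multistate generalization of MASH is a
  different theory and out of scope.
- One nuclear dimension: the momentum-rescaling direction is trivially
  along Q; the coupling-vector logic is not exercised in higher dimension.
- Rates come from direct population dynamics; flux-correlation machinery
  (Bennett–Chandler and friends) is not implemented.
- The decay fit assumes single-exponential two-state kinetics; when a
  method's long-time dynamics is not exponential (strongly overcoherent
  FSSH), the fitted p_eq absorbs some of the misfit and the half-life is
  the robust quantity.
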