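# Methods

## Model class

`neqadapt` analyzes continuous-time Markov jump processes on a finite state
space. A model is a generator matrix Q (off-diagonal entries q_ij ≥ 0 are
transition rates, rows sum to zero), an initial distribution π, and an
observable g; the scalar output is φ(t) = π e^{Qt} gᵀ. When Q has N simple
eigenvalues the output is a finite exponential sum

    φ(t) = φ∞ + Σ_{i<N} c_i e^{λ_i t},

with exactly one eigenvalue at 0 (its coefficient is the steady output
φ∞ = μ·g, μ the stationary distribution) and all others in the open left
half plane. Conjugate eigenvalue pairs −λ ± iω contribute damped cosines
2|c| e^{−λt} cos(ωt + arg c). The package computes this decomposition by a
dense eigendecomposition (`numpy.linalg.eig`); coefficients are
c_i = (πV)_i (V⁻¹g)_i.

Standing assumptions inherited from the adaptation setting: the output
initially rises (φ′(0) = πQgᵀ > 0) and the new plateau is not below the
start (φ∞ ≥ φ₀). Both are *reported*, never silently enforced; several
properties below hold only under them.

## Overshoot and phase classification

A response *overshoots* when φ(t) transiently exceeds both φ₀ and φ∞.
Classification:

* **NON** — no measurable interior peak above both endpoints.
* **SIMPLE** — an interior peak carried by real modes only; the return to
  the plateau is monotone (with ≤2 real decay modes the output can cross
  φ∞ at most once, so no ringing is possible).
* **OSCILLATORY** — an interior peak together with at least one conjugate
  complex mode whose coefficient magnitude exceeds a threshold
  (default 1e-12 × the observable range). Complex modes the observable is
  blind to do not make the *output* oscillatory.

Numerical choices:

* Overshoot threshold: φ_peak > max(φ₀, φ∞)·(1+1e-9) + 1e-12. The
  definition is a strict inequality; the margin guards against roundoff.
  Consequence: immediately past an overshoot onset the peak excess grows
  quadratically in the control parameter and can be below this resolution;
  such responses are reported NON. Monotone rises (peak at t→∞) are NON.
* An eigenvalue is "complex" iff |Im λ| > 1e-9·max(1, |λ|); eig noise on
  provably-real-spectrum matrices is ~1e-13, so the two regimes are well
  separated.
* Peak search: sign changes of φ′(t) = Σ c_i λ_i e^{λ_i t} are bracketed on
  a 2000-point log grid spanning 1e-3×(fastest time scale) to 20×(slowest),
  augmented with linear coverage of six periods of the slowest oscillation
  when complex modes are present, then refined by Brent root finding
  (relative 1e-12). Ties between equal-height maxima resolve to the
  earliest time.
* Near-degenerate spectra (pairwise gap < 1e-8 × spectral radius): the
  modal construction is abandoned, trajectories fall back to
  `scipy.linalg.expm` propagation, and classification falls back to
  trajectory shape (does the output ring below φ∞ after its peak). The
  exponential-sum form is only valid for simple spectra.
* Stationary distributions come from the null space of Qᵀ
  (`scipy.linalg.null_space`), not long-time integration; irreducibility is
  checked via strongly connected components of the transition graph.

Performance metrics for a step protocol I₀ → I₁ (relative step r =
(I₁−I₀)/I₀): sensitivity γ = [(φ_peak−φ₀)/φ₀]/r, error
ε = [(φ∞−φ₀)/φ₀]/r, accuracy δ = 1/ε (∞ at perfect adaptation), and the
input-independent efficiency η = 1 − ε/γ = (φ_peak−φ∞)/(φ_peak−φ₀) ∈ [0,1].
γ, ε, δ are undefined (None) without a protocol or when φ₀ = 0; η is
undefined when there is no peak excess.

## Detailed balance, cycle flux, and the DDK bound

Equilibrium (detailed balance, μ_i q_ij = μ_j q_ji) is tested pairwise
against the stationary distribution; the diagnostic also reports the basis
cycle of the transition graph with the largest |log| forward/backward
rate-product ratio (Kolmogorov's criterion). For reversible chains the
similarity transform S_ij = √(μ_i/μ_j) q_ij is symmetric, so the spectrum
is real — equilibrium systems can never ring.

Every conjugate pair −λ ± iω of an N-state generator obeys the
Dmitriev–Dynkin–Karpelevich bound λ/|ω| ≥ tan(π/N), with equality exactly
for the uniform unidirectional cycle. For N = 3 this forces a ring to decay
by e^{−2π tan(π/3)} ≈ 2e-5 per period — oscillatory overshoot in small
networks is physically present but practically invisible, which is why the
package classifies from the modal structure rather than from curve
inspection.

## Three-state cycle theory

An irreducible 3-state chain at stationarity carries a single net cycle
flux J; J = 0 ⟺ detailed balance. With edge sums
a, b, c the generator is fully parametrized by (μ, a, b, c, J); feasibility
requires J ≤ min(a, b, c) (beyond it an off-diagonal rate would be
negative — the builder rejects rather than clips). The nonzero eigenvalues
become complex exactly at

    β² = (μ₁μ₂μ₃/4)[(c+a)/μ₁ + (a+b)/μ₂ + (b+c)/μ₃]² − (ab+bc+ca),

implemented in closed form and cross-checked in the tests against an
independent oracle: the root in J of the discriminant of the characteristic
polynomial (trace² − 4 × minor-sum of the raw parametrized matrix). Below
β, simple overshoot occurs iff E + λ₂F > 0 with E = φ′(0), F = φ∞ − φ₀ and
λ₂ the more negative eigenvalue; the overshoot onset flux is the bracketed
Brent root of that expression on a 200-point grid (ties to the lower J),
with degenerate cases: onset 0 when the criterion is positive already at
J = 0 (equilibrium simple overshoot — possible), and "not reached" when it
stays negative up to min(β, min(a,b,c)). A trivial response (π = μ) is
explicitly excluded from registering an onset via a tolerance of
1e-12 × |λ₂| × range(g) on the criterion.

**Scope of the direction law.** The phase sequence NON → SIMPLE →
OSCILLATORY along increasing J rests on E being nondecreasing in J.
dE/dJ = ½ Σ_i π_i (g_{i+1} − g_{i+2})/μ_i (cyclic indices) has no fixed
sign for arbitrary (π, g): for start/observable pairs with dE/dJ < 0 the
overshoot can *shrink and vanish* as the drive grows, even with φ′(0) > 0
and φ∞ ≥ φ₀ throughout. The package treats E nondecreasing in J as part of
the standing assumptions of the direction law, and the property tests
filter fixtures accordingly. Within that scope, no reverse transition was
observed on any sampled fixture, and η(J) and φ_peak(J) are nondecreasing
over the overshoot regime.

**Fast-state elimination.** When one state's exit rate exceeds the others'
by a factor ρ, its probability is slaved to the slow states
(p_f = Σ_i p_i q_if/(−q_ff)), giving effective slow-state rates
q̃_ij = q_ij + q_if q_fj/(−q_ff) (a proper generator), an initial
distribution that redistributes the fast state's mass by its jump
probabilities, and an effective observable g̃_i = g_i + g_f q_if/(−q_ff).
The reduction is accurate to O(1/ρ) outside an initial boundary layer of a
few fast relaxation times; a warning is issued for ρ < 100. In the fast
regime the peak output is attained at the end of the boundary layer and is
exactly linear in J for the reduced model — the origin of the near-linear
φ_peak(J) seen in the full model under time-scale separation.

## The MCP receptor model

The E. coli chemoreceptor is a ten-state ladder (activity a ∈ {0,1} ×
methylation m ∈ {0..4}). Parameters (defaults in parentheses): methylation
energy e₀ (2, k_BT units), offset level m₀ (1), dissociation constants
K_i (18.2 μM, inactive) and K_a (3000 μM, active), energy scale k_BT (1),
activity-switching time τ_a (0.1 s), base methylation/demethylation rates
k = l (0.01 /s, giving a cycle time τ_m = 1/k + 1/l = 200 s), and the
dimensionless drive α ∈ (0, e^{e₀/2k_BT}]. These are the standard values
for this receptor; the ligand step is 10K_i → 15K_i.

Rates: activity flips at exp(∓E/2k_BT)/τ_a with E(m, I) = e₀(m₀−m) + f(I),
f(I) = k_BT log[(1+I/K_i)/(1+I/K_a)]; an active receptor methylates at αk
and demethylates at k, an inactive one methylates at l and demethylates at
αl. The sign convention of the vertical rates is the one under which
Kolmogorov's criterion gives detailed balance exactly at α = e^{e₀/2k_BT}
(verified in the tests: all four elementary squares of the ladder share
the cycle affinity (α e^{−e₀/2})²); the opposite convention would place
equilibrium at e^{−e₀/2}. α < e^{e₀/2} drives the system out of
equilibrium, modeling the SAM-fueled methylation cycle.

Step responses start from the stationary distribution of Q(I₀), evolve
under Q(I₁), and observe the total inactive probability. Eigenvalue counts
in drive scans use Q(I₁) — the post-step generator that governs the
response shape; the choice is configurable. The default scan grid is 0.01
steps over (0, e^{e₀/2}].

Numerically, with the default parameters: adaptation exists iff α < 1
(boundary located at 1.00 on the 0.01 grid for both τ_a values); with
τ_a = 200 s ≈ τ_m the response transitions from simple to oscillatory
adaptation at α = 0.91 and the complex-eigenvalue count of Q(I₁) steps
6/4/2/0 with increasing α — with one caveat the tests document: a narrow
re-entrant window near α ≈ 0.14–0.15 where one conjugate pair collides
onto the real axis and re-splits, briefly lowering the count by 2.
Efficiency: at τ_a = 200 s, max η ≈ 0.77 (< 0.8) over the grid; at
τ_a = 0.1 s, η ≈ 0.98 at α = 0.01 and decreases toward 0 at α = 1 —
fast activity switching improves sensitivity, accuracy and efficiency
simultaneously.

## Synthetic fixtures

The property suites run entirely on seeded generated models
(`neqadapt.fixtures`): reversible chains built from random stationary
weights and symmetric conductances (detailed-balanced and real-spectrum by
construction), dense driven chains with independent exponential rates,
uniform unidirectional cycles (the exact DDK equality case), and random
three-state cycle parametrizations with stationary weights bounded away
from the simplex boundary (each weight ≥ ~0.05/1.15), edge sums uniform on
[0.1, 2] per unit rate scale, and flux uniform on the feasible range.
These fixtures probe the mathematical structure, not biological realism:
real sensory networks have sparse topologies, widely separated time
scales and nonnegative observables, none of which the dense random
families emulate — so passing property tests establishes the theory's
internal consistency, not fit to any particular organism. The receptor
model with literature parameters is the realistic instance.

## Problem sizes

All computations are dense eigenproblems at N ≤ 10, so the full test suite
and the summary script run in seconds. Property suites use 200–1000 seeded
fixtures per invariant and 8–21-point flux/drive grids — enough for the
bracketing-based critical values to be located to the stated tolerances
(1e-8 for the oscillation onset vs its oracle, 0.01 grid resolution for
the receptor boundaries).

## Known limitations

* Classification is resolution-limited by design: overshoot below the
  1e-9 relative threshold and modal ringing below the trajectory sampler's
  resolution are reported as the simpler phase.
* The quasi-steady-state reduction mishandles the initial boundary layer
  by construction (it redistributes the fast state's mass instantly).
* No entropy-production accounting, no stochastic (Gillespie) sampling,
  no continuous-state models; the drive enters the receptor model only
  through α.
* Critical-value searches assume the criterion changes sign at most once
  on the searched bracket, which holds for the implemented families (E is
  linear and −λ₂F monotone in J) but is not verified for user-supplied
  generators outside the three-state parametrization.
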