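# Model and numerical methods

## Mechanical model of a titin strand

A single titin strand spanning the half sarcomere is a series chain of
one-dimensional elastic elements.  At imposed half-sarcomere length `l`
and a given number `i` of unfolded proximal Ig domains, the equilibrium
configuration minimises the sum of convex element potentials subject to
the extensions summing to `l`.  Because the potentials are convex and
one-dimensional, the first-order condition — equal tension `F` in every
element, `Σ_e x_e(F) = l` — characterises the unique minimiser, so the
chain is solved by a monotone scalar root-find in `F` rather than by a
generic convex-programming solver.

Elements and default parameters (SI internally; the CLI and CSV surfaces
use µm/pN/s):

| element | law | parameters (default) |
|---|---|---|
| PEVK | modified WLC with stretch modulus | `pl = 0.6 nm`, `cl = 800 × 0.36 nm = 288 nm`, `F0 = 150 pN` |
| folded Ig chain | WLC | `pl = 0.85 nm`, `cl = n_folded × 4.5 nm` |
| unfolded Ig chain | WLC | `pl = 0.85 nm`, `cl = n_unfolded × (4.5 + 25) nm` |
| end filament (distal Ig) | linear spring | `k_end = 2 N/m` |
| A-band + slack | linear spring + slack length | `k_rest = 2 N/m`, `slack = 1.0 µm` |

Conventions worth stating explicitly:

* The tabulated contour lengths are per-residue (PEVK) and per-unit (Ig)
  values; whole-chain contours are assembled from the isoform counts.
  A folded Ig domain contributes 4.5 nm (ten 0.45 nm units) of folded
  contour.  On unfolding, a domain moves from the folded to the unfolded
  chain and the *net* chain contour grows by exactly `d_u = 25 nm`, the
  per-domain unfolding gain; the unfolded chain therefore carries
  4.5 + 25 nm per unfolded domain.  All of these are configurable fields
  of `MechanicalParams`.
* The slack length is absorbed by the A-band/slack element at zero
  force; below it the force is exactly zero.  The default (1.0 µm)
  places force onset at a 1 µm half-sarcomere length.
* Temperature defaults to 300 K (not part of the tabulated parameter
  set); `kT/x_u ≈ 16.6 pN` sets the force scale of unfolding.
* The default isoform is rabbit psoas (3.4 MDa): 50 proximal Ig domains,
  800 PEVK residues, 26 distal Ig domains.  With N = 50 the strand force
  at a given length is a discrete random variable with 51 states
  `F_0(l) ≥ F_1(l) ≥ … ≥ F_50(l)`.

The force-curve family `F_i(l)` is tabulated once per model on a 1 nm
length grid (0.99–2.0 µm by default) and shared by both solvers, so the
Monte Carlo and the master equation see bit-identical forces.  Curves
are built per state by tabulating the chain extension on a dense
geometric force grid, interpolating to the target extensions, and
polishing with damped Newton iterations on the force balance until the
residual reaches roundoff (≲ 10⁻¹⁵ relative in force).  The WLC
interpolation formula is inverted by 60 bisection steps on
`x/cl ∈ [0, 1 − 10⁻⁹]` plus three Newton steps — machine precision,
vectorised, with `x = 0` returned exactly at `F = 0`.  The modified WLC
is reduced to the plain WLC by the substitution `y = x/cl − F/F0`, which
also supplies its exact inverse `x(F)`.

## Unfolding/refolding kinetics

Each domain is two-state with Bell rates
`u(F) = ω₀ e^{F x_u/kT}` and `r(F) = ω₁ e^{−F x_f/kT}`
(`x_u = 0.25 nm`, `x_f = 2.2 nm`).  Hierarchical mechanical stability is
modelled by m clusters with distinct spontaneous rates, ordered so
`u_1(F) ≤ … ≤ u_m(F)` for every force.  Clusters may instead differ in
barrier width `x_u` (supported, not default).

The tabulated parameter set does not include ω₀ or ω₁.  The defaults —
five clusters of ten domains, ω₀ geometric over 10⁻⁵…10⁻³ s⁻¹, ω₁ = 1 s⁻¹
— are placeholders calibrated only so that unfolding happens within a
1 → 2 µm ramp at the default 1 µm/s ramp speed; every quantitative output
that depends on them (Monte Carlo error magnitudes, unfolding-force
percentiles) should be read as conditional on this choice.  The Bell
exponent is capped at 500 to keep near-contour states finite; such states
are effectively instantaneous on any simulated time scale, which is the
physically correct limit.

For the cluster-granularity comparison, `noisy_linear_clusters` builds 50
single-domain clusters whose log₁₀ ω₀ declines linearly across the same
envelope and is perturbed by Gaussian noise (SD = 0.2 decades; the noise
scale — log or linear — is configurable since either reading is
plausible), then sorted to restore the rate ordering.

## Length protocols

Piecewise-linear `l(t)`: single ramps, stretch-shortening cycles with an
optional rest (default: two 1 → 1.7 → 1 µm cycles at 1 µm/s, 30 s rest,
one more cycle), and triangular cycling (default: ten +0.125 µm cycles
at a 1.85 µm base after an approach ramp — a 3.7 µm sarcomere cycled by
~0.25 µm, expressed per half sarcomere).  Ramp speeds are not part of
the tabulated parameter set; all fixtures carry their own (1 µm/s).
Cycle analysis splits traces at the breakpoints where loading begins
(half-open intervals; rests and shortening belong to the preceding
cycle), integrates the loop `∮F dl` by the trapezoidal rule for the
hysteresis area, and takes peak force over the loading phase.

## Monte Carlo solver

Fixed-step Bernoulli scheme: per strand and step, one uniform draw `z`
is compared against the cumulative intervals of the per-cluster event
probabilities `(n_k − i_k) u_k(F) dt` (plus `i_k r(F) dt` with refolding),
so at most one event occurs per step.  Without refolding the hazards are
evaluated at the force at the start of the step; with refolding both
hazard kinds are evaluated at the end-of-step length, following the
published update rules as printed ("start"/"end" can be forced for both
modes).  Strands start fully folded.  RNG streams are counter-seeded per
strand (`default_rng([seed, strand])`), so results are independent of
batching and bit-reproducible.

The scheme is only valid while the total per-step event probability is
small; the engine enforces a bound (default 0.1) and raises an error
advising a smaller `dt` when any strand exceeds it.  At `dt = 1 ms` the
default ramp drives strands past this bound during unfolding cascades
(measured maxima ≈ 0.1), so the canonical fixtures use `dt = 0.1 ms`,
which keeps the observed per-step probability ≈ 0.03 — a three-fold
margin — and nests the exact solver's 1 ms grid for direct pointwise
comparison.  The default ensemble size R = 200 balances cost against a
Monte Carlo error (sup-norm across-repeat SD of the ensemble mean) of
≈ 0.9 pN under the default kinetics; `mce(R, H, …)` estimates it from H
independent repeats, and it follows the CLT `R^{−1/2}` law.

## Exact solver

The joint unfolded-count state `(i_1, …, i_m)` evolves under a linear
master equation whose rates depend on time through `F_{i_1+…+i_m}(l(t))`.
The printed inflow terms of the multi-cluster equation carry a `u_1`
subscript for every cluster; this is read as a typographical slip and
implemented as `u_k` for the k-th cluster's inflow (the only reading that
conserves probability against the per-cluster outflows).

The state space (`Π(n_k+1)` states; 11⁵ = 161 051 for the default
5 × 10 model) is enumerated level-major with per-level sparse inflow
stencils.  Backward Euler with the generator evaluated at the step's end
time is used throughout.  Without refolding the generator is triangular
in the level ordering, so each implicit step is solved *exactly* by one
forward sweep over levels — no factorisation, O(states) per step — which
is why the full model integrates 1000 steps in seconds.  Column sums of
the generator vanish, so the sweep conserves probability to roundoff;
the solution is renormalised (and the event counted) only if the drift
exceeds 10⁻¹², and negative probabilities beyond −10⁻¹⁰ raise an error
advising a smaller step.  With refolding the system is tridiagonal for
one cluster (banded solve per step) and assembled sparsely with an LU
factorisation per step otherwise (intended for small-to-moderate state
spaces; the 50-single-domain-cluster model, 2⁵⁰ states, is Monte Carlo
territory by design).

Backward Euler is first-order: the level probabilities carry an O(dt)
bias that grows with the level (roughly `l·dt/t` in relative terms on
level `l` at constant rates).  The oracle tests therefore compare
step-doubling Richardson extrapolations of the solver output (two runs
at `dt` and `dt/2`) against matrix-exponential and quadrature references
at 10⁻⁶ relative tolerance, alongside raw first-order checks at their
native accuracy; `P_0`, a single exponential, meets 10⁻⁶ without
extrapolation at `dt = 10⁻⁶ s` on the toy models.

The expected strand force is `E[F](t) = Σ_l P_l(t) F_l(t)`; an optional
strand count scales it to a half-sarcomere force.  The distribution of
the force at the first unfolding event is computed in closed form from
the survival of the all-folded state,
`P_0(t) = exp(−Σ_k n_k ∫₀ᵗ u_k(F_0(τ)) dτ)` (trapezoidal quadrature),
with the hazard mapped through the monotone `F_0(l(t))`; if the force is
not monotone over the protocol the density is reported in the time
domain instead.

## What the simulations do and do not show

The generator of study conditions is the fixture set: default mechanics,
the five-cluster kinetics above, and the three canonical protocols.
These reproduce the qualitative phenomenology of titin mechanics —
sawtooth single-strand traces averaging to a smooth ensemble force,
MC/exact agreement within a ~2 pN band at R = 200, rest-dependent
hysteresis recovery, declining peak forces under repeated cycling, and
insensitivity of the mean force to cluster granularity at matched rate
envelopes.  They do **not** constitute a fit to any experimental data
set: spontaneous rates are placeholders, sarcomere-length non-uniformity
and series-sarcomere (myofibril) mechanics are out of scope, domains are
strictly two-state (no molten-globule intermediates), strands are
mechanically independent, and — because every simulation starts fully
folded — no cycle can ever exceed the first cycle's force, unlike some
single-molecule observations.

## Problem sizes and tolerances used in the tests

* MC/exact band: R = 200, `dt_MC = 0.1 ms`, `dt_exact = 1 ms`, three
  seeds; the sup-norm difference is a max-statistic of ensemble noise
  (mean ≈ 1.5 pN, SD ≈ 0.35 pN under the default kinetics), so the 2 pN
  band is asserted on the median across seeds with a 3 pN per-seed
  tripwire.
* MCE scaling: H = 50 repeats, R ∈ {10, 50, 100, 200, 500}, shortened
  ramp (1 → 2 µm at 2 µm/s); log-log slope asserted in (−0.6, −0.4).
* Oracle toys: m ≤ 2, n_k ≤ 3, frozen forces; expm/quadrature at 10⁻⁶
  (extrapolated), MC histograms at R = 10⁴ within total variation 0.05.
* Force-balance residuals < 10⁻¹² relative; probability conservation
  within 10⁻⁹ over every protocol without renormalisation.
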