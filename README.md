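# titinsim

Passive forces in striated muscle are dominated by titin, the giant protein
whose I-band region spans each half sarcomere as a serial molecular spring:
a PEVK segment, a chain of proximal immunoglobulin (Ig) domains that unfold
under force in a stochastic, time-dependent way, and a nearly inextensible
distal-Ig end filament.  In length-ramp experiments the sequential
unfolding of Ig domains produces the familiar sawtooth in single-molecule
force-extension curves, while in a half sarcomere — with ~10⁹ strands in
parallel — only the *expected* force survives.

`titinsim` computes that expected force two ways and cross-validates them:

* **Monte Carlo** — ensembles of independent titin strands simulated with
  a fixed-time-step event scheme (at most one unfolding/refolding event
  per step, selected from one uniform draw against the cumulative
  per-cluster event probabilities), and
* **Exact** — the chemical master equation for the probabilities
  `p_{i1..im}(t)` of the per-cluster unfolded counts, integrated with a
  backward-Euler scheme and aggregated into the level probabilities
  `P_0..P_N` and the expectation `E[F](t) = Σ_l P_l(t) F_l(t)`.

It is aimed at muscle biophysicists who need rigorous half-sarcomere
passive-force curves, unfolding-force distributions, or hysteresis/cycling
behaviour without running thousands of Monte Carlo repeats.

## Model

A strand at half-sarcomere length `l` with `i` unfolded domains is a series
chain in mechanical equilibrium — every element carries the same tension
`F_i(l)`, and the extensions sum to `l`:

* PEVK: modified worm-like chain with stretch modulus `F0`,
  `F = (kT/pl)[¼(1 − x/cl + F/F0)⁻² − ¼ + x/cl − F/F0]`;
* folded and unfolded proximal Ig chains: worm-like chains,
  `F = (kT/pl)[¼(1 − x/cl)⁻² − ¼ + x/cl]`, the unfolded chain gaining
  `d_u = 25 nm` of contour per unfolded domain;
* end filament and A-band/slack region: stiff linear springs, the latter
  absorbing the slack length (force onset near `l = 1 µm`).

Unfolding and refolding are Bell processes,
`u(F) = ω₀ e^{F x_u / kT}`, `r(F) = ω₁ e^{−F x_f / kT}`, with the N = 50
proximal domains partitioned into stability clusters (default: five
clusters of ten with ω₀ spaced geometrically over 10⁻⁵…10⁻³ s⁻¹).

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

```bash
titinsim fixtures --out fx --name ramp      # write the canonical config
titinsim compare --config fx/ramp_config.yaml --out ramp_results
```

prints

```
results written to ramp_results
max |MC - exact| = 2.127 pN
```

i.e. over the whole 1 → 2 µm ramp the 200-strand Monte Carlo mean force
never deviates from the exact expectation by more than ~2 pN (the exact
number is seed-dependent; its scale is the Monte Carlo error of the
ensemble mean, ≈ 0.9 pN at R = 200).  `ramp_results/` then contains
`mc.csv`, `exact.csv` (with the level probabilities `P_0..P_50`),
`compare.csv`, and a JSON manifest that fully reproduces the run.

The same quantities are available as a library:

```python
from titinsim import MechanicalParams, Isoform, solve_strand

F, segments = solve_strand(1.5e-6, 0, MechanicalParams(), Isoform())
print(F * 1e12)   # 44.26 pN  (all domains folded at l = 1.5 um)
F25, _ = solve_strand(1.5e-6, 25, MechanicalParams(), Isoform())
print(F25 * 1e12) # 5.07 pN   (25 unfolded: longer contour, lower force)
```

Other fixtures: `hysteresis` (two 1 → 1.7 → 1 µm stretch-shortening
cycles, a 30 s rest, then a third cycle — the loop area collapses in
cycle 2 and recovers after the rest as domains refold) and `cycles`
(ten ±0.125 µm cycles at a 1.85 µm base — ensemble peak forces decline
as unfolding accumulates).

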