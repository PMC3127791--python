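# Methods

## Model

The Psp response is modelled as a place/transition Petri net with test
arcs over eight places — `stress` (external condition, 0/1), `dm`/`im`
(percent damaged/intact membrane, summing to 100), `olg` (PspA 36-mer
oligomers), and the hexamer-grouped complex pools `hBCA`, `hBcCcAc`,
`hBCAF` plus free PspF hexamers `TF` (summing to 20) — and ten
transitions:

| transition | reaction | rate law | test places |
|---|---|---|---|
| tr1 | im → dm | k₁·stress·im | stress |
| tr2 | dm → im | k₂·olg (gated at dm = 0) | olg |
| tr3 | ∅ → 10 hBCA + olg | k₃·TF | TF |
| tr4 | hBCA + TF → hBCAF | k₄·hBCA·TF | — |
| tr5 | hBCAF → hBcCcAc + TF | k₅·hBCAF·dm | dm |
| tr6 | hBcCcAc → hBCA | k₆·hBcCcAc·im | im |
| tr7 | hBCA → hBcCcAc | k₇·hBCA·dm | dm |
| tr8 | hBCA → ∅ | k₈·hBCA | — |
| tr9 | hBcCcAc → ∅ | k₉·hBcCcAc | — |
| tr10 | olg → ∅ | k₁₀·olg | — |

Test (read) arcs condition enabling and rate on a place without moving
tokens; they are stored as a separate matrix so the incidence matrix
A = Post − Pre — and hence all invariants — ignores them. This is what
makes `stress` a conserved place even though it drives tr1.

The tr3 stoichiometry (ten hBCA plus one oligomer per firing) encodes
the measured 100:60:40 PspA:PspB:PspC production ratio under hexamer
grouping: 60 BCA complexes = 10 hexamer units, and the ~40 remaining
PspA ≈ one 36-mer oligomer. The total PspF pool (20 hexamers) is
fixed: production and degradation of PspF are excluded, consistent
with its observed constancy.

The deterministic counterpart is the mass-action mean field: the ODE
right-hand side is exactly the propensity-weighted incidence sum, with
dm, im treated as continuous percentages and the membrane-repair term
gated by an indicator 1{dm > 0}. Both dm+im and hBCAF+TF are conserved
by construction.

### The tr1 kinetic law

The damage step defaults to first order in the intact membrane,
rate k₁·stress·im. A constant-rate (zeroth-order) variant,
k₁·stress while any membrane remains intact, is available as
`tr1_law="zeroth_order"`. The first-order law is the default because,
with the damage-rate prior U(0,1) used throughout, a constant rate
caps the damage reached in a ten-unit stress window at 10 % — the
a = 60 endpoint the analysis conditions on would be unreachable —
whereas the first-order law reaches 60 % at k₁ = ln(2.5)/10 ≈ 0.092
and bounds dm ≤ 100 without clamping.

### Units

The default analysis runs in counts mode: tokens and percent on both
frameworks, with stochastic and deterministic rate constants identical
for every reaction order. Conversion utilities implement the
molar-mode rules (first order c = k; second order c = k/(n_A·V);
zeroth order c = k·n_A·V, with V = 1 μm³ = 10⁻¹⁵ l and
n_A = 6.02×10²³), but no molar-mode analysis is shipped: the scale
factor α linking counts to concentrations in the initial condition is
taken as 1 in counts mode.

## Structural analysis

Minimal P-invariants (semi-positive integer y with A y = 0) and
T-invariants (Aᵀ x = 0) are computed by positive-combination
constraint elimination (Martinez–Silva): starting from the identity
candidates, each constraint is eliminated by combining rows of
opposite residual sign, with gcd reduction after every combination and
pruning of candidates whose support strictly contains another's.
Arithmetic is exact integer throughout; the expected tables must match
exactly, so no floating-point kernel computation is used anywhere.
The test oracle is independent brute-force enumeration of all
non-negative integer vectors up to a bound on small random nets.

Coverage analysis splits places by membership in some P-invariant
support; uncovered places (olg, hBCA, hBcCcAc) have no conservation
law and are structurally unbounded — the ABC tolerances on complex
levels are what keeps posterior dynamics bounded in practice.
L1-liveness (every transition fireable at least once from M0) is
probed by randomized firing sequences; a fired transition is proof, an
unfired one only evidence of deadness.

## Simulation

**SSA.** Exact direct-method Gillespie (one exponential and one
uniform per event) on integer tokens. The piecewise stress input is
handled by splitting the run at every toggle and resampling the
waiting time at the boundary — exact for exponential clocks, by
memorylessness. Trajectories are step functions; observation at a time
t reads the state after the last event at or before t. Runs exceeding
`max_events` return with a truncation flag rather than raising.

**ODE.** LSODA (via `scipy.integrate.odeint`) restarted at every
stress toggle so the solver never steps across a discontinuity;
defaults rtol 1e-8, atol 1e-10. Output is reported on a grid merged
with the segment boundaries, so endpoint states are solver output, not
interpolation.

**Numerical regularization.** The sharp repair gate 1{dm>0} creates a
Filippov sliding mode at dm = 0 (damage pushing up, repair pushing
down) on which adaptive solvers chatter. The indicator is therefore
replaced by a linear ramp of width 10⁻⁶ percent; the induced solution
shift is below the solver tolerance everywhere it matters. A residual
handful of prior draws (~3 per 10⁵) are fast relaxation oscillators
that still exhaust the step budget; during fitting such proposals are
treated as rejections (infinite distance), as are SSA proposals
exceeding the event cap.

## Qualitative data, summaries, distance

No quantitative data exist. The study conditions are: stress on over
[0,10) and [30,40), off over [10,30) (an alternative schedule with
windows [0,20), [20,30), [30,50) is configured in
`configs/schedule_alt.yaml`); endpoint times t₁=10, t₂=30, t₃=40; and
a target damage level a (60 in the headline analysis; 10, 25 as
variants). The endpoint targets are dm(t₁)=a, hBCAF(t₁)=0, dm(t₂)=0,
TF(t₂)=0, dm(t₃)=a.

The five summaries are S = (dm(t₁), dm(t₂), 6·hBCAF(t₁), 6·TF(t₂),
dm(t₃)) and the distance d = (|S₁−a|, S₂, S₃, S₄, |S₅−a|/a). Design
choices: complexes are counted in PspF-monomer units (×6) so the
tolerance descent 100 → 20 is informative against the 0–120 range, and
the t₃ component is relative (dimensionless), matching the magnitude
(1.5 → 0.7) of its tolerance entries; the first two components are in
percent membrane. Acceptance is the conjunction of all five
component-wise comparisons d ≤ ε.

## ABC SMC

Independent uniform priors: k₁,k₃,k₄,k₈,k₉ ~ U(0,1), k₂ ~ U(0,100),
k₅ ~ U(0,0.05), k₆,k₇ ~ U(0,0.01), k₁₀ ~ U(0,5). Eight populations
with tolerance vectors stepping from (100, 13, 100, 100, 1.5) down to
(10, 3, 20, 20, 0.7). One fresh simulation per proposal. Proposals
for population t > 1 are drawn from the previous weighted population
and perturbed with a component-wise uniform kernel, σᵢ = half the
parameter range spanned by the previous population (floored at 10⁻⁶ of
the prior width for degenerate components); proposals outside the
prior support are redrawn before simulating. Weights are
prior-density over kernel mixture, normalized per population.
N = 100 particles by default (configurable). Reproducibility: the
master seed spawns one RNG stream per (population, particle slot).
A run aborts with a diagnostic naming the offending distance
components if the acceptance rate falls below 10⁻⁵.

ABC rejection is the single-row special case and shares the
implementation.

## Synthetic data and what it does (not) show

The generator produces endpoint datasets for arbitrary a and schedule,
and pseudo-endpoint data from a known parameter vector θ\* (a is set
to the simulated dm(t₁), rounded to a percent, with θ\* recorded for
scoring). It emulates exactly the information content of the real
study — five qualitative endpoint numbers — and nothing more: no
time-course structure, no measurement noise, no cell-to-cell
variability. Passing recovery tests therefore show that the inference
machinery is self-consistent at desk scale, not that real Psp kinetics
are identifiable; with five numbers only the directly constrained
parameters (foremost the damage rate k₁) localize sharply, the rest
stay prior-dominated.

The recovery ground truth θ\* = (0.7, 90, 0.02, 0.2, 0.012, 0.002,
0.01, 1.0, 0.9, 1.4) was chosen, before any fitting, to lie in the
qualitative regime the data describe (its own trajectory satisfies the
final tolerance row on its pseudo-data, a = 69); a truth violating the
endpoint constraints would make recovery ill-posed by construction.

## Qualitative diagnostics

Oscillation score: the number of local maxima of a species' time
course whose peak prominence (scipy.signal.find_peaks) exceeds 5 % of
the series range; a score ≥ 2 flags the trajectory as oscillatory.
The prominence threshold is a design choice — no operational
definition of "oscillation" is given by the qualitative data — and the
reported finding (oscillatory fraction higher at a = 25 than a = 60)
is insensitive to it over a wide range.

Noise profile: each stochastic replicate is time-averaged over a
window (step-function weighting), and the coefficient of variation is
taken across replicates per species; zero-mean species are undefined
and excluded from ranking.

## Problem sizes and runtimes

The shipped analyses use: N = 100 particles for the headline a = 60
fit (about a minute on one CPU; final-population acceptance rate
~10⁻³); N = 40 for the a = 25 fit used in the oscillation comparison
(its acceptance rates are roughly tenfold lower and the compared
fractions, ~0.6 vs ~0.2, are far from the decision boundary) and for
each of the 20 recovery refits; 100 stochastic replicates for the
noise ordering; 1000 particles for the prior-recovery control. These
sizes were chosen as the smallest that leave each conclusion clearly
resolved.

## Known limitations

- The five-component distance block and the counts↔concentration scale
  α are reconstructions documented above, not measured quantities.
- The full reaction network (separate PspA, PspBC, mRNA species;
  PspD/E/G; ArcA/ArcB amplification) is out of scope; the simplified
  net is the analysis object.
- The stochastic-framework priors default to the deterministic ones
  (exact in counts mode for all first-order reactions; the second-order
  tr4 would differ only in molar mode).
- L1-liveness is probed, not proven: no reachability graph is built.
- Posterior scatter shapes depend on the (unreported) particle count
  and sampler details; only qualitative posterior properties are
  asserted anywhere.
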