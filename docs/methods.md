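# Methods

## Knowledge representation

A knowledge library declares template entities and a forest of template
processes. Entities carry variable properties (molecule counts in the
stochastic setting, concentrations in the deterministic one; no unit algebra
is attempted) and constant properties with finite admissible ranges — the
formal carrier of parametric uncertainty. Processes carry entity slots,
constants, nested process references and, on taxonomy leaves only, reaction
templates; children inherit their parent's slots and constants. An
`optional` process is two-level sugar: a parent with an empty `absent` child
and a `present` child holding the declared body. The concrete syntax is a
small line-oriented block grammar (see the fixture documents in
`procdesign.casestudies`) chosen to be hand-writable and diffable; a JSON
mirror of every parsed object is available for interchange.

An incomplete model binds entity instances (with initial values and
fixed-or-ranged constants) and process instances. A process instance may
reference an inner taxonomy node or an optional node; each such reference is
an open design choice. Enumeration takes the Cartesian product over all
choices — an inner node contributes the sum of its children's alternatives, a
leaf the product over its nested references — and is purely combinatorial:
a combination whose reactions can never fire (e.g. bound-repressor
degradation chosen while the binding itself is absent) is retained and
counted in the complexity. Candidate ids are slash-joined
`choice-point:chosen-leaf` tokens, ordered by model declaration, and the
candidate list is sorted by id, so enumeration is deterministic and
order-stable.

## Simulation

Flattening substitutes entity bindings into the chosen leaves' reaction
templates (reversible arrows were already expanded to forward/backward pairs
at parse time), scopes constants by instance path so parameter symbols are
globally unique, and collects the *free* parameters — ranged constants
actually referenced by the flattened rate laws. Unreferenced inherited
constants (e.g. the Hill constants of the empty auto-interaction leaf) carry
no uncertainty and are excluded from the optimization box.

Deterministic interpretation: mass-action rates k·Πxᵢ^sᵢ and cooperative
inhibition/activation rates k·[substrate]·[catalyst]ⁿ/(Kⁿ + [catalyst]ⁿ).
The integrator is an adaptive embedded Dormand–Prince 5(4) scheme compiled
with numba (defaults rtol 1e-6, atol 1e-9, grid points hit exactly); a SciPy
LSODA path is kept as an independent cross-check (the test suite asserts
agreement on the Hill ring) and as a fallback for genuinely stiff corners.
The compiled path exists because ranking experiments need ~10⁵ integrations;
a non-finite state or step-count exhaustion flags the trajectory rather than
raising, and flagged trajectories map to worst-case objectives so the
optimizer stays total. States are clamped at zero inside rate evaluation to
tolerate integrator under-shoot.

Stochastic interpretation: exact Gillespie direct method over mass-action
propensities with the standard falling-factorial combinatorics;
Hill-type laws are deterministic-only and raise if simulated stochastically.
Trajectories are right-continuous piecewise-constant, sampled on the task
grid, and the ensemble mean over n realizations is returned. Finiteness of
the state space is enforced pragmatically by a configurable cap on the total
molecule count (default 10⁶; 2·10⁵ inside optimization loops) plus an event
budget per realization; a capped realization is an aborted realization.
Seeding is counter-based: realization i of master seed s is seeded from
SeedSequence((s, i)), so results depend only on (s, i), same-seed runs are
bit-identical, and ensembles are extensible without perturbing earlier
realizations. Piecewise-constant inputs (the toggle's inducer pulses) are
injection events handled by both simulators; the sample at an injection time
shows the post-injection state.

## Objectives

All objectives are minimized and normalized to an a-priori finite [0, 1]
domain with the optimum at the origin, the two prerequisites of the
hypervolume ranking.

*Switching* (toggle): with B̄(t) the ensemble-mean observed protein count, H
the target high level, and α/β the expected-high/expected-low windows,
O1 = mean over α of |B̄ − H|/H and O2 = mean over β of B̄/H, each clamped at
1. Window means are taken over sample points, which on the integer grid
coincides with interval-length normalization up to the endpoint convention.

*Oscillation*: the measured frequency f̂ is the largest-magnitude nonzero
bin of the discrete Fourier spectrum of the post-transient (t ≥ t₀ = 2 s),
mean-removed signal; the measured amplitude Â is peak-to-trough (max − min).
Both discrepancies use the symmetric relative form
u(target, measured) = |target − measured| / max(target, measured) ∈ [0, 1]
(0 at the target; 1 when the measurement is zero or far off). A constant
signal has f̂ = 0 and Â = 0. Failed simulations score (1, 1). The objective
forms are registered per task spec and can be overridden in user configs.

## Optimization

GDE3 is implemented directly: DE/rand/1/bin trial generation (defaults
population 40, F = 0.5, CR = 0.3), out-of-bounds components clipped to the
box, dominance-based selection (trial replaces parent if it weakly
dominates; both survive when incomparable), and pruning of the grown
population back to size by non-dominated sorting with crowding-distance
truncation. The returned front is the final population's non-dominated set
with exact duplicates collapsed. Runs are reproducible given the seed;
per-structure seeds are derived by hashing (master seed, structure id), and
each stochastic objective evaluation draws a fresh hashed substream, so
archived points are not re-evaluated — a deliberate cost/noise trade-off
noted as a limitation below.

## Ranking

HVUPF is the Lebesgue measure of ⋃ₚ [0, p] over the front points p — the
region between the front and the origin. It is computed exactly: a
containment filter plus a staircase sweep in 2-D, recursive slicing along
the last coordinate in higher dimensions; the tests cross-check against a
Monte-Carlo estimate. An empty front scores 1. Note a consequence of this
origin-anchored definition (as opposed to the complement of the standard
reference-point hypervolume): a front point lying on a coordinate axis
spans a zero-volume box, and adding points to a front can only grow the
union. The quantity is therefore a capability summary of the front, not a
convergence monitor — it can legitimately increase while an optimization
run fills in a fixed trade-off curve, which is why the optimizer tests pin
the final-front volume against a dense-grid oracle instead of asserting
per-generation monotonicity.

Scores combine min–max-normalized HVUPF and reaction-count complexity as
α·HV̄ + (1−α)·C̄ (α default 0.5; a degenerate component normalizes to 0 for
all candidates). Lower is better; ranks are tie-averaged so equal scores
share fractional ranks, and multi-task experiments are summarized by
per-structure medians of the per-task ranks.

## Case-study fixtures

The fixtures are the package's study conditions; their DSL texts are pinned
by content hash in the tests.

**Toggle switch** (stochastic, grid t = 0…100 at integer samples, 100
realizations per evaluation). Five entities: gene (production rate k_p ∈
[0, 10], decay k_d ∈ [0, 1], both per gene instance), protein, bound factor,
inducer, inducer–protein complex; instances gA, gB, A, B, S, R, AgB, BgA,
SA, RB, AB, gene copy number 1. Mandatory processes: expression
(g → g + p), decay (p → ∅), irreversible inducer sequestration
(S + A → SA, R + B → RB). The inhibition family is an alternative pair:
the *simple* branch nests three independent binary options — A→gB binding,
B→gA binding (each a reversible promoter binding p + g ↔ bound factor) and
degradation of the bound repressors (AgB → gB, BgA → gA, one shared rate,
toggled as a single linked choice) — while the *exclusive* branch models a
shared operator: binding requires both promoter-site species free
(A + gA + gB → AgB + gA, with gA catalytic, and symmetrically for B), so
repressor co-occupancy — the deadlock state of the non-cooperative switch —
is structurally impossible. Repressor heterodimerization (A + B ↔ AB) is a
separate top-level optional. This yields 1·1·1·1·(2·2·2 + 2)·2 = 20
candidate structures with 6–14 reactions. The expected behaviour is driven
by inducer pulses of 300 molecules: S at t = 0 (sequesters A, so B is
expected at H = 20 on α = [10, 45]) and R at t = 50 (sequesters B, expected
0 on β = [60, 95]). H and the pulse sizes were chosen so that mid-range
production rates can reach the plateau within the windows at gene copy 1.

**Oscillator** (deterministic, grid t = 0…28 s at 40 Hz, transient cutoff
2 s). One protein entity with active/passive concentration variables; three
instances A, B, C with conserved total 1 each (A starts active, B and C
passive, breaking symmetry). Per-protein basal turnover
(passive ↔ active, k_act ∈ [0.5, 5], k_inact ∈ [0, 2]) and a Hill
inhibition ring A ⊣ B ⊣ C ⊣ A (active form of the source catalyses
inactivation of the target; k ∈ [5, 60], K ∈ [0.3, 0.7], Hill exponent
fixed at n = 8). The open choice is one auto-interaction on A with five
leaves: none, weak/strong auto-activation, weak/strong auto-inhibition
(same loop template, k ∈ [0, 5] for weak and [5, 50] for strong, i.e.
below/above the basal turnover scale). The ranges were calibrated — before
any ranking experiment was run — so that the bare ring oscillates on a
substantial fraction of its parameter box rather than a measure-near-zero
sliver, emulating the robust relaxation-type oscillators this design task
is modelled on: steep cooperativity with half-saturation near mid-range
makes the bare ring oscillate over a broad region of the box, and the
auto-activation variants extend the reachable amplitude range towards
full swing — the capability contrast the ranking experiments probe. The
design tasks target the Cartesian product f_t ∈ {0.1, 1, 10} Hz × A_t ∈
{0.01, 0.1, 1} for observed active A and active C (B follows by symmetry);
since all candidates share the ring and turnover reactions, these tasks
rank by HVUPF alone (α = 1).

What the fixtures do *not* emulate: transcriptional leak, cell growth and
division, extrinsic noise, resource competition, or measured data of any
kind — passing the built-in experiments shows the design machinery ranks
mechanisms consistently with the fixtures' dynamics, not that those
mechanisms behave identically in a cell.

## Scaled problem sizes

The ranking experiments are run at a reduced optimizer budget chosen as the
package's default desk-scale protocol: GDE3 population 20 × 40 generations
(~820 evaluations per structure) for the 2 × 9 oscillator task grids, and,
for the stochastic toggle, a four-structure subset (basic, exclusive,
protein–protein, bound degradation — the variants studied before this space
was enumerated) at population 12 × 12 generations with the full
100-realization ensembles. The full 20-structure stochastic experiment is a
matter of CPU hours, not of different code, and can be launched with
`procdesign run` on a larger budget.

## Numerical choices and degenerate inputs

Tolerances: ODE rtol 1e-6 / atol 1e-9; divergence guard |y| > 1e9; SSA state
cap and event budget as above. Ties: candidate ordering is lexicographic by
id everywhere; rank ties are averaged; duplicate front points collapse to
the first occurrence. Empty objective windows, overlapping α/β windows,
non-uniform post-transient sampling, negative states passed to the rate
evaluator, and Hill laws in stochastic networks are rejected with explicit
errors. A model with no open choices enumerates to exactly one candidate; a
structure with no free parameters skips the optimizer and is scored from a
single evaluation.

## Known limitations

Exhaustive enumeration only (no heuristic search over structures); no
re-evaluation of archived stochastic points (optimizer may keep lucky noise
draws); SBML export targets this package's own round-trip (a minimal L3V2
writer/reader with a rate-law annotation) rather than arbitrary third-party
import; the exclusive-switch encoding uses a third-order binding step to
express shared-operator exclusivity in pure mass action, which is a modelling
idealization at gene copy number 1.
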