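# Methods

## Model

The population model is a consumer-resource formulation of plant–
pollinator mutualism. Plants benefit from pollinator visits through the
product of visit *quantity* `v_ij = A_j P_i τ_j α_ij` and visit
*quality* `σ_ij`, the fraction of conspecific pollen among all pollen
carried by pollinator `j`; pollinators benefit from plants only through
consumption of floral rewards `R_i`, a depletable resource produced at
rate `β_i P_i` and self-limited at rate `φ_i`. Both guilds are obligate
mutualists: a plant with no visitors and a pollinator with no rewards
decline exponentially at their mortality rates. Rewards consumption is
linear in `R_i` (Type I); saturation emerges dynamically because the
rewards pool itself is capped by its production/decay balance.

Adaptive foraging is a replicator equation on each pollinator's effort
simplex: effort flows toward diet plants whose rewards yield the
highest per-effort intake `c_ij τ_j b_ij R_i`. Summing the equation over
a pollinator's diet gives exactly zero, so `Σ_i α_ij = 1` is conserved
analytically; the integrator is only trusted to keep it within 1e-6 and
efforts are renormalized at event boundaries. The fixed-forager variant
pins `α_ij = 1/degree_j`, re-uniformized whenever a diet changes.

Two behaviors of this system drive everything downstream:

* **Specialist plants under adaptive foraging.** A rare plant's rewards
  per unit abundance are undepleted, so its sole pollinator shifts
  effort toward it; because plant fitness scales with `Σ_j A_j α_ij²`
  (quality times quantity), concentrating one pollinator's effort beats
  spreading the same total consumption across many visitors. Specialist
  colonizers therefore establish at the highest rate among plants.
* **Generalist pollinators.** They hold the widest rewards portfolio
  and, having more than one option, are the only ones that can
  reallocate; with fixed foraging their abundance advantage instead
  drains shared rewards pools and starves specialist pollinators.

## Assembly procedure

Assembly begins empty. Each event introduces three plants then three
pollinators (plants first so the first cohort of pollinators has
something to attach to; a colonizer facing an empty opposite guild
enters unlinked and almost surely dies). Specialists get one uniformly
chosen partner; generalist degree is uniform on {2, …, N_opposite},
clamped in tiny networks. Colonizers enter at the extinction-threshold
abundance; a new plant's rewards start at the zero-consumer equilibrium
`β P₀ / φ`; a new pollinator's efforts start uniform over its diet. A
new link into an *existing* pollinator starts at a small seed effort
(1% of the simplex, capped at the uniform share) with existing efforts
rescaled: under adaptive foraging a colonizer must earn effort through
the replicator dynamics rather than being granted an instant uniform
share (granting it swamps the specialist/generalist asymmetry the
adaptive model is meant to express; the fixed variant, by definition,
does re-uniformize).

Between events the system is integrated for 2000 timesteps (LSODA,
rtol 1e-6, atol 1e-8); at each event boundary species at or below the
extinction threshold are removed, survivors' efforts renormalized, and a
binary snapshot is stored both right after introductions and after
extinction processing. Establishment is survival beyond 4000 timesteps;
species arriving too close to the end to be assessed are flagged as
censored rather than counted either way.

## Parameters

Each colonizer draws every demographic parameter from a uniform
distribution parameterized by mean and variance — uniform on
`[m − √(3v), m + √(3v)]`, which matches the stated moments exactly,
truncated at zero where positivity is required. Shipped defaults
(mean, half-width):

| parameter | meaning | default |
|---|---|---|
| g | max seed-to-adult recruitment | 0.4 ± 0.1 |
| u | interspecific plant competition | 0.12 ± 0.06 |
| w | intraspecific plant competition | 0.3 ± 0.1 |
| β | rewards production rate | 0.4 ± 0.2 |
| φ | rewards saturation rate | 0.04 ± 0.01 |
| ε | pollen picked up per visit | 1.0 ± 0.4 |
| µ^P | plant mortality | 0.014 ± 0.007 |
| e | seeds per pollination event | 0.8 ± 0.2 |
| τ | visitation efficiency | 1.0 ± 0.8 |
| c | rewards→births conversion | 0.2 ± 0.05 |
| b | rewards extraction per visit | 0.4 ± 0.3 |
| µ^A | pollinator mortality | 0.001 (fixed) |
| G | adaptive foraging rate | 30 (fixed; 0 in the fixed variant) |

Pollinator mortality is the model's clock (doubling time ln 2 / µ^A ≈
693 timesteps ≈ one generation). The remaining defaults are this
package's calibration choices, anchored to the published
parameterizations of the underlying consumer-resource model and to the
regime the assembly analysis requires: interspecific plant competition
stronger than intraspecific (u > w) so that plant turnover occurs; wide
τ and b spreads so pollinator fitness differences drive turnover; plant
mortality high enough that colonization is selective; and a fast
adaptation rate so effort reallocation completes within an inter-event
interval (the replicator timescale is 1/(G · c τ b R) and rewards sit
near µ^A/(c τ b), making G ≫ 1 necessary for within-event convergence).
All are overridable through `ParamDistributions` or the YAML config.

The extinction threshold (default 0.05 abundance units, also the
introduction abundance) is a modeling assumption: no printed value
exists for it. It sits roughly an order of magnitude below typical
resident plant abundances; far smaller values make rare-plant invasion
growth (which scales superlinearly in P near the ideal-free effort
distribution) numerically hopeless and suppress the specialist-plant
pathway entirely.

## Motif analysis

Two same-guild species interact indirectly when they share at least one
direct partner; longer paths are ignored. The four motif groups cross
the focal colonizer's niche class (specialist = degree 1) with whether
*any* indirect partner is a specialist. Focal colonizers whose partners
host no other same-guild species have no indirect interactions and are
excluded, as are the first nine attempted colonizers of each guild
(networks too small to analyze; "attempted" is counted in arrival
order). Trajectories are evaluated at arrival (with the focal's links
as introduced — same-event pollinators may already have attached to a
plant colonizer by snapshot time), one interval later on the
post-extinction network, and two intervals later after the subsequent
colonization event.

At the two later timepoints the focal's specialist/generalist prefix is
frozen at its arrival value and only the indirect-partner suffix is
re-evaluated. Focal-degree changes are caused by opposite-guild
turnover (new pollinators attaching to a resident plant, partners going
extinct); treating them as motif transformations would conflate them
with the intra-guild events the groups are designed to detect — indeed
any attachment rule that lets generalists sample half the opposite
guild re-links most specialists within two events. Such drift is still
recorded separately (`focal_type_changed`). The two headline flags are
then pure suffix transitions: `*-Spec → *-Gen` between arrival and
+2000 (all indirect specialists excluded) and `*-Gen → *-Spec` between
+2000 and +4000 (a subsequent specialist established on a shared
partner).

## Network metrics

Connectance is links over the product of guild richnesses. NODF follows
the paired-overlap-with-decreasing-fill definition over both guilds:
for every unordered pair of rows (and columns) with strictly different
marginal totals, the pair contributes the percentage of the sparser
member's links shared with the denser one; ties contribute zero. The
implementation is cross-checked in the test suite against a literal
brute-force version and against R's `vegan::nestednodf`. The
size/connectance correction `NODFc = NODF / (C · log10 √(n_p n_a))` is
one of several published normalizations; it is isolated in a single
function, returns NaN for degenerate networks, and the raw NODF is
always reported alongside.

Variant comparisons match grid cells by probability pair and report
both a paired one-sided t-test (the headline, since pairing by cell is
the design) and a one-sided Welch unequal-variance test; "paired Welch"
is a contradiction, so both are computed. Trajectory summaries use a
seeded percentile bootstrap (default 1000 resamples) over simulations.

## Numerical choices

* LSODA with rtol 1e-6 / atol 1e-8 (configurable): rewards and effort
  dynamics are much faster than demographic change, so a
  stiffness-switching method is used.
* Abundances are clamped at zero inside the right-hand side; efforts are
  floored at 1e-12 before renormalization to avoid absorbing states
  created by floating-point underflow in the replicator equation (which
  preserves positivity analytically).
* Extinction checks happen at fixed 2000-step checkpoints aligned with
  colonization events, not by continuous root-finding: the event cadence
  defines the observation grid, and continuous detection over dozens of
  species is costly with no effect on event-boundary snapshots.
* Integrating with `t_span = 0` is an exact no-op; a failed solve raises
  with the community state attached.

## Problem sizes and what the tests show

The test suite and the acceptance script run a reduced design — 3×3
probability grid {0, 0.5, 1}², 20 colonization events, 3 seeds per
variant — chosen so the full suite completes in a few minutes on one
CPU. At this scale the qualitative contrasts between variants are
reproduced: adaptive-foraging networks are sparser, lose almost no
established plants, and their modal motifs are Spec-Gen (plants) and
Gen-Spec (pollinators), versus Gen-Gen for both guilds with fixed
foragers. Two caveats at reduced scale: the richness advantage of
adaptive foraging accrues mostly from the fixed model's slow extinction
debt (established species decline at rates bounded by their small
mortality) and is therefore modest after 20 events; and modal-motif
counts rest on a few hundred colonizers, so individual seeds can
reorder closely ranked groups. Both sharpen with the full 11×11 grid
and 50 events.

The generator *is* the study design — there is no external data. What
passing tests show is that the implemented mechanisms produce the
documented regime under the shipped parameter distributions; they do
not validate those distributions against field measurements, and the
model omits demographic stochasticity, saturating (Type II+) functional
responses, spatial structure and phenology by design.
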