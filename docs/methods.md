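# Methods

## The modeling language

`mlrules` implements a rule-based language for multi-level models of
cell-biological systems, with an exact stochastic simulator as its
semantics.

**State.** The state is a *solution*: a multiset of species
populations.  A species has a name, a fixed-arity tuple of attribute
values (numbers, symbols, booleans, or opaque fresh identifiers), and
optionally an enclosed solution of further species, to arbitrary depth.
A species with empty content *is* an atomic species.  Solutions are
kept in canonical form: populations with identical name, attributes and
(recursively canonical) content are always merged, amounts are positive
integers, and populations are ordered by an injective serialization of
the species.  Attribute identity is exact and type-tagged — `1`, `1.0`
and `true` are three different values; there is no numeric tolerance in
species identity.

**Rules.** A rule schema rewrites a reactant multiset into a product
multiset at a kinetic rate given by an arbitrary non-negative
expression.  Schemata bind attribute variables (`A(x)`), filter by
attribute expressions (`A(2 * x)`), bind a population's amount to a
*species identifier* (`A(x):a`, usable in the rate, e.g. mass action
`k * a`), match nested content (`C(v)[M_A:a + s?]`), capture the
unmatched rest of a content solution in a rest variable (`s?`) that can
be reused — including several times — on the product side, and create
globally fresh attribute values with `nu(x)` (the private-channel idiom
for bonds and individual identities).  `@ r if c` is sugar for the rate
`if c then r else 0`.  Rules are uni-directional; reversible reactions
are written as two rules.

**Matching and propensities.** A rule's top-level reactants must all be
found within one sub-solution (the *site*); every rule is tried at the
root and inside every nested species.  Population-level semantics make
the propensity of an instance the product of its rate-expression value
and the amounts of all populations strictly enclosing the site (a
reaction is proportionally more likely if more enclosing individuals
exist in which it could take place).  Two deliberate conventions:

* Reactant amounts are never folded into the propensity automatically;
  mass action is written explicitly through identifiers (`k * a`).
  Only the enclosing-context amounts are automatic.  This reconciles
  per-instantiation rates like `k*2` / `k*4` over `[2 A(1) + 4 A(2)]`
  with context products such as `2*2*1*2 = 8` for a match under one
  enclosing species inside an outer population of two.
* Two identical patterns may match one population iff its amount is at
  least the number of patterns; each identifier binds the same total
  amount, and combinatorial factors (n(n-1)/2 and the like) are the
  modeler's responsibility in the rate expression.

Equivalent instantiations (same site, same grounded reactants and
products, same rate value) are grouped into one reaction instance with
summed weight.  Matched nested reactants lose any content not captured
by a rest variable when the rule fires — preservation must be written
explicitly, which is the language's way of making content flow visible.

**Execution.** Simulation is the Gillespie direct method on the grounded
instances: exponential waiting time with the total propensity, linear
selection in canonical order, then removal of the grounded reactants
and insertion of the grounded products at the site.  Removing or
inserting deep inside a nested population splits one representative off
every enclosing population and re-merges the modified copy at every
level (the split/merge bookkeeping), so the state stays canonical.
Rest-solutions are reused by reference (solutions are immutable), so
copying a mother cell's content into two daughters is exact and cheap.
Fresh values come from a counter separate from the random stream, so
identifier creation never perturbs the random sequence.  Trajectories
record pattern-counting observables at equidistant instants using the
state right before each instant; runs are bit-reproducible for a fixed
(seed, replicate) pair.

**Network expansion.** For flat models with finitely many reachable
attribute values, `expand_network` unfolds the schema model into an
explicit species/reaction list by fixed-point closure from the initial
species.  Rates in the expanded network are rule rates evaluated with
identifiers set to one (the per-configuration constant).  The classic
scaffold example — one protein with n independent binding sites plus n
partners — expands to `2^n + n` species and `2·n·2^(n-1)` reactions
from `n + 1` species definitions and `2n` rules.

## Numerical and engineering choices

* Arithmetic: integer-by-integer division yields an integer when exact,
  a float otherwise; rates must evaluate to non-negative numbers, and a
  division by zero in a rate aborts the run rather than being silently
  absorbed.  Booleans are legal only in conditions, never as rates.
* Rate and attribute expressions are compiled once per model to Python
  callables (constants inlined, user functions as positional lambdas);
  the interpretive evaluator defines the semantics and the test suite
  asserts parity between the two.
* Matching results are memoized against canonical forms at three
  granularities — per (rule, sub-solution), per population for
  single-reactant rules, and per species subtree for the aggregate
  propensity below it — so a simulation step only re-matches the spine
  of the hierarchy the previous firing actually changed.  The caches
  are value-keyed and never invalidated, only size-capped (50k entries
  per table).  This is a memoization of the full re-match semantics,
  not a reaction dependency graph.
* The cyclic garbage collector is paused inside run loops (all engine
  data structures are acyclic, so reference counting reclaims them);
  long simulations otherwise spend most of their time in GC scans.
* Selection descends the nesting hierarchy using the cached subtree
  aggregates; a float round-off at the last ulp of the cumulative sum
  falls back to re-selection just inside the total, then to the last
  available instance.

## The yeast example models

The fixtures implement a three-level fission-yeast study: an
intracellular MPF control circuit, cell-level growth/phase/division
dynamics, and cell-cell communication, optionally on a spatial grid.

**Intracellular layer** (after Tyson's cyclin/cdc2 oscillator, reduced
to five species): cyclin `Y` is synthesized and associates with free
cdc2 `D` into inactive MPF `M_I`; activation `M_I -> M_A` is
autocatalytic with rate `k3 * m_i * (m_a / d_tot)^2`; dissociation
`M_A -> D + Y_P` has rate `k4 * m_a` under the constraint `a > 1`, so
one active complex always survives to seed the autocatalysis;
phosphorylated cyclin `Y_P` and free cyclin turn over.  `k3 = 180` and
`k4 = 0.9` min⁻¹ are the published oscillation-region constants; the
remaining constants have no published values here and are ESTIMATED
(marked in the fixture source): `k1 = 0.03·d_tot` (synthesis),
`ka = 200` (association), `k2 = 0.05`, `k7 = 0.6` (turnover), with a
default pool of `d_tot = 400` cdc2 per cell.  With these choices the
flat model bursts with a ~30–40 minute period.

**Cell level.** A cell `C` carries its volume as an integer number of
growth steps of `1/T_d` (so repeated increments never fragment
populations through float drift); volume 1 and 2 (i.e. `T_d` and
`2·T_d` steps) are the typical sizes at birth and division.  Growth
fires at `k6 = 1` per minute per cell.  Inside a cell, dissociation is
diluted by volume: rate `k4 * a * v_ref * T_d / v`.  Tyson's dilution
argument (the dissociating activity halves over one mass-doubling time)
fixes the 1/volume shape but not its reference point; `v_ref` — the
volume, in birth units, at which the machinery runs at exactly `k4` —
is ESTIMATED at 4.5.  This single constant is what makes small cells
sit below the ignition threshold of the autocatalytic burst until they
have grown, which is the mechanism that locks the multi-level model's
mean cycle to the mass-doubling time: calibrated at `d_tot = 400`,
`v_ref = 4.5` the measured mean division-to-division time is ≈ 118 min
against `T_d = 116` min.  Phase transitions are threshold-gated upward
causation: `G1 -> S/G2` when `M_I` exceeds `t7`, `S/G2 -> M` when `M_A`
exceeds `t8`, and `M -> G1` with volume halving (division) when `M_A`
falls below `t9` (`t9` far below `t8`).  Thresholds default to the
calibrated fractions (0.30, 0.15, 0.02) of the pool.  Growth is allowed
in every phase except M.

**Population layer.** Division produces two daughters, each with a
complete copy of the mother's content (total cdc2 per cell — `D + M_I +
M_A + M_R` — is conserved), volume split exactly in half, and mating
type/switchability assigned by the published lineage pattern: an
unswitchable (U) mother yields one U and one S daughter of her own
type; a switchable (S) mother yields one S daughter of her own type and
one U daughter of the *opposite* type (`if t = P then M else P`).
Cells die at `k_death` (0.006 min⁻¹ at full scale, which balances the
wild-type cycle).  With pheromones enabled, P cells secrete `F_P`,
M cells secrete `F_M` and the protease `Sxa2` that degrades `F_P`;
extracellular pheromone of the opposite type represses MPF across the
membrane (`F + C[M_I + s?] -> F + C[M_R + s?]`, downward causation
across a nested boundary) at a Hill-type rate
`hmax·f³/(hillk³+f³) · i · T_d/v`, and repression relaxes back
volume-proportionally.  Hill, secretion, loss and de-repression
constants are ESTIMATED to place half-saturation at a few hundred
extracellular molecules, matching the reported no-effect/arrest
contrast between ~200 and ~600 molecules.

**Spatial layer.** Voxels `G(x, y, n_cells)` tile a 2-D grid, one per
coordinate pair; pheromones hop between von-Neumann neighbors (the
`nb()` predicate), leave the system at the rim, and cells are displaced
from crowded voxels at a rate ∝ `1/(n_target + 1)` (ESTIMATED — the
displacement rate function is only described qualitatively).  Division
and death inside a voxel update its `n_cells` attribute through
extended-context rules, and the suite checks the attribute stays equal
to the structurally counted cells after every firing.

## What the fixtures do and do not show

The fixtures are study conditions, not quantitative fission-yeast
biology: molecular counts are scaled (hundreds, not realistic copy
numbers), several constants are reconstructed rather than published,
and spatial rates are qualitative.  Passing tests demonstrate the
*language semantics* (matching, context propensities, split/merge,
conservation under content copying) and the *qualitative multi-level
phenomena* (sustained bursts, cycle/size homeostasis, mating-type
equilibration, pheromone-induced G1 arrest); they do not validate
parameter values against experiments.

## Problem sizes used by the test suite

Stochastic end-to-end checks run at reduced sizes chosen once:
oscillation, 20 runs × 200 min of the flat model; cycle length, 2 runs
× 2500 min of one multi-level cell; SSA cross-validation, 10⁴
replicates of a 3-species network against an independently coded direct
method plus a 10⁴-minute immigration–death run; conservation, ~2500
firings of each cell-bearing fixture (pool 100, 3 cells); pheromone
contrast, 3 paired seeds, 8 cells, T_d = 232, 700 min; mating-type
equilibration, 8 runs, 40 cells (pool 100, thresholds at the calibrated
fractions), 1000 min, with the equal-mix band [0.35, 0.65] assessed on
the across-run mean P-fraction — at these population sizes single-run
fractions fluctuate with σ ≈ 0.1, so the replicate mean carries the
equilibration claim at the statistical strength that single runs have
at full scale.  Reduced-pool population runs use a death rate balancing
their measured division rate, preserving the full-scale design relation
between death and cycle time.

## Known limitations

* Functions over solutions (e.g. counting or splitting a bound
  solution) are not supported; content can be copied or moved whole.
  The spatial fixture therefore tracks cell counts in a voxel
  attribute.
* Attribute expressions in reactant patterns can only be checked once
  their variables are bound by earlier positions (left-to-right);
  `A(x) + A(2 * x)` works, `A(2 * x) + A(x)` finds no match.
* Network expansion requires flat rules and finite reachable attribute
  sets; nu-rules and nested models are rejected.
* Exponential waiting times only; no hybrid or delayed dynamics.
* The matcher re-derives instances from canonical forms each step
  (memoized); models whose every sub-solution changes every step run at
  Python speed, a few thousand events per second.
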