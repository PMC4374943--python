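# Methods

`hollownet` analyses bipartite species–microhabitat networks in which the
rows are saproxylic insect species, the columns are tree hollows, and a
cell `a_ij` counts the individuals of species *i* that emerged from hollow
*j*.  The package implements the statistics used to characterise such
networks — nestedness with null-model significance, bipartite modularity,
categorical core/periphery structure, descriptive indices, and robustness
to microhabitat loss — together with a synthetic-matrix generator that
emulates three Mediterranean woodland communities for which no raw
matrices are publicly available.

## Data model

`AbundanceMatrix` holds nonnegative integer counts with unique,
whitespace-trimmed, case-sensitive labels on both axes; `IncidenceMatrix`
is its 0/1 view (cell = 1 iff the count is positive).  The orientation is
fixed throughout: rows are the higher trophic level (insects), columns the
lower (hollows); robustness simulations remove columns and count surviving
rows.  All-zero rows or columns are dropped (with a logged warning) before
any statistic is computed — a sampled hollow without emergences carries no
information for these pattern statistics.  Degenerate results (nothing
left on an axis) raise instead of returning arbitrary numbers.

## Nestedness: NODF and WNODF

NODF scores every pair of rows and every pair of columns.  A pair
contributes only when the first member's fill (number of presences) is
strictly larger than the second's; the contribution is the percentage of
the lighter member's presences that coincide with presences of the heavier
member.  The total is the mean over all C(R,2)+C(C,2) pairs, 0–100.
WNODF replaces both conditions with their quantitative counterparts:
strictly larger marginal totals, and cells of the lighter member that are
positive and strictly smaller than the matching cell of the heavier one,
divided by the lighter member's positive-cell count.

Ties contribute zero in both estimators (they are never broken by stored
order), which makes both statistics invariant under row and column
permutation — this is asserted by tests, together with exact agreement
against an independent exhaustive pairwise enumeration and against
`vegan::nestednodf`.  One subtlety uncovered by the cross-check: vegan's
weighted variant conditions pairs on *binary fill* (tie-broken by weighted
totals) where this package conditions on *marginal totals*.  The two
conventions coincide whenever fills and totals decrease together, which is
how the cross-check fixture is constructed.  A consequence of the
strictly-smaller rule worth knowing: WNODF of any 0/1 matrix is exactly 0.

## Null models and significance

Two null models feed the Monte-Carlo significance machinery:

* **CE** (qualitative): each null cell is an independent Bernoulli draw
  with `p_ij = (r_i/C + c_j/R)/2`, the average of the row's and the
  column's occupancy proportion, so the chance of an interaction tracks
  the generalization level of both partners.  The identity
  `sum_ij p_ij = L` holds analytically, so the ensemble conserves the
  expected fill.  Replicates containing empty rows/columns are retained;
  if a statistic is undefined on a replicate it is dropped and counted,
  with a warning above 1% drops.
* **RC** (quantitative): the observed `m` individuals are placed one at a
  time; the row is drawn proportionally to the observed row totals among
  rows that have not reached their total, the column likewise, and draws
  into saturated margins are rejected.  Every replicate reproduces all
  row totals, column totals and the grand total exactly (asserted per
  replicate).  The implementation batches draws and accepts each batch up
  to the first margin-saturation event, which is exactly the sequential
  process vectorised; a 137×30 matrix with 2343 individuals takes about
  20 ms per replicate.

Significance is one-tailed ("observed greater") with the add-one rule
`p = (#{null >= obs} + 1)/(n_rep + 1)`; with 1000 replicates the smallest
attainable p is 1/1001, printed as 0.001.  z-scores use the null mean and
sd (ddof=1).

Calibration is checked in the exchangeable design: a matrix drawn from the
CE ensemble of a fixed reference is tested against further draws from that
same ensemble (`significance(..., null_basis=reference)`), under which the
p-value is uniform by construction; the rejection rate at α = 0.05 over
200 trials must sit inside the binomial 95% band.  The everyday usage —
re-deriving CE probabilities from the tested matrix itself — is *not*
exactly calibrated (the data enter twice); in our experiments it rejected
~11% of true-null draws at the 5% level.  This is a property of the
conditional null itself, not of the implementation, and is worth keeping
in mind when p-values sit near the threshold.

## Bipartite modularity

For a joint partition of row and column nodes,

    M = sum_m [ L_m/L − K_m^A K_m^B / L² ]

with `L` the total links, `L_m` the within-module links and `K_m^A`,
`K_m^B` the summed row/column degrees of module *m*.  The one-module
partition scores 0; a complete bipartite graph admits no positive
partition (checked exhaustively on K₂,₂); evaluation agrees with a
rational-arithmetic oracle at 1e−12.

Maximisation is simulated annealing over single-node reassignments (a
move into an empty module slot acts as the minimal split) plus explicit
module–merge proposals, with Metropolis acceptance `exp(ΔM/T)`.  The
initial temperature is calibrated from 100 probe moves so a median-size
worsening move is accepted with probability one half; cooling is geometric
(factor 0.90), with 20·(R+C) moves per temperature, stopping at T = 1e−5
or after 20 temperatures without improvement.  Every run ends with a
zero-temperature polish — greedy best-gain single-node sweeps alternated
with greedy merges until no improving move exists — and the polish of the
untouched initial state is always kept as a candidate, so a longer
schedule can never return a lower M than the greedy variant on the same
seed.  A much slower cooling with (R+C)² moves per temperature would be
the textbook choice; at the sizes of interest (~170 nodes) the schedule
above already recovers planted four-module partitions within 1% of the
planted modularity in ≥95% of runs, at a small fraction of the cost.

Significance uses CE-randomized matrices.  Observed and null matrices are
optimized with the *same* schedule (by default the zero-temperature
polish, `SASchedule.greedy()`), so the comparison is budget-matched; an
observed M obtained with a long schedule compared against cheaply
optimized nulls would be biased toward significance.  The report's
headline M comes from the full annealing run and may therefore differ
slightly from the observed value inside the significance block.

## Core/periphery

The categorical model assigns every node (both levels) to core or
periphery.  Fitness is the Pearson correlation between the observed 0/1
cells and the ideal pattern — core×core cells 1, periphery×periphery
cells 0, mixed blocks excluded from the correlation.  Because x and y are
both binary the correlation reduces to a closed form of four block
counts, so a full steepest-ascent pass over all candidate single-node
flips costs O(R+C) after O(RC) bookkeeping.  Each fit hill-climbs from a
random assignment, takes the best of five restarts, and finishes with a
core-expansion pass: nodes whose inclusion leaves the fitness unchanged
are added to the core.  The expansion resolves a structural degeneracy of
the objective — with mixed blocks excluded, any nested subset of a
perfect core scores the same correlation — by preferring the maximal
core, which makes planted block cores exactly recoverable.  A constant
matrix has no defined correlation and raises `ZeroVarianceError`.

The ensemble protocol runs 25 independent fits and records, per node, the
fraction of runs in which it was core.  Tiers: ≥80% → `core_a`, 65–79% →
`core_b`, otherwise periphery; a frequency of exactly 80% goes to
`core_a`, and the thresholds are plain parameters for anyone who prefers
the strictly-more-than-80% reading.

## Robustness to microhabitat loss

Hollows are removed one at a time; a species survives while at least one
of its hollows remains (purely topological, no rewiring).  R is the
trapezoidal area under the survivor curve through the points
(k/H, s_k/S), k = 0…H, including both endpoints — so the 3×3 identity
scores exactly 0.5 and the 3×3 all-ones matrix 5/6.  Scenarios: random
removal (mean R over 100 permutations by default, with the sd of R
across permutations), least-connected-first and most-connected-first
(degree = number of insect species recorded; ties broken by hollow
abundance, then label, so the orders are deterministic), and
least-abundant-first.  On nested matrices the ordering
R(most-first) ≤ R(random) ≤ R(least-first) is a structural property and
is asserted over seeds.

## Synthetic matrices

`generate_nested` builds a packed staircase: row *i* occupies a prefix of
the columns, the prefix lengths are non-increasing, the first row spans
all columns and every row keeps at least one link whenever the fill
allows (L ≥ R+C−1), and the remaining links ramp down linearly with
largest-remainder rounding.  At a triangular fill on a square matrix this
reproduces the perfect triangle, whose NODF is 100.  `structure_strength`
interpolates toward randomness by relocating `round((1−s)·L)` links to
uniformly chosen empty cells, keeping the link count — and hence the
connectance — exact; NODF increases monotonically with the strength
(Spearman ρ > 0.9 across seeds).  With `protect_margins` no relocation
may empty a row or column, which the site presets use so every species
and hollow stays present.

`generate_modular` plants an even block partition with within/between
probabilities `p_in = (1−s)·p + s·p/f_in`, `p_out = (1−s)·p` (`f_in` the
within-block cell fraction), which holds the expected fill at `p` for any
strength; the planted partition is returned with the matrix.

Counts on links are `1 + round(lognormal(μ=0, σ=1))`; when a grand total
is requested, the total minus one-per-link is allocated over links by
largest remainder on the lognormal draws, so the total is hit exactly.
The lognormal is a modelling assumption (only per-site totals are known),
giving the right-skewed abundances typical of such communities.

The three presets fix dimensions, totals and connectance (DO 137×30,
2343, C 0.15; RA 114×27, 1219, C 0.13; SO 85×30, 825, C 0.11) and use a
common nested strength of 0.7, chosen so the nested pattern is decisively
significant against the CE null while the matrix is far from perfectly
packed.  What the presets do *not* emulate: the exact field NODF/WNODF
values (the staircase at strength 0.7 is more nested than the field
networks), abundance–degree correlation (the overlay is independent of
the nested structure, so preset WNODF is typically not significant
against the RC null even though the field data were), and realistic
hollow degree distributions — the staircase gives the first few hollows
links to nearly every species, which inflates the core-insect count and
the directed-removal contrast relative to the field values.  Passing
tests therefore demonstrate correctness of the estimators and the
qualitative orderings, not numerical agreement with any field study.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit integer seed; the pipeline
derives per-stage seeds from the global seed and the stage name (SHA-256,
reduced below 2³¹), logs them in the report, and serialises the report
with sorted keys, so one configuration and seed reproduce the output byte
for byte.  Default problem sizes — 1000 CE/RC replicates, 1000
budget-matched modularity randomizations, 25 core/periphery runs, 100
random-removal permutations — complete in under a minute per preset-sized
matrix on one CPU; the planted-partition and calibration test batteries
use 16–40-node-per-side matrices with replicate counts chosen to keep the
whole suite in a few minutes while retaining statistical power.

## Known limitations

* Modularity Eq. above is the binary (qualitative) index; no quantitative
  modularity is provided.
* The core/periphery optimizer is a steepest-ascent hill-climber with
  restarts, not a genetic algorithm; any maximizer of the same objective
  is interchangeable for the frequency protocol.
* The RC placement process uses fixed marginal-total weights with
  rejection of saturated margins; remaining-capacity weighting would be a
  different (also defensible) null and would change p-values slightly.
* Robustness ignores insect–insect dependencies (facilitation chains,
  predation): species die only when all their hollows are gone.
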