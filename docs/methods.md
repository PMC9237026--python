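# Methods

This note records the models, conventions and numerical choices behind
`trophicstab`, and what the synthetic test conditions do and do not show
about real data.

## Food-web representation

A web is a set of nodes (species, trophospecies, detritus, and at most one
fishery and one discard node) and directed predator→prey links weighted by
diet proportion. The matrix view is **prey-rows × predator-columns**: the
column of predator *j* is its diet composition and sums to 1, so the
weight-randomization step ("shuffle diets keeping column sums fixed") is a
literal column operation. Binarizing the matrix recovers the topology.
Unweighted analyses materialize equal shares (1/k over k prey) so weighted
and unweighted code paths differ only in the matrix, never in the
algorithm.

Diet sums within 10⁻³ of 1 are renormalized on load (published diet tables
rarely sum exactly to 1); after normalization the tolerance is 10⁻⁶.
Cannibalistic self-links are legal and flagged; they are ignored when
deciding whether a node is basal.

## Trophic levels and derived metrics

`TL = 1` for basal nodes; consumers solve `(I − Qᵀ)·TL = 1` by a direct
dense solve (webs of interest have ≲ 500 nodes; the solution is checked to
a residual max-norm of 10⁻⁹). The system is singular exactly when a group
of consumers forms a strongly connected component whose diets never leak
toward a basal resource; the error names that component.

- **mTL** averages TL over all nodes (a consumers-only filter is
  available).
- **Unweighted omnivory** is the fraction of *all* nodes that are
  consumers whose prey TLs span more than ε. With fractional TLs, ε = 0
  marks nearly every consumer omnivorous, so the default ε = 1 demands a
  full trophic level between the extremes of a diet; 0.5 and 0 remain
  available. **Weighted omnivory** is the classical index: the
  diet-weighted variance of prey TLs, averaged over consumers (plus a
  thresholded companion, `weighted_omnivory_fraction`).
- **TL classes**: basal = no prey, top = prey but no predators,
  intermediate = both; reported as percentages of all nodes.

## Modularity

Directed Newman modularity with in/out strengths as the null expectation.
This form permits negative values for weighted diet webs (each consumer
column sums to 1, so strengths are very uneven), which is why it was
chosen over undirected or bipartite variants. The maximization is
simulated annealing: starting from singletons, 90% single-node moves, 5%
community merges, 5% random splits, Metropolis acceptance (ΔQ = 0 always
accepted), geometric cooling. The default schedule calibrates the initial
temperature so about half of 100 random moves would be accepted, cools by
0.995 with n² proposals per temperature, and stops after 50 temperatures
without improvement. A `FAST_SCHEDULE` (cooling 0.9, n²/4 proposals,
patience 8) is used inside null ensembles where the search runs hundreds
of times; on 80-node webs it loses ≲ 0.3% of the default schedule's Q at
~15× the speed. The best partition ever visited is returned, re-scored
exactly (incremental ΔQ accumulates round-off), and labeled by first
appearance in node order. Determinism is guaranteed given a seed.

## Quasi-sign-stability

The Jacobian sign pattern is fixed by topology: for each link, the prey's
effect on the predator is positive and the predator's on the prey
negative; magnitudes are independent Uniform(0, `max_magnitude`), and in
weighted mode both magnitudes of a link are multiplied by its diet
proportion. Every node receives a negative diagonal ~ Uniform(−1, 0):
without universal self-limitation essentially no large random web is ever
stable and the index carries no information (self-limitation restricted to
basal nodes remains available). Stability means every eigenvalue real part
< −10⁻¹⁰; the strict tolerance guards against numerically zero real parts
counting as stable. Cannibal self-links fold into the (already negative)
diagonal.

`max_magnitude` sets the index's operating point and should be chosen so
QSS is neither 0 nor 1 on the web under study. At the synthetic fixture's
scale (~80 nodes, ~400 links) the default Uniform(0,1) magnitudes give
QSS ≈ 0 (a May-type complexity bound dominates) while diet-weighted
magnitudes give ≈ 0.99; the scenario comparisons in the acceptance script
and the tendency test therefore use `max_magnitude = 0.5`, calibrated once
on a baseline web to put QSS mid-range. This is an instrument-sensitivity
choice, not a fit to any expected difference.

## Null models

Topology nulls use the curveball algorithm on predator columns: pick two
predators, pool the prey each holds exclusively, reshuffle the pool and
re-split it keeping each predator's count. Every trade preserves all row
and column sums, so each species keeps its number of prey and predators
and basal/consumer identities are invariant. The trade kernel is the
canonical symmetric, aperiodic one (uniformity over the fixed-marginal
ensemble is verified by exhaustive enumeration on a 4×4 case in the test
suite). For food webs the diagonal is frozen (`fix_diagonal`): trades
never invent cannibalism and never remove real cannibalism — without this,
roughly a third of randomized webs contained self-feeding loops that made
the TL system singular. Defaults: 5 trades per node per randomization;
topology first, then (in weighted mode) the predator's original multiset
of diet proportions is re-dealt uniformly over its new prey set, keeping
column sums exactly 1.

Randomized webs whose TL system is singular (new consumer loops with no
basal leakage) are redrawn and counted; on ~80-node niche webs this
affects ~7–10% of draws, so the abort threshold for "too many redraws" is
25% of the ensemble size.

Degree-preserving randomization of a loop-rich interval web lets consumers
feed on former top predators, creating strong trophic recycling: null mTL
medians on the synthetic webs sit far above the empirical value (≈ 11–14
vs ≈ 3.7). The scenario comparison is unaffected — both scenarios are
randomized identically and compared ensemble-to-ensemble — but null
medians should not be read as plausible web configurations.

## Scenario construction

`build_fishing_web` adds a fishery (consumer of the caught set, diet =
capture composition, no predators) and a discard node (basal, TL = 1).
Each discard consumer assigns a share (default 0.1) of its diet to the
discard and rescales its natural diet by (1 − share), so all diet sums
stay 1 and the link count grows by exactly |caught| + |discard consumers|.
The construction is exactly invertible (`strip_fishing_nodes`).

## Synthetic webs

The niche model draws a niche value n ~ U(0,1) per species, a feeding
range r = n·x with x ~ Beta(1, 1/(2C) − 1), and a range center ~
U(r/2, n); a species eats everything inside its interval. Two departures
from the textbook model, both aimed at emulating a speciose coastal shelf
web:

- **Few basal species.** The plain model at C ≈ 0.06 produces 15–18%
  basal species; resolved marine webs of this size have far fewer. With
  `basal_frac` (0.06 in the scenario generator) the lowest-niche species
  are the producers and every other species redraws an empty feeding
  interval until it has prey.
- **Honest connectance.** Replacing isolated and duplicate-role species
  (the classic repair rule) inflates realized links; draws are therefore
  rejection-sampled until the realized link count is within 10% of C·S²
  (mean realized connectance then tracks the target to a few percent).

Diet proportions are Dirichlet(α) over each consumer's prey (α = 1,
uniform simplex, by default; α < 1 stresses skewed diets; α → ∞ recovers
equal shares).

`sjg_like_scenario_pair` (the study-condition fixture) generates an
S = 80, C = 0.0625 web (≈ 400 links, 5 basal species) whose weighted
maximum TL falls in [4, 7] — loop-heavy draws can exceed TL 12, beyond
anything empirical, and are rejected. The fishery preys on the 22
highest-degree species with TL in [2, 4] (about a quarter of the web,
matching an intense trawl's bycatch footprint), with Dirichlet(1) capture
weights. The discard feeds the **highest-TL 15% of consumers**: the
scavenger/opportunist guild that gains access to discarded demersal fish
sits near the top of the web, and it is precisely this cross-level wiring
that raises omnivory in the fishing scenario. Wiring the discard to random
consumers instead produces no systematic stability contrast — the
omnivory-raising placement is the mechanism, not an incidental detail.

**What the fixture does not emulate:** empirical degree distributions and
diet-interval violations, trophospecies aggregation, detritus recycling,
literature-derived diet uncertainty, and absolute metric values of any
real web. Passing tests on these webs demonstrate that the pipeline's
machinery (solves, searches, null models, statistics) is correct and that
the scenario contrast has the expected direction under the stated
conditions — not that any particular real system is unstable.

## Scenario comparison statistics

- Two-sample Anderson–Darling (midrank ties), p from the published
  approximation, floored at 0.001 and capped at 0.25 — values at the
  bounds mean "beyond the approximation's range", and are reported as the
  bound rather than 0.
- Effect size = (median(x) − median(y)) / pooled sd, with pooled sd the
  root-mean-square of the two sample standard deviations (ensembles are
  equal-sized by construction; a variance-weighted pooling would coincide).
- QSS comparison: Pearson chi-squared without continuity correction on the
  2×2 stable/unstable table; Fisher's exact test replaces it when an
  expected count drops below 5.
- IQR trimming (drop outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], type-7
  quartiles) exists for display only and never feeds statistics.

## Problem sizes and determinism

The acceptance script uses 200 null randomizations per web for mTL and
omnivory, 50 for modularity (the annealing search dominates cost), 2000
Jacobian draws per web for the QSS comparison, and 10 generator seeds ×
400 draws for the paired tendency — sizes at which Monte-Carlo error is
well below the effects measured while a full run stays within a few
minutes on one CPU. Every stage consumes a sub-seed derived from the
single `--seed`; the pipeline's `run()` expands its global seed into
per-stage streams via `numpy.random.SeedSequence([seed, stage, index])`,
so any stage reproduces in isolation and identical configs give
bit-identical reports.

## Known limitations

- The annealing schedule is a heuristic; on webs much larger than ~200
  nodes the default n² proposals per temperature becomes expensive and
  `FAST_SCHEDULE` (or a custom schedule) should be used deliberately.
- QSS compares sign-structure ensembles, not parameterized dynamics; its
  absolute value depends on the magnitude distribution chosen and only
  contrasts under a fixed spec are meaningful.
- The curveball null preserves degree sequences but nothing else; webs
  whose structure is strongly interval-like will be randomized into
  configurations (e.g. strong trophic recycling) no empirical web visits.
- The weighted-omnivory and weighted-QSS formulations are the standard
  diet-proportion-based analogues; other weightings (energy flux, biomass)
  are out of scope.
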