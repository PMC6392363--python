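# Methods

## Model and assumptions

All branch lengths are coalescent units: two lineages entering a branch
of length `t` fail to coalesce along it with probability `e^(−t)`.
Population sizes are not separate parameters; they are absorbed into the
branch lengths, which is all the quartet-CF machinery depends on.

**Quartet CFs under the MSC.** One lineage is sampled per species. For a
4-taxon set whose induced unrooted species tree has internal branch
length `t` (the sum of internal-edge lengths separating the two pairs),
the gene-tree resolution matching the species tree has probability
`1 − (2/3)e^(−t)` and each alternative `(1/3)e^(−t)`. The implementation
finds the internal path of a quartet as the set of edges whose descendant
leaf set contains exactly two of the four taxa; an induced polytomy falls
back to `t = 0`, i.e. the uniform 1/3 CFs of the star tree.

**Networks.** A rooted level-1 network (no two reticulation cycles share
an edge) with `k` hybrid nodes displays `2^k` trees, each keeping one
parent edge per hybrid node, weighted by the product of the chosen
inheritance probabilities. The expected CF of a quartet is the weighted
mixture of the tree formula over displayed trees. This is exact when
every hybrid node relevant to a quartet subtends exactly one sampled leaf
of it (the case for all bundled fixtures, where hybrids sit directly
above single leaves); otherwise lineages could coalesce before reaching
the hybrid node and choose a parent jointly, the mixture is an
approximation, and an `ApproximationWarning` is raised.

**ILS null test.** Given per-locus topology counts `(c1, c2, c3)`,
`n = Σc`, the ML ILS null is `p_major = max(c)/n`,
`p_minor = (n − max(c))/(2n)`. The statistic is the difference between
the two minor-category counts. The wording "the two minor trees" is
ambiguous about whether the major tree is fixed in advance or
re-identified per dataset; the default re-identifies it (sort the counts,
take middle minus smallest), which on counts `(4,4,0)` gives an exact
tail probability of 0.03525, while fixing the major category a priori
gives 0.07681. Both conventions are implemented (`fixed_major=True`) and
both values are pinned by a regression test so the choice cannot drift
silently. The exact p-value enumerates all `C(n+2, 2)` compositions with
rational arithmetic (`fractions.Fraction`), converting to float only at
the end; the Monte-Carlo p-value draws multinomial replicates with a
seeded generator and reports the binomial standard error.

**Pseudolikelihood and AIC.** Networks are scored against an observed CF
table by the weighted multinomial cross-entropy

    pseudolik = Σ_q n_eff(q) Σ_r cf_obs(q,r) · ln cf_model(q,r)

with `0·ln 0 ≡ 0` and model CFs floored at 1e−12, and ranked by
`AIC = −2·pseudolik + 2k` (`k` = number of hybrid edges). This is this
package's own composite-likelihood analog: its absolute values are not
comparable with other tools' scoring conventions — only differences
between networks evaluated on the same table are meaningful. By Gibbs'
inequality the score is maximized when model equals observation, which
the tests exploit as an optimality oracle. Goodness of fit is
`R² = 1 − SS_res/SS_tot` of observed vs fitted CFs measured against the
identity line (squared Pearson correlation available via
`method="pearson"`); it is undefined (error) when the observed CFs are
constant.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `gamma` | 0.5 (scenario), 0.3 (backbone) | minor-edge inheritance probability |
| `t_max` | 20 coalescent units | optimizer bound; CFs are within 1e−8 of their asymptote |
| `n_starts` | 10 (fit), 4 (search) | seeded multi-start count for L-BFGS-B |
| `ftol` | 1e−8 | relative convergence tolerance of the optimizer |
| `n_boot` | caller-set | bootstrap replicates; percentile 95% intervals |
| consensus `threshold` | (0.5, 1] | bipartition frequency cut; ties at the threshold are **included** (tools differ; stated here deliberately) |

Optimization fixes the topology and frees one γ per hybrid node plus the
lengths of every edge lying on at least one quartet internal path. Edges
no quartet is sensitive to are not identifiable from CFs: internal ones
are flagged in `NetworkFit.non_identifiable` and pinned to `t_max`,
pendant ones are left untouched. Bounds are `γ ∈ [0,1]`,
`t ∈ [0, t_max]`; starts are the current values plus uniform draws
(`t ~ U(0.01, 5)`, `γ ~ U(0.05, 0.95)`) from a seeded generator, so fits
are deterministic given the seed.

The greedy search enumerates, at each level, every ordered pair of
non-adjacent edges of the current best network as a (source, target)
minor-edge attachment, skips attachments that would break acyclicity or
level-1-ness, optimizes each candidate, and keeps the best
pseudolikelihood (ties resolved by enumeration order, lexicographic in
edge ids). It refuses more than 10 taxa: candidate counts and
optimization cost grow too fast beyond that, and dedicated search tools
are the right instrument at that scale.

## Synthetic data

The simulator runs the standard MSC on a tree or level-1 network: within
each branch, pairs of lineages coalesce at rate 1 per pair; at hybrid
nodes lineages route to the major parent with probability γ, either
independently per lineage (`"independent"`) or with the whole locus
committed to one displayed tree (`"locus"`). The two rules coincide when
each hybrid subtends one sampled lineage, which a test verifies
distributionally via CF agreement.

The bundled `aulophallus` scenario emulates the data structure this kind
of analysis assumes: 8 unlinked loci, one sample per species, a 4-taxon
set in which `H` is a candidate hybrid between `A` and `B` with outgroup
`O`. Its defaults — γ = 0.5 and internal branches of 5 coalescent units —
produce the signature reticulation pattern in which the two `H`-pairings
each occur at about half the loci and the third resolution is essentially
absent (per-displayed-tree minor probability `(1/3)e^(−5)` ≈ 0.2%). The
6-taxon `backbone` fixtures (a species tree and a one-reticulation
network with minor γ = 0.3 and internal branches of 0.5–1 units) provide
an informative-CF regime for optimization and search tests. What the
generator does **not** emulate: gene-tree estimation error (gene trees
are observed exactly), linkage, missing taxa, or sequence-level noise —
so passing tests demonstrate correctness of the coalescent/network
arithmetic, not robustness to real-data estimation error. Posterior-tree
weighting is a plain per-locus sample-frequency average, not a Bayesian
concordance analysis with a Dirichlet prior over tree distributions;
with few loci the two can differ.

## Numerical choices

- Exact ILS p-values use rational arithmetic; everything else is float64.
- Model CFs are floored at 1e−12 inside logs; CF-table rows must sum to
  one within 1e−9; displayed-tree weights sum to one within 1e−12.
- γ pairs must sum to one within 1e−6 at parse time; a missing γ pair
  defaults to 0.5/0.5 with a warning.
- Quartet resolutions are indexed in canonical sorted-label order
  (`12|34`, `13|24`, `14|23`), and CSV tables use the TICR column order
  `taxon1..taxon4, CF12_34, CF13_24, CF14_23, ngenes`.
- Bootstrap resamples loci with replacement (and one tree per posterior
  sample per replicate, switchable), since a posterior-only bootstrap is
  uninformative at very few loci; with a single locus the intervals are
  degenerate and a warning is raised.
- Unresolved induced quartets are excluded from `n_resolved` by default;
  `unresolved="split"` spreads them 1/3 each.
- Ties at the consensus threshold are included (`≥`).
- The geographic filter is deliberately binary: a hybrid edge is flagged
  when the region-label unions of its donor and recipient clades are
  disjoint. Distances between regions are not modeled.

## Problem sizes

The test suite and the acceptance script use 4–6-taxon fixtures,
10⁴ loci for simulator/CF agreement and model selection, 10⁵–10⁶
multinomial replicates for Monte-Carlo/exact agreement, and ten seeded
replicates for the model-selection experiment; these sizes give
Monte-Carlo standard errors a decade below the effects being checked
while keeping a full run in the low minutes on one CPU.

## Known limitations

- Greedy forward selection over many candidate attachments maximizes the
  pseudolikelihood gain over ~10² correlated candidates, so the selected
  extra edge's improvement is biased upward relative to the χ²-style
  "ΔAIC ≤ 2" intuition for a single pre-specified extra parameter. On
  data simulated from a one-reticulation network, the search reliably
  prefers k = 1 over k = 0, but in roughly a quarter to a third of
  replicates it also "prefers" a spurious second edge by more than 2 AIC
  units. This is a property of the search design (shared with composite-
  likelihood network searches generally), not of the scoring arithmetic;
  the per-level fits themselves sit at their global optima in these
  replicates.
- Pseudolikelihood treats quartets as independent although they share
  loci; AIC differences are therefore heuristic rankings, not calibrated
  tests.
- Only level-1 networks are supported; the expected-CF mixture is exact
  only under the single-sampled-leaf condition described above.
- γ and branch lengths can trade off along nearly flat likelihood ridges
  when fitted to noisy CF tables at moderate locus counts; recovery from
  exact (analytic) CFs is sharp, recovery from 10⁴ simulated loci can
  move γ by ~0.1.
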