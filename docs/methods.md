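# Methods

## Problem setting

Given m individuals with a discrete target Z (here: case/control disease
status) and p discrete predictors (here: SNP genotypes with three states),
find *sets* of predictors that jointly predict Z — including sets whose
members have little or no marginal effect, the regime in which single-locus
association scans and marginal-greedy model search fail.

## Information measures

All quantities are in bits (base-2 logarithms), with the limit convention
0·log2(0) = 0 and zero-probability conditioning instantiations skipped.

- Entropy H(Z) = −Σ P(z) log2 P(z).
- Conditional entropy H(Z|A) = Σ_j H(Z | a_j) P(a_j) over instantiations
  of the set A.
- Information gain IG(Z; A) = H(Z) − H(Z|A); IG(Z; ∅) = 0.
- Conditional information gain IG(Z; X | Y) = Σ_i IG(Z; X | y_i) P(y_i).
- Interaction strength IS(Z; X, A) = IG(Z; {X}∪A) − IG(Z; X) − IG(Z; A);
  the set form is IS(Z; A) = IG(Z; A) − Σ_{X∈A} IG(Z; X).

IG satisfies non-negativity (zero exactly under independence), symmetry,
the chain rule IG(Z;{X,Y}) = IG(Z;X|Y) + IG(Z;Y), and monotonicity in the
conditioning set. IS is sign-indefinite: on a Markov chain X→Y→Z it equals
−IG(Z;X) ≤ 0; for marginally independent causes (X→Z←Y) it is ≥ 0. Both
sign regimes are shipped as constructible population fixtures and verified
by the test suite.

Empirical variants plug in maximum-likelihood (relative-frequency)
probabilities with **no smoothing** — smoothing would shift IG and hence
the MDL score away from their plug-in definitions. Small negative results
of magnitude below 1e-12 (floating-point round-off of quantities that are
mathematically non-negative) are clamped to exactly 0 before any threshold
comparison; genuinely negative interaction strengths pass through.

## Model scoring

Only parent sets of the single distinguished target are ever scored; no
general DAG structure learning is performed. For a parent set with q joint
instantiations and target cardinality r, with counts s_jk:

- **Bayesian (Dirichlet) log score**: the log of the standard double
  product of Gamma-ratio terms with hyperparameter grid a_jk, computed
  via log-Gamma throughout (the raw products overflow at realistic m).
- **BDeu**: the same with a_jk = α/(rq), a prior uniform distribution per
  node governed by the prior equivalent sample size α. Default α = 4; the
  α grid {1, 4, 9, 54, 128} is a configuration option, not separate code.
- **MDL**: d·log2(m)/2 − m·IG(Z; PA) with d = (r−1)·q. The parameter
  count d is the number of free parameters of the target's conditional
  distributions; smaller is better.

Searches compare models on a unified higher-is-better *fitness* (BDeu log
score, or negated MDL). The identity
IS(Z;X,A) = (mdl(X) + mdl(A) − mdl(X∪A))/m + C with
C = −(d_X + d_A − d_{X∪A})·log2(m)/(2m) ties the two views together and is
verified to 1e-9 on random datasets.

Parent-instantiation indices are mixed-radix over the dataset column
order, last predictor fastest. Every score depends on the counts only up
to a relabelling of j, so the incremental codes used during beam growth
are score-equivalent to the canonical order; the convention is fixed so
runs are bit-for-bit reproducible.

Tie-breaking everywhere: larger fitness first, then smaller predictor-set
size, then lexicographic identifiers. The MBS backward phase deletes the
lexicographically smallest identifier among tied improvements.

## Search algorithms

**MBS-IGain** (primary): one beam per prefiltered predictor. Each step
selects the candidate X (from the full prefiltered pool minus the beam)
maximizing the empirical IS(Z; G, X) and stops when

1. IS(Z;G,X) / (IG(Z;G) + IG(Z;X)) ≤ T — the interaction is small
   relative to the marginal gains. A zero denominator stops the beam (no
   information implies no interaction evidence).
2. fitness(G ∪ {X}) < fitness(G) — strict comparison, so growth never
   decreases fitness; or
3. M predictors have been added (models contain at most M+1 predictors).

**MBS**: greedy forward additions by largest fitness improvement (capped
at M) while an addition strictly improves, then greedy backward deletions
while a deletion improves, never below one predictor.

**REGAL**: MBS run `regal_iterations` times (default 5), after each
iteration removing the top model's predictors from the candidate pool so
weaker interactions masked by stronger ones can surface; stops early with
a logged note if the pool empties.

All outputs are deduplicated by predictor set (best fitness kept) and
sorted descending. Work is bounded by n·M·n interaction-strength (or
score) evaluations for a pool of size n.

Defaults: T = 0.1, M = 4, MDL criterion, prefilter disabled (a beam from
every predictor). Prefiltering by top-scoring 1-predictor models is the
intended scaling device for large panels, but note that it ranks by
*marginal* score and can therefore exclude members of pure interactions —
on the benchmark-style data the pure pair is only found when its members
seed or remain in the pool.

## Evaluation criteria

- **Power1(K)**: predictors are ranked by the first (highest-fitness)
  model in which they appear, members of one model flattened in
  lexicographic order; the score is the average fraction of causative
  predictors among the first K, normalized by R·M_true over R datasets.
- **Power2(K, C)**: per dataset, the maximum Jaccard index between the
  truth group C and any of the first K models, averaged with the same
  1/(R·M_true) normalization. As printed this cannot reach 1 even on
  perfect recovery (the per-dataset maximum is 1, divided by the total
  causative count M_true); the deliberate `natural=True` flag switches to
  the 1/R average. The printed form is the default; the discrepancy is
  noted, not resolved.
- **ROC**: at cutoff m into the predictor ranking, tpr = x/M_true and
  fpr = y/(total − M_true) with x causative and y non-causative among
  the top m. The default cutoff grid is every integer up to the universe
  size (a logarithmic grid above 10⁴); methods that rank only part of
  the universe can have the remainder appended in identifier order.
- **is_gain_ratio**: the rounded ratio IS/IG used to report how much a
  discovered model adds over its strongest single locus.

## Simulator

Genotypes are drawn per predictor under Hardy-Weinberg proportions
((1−p)², 2p(1−p), p²); noise MAFs are uniform in (0.05, 0.5), causative
MAFs default to 0.25. Disease risk combines the planted groups'
penetrances by Noisy-OR — P(disease) = 1 − Π_k (1 − f_k) — so each group
is an independent potential cause. Individuals are banked by rejection
until the case and control quotas are met exactly (retrospective
case-control sampling; draw cap 10⁷, with an error naming the analytic
prevalence if quotas are unreachable or the prevalence is degenerate).
Everything is reproducible from the specification seed.

Penetrance patterns shipped:

- `pair_pure_interaction_table(p1, p2)`: risk p1 when the first member is
  heterozygous and the second is not, p2 in the mirrored case, else 0 — a
  pure two-locus interaction whose members are marginally nearly silent.
- `threshold_interaction_table(g, k, p)`: risk p when at least k of g
  members are heterozygous — members carry modest marginal signal and
  pairs already show interaction strength, so the group is greedily
  discoverable (the typical multi-locus disease model).
- `parity_interaction_table(g, p)`: risk p when an odd number of members
  is heterozygous — a pure g-way XOR with *no* lower-order signal at all,
  undiscoverable by greedy pairwise growth by construction; provided as
  the stress-test extreme.

The default benchmark-style specification is 1000 predictors, 1000 cases
+ 1000 controls, and five disjoint groups of sizes {5, 3, 3, 2, 2} (15
causative SNPs): a strong pure pair with penetrances 0.5/0.7, a weak pure
pair at 0.07, two 3-locus threshold groups (p = 0.7 and 0.5, k = 2) and a
5-locus threshold group (p = 0.5, k = 4). The exact penetrance models of
the original benchmark generator are not public; these tables echo its
printed anchors and reproduce its qualitative behaviour (the strong pair
is found first and exactly; the 3-locus groups are found early; the weak
pair and the 5-locus group are hard for every method). Quantitative power
curves of the original benchmark are *not* reproduced. The implied
population prevalence of the default specification is ≈ 0.47 — high for a
disease model, but immaterial under retrospective fixed-quota sampling.
Linkage disequilibrium between causal and observed loci, quantitative
traits and covariates are not modelled, so passing tests say nothing
about LD-proxied or confounded real data.

## Numerical and design choices

- Log-space throughout for Bayesian scores; scipy's `gammaln` is the only
  special-function dependency.
- Sample sizes in tests and the reproduction script are scaled down
  (50-predictor, 800-individual replicates; 20 replicates) — chosen as
  the smallest sizes at which the planted-pair regime is comfortably
  identifiable.
- The confound analysis (a pure pair plus a strong-marginal additive
  nuisance SNP combined by Noisy-OR) is run with the BDeu score (α = 4)
  and T = 0.2: absorption of marginal predictors by score-greedy search
  is most visible under BDeu's smaller structure penalty, and under
  Noisy-OR the nuisance SNP's IS with the pair grows with its own
  marginal gain, so the ratio threshold must sit above the resulting
  IS ratio band (≈ 0.09–0.18) while remaining inside the method's useful
  range; with MDL's larger penalty neither method absorbs the nuisance
  and the contrast vanishes.
- An empirical-IS variant of beam growth using BDeu score differences in
  place of the information-theoretic IS is deliberately not provided.

## Known limitations

- Greedy growth cannot discover pure interactions whose proper subsets
  carry no signal (the parity pattern); this is inherent to any pairwise
  beam strategy, not an implementation limit.
- The prefilter ranks by marginal score and can exclude pure-interaction
  members; at full panel scale a beam from every predictor is O(n²·m)
  and is the cost to pay for finding them.
- Empirical IS carries a positive finite-sample bias that grows with the
  instantiation count of the candidate set; the score-decrease stop is
  the main guard against chance growth.
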