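# mbsigain

Discovery of interacting predictors in discrete case-control data, built
for the epistasis setting: SNP genotypes (coded 0/1/2 copies of the minor
allele) where two or more loci jointly affect disease status while each
locus alone shows little marginal effect. Standard single-locus scans and
score-greedy model search both fail in this regime — the first because
marginal signals are tiny, the second because it absorbs strong-marginal
loci into "interactions" that are not interactions at all.

The package implements **MBS-IGain** — multiple beam search in which beam
growth is driven by *interaction strength* and stopping by Bayesian-network
model scoring — alongside its comparators **MBS** (score-greedy multiple
beam search with forward and backward phases) and **REGAL** (iterated MBS
with top-model deletion), the **Power1 / Power2 / ROC** evaluation criteria
for benchmarking against planted truth, and a **Noisy-OR case-control
simulator** so the whole pipeline runs end-to-end without external data.

## The statistics at the core

For a discrete target *Z* and predictor set *A*, the information gain is

    IG(Z; A) = H(Z) − H(Z | A)        (bits, base-2 logs)

and the interaction strength of a predictor *X* with a set *A* is

    IS(Z; X, A) = IG(Z; {X} ∪ A) − IG(Z; X) − IG(Z; A),

the gain from considering the predictors jointly beyond what they provide
separately. IS can be negative (a Markov chain X→Y→Z gives
IS = −IG(Z;X) ≤ 0) and is non-negative for marginally independent causes.

Candidate parent sets of *Z* are scored either by the **BDeu** log marginal
likelihood with prior equivalent sample size α (hyperparameters α/(rq)),
or by the **MDL** description length

    score_MDL(Z; PA) = d·log2(m)/2 − m·IG(Z; PA),   d = (r − 1)·q,

where m is the sample size, r the target cardinality and q the number of
parent instantiations (smaller MDL is better; both criteria are exposed
through a single higher-is-better fitness).

MBS-IGain starts one beam per (optionally prefiltered) predictor. On each
beam with current set *G* it finds the candidate *X* maximizing IS(Z; G, X)
and stops when IS(Z;G,X) / (IG(Z;G) + IG(Z;X)) ≤ T (the interaction is
small relative to the marginal gains), when adding *X* would lower the
model score, or after M additions. Defaults: T = 0.1, M = 4, MDL score.

## Worked example

```python
import mbsigain as mg

pair = mg.InteractionGroup(
    indices=(10, 11), mafs=(0.25, 0.25),
    penetrance=mg.pair_pure_interaction_table(0.5, 0.7),
)
spec = mg.SimulationSpec(
    n_predictors=50, n_cases=400, n_controls=400, groups=(pair,), seed=11,
)
dataset, truth = mg.generate_dataset(spec)
models = mg.mbs_igain(dataset, mg.SearchParams())
print("planted interaction:", sorted(next(iter(truth.groups))))
for m in models[:3]:
    print(f"{sorted(m.predictor_set)}  fitness={m.fitness:.1f}  "
          f"IS={m.interaction_strength:.3f} bits")
print("Power1(K=2):", mg.power1([models], truth, 2))
```

prints

```
planted interaction: ['S11', 'S12']
['S11', 'S12']  fitness=378.2  IS=0.449 bits
['S37']  fitness=-6.5  IS=0.000 bits
['S32']  fitness=-8.3  IS=0.000 bits
Power1(K=2): 1.0
```

The planted pure pair — penetrance 0.5/0.7 only when exactly one member is
heterozygous, so either locus alone is nearly silent — is returned as the
top-ranked model, exactly, with an interaction strength of 0.45 bits, while
the best noise models are singletons with IS = 0. Power1(K) is the fraction
of causative predictors among the first K in the flattened model ranking,
so 1.0 at K = 2 means both members were ranked first.

The same pipeline is available from the shell:

```
mbsigain simulate --seed 1 --out-dir sim      # benchmark-style dataset
mbsigain search --data sim/genotypes.tsv --method mbs-igain --out-dir run
mbsigain evaluate --models run/models.json --truth sim/truth.json \
    --total-predictors 1000 --out-dir eval
mbsigain bench --replicates 5 --seed 1 --out-dir bench   # all of the above
```

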