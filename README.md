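# cocktailnet

Network analysis of drug combinations over genetic interaction networks.

Effective drug combinations ("cocktails") tend to be composed of drugs whose
target proteins sit close together in a genetic interaction network, and
whose targeted pathways are functionally related. `cocktailnet` implements
the full analysis that makes those two statements quantitative and testable,
for systems biologists studying combination therapy:

1. **Effect radius.** The distance between two drugs *i* and *j* is
   `dis(i, j) = min over target pairs (t_i, t_j) of d(t_i, t_j)`, where `d`
   is the unweighted shortest-path hop distance in the genetic interaction
   network. The effect radius of a combination with member-pair set *D* is

   ```
   R = Σ_{(i,j) ∈ D, i≠j} dis(i, j) / |D|
   ```

   i.e. the mean drug–drug distance over all C(k,2) unordered member pairs,
   restricted to pairs with a defined (reachable) distance.

2. **Pathway-pair classification.** Each drug is associated with the
   pathways containing its targets; every pathway pair targeted by two
   combination partners is classified as **identical** (same pathway),
   **cross-talking** (≥1 shared gene), **interacting** (disjoint gene sets
   bridged by ≥1 genetic-interaction edge) or **parallel** (neither), with
   precedence in that order. Per-combination proportions of the four
   relations form its pathway profile.

3. **Degree-preserving null model.** Random combinations are generated by
   double-edge-swap shuffles of the drug cocktail network (drugs as nodes,
   edges between co-combined drugs) that preserve every node's degree; each
   shuffled edge becomes one random pairwise combination.

4. **Rank-sum comparison.** Real-combination radii and pathway proportions
   are compared with the pooled null ensemble by the Wilcoxon rank-sum test
   (exact enumeration for small tie-free samples, normal approximation with
   midranks, tie and continuity corrections otherwise).

Ingestion applies the strict curation filters: genetic interactions are
kept only at p-value **strictly below** 1e-7, and combinations containing a
drug without target or ATC annotation are discarded.

A synthetic-data generator produces complete input bundles (interaction
network, pathway gene sets in GMT, drug→target and drug→ATC tables, and a
combination list) with *planted* short-radius and related-pathway structure,
so the whole pipeline is testable without access to proprietary databases.

## Worked example

Generate the standard benchmark bundle and run the pipeline:

```sh
cocktailnet generate --outdir demo/bundle --seed 42
cocktailnet run \
  --interactions demo/bundle/interactions.tsv \
  --targets demo/bundle/targets.tsv \
  --atc demo/bundle/atc.tsv \
  --combinations demo/bundle/combinations.tsv \
  --pathways demo/bundle/pathways.gmt \
  --outdir demo/out --replicates 100 --seed 1
```

which prints (abridged):

```
Ingestion
  combinations read:      100
  combinations retained:  85
  combinations discarded: 15

Effect radius (drug-drug shortest-path distance over the genetic interaction network)
  R <= 3: 76 combinations (89.4%)
  R >  3: 9 combinations (10.6%)

Pathway-pair relations
  interacting-proportion > 0.4: 43 combinations

Rank-sum comparisons vs 100-replicate degree-preserving null (two_sided, pooled nulls)
  effect_radius: p = 1.57e-29 (... rank-biserial = -0.697)
  proportion_cross_talking: p = 0.0923 (... rank-biserial = -0.106)
  proportion_interacting: p = 0.000121 (... rank-biserial = +0.243)
```

Reading this: 15 of the 100 generated combinations touched a drug stripped
of targets or ATC codes and were discarded by the annotation filter. The
planted structure (80% of true combinations seeded within one hop, 80%
seeded at edge-bridged pathway pairs) is recovered — real combinations have
far shorter radii than the degree-matched random combinations (negative
rank-biserial: real radii rank lower) and significantly higher
interacting-pathway proportions. 43 combinations target interacting
pathways at proportion strictly above 0.4.

The same analysis is available as a library:

```python
import cocktailnet as ck

net     = ck.read_genetic_interactions("demo/bundle/interactions.tsv")  # p < 1e-7
drugs   = ck.read_drugs("demo/bundle/targets.tsv", "demo/bundle/atc.tsv")
combos  = ck.filter_combinations(ck.read_combinations("demo/bundle/combinations.tsv"), drugs)
index   = ck.DistanceIndex(net)
radii   = [ck.effect_radius(index, c, drugs) for c in combos]
small, large = ck.stratify_by_radius(radii, 3.0)   # boundary R = 3 inclusive
```

`cocktailnet generate --toy --outdir toy/` writes a 12-gene hand-computed
fixture whose every radius, classification and proportion is recorded in
its `manifest.json`.

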