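# mycoweb

Metaweb-to-local-network analysis of soil fungal (or any microbial)
communities from OTU count tables.

## The problem

Amplicon surveys of soil fungi describe *who is there*, but community
ecology increasingly asks *how the community is organised*: is it a
densely interconnected, mixed assemblage, or a set of niche-specialised
modules held apart by competitive exclusion?  `mycoweb` answers this at
the level of individual samples by a two-step construction:

1. **Metaweb inference.**  Across all samples of a stratum (e.g. a
   country), every OTU pair is tested with the exact probabilistic
   co-occurrence model: for species observed in `n1` and `n2` of `N`
   sites, the number of shared sites `J` under independent placement
   follows the hypergeometric law

   `P(J = j) = C(n1, j) C(N − n1, n2 − j) / C(N, n2)`.

   Pairs with `P(J ≥ j_obs) < 0.05` co-occur (positive edge), pairs with
   `P(J ≤ j_obs) < 0.05` co-exclude (negative edge).  The test is
   analytically exact, correlation-free and conservative; it requires
   rarefied presence/absence data so that detectability is equal across
   samples.  The union of significant pairs is the **metaweb**.

2. **Local network projection.**  For each sample, the metaweb's positive
   and negative edge sets are restricted to the species present in that
   sample.  Community-level properties are computed per sample and sign:
   connected components, modularity `Q` (walktrap partition), clustering
   coefficient (average transitivity), average path length, and the
   co-occurrence / co-exclusion proportions — edges of each sign over all
   `C(S, 2)` species pairs of the sample.

Around this core, the package provides randomisation null models
(z-scores of each property against equal-richness random species draws
from the metaweb), the community-ecology primitives used to validate the
inputs (rarefaction, prevalence filtering, Shannon H′, Bray–Curtis,
nMDS, ANOSIM, Mantel, betadisper), and the downstream statistical layer
(Spearman relationship screens, envfit, variation partitioning with
forward selection, linear mixed models with a regional random effect,
two-way ANOVA, and a binomial GLM for plant-pathogen presence).

A fully ground-truthed synthetic metacommunity generator
(`mycoweb.synthetic_data`) plants guild structure, temperature niches,
and two management-dependent assembly regimes — *cooperative*
(biodynamic-like: mixed, densely associated communities) and
*partitioned* (conventional-like: guild-dominated, exclusion-structured
communities) — so every stage of the pipeline can be tested against a
known answer.

## Worked example

```python
import mycoweb as mw

matrix, metadata, truth = mw.generate_metacommunity(mw.standard_config(seed=1))
print(f"generated {matrix.n_samples} samples x {matrix.n_otus} OTUs")

rare = mw.rarefy(matrix, depth=20_000, seed=1)
filt = mw.prevalence_filter(rare, min_prevalence=0.02)
presence = mw.to_presence(filt)
print(f"after rarefaction + 2% prevalence filter: "
      f"{filt.n_samples} samples x {filt.n_otus} OTUs")

assoc = mw.all_pair_associations(presence, alpha=0.05)
web = mw.build_metaweb(assoc, filt.otu_ids, stratum="ES")
print(f"metaweb: {len(web.positive_edges)} co-occurrence edges, "
      f"{len(web.negative_edges)} co-exclusion edges, "
      f"{web.modules.n_modules} modules (Q = {web.modules.Q:.3f})")

profiles = mw.profile_all(web, presence)
row = profiles.iloc[0]
print(f"sample {row['sample_id']}: S = {row['richness_S']}, "
      f"modularity(+) = {row['modularity_pos']:.3f}, "
      f"clustering(+) = {row['clustering_pos']:.3f}, "
      f"coexclusion proportion = {row['coexclusion_proportion']:.5f}")
```

prints:

```
generated 120 samples x 600 OTUs
after rarefaction + 2% prevalence filter: 120 samples x 599 OTUs
metaweb: 23795 co-occurrence edges, 2615 co-exclusion edges, 4 modules (Q = 0.467)
sample ES_000: S = 96, modularity(+) = 0.315, clustering(+) = 0.541, coexclusion proportion = 0.00088
```

The metaweb's four modules recover the four planted thermal guilds; the
first sample's local network is moderately modular with about 0.09 % of
its species pairs in significant co-exclusion.  `profiles` is a tidy
DataFrame (one row per sample, columns suffixed `_pos`/`_neg`) that joins
directly onto the metadata for the statistical layer.

The same pipeline is available from the shell:

```sh
mycoweb simulate --out data --seed 1 --preset standard
mycoweb run --table data/otu_table.tsv --metadata data/metadata.tsv \
            --out results --seed 1
```

which writes per-stratum TSV artifacts (filtered table, association
table, metaweb edges and modules, local profiles, null-model z-scores)
plus a manifest making the run bit-identical on re-execution.

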