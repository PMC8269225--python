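# Methods

This note documents the models, defaults and design decisions behind
`mycoweb`, in the order data flows through the pipeline.

## Input preparation

**Rarefaction** (`rarefy`, default depth 20,000 reads) draws a single
multivariate-hypergeometric subsample per sample (without replacement),
dropping samples below the target depth.  A single draw — rather than an
average over many — keeps counts integral and the presence/absence layer
honest; the depth default reflects the detectability floor needed by the
exact co-occurrence test, which assumes equal detection effort per site.

**Prevalence filtering** (`prevalence_filter`, default 2 %, boundary
inclusive) is applied per stratum after rarefaction, because each
stratum's metaweb is inferred independently and a species that is rare
continent-wide may be common regionally.  Filtering is idempotent.  That
the filtered matrix still represents full community structure is checked
with a Mantel test between Bray–Curtis matrices of the filtered and
unfiltered data (the benchmark gives r > 0.99).

**Diversity** is computed on the rarefied, *unfiltered* matrix (Shannon
H′ in nats); association inference uses the rarefied, filtered,
binarised matrix.  The two layers answer different questions and the
filter would bias alpha diversity downward.

## The exact co-occurrence model

For a pair of species present in `n1` and `n2` of `N` sites, the shared
site count under independent placement is hypergeometric.
`cooccurrence_pmf` evaluates it through log-gamma binomial coefficients
(stable for N in the tens of thousands); `all_pair_associations` walks
the support of all `C(S,2)` pairs simultaneously with the hypergeometric
ratio recurrence accumulated in log space, so a 600-OTU stratum
(~180,000 pairs) takes seconds.  Design choices:

* **Inclusive tails.** `P(J ≤ j)` and `P(J ≥ j)` both include the
  observed count, the convention of the standard implementations of this
  model; consequently `p_lt + p_gt = 1 + pmf(j)` and a pair can never be
  significant in both directions at any alpha < 0.5.
* **No multiplicity correction by default.** The pipeline thresholds raw
  per-pair tail probabilities at 0.05, treating the test as a
  conservative screen; a Benjamini–Hochberg variant (`bh_adjust`) exists
  but is off.
* **No-variation pairs** (`n ∈ {0, N}`) are classified `none`: with no
  variation there is no evidence either way.
* **Low-expectation pairs** are *not* excluded by default (some
  implementations drop pairs with expected co-occurrence < 1); the
  `min_expected` flag restores that convention when wanted.

The test suite validates the model against full enumeration of all site
placements for every `(N ≤ 8, n1, n2, j)` and against the independent
`scipy.stats.hypergeom` tails for large random tuples.

## Metaweb and graph metrics

The metaweb's node set is the whole filtered OTU universe — including
species with no significant edge — because those species still count in
the denominators of the local edge proportions.  Modules are detected on
the **positive-edge subgraph only**: modularity of signed graphs is not
defined for the random-walk method used here, so negative edges are
overlaid for reporting rather than partitioned.

Community detection is the walktrap algorithm (4-step random walks,
agglomerative Ward-style merging, dendrogram cut at maximal
Newman–Girvan modularity), delegated to python-igraph — the same
implementation family practitioners use — and its partition's Q is
recomputed by the package's own `newman_modularity` as a consistency
check.  The procedure is deterministic.  Metric conventions (matching
igraph):

* **Clustering** = average transitivity: mean local clustering over
  nodes of degree ≥ 2; missing (not 0) when no node qualifies.
* **Average path length** = mean geodesic over *connected* node pairs
  only, which keeps the property finite and meaningful on the
  disconnected graphs that local networks usually are.
* **Components** are counted on the non-isolated node set.
* All metrics are verified against brute-force networkx/BFS oracles on
  random graphs ≤ 30 nodes, and the walktrap cut against reference
  graphs with analytically known partitions (two triangles Q = 1/2,
  K4 single module Q = 0, K5–K5 barbell Q = 19/42).

All-module reporting: every module is kept and sorted by size; no small
modules are merged.

## Local networks

A sample's local network is the metaweb's induced subgraph on the
species present.  The proportion denominators use `C(S, 2)` with **S =
the sample's filtered richness** (its species within the metaweb
universe), since only those species can carry edges; the
`--denominator` choice would otherwise mix universes.  Properties are
computed on non-isolated nodes; isolated species count only in S.  Local
modularity is the walktrap Q of the *local* subgraph, recomputed per
sample, not inherited from metaweb modules.  Missing values (e.g.
modularity of an edge-less subgraph) are encoded as NaN, never as 0.

## Null models

Each sample's observed properties are z-scored against `n_rand`
(default 1,000) random species sets of the same richness drawn uniformly
without replacement from the metaweb nodes.  This null preserves
richness and destroys identity; an occurrence-frequency-weighted draw is
available (`weighted`), and a degree-preserving null is deliberately
absent (a different null family).  Randomisations where a property is
undefined are excluded from that property's null distribution and the
count used is reported.  sd uses the n−1 denominator; identical draws
give an exact sd of 0 and a flagged (NaN) z rather than a division
artifact.  The ±2-sd deviation bands use strict inequalities.  The suite
checks calibration: species sets drawn from the null itself have mean z
within (−0.3, 0.3).

## Statistical layer

* **Relationship screens**: Spearman correlations between all property
  pairs, per stratum and pooled; a pair is a "relationship" when
  |r| > 0.5 in at least one stratum with p < 0.01.  No extra
  multiplicity correction is stacked on this joint rule.
* **envfit**: least-squares fit of each variable onto ordination axes,
  r² and a permutation p (default 999 permutations).
* **Variation partitioning**: Ezekiel-adjusted R² of every block union,
  unique/pairwise/three-way fractions by inclusion–exclusion (vegan's
  varpart convention); negative shared fractions are reported, not
  truncated; block order is irrelevant.  Forward selection adds
  variables by largest adjusted-R² gain with a permutation entry test,
  after a VIF collinearity screen, and stops once the selected model
  reaches the full model's adjusted R² (double stopping rule).
* **Mixed models**: the management/weather model is a Gaussian linear
  mixed model on ln(property) — the magnitudes of typical estimates for
  proportion-type responses are consistent with a log link, and a Beta
  GLMM is out of scope — with management as cell means (no global
  intercept), continuous covariates centred and scaled per country, a
  regional random intercept fit by REML, and the marginal R² of
  Nakagawa & Schielzeth.  Singular random effects trigger a flagged OLS
  refit.
* **Two-way ANOVA** uses Type-II sums of squares (group sizes are
  unbalanced by design); empty cells drop the interaction with a log.
* **Pathogen model**: presence (≥ 1 pathogen OTU) by a binomial GLM on
  clustering(+), modularity(+), average path length(−) and the
  co-exclusion proportion; complete separation falls back to a
  ridge-penalised fit, flagged.  "Presence" means at least one pathogen
  OTU — no abundance threshold.
* Permutation tests are exhaustive (exact) whenever the permutation
  space has ≤ 10,000 elements, and seeded otherwise.
* nMDS is nonmetric SMACOF (isotonic regression) minimising Kruskal
  stress-1, best of 20 random restarts, k = 2.

## The synthetic metacommunity generator

The generator is the testbed for every claim the pipeline makes, so its
structure and defaults *are* the study conditions of the test suite.

**Survey design.** Two countries with 175 sites each; management counts
echo a realistic vineyard survey (ES: 65 conventional / 39 organic /
20 biodynamic / 51 unknown; US: 78 / 79 / 15 / 3).  The "standard"
benchmark used by the acceptance checks is a single country with 120
sites (50 conventional / 20 organic / 50 biodynamic) and 600 OTUs — the
balanced regime split gives the management contrasts equal power.  The
"small" benchmark (30 sites x 150 OTUs) exercises I/O and determinism
cheaply.

**Ecological model.**  OTUs belong to one of K = 4 guilds whose niche
optima tile the temperature gradient (optimum = guild centre +
N(0, 2.5 °C) jitter).  Sites follow one of two occupancy regimes:

* *Cooperative* (biodynamic-like): occupancy
  `p = b · exp(−(T − μ)² / 2σ²)` with a narrow thermal filter
  (σ = 1.8 °C) times a shared lognormal site-quality factor
  (sd 0.7) that co-boosts all residents.  Communities are thermally
  coherent slices whose members associate densely with one another —
  one integrated module.
* *Partitioned* (conventional-like): a broad thermal filter (σ = 9 °C)
  with the guild nearest the site temperature dominant and all other
  guilds suppressed by the exclusion strength ε = 0.7.  Communities
  span several thermal bands as thinned fragments — multiple sparse
  modules with cross-band co-exclusions.

Organic (and unknown-management) sites mix the regimes 50/50.  Base
occupancy b = 0.35 keeps the inferred metaweb at a realistic density
(positive edges ≈ 14 % of pairs, negative ≈ 1–4 %).  These values were
chosen together so that the planted contrasts — higher modularity(+),
lower clustering(+) and higher co-exclusion proportion in partitioned
communities, and the negative clustering–path-length and
modularity–clustering relationships with a positive
modularity–co-exclusion relationship — hold robustly across seeds; an
earlier variant in which the dominant guild was near-fully present
produced a single dense clique per sample and inverted the modularity
and clustering contrasts, which is why dominance is expressed through
suppression of others at a moderate base occupancy rather than through
boosting the dominant guild.

**Occupancy carries all the signal.**  Abundances (lognormal weights,
multinomial reads at a uniform 21,000–40,000 depth) exist only to
exercise rarefaction realistically; the inference chain is
presence/absence-based.

**Pathogens.**  5 % of OTUs are flagged; their occupancy is additionally
suppressed by 80 % at partitioned sites.  This plants a negative
correlation between pathogen richness and the co-exclusion proportion
(benchmark r ≈ −0.33) — communities with more exclusion structure carry
fewer pathogens — the direction the analysis layer is meant to detect.
The suppression strength is configurable, including off.

**What the generator does *not* emulate**: sequence-level noise
(chimeras, clustering artefacts), spatial autocorrelation beyond
temperature-banded regions, temporal dynamics, abundance-mediated
interactions, and taxonomy.  Passing tests therefore demonstrate that
the pipeline recovers planted *occupancy* structure through the full
rarefy → filter → test → project → model chain, not that any particular
field system behaves this way.

## Problem sizes and determinism

The test suite runs the standard benchmark at 120 x 600 for three seeds,
null-model calibration with 200 samples at 500 randomisations, and
parameter-recovery simulations at 200 replicates — sizes chosen so the
whole suite completes in a few minutes on one CPU while leaving the
statistical checks well-powered.  Every stochastic step takes an
explicit seed; the CLI manifest records config, seeds and row counts,
and re-running a manifest reproduces every TSV byte-for-byte.

## Known limitations

* Modularity of signed networks is sidestepped (positive subgraph only).
* The uniform null ignores species' occurrence frequencies unless the
  weighted mode is chosen; neither mode preserves degree.
* The exact pairwise test is marginal: it does not condition on the
  rest of the community, so indirect associations are not removed.
* The mixed model treats proportions on the log scale; responses at or
  near zero are dropped for that response rather than modelled.
* BIOM support covers the JSON (1.0) dialect, not HDF5 (2.x).
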