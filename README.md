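# commphylo

Community phylogenetic and functional structure analysis for incidence
(presence/absence) data, built around the workflow common in regional bird
community ecology:

- **treeio** — array-based `Phylogeny` container; Newick/NEXUS reading and
  writing (via dendropy), pruning with root-path retention, patristic
  distances, Brownian covariance matrices, and maximum-clade-credibility
  summarization of a tree sample with mean node heights.
- **traitspace** — typed continuous/binary `TraitTable`, Gower dissimilarity
  with per-column or per-group weights, and UPGMA functional dendrograms
  (merge height = half the merge dissimilarity, so cophenetic distances
  reproduce the merge values).
- **metrics** — per-site species richness, Faith-style branch-length
  diversity (PD on the phylogeny, FD on the functional dendrogram, with or
  without the root path), mean pairwise distances (MPD/MFD) and index
  intercorrelations.
- **structure** — randomization nulls (taxa-label shuffling or richness-
  preserving random draws) and standardized effect sizes (SESmpd/SESmfd)
  with add-one rank p-values. Default sign convention: negative = clustered,
  positive = dispersed; `nri` negates it.
- **signal** — Blomberg's K (closed-form Brownian expectation + permutation
  test) for continuous traits and the Fritz–Purvis D statistic (shuffled and
  threshold-Brownian references preserving prevalence) for binary traits.
- **spatialstats** — haversine distances, inverse-distance/kNN spatial
  weights, Moran's I (analytic and permutation tests), standardized
  bivariate OLS, maximum-likelihood spatial-error SAR with eigenvalue-based
  log-determinants, VIF screening and a batch response × predictor table.
- **sem** — piecewise structural equation models: component regressions on
  z-scored variables, the d-separation basis set, and Fisher's C with its
  chi-square global test.
- **synth** — synthetic studies with known ground truth: Yule trees,
  Brownian continuous + threshold-Brownian binary traits, community assembly
  under random / filtering / competition regimes, and site tables with
  spatially autocorrelated responses.

## CLI

```sh
# generate a synthetic study bundle (tree.nwk, traits.csv, communities.csv,
# sites.csv, truth.json)
commphylo synth --out bundle --seed 11

# full pipeline: diversity.csv, structure.csv, signals.csv, table1.csv,
# sem.csv, correlations.csv + manifest.json
commphylo run --tree bundle/tree.nwk --traits bundle/traits.csv \
    --communities bundle/communities.csv --sites bundle/sites.csv \
    --out results --seed 2 --null-reps 999

# stage-wise verbs
commphylo structure --tree bundle/tree.nwk --communities bundle/communities.csv \
    --out ses.csv --null-reps 999 --seed 2
commphylo signal --tree bundle/tree.nwk --traits bundle/traits.csv --out signals.csv
commphylo regress --sites bundle/sites.csv --diversity results/diversity.csv --out tab.csv
commphylo sem --data bundle/sites.csv --dag dag.txt --out sem.csv
```

`run` also accepts `--config FILE` (YAML with the `RunConfig` fields),
`--weights {invdist,knn}` and `--sign-convention {ses,nri}`. A single master
seed is split deterministically per stage; reruns are byte-identical.

Input formats: Newick tree (a multi-tree file triggers MCC summarization
first); trait CSV with a `#type` row typing each column
(`continuous|binary`); community CSV (sites × species, 0/1); site CSV with
`longitude`, `latitude` and habitat covariate columns.

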