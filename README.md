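# biofilmnet

Diversity, ordination and co-occurrence network analysis of microbial
community OTU tables, built for amplicon surveys of stream biofilms
along environmental gradients (e.g. grassland-degradation gradients
summarised by NDVI) but applicable to any samples × OTUs count table
with per-sample environmental metadata.

## What it does

Starting from an OTU count table (QIIME-classic TSV or BIOM-JSON), a
metadata TSV and an optional rooted Newick tree, the package covers the
full desk pipeline:

- **Preprocessing** — singleton/lineage filtering and rarefaction to a
  common depth by uniform subsampling without replacement.
- **Alpha diversity** — observed OTUs, Chao1
  (S_obs + F₁(F₁−1)/(2(F₂+1))), Shannon H = −Σ pᵢ log₂ pᵢ (bits), and
  Faith's PD (branch length spanning the observed taxa and the root),
  with Pearson diversity–environment correlations, BH-adjusted.
- **Abundance categories** — each OTU is classified from its per-sample
  minimum m and maximum M relative abundance against thresholds 0.01%
  and 1%: abundant (M ≥ 1% and m ≥ 0.01%), moderate, conditionally
  rare/abundant, rare — a strict partition of the OTU set.
- **Ordination** — Bray–Curtis dissimilarity
  d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); PCoA and distance-based redundancy
  analysis (dbRDA), permutation `envfit` of environmental vectors, and
  variation partitioning with Ezekiel-adjusted R².
- **Co-occurrence network** — Spearman ρ over prevalent OTUs,
  BH-adjusted p over all pairs, edges kept when |ρ| > 0.8 and
  p_adj < 0.05; topology (average degree 2E/N, path length over
  connected pairs, clustering, Freeman betweenness centralization,
  Newman modularity Q) compared against 99 Erdős–Rényi G(n, m) null
  graphs by Z-tests; degree power-law fit; Louvain module detection;
  node roles from the Zi–Pi plane (module hubs Zi > 2.5, connectors
  Pi > 0.62).
- **Module–environment screen** — Mantel and partial Mantel tests
  (one-sided, 999 permutations, controlling altitude) between each major
  module's Bray–Curtis dissimilarity and each environmental distance,
  BH-adjusted.
- **Synthetic data** — a generator with planted structure (heavy-tailed
  lognormal abundances, an NDVI-like gradient, latent-factor
  co-occurrence modules, multinomial counts) so the whole pipeline is
  testable without any external download.

## Worked example

`examples/04_network_roles.py` simulates 100 samples × 400 OTUs with
five planted modules, builds the network and compares it to its random
nulls:

```
network: 69 nodes, 264 edges (0 negative), modularity 0.793

real vs G(n,m) random ensemble (Z-test):
                 parameter     real  random_mean  random_sd        z      p
       average_path_length   1.4180       2.2765     0.0118 -72.8707 0.0000
    clustering_coefficient   0.8001       0.1109     0.0111  61.9223 0.0000
                modularity   0.7928       0.2929     0.0113  44.2685 0.0000
```

The planted modules surface as clustering and modularity tens of
standard deviations above the random expectation — the signature of a
non-random, modular community — while the path length is shorter than
random because modules are internally dense.  The other examples cover
abundance classification (`01`), alpha diversity (`02`), dbRDA/envfit
and variation partitioning (`03`), and the module–environment Mantel
screen (`05`); each prints its numbers with a note on what they mean.

A thin CLI mirrors the library:

```bash
biofilmnet simulate --seed 2 --out-dir sim/
biofilmnet rarefy --table sim/otu_table.tsv --depth 25884 --seed 42 --out rare.tsv
biofilmnet network --table sim/otu_table.tsv --nulls 99 --seed 1 --out-dir net/
biofilmnet run --config pipeline.yaml --out-dir results/
```

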