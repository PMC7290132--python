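# Methods

This note records the models, conventions and design choices behind
`biofilmnet`, in the order the pipeline applies them.

## Scope and data model

The pipeline begins at a clustered OTU count table (samples × OTUs in
memory; QIIME-classic orientation on disk) with per-sample environmental
metadata and an optional rooted phylogeny.  Upstream read processing
(joining, demultiplexing, chimera removal, OTU picking) is out of scope.
Missing metadata values are never imputed: any analysis naming a
variable with missing entries fails fast, which is the correct behaviour
for the complete small-n survey designs this package targets.

## Preprocessing

Rarefaction draws, per sample, a uniform subsample without replacement
(multivariate hypergeometric) at a fixed depth, so each retained sample
sums exactly to the depth and no cell exceeds its original count.
Samples below the depth are dropped with a logged warning, not padded.
The retained-richness expectation has the closed form
`S_obs − Σᵢ C(N−nᵢ, d)/C(N, d)`, which the test suite checks against
1,000 replicate draws.  Lineage filtering is case-insensitive substring
matching on the taxonomy string (typical keywords: Archaea, chloroplast,
unknown); singleton removal drops OTUs with table-wide total ≤ 1.

## Diversity conventions

- Shannon uses log base 2 (bits).  The natural log is available via the
  `base` parameter.  Base 2 makes a community of ~681 evenly abundant
  OTUs score ~9.41, the magnitude scale users of QIIME-era pipelines
  expect.
- Chao1 defaults to the bias-corrected form
  `S_obs + F₁(F₁−1)/(2(F₂+1))`; the classic form `S_obs + F₁²/(2F₂)`
  falls back to the corrected one when F₂ = 0.
- Faith's PD includes the path from each observed leaf to the root
  ("whole-tree" convention): a single observed leaf on
  `((A:1,B:1):1,C:2);` scores 2.0, not 1.0.
- Bray–Curtis is computed on relative abundances; it is symmetric, zero
  on the diagonal and bounded by 1 (disjoint supports).

Abundance categories use each OTU's minimum m and maximum M relative
abundance across samples with thresholds low = 10⁻⁴ and high = 10⁻²:
AT if M ≥ high and m ≥ low; MT if m ≥ low and M < high; CRAT if m < low
and M ≥ high; RT otherwise.  The inequalities are inclusive on the
abundant/moderate side and strict on the rare side, and the four classes
partition the OTU set by construction.

## Ordination

PCoA double-centers the squared distances (Gower) and eigendecomposes;
coordinates are eigenvectors scaled by √eigenvalue.  Bray–Curtis is not
Euclidean-embeddable, so negative eigenvalues occur; the default policy
discards them with a logged warning (total inertia = sum of positive
eigenvalues), and a Lingoes additive correction is available.  The
implementation is direct linear algebra; the test suite cross-checks the
spectrum against scikit-bio's PCoA on Euclidean inputs and verifies the
isometry property to 1e-9.

dbRDA regresses the full PCoA coordinate matrix on standardized
(z-scored) environmental variables via QR; the constrained axes are the
principal axes of the fitted values and the constrained proportion is
tr(Ŷ′Ŷ)/tr(Y′Y).  Standardization is required because the variables mix
units (pH, µS/cm, mg/L, m).  Collinear designs (condition number > 1e10)
are rejected.  With zero variables the function returns the plain PCoA.

`envfit` projects each variable onto the first two axes; R² is the
fraction of the variable's variance explained, and the p-value is
`(1 + #{R²* ≥ R²})/(1 + n_perm)` under free permutation of sample
labels (999 by default).  Note that when the ordination is constrained
on few variables, the axes span those variables' space and their R²
is near 1 by construction — envfit p-values are most informative on
ordinations with many constraints or on unconstrained PCoA.

Variation partitioning uses Ezekiel-adjusted R²,
`1 − (1−R²)(n−1)/(n−m−1)`, with unique/shared fractions by
inclusion–exclusion over 2 or 3 disjoint variable groups.  Negative
adjusted fractions are reported as-is (standard practice; they indicate
a group explaining less than chance).  The fractions plus the residual
sum to 1 identically.

## Co-occurrence network

Candidate OTUs must be present in ≥ 11 samples (or a fraction of
samples when the threshold is < 1) and have mean relative abundance
≥ 0.01% across all samples.  Spearman ρ and two-sided p (t
approximation, n−2 df) are computed for all candidate pairs; BH
adjustment runs over all pairs jointly.  Edges require |ρ| > 0.8
(strict) and adjusted p < 0.05; OTUs left without edges are dropped.

Topology conventions (fixed because the real networks are typically
fragmented):

- average path length is the mean over *connected ordered pairs only*
  (unreachable pairs excluded), computed by BFS on the sparse adjacency;
- local clustering of degree-0/1 nodes counts as 0 in the mean;
- betweenness centralization is Freeman's index on normalized
  betweenness, `Σ(b_max − bᵢ)/(n−1)` (a path graph scores 1);
- modularity is Newman's Q of the supplied partition, unweighted;
- all topology, module detection and Zi/Pi are sign-blind and
  unweighted; the correlation sign survives only as an edge attribute.

The null model is G(n, m) — uniform simple graphs with exactly the real
node and edge counts — because "same size" requires matching both.  An
ensemble of 99 graphs supports per-parameter Z-tests
`z = (real − mean)/sd` with two-sided normal p; ensembles that are
analytically constant (e.g. average degree under G(n, m)) are treated as
degenerate with p = 1 when the real value matches.

Module detection defaults to Louvain multilevel modularity optimization
with a fixed seed (greedy agglomeration available); module ids are
ordered by size descending.  For a node i in module s, Zi is the
z-score of its within-module degree against the module's mean and
population SD (0 when the SD is 0), and Pi = 1 − Σ_t (k_it/k_i)².
Roles: module hub (Zi > 2.5, Pi ≤ 0.62), connector (Pi > 0.62,
Zi ≤ 2.5), network hub (both exceeded), else peripheral; boundary
values are peripheral.  The degree power-law check is least squares of
log frequency on log degree over positive-frequency degrees ≥ 1
(maximum-likelihood fitting is a documented alternative, not
implemented).

## Module–environment tests

Each module's subcommunity distance is Bray–Curtis over the module's
OTU columns of the whole-table relative abundances, without
renormalization; a sample pair with no module abundance on either side
takes the limiting value 1.  Environmental distance is the absolute
difference of one variable.  The Mantel statistic is the Pearson
correlation of the off-diagonal triangles; p-values permute one
matrix's rows and columns jointly, one-sided "greater" by default
(999 permutations), with a two-sided option.  The partial statistic is
the first-order partial correlation
`(r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²))`, recomputing r_AB and r_BC
per permutation of B.  The screen covers modules with more than 50
member OTUs by default, controls altitude (skipping the partial test
when the variable *is* the control), and BH-adjusts across the whole
module × variable grid separately per test type.

## Synthetic communities

`generate_community` composes per-sample expected abundances as

```
λ_si = base_i · exp(β_i z_s) · exp(λ_m g_ms) · exp(ε_si)
```

with `base_i ~ LogNormal(0, σ)` (σ = 2 by default; heavy-tailed so
< 1% of OTUs classify abundant while carrying an outsized sequence
share), `z_s` the standardized NDVI-like gradient (uniform 0.05–0.85),
`β_i` signed effects of magnitude ~`env_effect_size` for a responsive
fraction (30%) of OTUs, one standard-normal latent factor `g_ms` per
planted module with loading 1.2, and lognormal noise (SD 0.25).  Counts
are multinomial at depth ~N(30000, 3000²) (column sums equal the drawn
depths exactly); a Dirichlet-multinomial overdispersion switch exists
but is off by default because plain multinomial resampling is the
simplest model reproducing rarefaction behaviour.  Two same-module OTUs
have latent log-abundance correlation λ²/(λ² + σ_noise²) ≈ 0.96 at the
defaults, which is what makes modules recoverable through a |ρ| > 0.8
network.  Remaining metadata columns (NDVI.R, altitude 3194–5174 m,
pH ~8.4, conductivity, DOC, TN, TP, biofilm C/N/P) are independent
nuisance draws at field-realistic scales for a high-altitude semi-arid
watershed.  Default sample count is 22 and OTU count 3,000, matching
the survey design the pipeline targets.

What the generator does **not** emulate: taxonomic structure (no
lineage strings), compositional correlation beyond the closure effect,
spatial autocorrelation among sites, true phylogenetic signal in
abundances (the tree is random), and sequencing error.  Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted structure, not performance on any particular
real community.  One consequence of closure worth noting: a gradient
moving the responsive subcommunity induces weak opposite trends in
other subcommunities, so gradient-free modules can show small but real
Mantel correlations with the gradient.

Responsive OTUs and module members are drawn independently, so an OTU
can be both; ground truth records both labels.

## Numerical choices and problem sizes

- Permutation p-values always use the `(1 + hits)/(1 + n_perm)`
  estimator, so p ∈ (0, 1].
- All randomness flows through `numpy.random.default_rng`; the pipeline
  derives per-stage seeds from one root seed via CRC32-labelled
  `SeedSequence`, so stages re-run in isolation reproduce their
  in-pipeline output exactly.
- Eigenvalue/rank tolerances are relative at 1e-10; distance symmetry
  is enforced by scikit-bio's `DistanceMatrix`.
- Test-suite problem sizes are chosen as the smallest that make the
  statistical assertions sharp: type-I calibrations run 500 replicates
  at n = 22 with 999 permutations (binomial SE ≈ 1%), planted-module
  recovery uses 200 samples × 400 OTUs, gradient-detection power uses
  20 replicates at n = 50 with 199 permutations, and the null-ensemble
  checks use the full 99 × G(942, 3206) ensemble.

## Known limitations

- Spearman co-occurrence on relative abundances is not
  compositionality-aware (no SparCC/SPIEC-EASI); spurious negative
  correlations from closure are possible and are a property of the
  method, not a bug.
- The degree power-law fit is the conventional log–log least squares,
  which is known to be biased relative to MLE; it is provided for
  comparability, not as a rigorous scale-freeness test.
- Signed or weighted modularity is not implemented; edge signs are
  annotations only.
- NMDS is not provided; dbRDA carries the gradient inference.
- BIOM support covers the JSON dialect (format 1.0) only, not HDF5.
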