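"""Constrained ordination of community dissimilarity on environmental
variables: dbRDA, envfit significance, and variation partitioning.

A third of the OTUs respond to the NDVI gradient, so NDVI should emerge
as the dominant, significant envfit vector, and the NDVI group should
own most of the explained variance in the partitioning.
"""

from biofilmnet import diversity, ordination, preprocess
from biofilmnet.simulate import SimulationConfig, generate_community

config = SimulationConfig(n_samples=50, n_otus=400, depth_mean=5000,
                          depth_sd=500, n_planted_modules=0, module_size=0,
                          seed=21)
table, meta, _, _ = generate_community(config)
rel = preprocess.relative_abundance(table)
dm = diversity.bray_curtis(rel)

variables = list(meta.columns)
res = ordination.dbrda(dm, meta, variables)
print(f"constrained proportion of inertia: {res.constrained_proportion:.3f}")
print("first two axes explain "
      f"{100 * res.proportion_explained[:2].sum():.1f}% of total variance")

fit = ordination.envfit(res, meta, variables, n_permutations=999, seed=1)
print("\nenvfit on the first two axes (significant variables drive the"
      " ordination):")
print(fit[["variable", "r2", "p"]].round(3).to_string(index=False))

vpa = ordination.variation_partitioning(
    dm, meta,
    {"ndvi": ["NDVI", "NDVI.R"],
     "chemistry": ["pH", "Cond", "DOC", "TN", "TP"],
     "biofilm": ["BFC", "BFN", "BFP"]},
)
print("\nvariation partitioning (Ezekiel-adjusted R2 fractions):")
print(vpa.round(3).to_string(index=False))
# unique[ndvi] should dominate; noise groups hover near (possibly below) 0.
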