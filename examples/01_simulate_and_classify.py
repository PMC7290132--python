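"""Simulate a biofilm-like community and partition its OTUs into
abundance categories.

The generator plants a heavy-tailed abundance distribution, so a handful
of OTUs dominate the sequence pool while most are rare — the structure
the abundant/rare classification is designed to expose.
"""

from biofilmnet import diversity, preprocess
from biofilmnet.simulate import SimulationConfig, generate_community

config = SimulationConfig(
    n_samples=22, n_otus=2000, depth_mean=20000, depth_sd=2000,
    lognormal_sigma=2.5, seed=13,
)
table, meta, tree, truth = generate_community(config)
print(f"community: {table.shape[0]} samples x {table.shape[1]} OTUs, "
      f"{int(table.counts.to_numpy().sum()):,} sequences")

rel = preprocess.relative_abundance(table)
classes = diversity.classify_abundance(rel, low=1e-4, high=1e-2)
print("\nOTUs per abundance class (AT abundant, MT moderate, "
      "CRAT conditionally rare/abundant, RT rare):")
print(classes.value_counts().to_string())

for cls in ("AT", "RT"):
    otus = classes.index[classes == cls]
    share = table.counts[otus].to_numpy().sum() / table.counts.to_numpy().sum()
    print(f"{cls}: {len(otus) / len(classes):.1%} of OTUs carry "
          f"{share:.1%} of all sequences")
# The abundant class is a tiny fraction of the richness but an outsized
# fraction of the reads; the rare class is the mirror image.
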