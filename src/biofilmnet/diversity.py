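"""Alpha diversity, Bray-Curtis dissimilarity, abundance-category
classification and diversity-environment correlations.

Conventions follow the QIIME 1.9 toolchain this pipeline mirrors:
Shannon entropy in bits (log base 2), bias-corrected Chao1 by default,
and Faith's phylogenetic diversity including the path to the root
("PD whole tree").

Abundance categories partition the OTU set by each OTU's minimum (m)
and maximum (M) relative abundance across samples against two
thresholds, by default 0.01% (``low``) and 1% (``high``):

========  ==========================================
class     rule
========  ==========================================
AT        abundant: M >= high and m >= low
MT        moderate: m >= low and M < high
CRAT      conditionally rare/abundant: m < low, M >= high
RT        rare: m < low and M < high
========  ==========================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, ValidationError
from .io import OtuTable

__all__ = [
    "observed_otus",
    "chao1",
    "shannon",
    "faith_pd",
    "alpha_diversity",
    "bray_curtis",
    "classify_abundance",
    "alpha_env_correlations",
]

ABUNDANCE_CLASSES = ("AT", "MT", "CRAT", "RT")


def observed_otus(counts) -> int:
    """Number of OTUs with a positive count."""
    return int(np.count_nonzero(np.asarray(counts)))


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form: ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``.  The
    classic form ``S_obs + F1^2 / (2 F2)`` falls back to the corrected
    one when no doubletons exist.
    """
    counts = np.asarray(counts)
    if np.any(counts != np.floor(counts)):
        raise ValidationError("chao1 requires integer counts")
    return float(skbio_alpha.chao1(counts.astype(int), bias_corrected=bias_corrected))


def shannon(counts, base: float = 2) -> float:
    """Shannon diversity index, in bits by default."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValidationError("shannon requires at least one positive count")
    return float(skbio_alpha.shannon(counts, base=base))


def faith_pd(counts, otu_ids, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity including the path to the root.

    Sum of branch lengths of the minimal subtree spanning the observed
    leaves and the root of ``tree``.
    """
    counts = np.asarray(counts)
    present = [otu for otu, c in zip(otu_ids, counts) if c > 0]
    tip_names = {t.name for t in tree.tips()}
    missing = [otu for otu in present if otu not in tip_names]
    if missing:
        raise ValidationError(f"OTUs absent from the tree: {missing[:5]}")
    return float(skbio_alpha.faith_pd(counts, list(otu_ids), tree))


def alpha_diversity(table: OtuTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity table.

    Columns: ``observed_otus``, ``chao1``, ``shannon`` (bits) and, when
    a tree is supplied, ``pd`` (branch-length units).
    """
    records = {}
    otu_ids = table.otu_ids
    for sample in table.sample_ids:
        row = table.counts.loc[sample].to_numpy()
        rec = {
            "observed_otus": observed_otus(row),
            "chao1": chao1(row),
            "shannon": shannon(row),
        }
        if tree is not None:
            rec["pd"] = faith_pd(row, otu_ids, tree)
        records[sample] = rec
    return pd.DataFrame.from_dict(records, orient="index")


def bray_curtis(rel_table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``d(x, y) = sum |x_i - y_i| / sum (x_i + y_i)``, in [0, 1].
    """
    if rel_table.shape[0] < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    X = rel_table.to_numpy(dtype=float)
    if np.any(X.sum(axis=1) == 0):
        raise ValidationError("zero-sum sample rows make Bray-Curtis undefined")
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in rel_table.index])


def classify_abundance(
    rel_table: pd.DataFrame, low: float = 1e-4, high: float = 1e-2
) -> pd.Series:
    """Partition OTUs into abundant / moderate / conditionally-rare /
    rare classes from their per-sample min and max relative abundance."""
    if low >= high:
        raise ConfigError(f"low threshold {low} must be < high threshold {high}")
    m = rel_table.min(axis=0)
    M = rel_table.max(axis=0)
    classes = pd.Series("RT", index=rel_table.columns, dtype=object)
    classes[(M >= high) & (m >= low)] = "AT"
    classes[(M < high) & (m >= low)] = "MT"
    classes[(M >= high) & (m < low)] = "CRAT"
    return classes


def alpha_env_correlations(
    alpha: pd.DataFrame,
    meta: pd.DataFrame,
    variables: list[str],
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each alpha-diversity index with each environmental
    variable; BH-adjust the p-values across the whole table.

    Constant vectors leave the correlation undefined; those pairs are
    flagged and excluded from the adjustment.
    """
    corr = {"pearson": sps.pearsonr, "spearman": sps.spearmanr}[method]
    meta = meta.loc[alpha.index]
    rows = []
    for index_name in alpha.columns:
        x = alpha[index_name].to_numpy(dtype=float)
        for var in variables:
            y = meta[var].to_numpy(dtype=float)
            if np.isnan(x).any() or np.isnan(y).any():
                raise ValidationError(f"missing values in {index_name!r}/{var!r}")
            if len(x) < 3:
                raise ValidationError("need >=3 paired observations")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((index_name, var, np.nan, np.nan, True))
                continue
            r, p = corr(x, y)
            rows.append((index_name, var, float(r), float(p), False))
    out = pd.DataFrame(
        rows, columns=["index", "variable", "r", "p", "degenerate"]
    )
    out["p_adjusted"] = np.nan
    ok = ~out["degenerate"]
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(
            out.loc[ok, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out
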