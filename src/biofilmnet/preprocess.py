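"""OTU-table filtering, rarefaction and relative-abundance conversion.

Rarefaction equalises sequencing effort by drawing, for each sample, a
uniform random subsample *without replacement* at a common depth (the
study design this package targets used 25,884 sequences per sample
across 22 biofilm samples).  Samples below the requested depth are
dropped with a logged warning rather than padded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .io import OtuTable

logger = logging.getLogger(__name__)

__all__ = ["filter_otus", "rarefy", "relative_abundance"]


def filter_otus(
    table: OtuTable,
    remove_singletons: bool = True,
    exclude_lineage_keywords: list[str] | tuple[str, ...] = (),
) -> OtuTable:
    """Drop unwanted OTUs; samples are untouched.

    ``remove_singletons`` drops OTUs whose total count across all samples
    is <= 1.  ``exclude_lineage_keywords`` drops OTUs whose taxonomy
    lineage contains any keyword as a case-insensitive substring (the
    usual targets being Archaea, chloroplast and unknown assignments).
    """
    keep = pd.Series(True, index=table.counts.columns)
    if remove_singletons:
        keep &= table.counts.sum(axis=0) > 1
    if exclude_lineage_keywords:
        if table.taxonomy is None:
            raise ValidationError(
                "lineage keywords given but the table has no taxonomy"
            )
        lineages = table.taxonomy.astype(str).str.lower()
        for kw in exclude_lineage_keywords:
            keep &= ~lineages.str.contains(kw.lower(), regex=False)
    counts = table.counts.loc[:, keep]
    taxonomy = table.taxonomy[keep] if table.taxonomy is not None else None
    return OtuTable(counts, taxonomy)


def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` sequences.

    Drawing is uniform without replacement (multivariate hypergeometric),
    so no cell can exceed its original count and each retained sample
    sums exactly to ``depth``.  Samples whose total is below ``depth``
    are dropped and logged.
    """
    if depth <= 0:
        raise ConfigError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    kept_rows = []
    kept_ids = []
    for sample in table.counts.index:
        row = table.counts.loc[sample].to_numpy()
        total = int(totals[sample])
        if total < depth:
            logger.warning(
                "sample %s has %d < %d sequences; dropped from rarefied table",
                sample,
                total,
                depth,
            )
            continue
        kept_rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sample)
    counts = pd.DataFrame(
        np.asarray(kept_rows, dtype=np.int64).reshape(len(kept_ids), table.shape[1]),
        index=kept_ids,
        columns=table.counts.columns,
    )
    return OtuTable(counts, table.taxonomy)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValidationError(f"samples with zero total count: {zero}")
    return table.counts.div(totals, axis=0)
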