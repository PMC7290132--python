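"""Readers and writers for the external formats the pipeline touches.

The universal input is an OTU count table.  On disk the QIIME-classic
convention is OTUs as rows and samples as columns (with a leading
``#OTU ID`` header and an optional trailing ``taxonomy`` column); in
memory every analysis works on the transposed samples x OTUs orientation,
so the conversion happens here at the boundary and nowhere else.

Also handled: per-sample environmental metadata (TSV), rooted Newick
trees with branch lengths (via scikit-bio), BIOM-JSON v1.0 tables, and
GraphML / edge-list TSV serialisations of co-occurrence networks.
Missing values are never imputed; malformed input fails fast with an
error naming the offending cell.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .exceptions import ParseError, ValidationError

__all__ = [
    "OtuTable",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "write_network",
    "read_network",
]

_FLOAT_FMT = "%.12g"  # attribute round-trips hold to 12 significant digits


class OtuTable:
    """Integer count matrix (samples x OTUs) with optional taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with OTU ids as columns.  Values
        must be non-negative integers (integral floats are cast).
    taxonomy
        Optional mapping ``otu_id -> semicolon-delimited lineage``.  When
        given it must cover every OTU in the table.
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: pd.Series | dict | None = None):
        counts = pd.DataFrame(counts)
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("counts must be finite integers")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {counts.index[i]!r}, OTU {counts.columns[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        if taxonomy is not None:
            taxonomy = pd.Series(taxonomy, dtype=object)
            missing = self.counts.columns.difference(taxonomy.index)
            if len(missing):
                raise ValidationError(
                    f"taxonomy missing for {len(missing)} OTUs, e.g. {missing[0]!r}"
                )
            taxonomy = taxonomy.reindex(self.counts.columns)
        self.taxonomy = taxonomy

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        same_counts = self.counts.equals(other.counts)
        if self.taxonomy is None or other.taxonomy is None:
            return same_counts and (self.taxonomy is None) == (other.taxonomy is None)
        return same_counts and self.taxonomy.equals(other.taxonomy)

    def __repr__(self) -> str:
        n, m = self.shape
        tax = "with" if self.taxonomy is not None else "without"
        return f"<OtuTable: {n} samples x {m} OTUs, {tax} taxonomy>"


# ---------------------------------------------------------------------------
# OTU tables


def read_otu_table(path, format: str = "classic_tsv") -> OtuTable:
    """Read an OTU table from ``path`` in the named dialect.

    ``classic_tsv`` is the QIIME-classic layout (OTU rows, sample
    columns, ``#OTU ID`` header, optional trailing taxonomy column);
    ``biom_json`` is BIOM format version 1.0.  The returned table is
    transposed to the in-memory samples x OTUs orientation with file
    order preserved.
    """
    path = Path(path)
    if format == "classic_tsv":
        return _read_classic_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown OTU table format: {format!r}")


def _read_classic_tsv(path: Path) -> OtuTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header_idx = None
    for i, ln in enumerate(lines):
        if ln.startswith("#OTU ID"):
            header_idx = i
            break
        if not ln.startswith("#"):
            raise ParseError(f"{path}: no '#OTU ID' header line found before data")
    if header_idx is None:
        raise ParseError(f"{path}: no '#OTU ID' header line found")
    df = pd.read_csv(
        _io.StringIO("\n".join(lines[header_idx:])), sep="\t", dtype=str, index_col=0
    )
    taxonomy = None
    if len(df.columns) and df.columns[-1].strip().lower() == "taxonomy":
        taxonomy = df.iloc[:, -1].copy()
        df = df.iloc[:, :-1]
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df.iloc[:, j]):
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: malformed count {raw!r} at OTU {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
            if not np.isfinite(val) or val != int(val):
                raise ParseError(
                    f"{path}: non-integral count {raw!r} at OTU {df.index[i]!r}, "
                    f"sample {col!r}"
                )
            counts[i, j] = int(val)
    table = pd.DataFrame(counts.T, index=df.columns, columns=df.index)
    table.index.name = None
    table.columns.name = None
    if taxonomy is not None:
        taxonomy.index.name = None
    return OtuTable(table, taxonomy)


def _read_biom_json(path: Path) -> OtuTable:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from None
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise ParseError(f"{path}: BIOM document missing {key!r}")
    n_rows, n_cols = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    if len(otu_ids) != n_rows or len(sample_ids) != n_cols:
        raise ParseError(f"{path}: shape disagrees with rows/columns lists")
    dense = np.zeros((n_rows, n_cols))
    if doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            dense[int(i), int(j)] = v
    elif doc["matrix_type"] == "dense":
        dense[:] = np.asarray(doc["data"], dtype=float)
    else:
        raise ParseError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    taxonomy = None
    metas = [r.get("metadata") or {} for r in doc["rows"]]
    if any("taxonomy" in m for m in metas):
        tax = {}
        for otu, m in zip(otu_ids, metas):
            t = m.get("taxonomy", "")
            tax[otu] = ";".join(t) if isinstance(t, (list, tuple)) else str(t)
        taxonomy = pd.Series(tax)
    return OtuTable(pd.DataFrame(dense.T, index=sample_ids, columns=otu_ids), taxonomy)


def write_otu_table(table: OtuTable, path, format: str = "classic_tsv") -> None:
    """Write ``table`` to ``path`` in the named dialect."""
    path = Path(path)
    if format == "classic_tsv":
        df = table.counts.T  # back to OTUs x samples on disk
        with open(path, "w") as fh:
            cols = "\t".join(str(s) for s in df.columns)
            header = f"#OTU ID\t{cols}"
            if table.taxonomy is not None:
                header += "\ttaxonomy"
            fh.write(header + "\n")
            for otu in df.index:
                row = "\t".join(str(int(v)) for v in df.loc[otu])
                line = f"{otu}\t{row}"
                if table.taxonomy is not None:
                    line += f"\t{table.taxonomy[otu]}"
                fh.write(line + "\n")
    elif format == "biom_json":
        dense = table.counts.T.to_numpy()
        data = [
            [int(i), int(j), int(dense[i, j])]
            for i, j in zip(*np.nonzero(dense))
        ]
        rows = []
        for otu in table.otu_ids:
            meta = None
            if table.taxonomy is not None:
                meta = {"taxonomy": table.taxonomy[otu]}
            rows.append({"id": str(otu), "metadata": meta})
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "biofilmnet",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(table.otu_ids), len(table.sample_ids)],
            "rows": rows,
            "columns": [{"id": str(s), "metadata": None} for s in table.sample_ids],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown OTU table format: {format!r}")


# ---------------------------------------------------------------------------
# Sample metadata


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample environmental metadata from a TSV.

    First column is the sample id.  Columns that parse as numbers become
    numeric; anything else is kept as a label column — except cells that
    are numeric only after stripping thousands separators (``3,299``),
    which are rejected as a dialect error rather than silently kept.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated sample ids: {dups}")
    out = {}
    for col in df.columns:
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() & series.notna()
        if bad.any():
            # reject locale-style grouped digits outright
            degrouped = pd.to_numeric(
                series[bad].str.replace(",", "", regex=False), errors="coerce"
            )
            if degrouped.notna().any():
                sample = series[bad][degrouped.notna()].iloc[0]
                raise ParseError(
                    f"{path}: thousands separators are not supported "
                    f"(column {col!r}, value {sample!r})"
                )
            out[col] = series  # genuine label column
        else:
            out[col] = numeric
    result = pd.DataFrame(out, index=df.index)
    result.index.name = df.index.name
    return result


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label=meta.index.name or "#SampleID")


# ---------------------------------------------------------------------------
# Phylogenetic trees


def read_tree(path) -> TreeNode:
    """Read a single rooted Newick tree and validate it.

    Leaves must be uniquely labelled and all stated branch lengths must
    be non-negative (the root may have no length).
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ParseError(f"{path}: could not parse Newick tree: {exc}") from None
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        raise ValidationError("tree has duplicate leaf labels")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} at node {node.name!r}"
            )
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Co-occurrence networks

_EDGE_COLUMNS = ("source", "target", "rho", "sign", "p_adjusted")


def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Serialise a co-occurrence network.

    ``edge_tsv`` writes one row per edge with columns
    ``source  target  rho  sign  p_adjusted``; ``graphml`` stores the
    same values as edge attributes plus any node attributes.
    """
    path = Path(path)
    if format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for u, v, attrs in net.edges(data=True):
                rho = attrs.get("rho", float("nan"))
                padj = attrs.get("p_adjusted", float("nan"))
                sign = attrs.get("sign", "+" if rho >= 0 else "-")
                fh.write(
                    f"{u}\t{v}\t{_FLOAT_FMT % rho}\t{sign}\t{_FLOAT_FMT % padj}\n"
                )
    elif format == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    path = Path(path)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        missing = set(_EDGE_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: edge TSV missing columns {sorted(missing)}")
        net = nx.Graph()
        for row in df.itertuples(index=False):
            net.add_edge(
                row.source,
                row.target,
                rho=float(row.rho),
                sign=str(row.sign),
                p_adjusted=float(row.p_adjusted),
            )
        return net
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format: {format!r}")
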