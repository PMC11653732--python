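"""Tabular IO and shared community statistics.

The canonical in-memory feature table is a pandas ``DataFrame`` of
non-negative counts with samples as rows and taxa as columns. Distance
matrices are :class:`skbio.DistanceMatrix` objects (symmetric, zero
diagonal, sample-labelled), which read and write the labelled square
TSV ("lsmat") format directly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "RANKS",
    "validate_feature_table",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "read_taxonomy",
    "read_trait_map",
    "relative_abundance",
    "alpha_diversity",
    "bray_curtis",
]

#: Taxonomic ranks recognised in lineage strings, outermost first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Soil physicochemical variables carried by sample metadata when present.
SOIL_VARIABLES = ("pH", "TN", "AN", "TP", "AP", "SOM", "DOC", "SWC", "Ca", "Mg")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dups}")


def validate_feature_table(table: pd.DataFrame, require_int: bool = False) -> pd.DataFrame:
    """Validate a samples x taxa feature table and return it unchanged.

    Parameters
    ----------
    table
        Samples as rows, taxa as columns, non-negative numeric entries.
    require_int
        If true, additionally require every entry to be integer-valued
        (counts rather than proportions).
    """
    if table.empty:
        raise ValueError("feature table is empty")
    _check_unique(table.index, "sample")
    _check_unique(table.columns, "taxon")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("feature table contains non-numeric entries")
    if np.isnan(values).any():
        raise ValueError("feature table contains missing values")
    if (values < 0).any():
        bad = table.columns[(values < 0).any(axis=0)].tolist()
        raise ValueError(f"negative counts in taxa: {bad}")
    if require_int and not np.allclose(values, np.round(values)):
        raise ValueError("feature table contains non-integer counts")
    return table


def read_feature_table(
    path, orientation: str = "taxa_by_samples", require_int: bool = True
) -> pd.DataFrame:
    """Read a TSV feature table, normalising to samples x taxa.

    ``orientation="taxa_by_samples"`` (the common ASV-table dialect) has
    taxon ids in the first column and sample ids in the header;
    ``"samples_by_taxa"`` is the transpose.
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_by_samples":
        _check_unique(table.index, "taxon")
        table = table.T
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    return validate_feature_table(table, require_int=require_int)


def write_feature_table(table: pd.DataFrame, path, orientation: str = "taxa_by_samples") -> None:
    """Write a samples x taxa table as TSV in the requested orientation."""
    if orientation == "taxa_by_samples":
        out = table.T.rename_axis("taxon_id")
    elif orientation == "samples_by_taxa":
        out = table.rename_axis("sample_id")
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    out.to_csv(path, sep="\t")


def read_sample_metadata(path, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read per-sample metadata (island id, area, isolation, soil variables).

    ``area`` must be strictly positive wherever present (log-transforms
    downstream). If ``table`` is given, every one of its samples must
    appear exactly once in the metadata.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    _check_unique(meta.index, "sample")
    if "area" in meta.columns and (meta["area"] <= 0).any():
        bad = meta.index[meta["area"] <= 0].tolist()
        raise ValueError(f"non-positive area for samples: {bad}")
    if "isolation" in meta.columns and (meta["isolation"] < 0).any():
        raise ValueError("negative isolation values")
    if table is not None:
        missing = table.index.difference(meta.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {missing.tolist()}")
    return meta


def _parse_lineage(lineage: str) -> dict:
    """Parse a semicolon-delimited lineage, accepting QIIME-style prefixes."""
    out = {}
    if not isinstance(lineage, str):
        return out
    for i, part in enumerate(lineage.split(";")):
        part = part.strip()
        if len(part) >= 3 and part[1:3] == "__":
            part = part[3:]
        if i < len(RANKS) and part:
            out[RANKS[i]] = part
    return out


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxon_id -> lineage TSV into a ranks-as-columns DataFrame.

    The lineage column is semicolon-delimited, outermost rank first;
    QIIME-style ``k__...;p__...`` prefixes are stripped. Unassigned ranks
    come back as missing values.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "taxon")
    lineages = raw.iloc[:, 0]
    parsed = pd.DataFrame(
        [_parse_lineage(lin) for lin in lineages], index=raw.index, columns=list(RANKS)
    )
    parsed.index.name = "taxon_id"
    return parsed


def read_trait_map(path, value_column: str | None = None) -> pd.Series:
    """Read a two-column taxon -> trait TSV into a Series."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "taxon")
    col = value_column if value_column is not None else raw.columns[0]
    return raw[col]


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample proportions (each row sums to 1)."""
    validate_feature_table(table)
    totals = table.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    return table.div(totals, axis=0)


def alpha_diversity(table: pd.DataFrame, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity.

    ``observed_richness`` counts taxa with count > 0; ``shannon`` is
    H = -sum p ln p over non-zero proportions (natural log).
    """
    validate_feature_table(table)
    if metric == "observed_richness":
        return (table > 0).sum(axis=1).rename("observed_richness")
    if metric == "shannon":
        props = relative_abundance(table).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(props > 0, props * np.log(props), 0.0)
        return pd.Series(-terms.sum(axis=1), index=table.index, name="shannon")
    raise ValueError(f"unknown alpha-diversity metric: {metric!r}")


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(x, y) = sum |x_i - y_i| / sum (x_i + y_i); in [0, 1] on
    proportion input. Undefined between two all-zero samples.
    """
    validate_feature_table(table)
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    empty = table.index[table.sum(axis=1) == 0].tolist()
    if len(empty) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples: {empty}"
        )
    if empty:
        warnings.warn(f"all-zero sample in distance computation: {empty}")
    dm = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(dm, ids=[str(s) for s in table.index])
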