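"""Trait-based r/K life-strategy indices.

Three community-level indices summarise where a community sits on the
r-K (copiotroph-oligotroph) axis:

* the community-weighted mean (CWM) rrn operon copy number — a
  growth-rate proxy for bacteria; higher means more r-selected;
* the ectomycorrhizal / saprotroph abundance ratio (E/S) for fungi —
  ectomycorrhizal fungi are treated as K-strategists, saprotrophs as
  r-strategists, so a higher ratio means more K-selected;
* the oligotroph / eutroph phylum ratio, from fixed phylum sets for
  either kingdom.

All indices operate on relative abundances and renormalise over the
annotated fraction of the community; that coverage is always reported
so low-annotation samples are auditable rather than silently wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import relative_abundance, validate_feature_table

__all__ = [
    "CopyNumberMap",
    "PhylumStrategyScheme",
    "BACTERIAL_SCHEME",
    "FUNGAL_SCHEME",
    "CwmResult",
    "RatioResult",
    "community_weighted_copy_number",
    "normalize_guild",
    "guild_ratio",
    "phylum_strategy_ratio",
    "strategy_indices",
    "island_aggregate",
]


@dataclass
class CwmResult:
    """Community-weighted mean with annotation coverage diagnostics."""

    value: float
    coverage: float  # summed proportion of taxa with a known trait value
    n_taxa: int  # annotated taxa with positive abundance
    defined: bool = True
    reason: str | None = None


@dataclass
class RatioResult:
    """A non-negative strategy ratio, flagged undefined on a zero denominator."""

    value: float
    defined: bool = True
    reason: str | None = None
    numerator: float = 0.0
    denominator: float = 0.0


class CopyNumberMap:
    """taxon (or genus) -> rrn operon copy number, with genus fallback.

    Copy numbers must be >= 1. Lookup tries the taxon id first, then the
    taxon's genus (when a taxonomy is supplied), then gives up; taxa
    without a match are tracked through the coverage diagnostic, never
    silently dropped.
    """

    def __init__(self, mapping: pd.Series | dict):
        series = pd.Series(mapping, dtype=float)
        if (series < 1).any():
            bad = series.index[series < 1].tolist()
            raise ValueError(f"copy numbers must be >= 1; offending keys: {bad}")
        if series.index.has_duplicates:
            raise ValueError("duplicate keys in copy-number map")
        self.mapping = series

    @classmethod
    def from_tsv(cls, path, value_column: str | None = None) -> "CopyNumberMap":
        from .core_io import read_trait_map

        return cls(read_trait_map(path, value_column))

    def lookup(self, taxon_ids, taxonomy: pd.DataFrame | None = None) -> pd.Series:
        """Copy number per taxon id; NaN where neither id nor genus matches."""
        out = self.mapping.reindex(taxon_ids)
        if taxonomy is not None and out.isna().any():
            genera = taxonomy["genus"].reindex(taxon_ids)
            fallback = self.mapping.reindex(genera.fillna("")).to_numpy()
            out = out.fillna(pd.Series(fallback, index=out.index))
        out.index = pd.Index(taxon_ids)
        return out


def community_weighted_copy_number(
    proportions: pd.Series,
    copy_map: CopyNumberMap | pd.Series | dict,
    taxonomy: pd.DataFrame | None = None,
    weighting: str = "abundance",
) -> CwmResult:
    """Abundance-weighted mean copy number, renormalised over annotated taxa.

    CWM = sum(p_i * c_i) / sum(p_i) over taxa with known copy number c_i;
    coverage = sum(p_i) over those taxa. ``weighting="presence"`` instead
    averages copy numbers unweighted over annotated taxa with p_i > 0.
    """
    if weighting not in ("abundance", "presence"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    if not isinstance(copy_map, CopyNumberMap):
        copy_map = CopyNumberMap(copy_map)
    p = pd.Series(proportions, dtype=float)
    copies = copy_map.lookup(p.index, taxonomy)
    known = copies.notna() & (p > 0)
    coverage = float(p[known].sum())
    if coverage == 0:
        return CwmResult(np.nan, 0.0, 0, defined=False, reason="zero coverage")
    if weighting == "abundance":
        value = float((p[known] * copies[known]).sum() / coverage)
    else:
        value = float(copies[known].mean())
    return CwmResult(value, coverage, int(known.sum()))


def normalize_guild(label) -> str | None:
    """Map a free-form guild string to 'E', 'S' or None.

    Any label containing "ectomycorrhizal" maps to E; any containing
    "saprotroph" or "saproph" (Soil/Wood Saprotroph, Saprophytic) maps
    to S. Compound labels containing both are excluded (None): the
    conservative choice for multi-guild annotations.
    """
    if not isinstance(label, str):
        return None
    low = label.lower()
    is_e = "ectomycorrhizal" in low
    is_s = "saprotroph" in low or "saproph" in low
    if is_e and is_s:
        return None
    if is_e:
        return "E"
    if is_s:
        return "S"
    return None


def guild_ratio(proportions: pd.Series, guild_map: pd.Series | dict) -> RatioResult:
    """Ectomycorrhizal / saprotroph abundance ratio (E/S).

    Guild labels are normalised via :func:`normalize_guild`; taxa without
    a recognised guild are excluded. Undefined when the saprotroph sum is
    zero (flagged, with a reason).
    """
    p = pd.Series(proportions, dtype=float)
    guilds = pd.Series(guild_map).reindex(p.index).map(normalize_guild)
    ecto = float(p[guilds == "E"].sum())
    sapro = float(p[guilds == "S"].sum())
    if sapro == 0 and ecto == 0:
        return RatioResult(np.nan, False, "no ectomycorrhizal or saprotroph abundance", ecto, sapro)
    if sapro == 0:
        return RatioResult(np.nan, False, "zero saprotroph abundance", ecto, sapro)
    return RatioResult(ecto / sapro, True, None, ecto, sapro)


# Known -ota/-etes naming variants of the strategy-scheme phyla
# (Acidobacteria == Acidobacteriota etc.), lower-case.
_PHYLUM_ALIASES = {
    "acidobacteriota": "acidobacteria",
    "actinobacteriota": "actinobacteria",
    "actinomycetota": "actinobacteria",
    "planctomycetota": "planctomycetes",
    "chloroflexota": "chloroflexi",
    "bacteroidota": "bacteroidetes",
    "gemmatimonadota": "gemmatimonadetes",
    "bacillota": "firmicutes",
}


def _phylum_key(name: str) -> str:
    key = str(name).strip().lower()
    if key.startswith("p__"):
        key = key[3:]
    return _PHYLUM_ALIASES.get(key, key)


@dataclass
class PhylumStrategyScheme:
    """Disjoint oligotroph (K) and eutroph (r) phylum sets for one kingdom."""

    oligotroph: frozenset
    eutroph: frozenset
    kingdom: str = "bacteria"

    def __post_init__(self):
        if not self.oligotroph or not self.eutroph:
            raise ValueError("both phylum sets must be non-empty")
        self._k_keys = {_phylum_key(p) for p in self.oligotroph}
        self._r_keys = {_phylum_key(p) for p in self.eutroph}
        if self._k_keys & self._r_keys:
            raise ValueError("oligotroph and eutroph phylum sets overlap")

    def classify(self, phylum) -> str | None:
        key = _phylum_key(phylum) if isinstance(phylum, str) else None
        if key in self._k_keys:
            return "K"
        if key in self._r_keys:
            return "r"
        return None


BACTERIAL_SCHEME = PhylumStrategyScheme(
    oligotroph=frozenset({"Acidobacteria", "Actinobacteria", "Planctomycetes", "Chloroflexi"}),
    eutroph=frozenset({"Bacteroidetes", "Gemmatimonadetes", "Firmicutes"}),
    kingdom="bacteria",
)

FUNGAL_SCHEME = PhylumStrategyScheme(
    oligotroph=frozenset({"Basidiomycota"}),
    eutroph=frozenset({"Ascomycota"}),
    kingdom="fungi",
)


def phylum_strategy_ratio(
    proportions: pd.Series,
    taxonomy: pd.DataFrame,
    scheme: PhylumStrategyScheme = BACTERIAL_SCHEME,
) -> RatioResult:
    """Oligotroph / eutroph summed-abundance ratio under a phylum scheme."""
    p = pd.Series(proportions, dtype=float)
    phyla = taxonomy["phylum"].reindex(p.index)
    classes = phyla.map(scheme.classify)
    k_sum = float(p[classes == "K"].sum())
    r_sum = float(p[classes == "r"].sum())
    if k_sum == 0 and r_sum == 0:
        return RatioResult(
            np.nan, False, "community entirely outside both phylum sets", k_sum, r_sum
        )
    if r_sum == 0:
        return RatioResult(np.nan, False, "zero eutroph abundance", k_sum, r_sum)
    return RatioResult(k_sum / r_sum, True, None, k_sum, r_sum)


def strategy_indices(
    table: pd.DataFrame,
    copy_map: CopyNumberMap | pd.Series | dict | None = None,
    guild_map: pd.Series | dict | None = None,
    taxonomy: pd.DataFrame | None = None,
    scheme: PhylumStrategyScheme | None = None,
    weighting: str = "abundance",
) -> pd.DataFrame:
    """Per-sample strategy indices for whichever trait maps are supplied.

    Returns a samples x index DataFrame with columns among
    ``cwm_copy_number`` / ``cwm_coverage``, ``es_ratio``,
    ``oligotroph_eutroph_ratio``; undefined values are NaN.
    """
    validate_feature_table(table)
    props = relative_abundance(table)
    rows = {}
    for sample in props.index:
        p = props.loc[sample]
        row = {}
        if copy_map is not None:
            cwm = community_weighted_copy_number(p, copy_map, taxonomy, weighting)
            row["cwm_copy_number"] = cwm.value
            row["cwm_coverage"] = cwm.coverage
        if guild_map is not None:
            row["es_ratio"] = guild_ratio(p, guild_map).value
        if scheme is not None:
            if taxonomy is None:
                raise ValueError("phylum strategy ratio requires a taxonomy")
            row["oligotroph_eutroph_ratio"] = phylum_strategy_ratio(p, taxonomy, scheme).value
        rows[sample] = row
    if not rows or not any(rows.values()):
        raise ValueError("no trait map supplied; nothing to compute")
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def island_aggregate(per_sample: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean of defined per-sample index values within each island.

    Carries island-level covariates (area, isolation, soil variables)
    through unchanged when they are constant within the island, and adds
    ``n_<index>`` columns recording how many samples contributed.
    """
    missing = per_sample.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples without metadata: {missing.tolist()}")
    islands = metadata.loc[per_sample.index, "island_id"]
    grouped = per_sample.groupby(islands)
    out = grouped.mean()  # NaNs excluded per column
    counts = grouped.count().add_prefix("n_")
    out = pd.concat([out, counts], axis=1).rename_axis("island_id")
    covars = metadata.loc[per_sample.index].drop(columns=["island_id"])
    numeric = covars.select_dtypes("number")
    if not numeric.empty:
        island_covars = numeric.groupby(islands).mean()
        out = out.join(island_covars)
    return out
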