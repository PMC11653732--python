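"""Synthetic island-structured microbial communities with known ground truth.

The generator emulates the processed data layer of a habitat-island
amplicon survey: a counts table over islands whose areas span three
orders of magnitude, taxon traits (rrn copy number, fungal guild,
phylum), an area-dependent selection gradient on copy number, planted
abundant/rare taxa, correlation-block structure for network tests, and
an area -> soil -> strategy mediation chain. Everything is deterministic
given the scenario seed.

Generative model
----------------
Per-island taxon fitness is ``w_i = base_i * exp(beta * z(log10 area) *
z(c_i))`` where ``c_i`` is the taxon's copy number: ``beta`` > 0 makes
high-copy (r-selected) taxa fitter on large islands, so the island-level
community-weighted copy number rises approximately linearly with log10
area. Sample compositions are Dirichlet perturbations of the island
composition and counts are multinomial at fixed depth, so sample totals
equal the configured depth exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import RANKS

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_taxa",
    "generate_counts",
    "generate_planted_network_data",
    "generate_island_strategy",
    "generate_mediation_data",
]


@dataclass
class ScenarioConfig:
    """Stated world for the default island scenario.

    Defaults follow the surveyed system: 14 islands (the larger of the
    two studied island groups), 3 samples each (2-6 plots per island in
    the field, ~3.6 on average), areas log-uniform over 10^3-10^6 m^2,
    isolation (depth) uniform over 50-300 m. Copy numbers are a
    discretized log-normal on [1, 15] (median ~3, matching genomic rrn
    surveys); guilds cover a realistic soil-fungal split (15%
    ectomycorrhizal, 35% saprotroph, the rest unassigned). The Dirichlet
    concentration (15) is calibrated once so the within-island CV of
    sample-level CWM is ~10%.
    """

    seed: int  # mandatory
    n_islands: int = 14
    samples_per_island: int = 3
    n_taxa: int = 300
    area_range: tuple = (1e3, 1e6)
    isolation_range: tuple = (50.0, 300.0)
    beta: float = 1.0  # selection of log10 area on copy number
    copy_number_log_mean: float = float(np.log(3.0))
    copy_number_log_sd: float = 0.5
    copy_number_constant: float | None = None  # overrides the distribution
    guild_fractions: dict = field(
        default_factory=lambda: {"Ectomycorrhizal": 0.15, "Saprotroph": 0.35}
    )
    oligotroph_fraction: float = 0.35  # share of taxa in K-strategy phyla
    eutroph_fraction: float = 0.25
    base_abundance_log_sd: float = 1.5
    n_planted_abundant: int = 0
    n_planted_rare: int = 0
    planted_abundant_share: float = 0.01  # per planted-abundant taxon
    # far below the rare band: any share under 1/depth is unresolvable in
    # counts, and the heavy-tailed Dirichlet marginal then cannot spike a
    # planted-rare taxon across the threshold
    planted_rare_share: float = 1e-8
    # correlation-block structure for network recovery
    n_blocks: int = 2
    block_size: int = 10
    rho_within: float = 0.9
    n_hubs: int = 0
    # mediation chain
    mediation_a: float = 0.6  # area -> soil
    mediation_b: float = 0.5  # soil -> strategy
    mediation_c: float = 0.0  # direct area -> strategy
    depth: int = 10_000
    concentration: float = 15.0
    n_samples: int = 40  # samples for planted-network tables

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_islands", "samples_per_island", "n_taxa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth < 1_000:
            raise ValueError("sequencing depth must be >= 1000")
        for name in ("beta", "mediation_a", "mediation_b", "mediation_c"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def rng(self, stream: int = 0) -> np.random.Generator:
        # independent, platform-stable streams per generator stage
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted quantities sufficient to score every recovery metric."""

    traits: pd.DataFrame | None = None  # copy_number, guild, phylum, intent
    island_table: pd.DataFrame | None = None  # area, isolation, soil, expected_cwm
    beta: float | None = None
    mediation: dict | None = None
    expected_edges: set | None = None
    hubs: dict | None = None  # hub taxon -> tuple of linked blocks
    blocks: dict | None = None  # taxon -> block id

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.traits is not None:
            self.traits.to_csv(outdir / "truth_traits.tsv", sep="\t")
        if self.island_table is not None:
            self.island_table.to_csv(outdir / "truth_islands.tsv", sep="\t")
        scalars = {
            "beta": self.beta,
            "mediation": self.mediation,
            "expected_edges": sorted(map(list, self.expected_edges)) if self.expected_edges else None,
            "hubs": {k: list(v) for k, v in self.hubs.items()} if self.hubs else None,
            "blocks": self.blocks,
        }
        (outdir / "truth.json").write_text(json.dumps(scalars, indent=2))

    @classmethod
    def read(cls, outdir) -> "GroundTruth":
        outdir = Path(outdir)
        truth = cls()
        traits = outdir / "truth_traits.tsv"
        if traits.exists():
            truth.traits = pd.read_csv(traits, sep="\t", index_col=0)
        islands = outdir / "truth_islands.tsv"
        if islands.exists():
            truth.island_table = pd.read_csv(islands, sep="\t", index_col=0)
        scalars = json.loads((outdir / "truth.json").read_text())
        truth.beta = scalars["beta"]
        truth.mediation = scalars["mediation"]
        if scalars["expected_edges"] is not None:
            truth.expected_edges = {frozenset(e) for e in scalars["expected_edges"]}
        if scalars["hubs"] is not None:
            truth.hubs = {k: tuple(v) for k, v in scalars["hubs"].items()}
        truth.blocks = scalars["blocks"]
        return truth


def _taxon_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"ASV{i:0{width}d}" for i in range(n)]


def generate_taxa(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample per-taxon traits and a matching taxonomy.

    Returns (traits, taxonomy): traits has columns copy_number, guild,
    phylum, strategy_class and intent (planted abundance class); the
    taxonomy holds QIIME-rank columns with the phylum filled in.
    """
    rng = config.rng(stream=1)
    ids = _taxon_ids(config.n_taxa)
    if config.copy_number_constant is not None:
        copies = np.full(config.n_taxa, float(config.copy_number_constant))
    else:
        raw = rng.lognormal(config.copy_number_log_mean, config.copy_number_log_sd, config.n_taxa)
        copies = np.clip(np.round(raw), 1, 15)

    guilds = np.array([None] * config.n_taxa, dtype=object)
    fracs = config.guild_fractions
    labels = list(fracs)
    probs = np.array([fracs[g] for g in labels])
    if probs.sum() > 1:
        raise ValueError("guild fractions sum beyond 1")
    draw = rng.choice(len(labels) + 1, size=config.n_taxa, p=[*probs, 1 - probs.sum()])
    for k, lab in enumerate(labels):
        guilds[draw == k] = lab

    k_phyla = ["Acidobacteriota", "Actinobacteriota", "Planctomycetota", "Chloroflexi"]
    r_phyla = ["Bacteroidota", "Gemmatimonadota", "Firmicutes"]
    other_phyla = ["Proteobacteria", "Verrucomicrobiota", "Myxococcota"]
    u = rng.random(config.n_taxa)
    phyla = np.empty(config.n_taxa, dtype=object)
    strategy = np.empty(config.n_taxa, dtype=object)
    k_cut = config.oligotroph_fraction
    r_cut = k_cut + config.eutroph_fraction
    for i in range(config.n_taxa):
        if u[i] < k_cut:
            phyla[i] = k_phyla[rng.integers(len(k_phyla))]
            strategy[i] = "K"
        elif u[i] < r_cut:
            phyla[i] = r_phyla[rng.integers(len(r_phyla))]
            strategy[i] = "r"
        else:
            phyla[i] = other_phyla[rng.integers(len(other_phyla))]
            strategy[i] = None

    intent = np.array(["free"] * config.n_taxa, dtype=object)
    n_planted = config.n_planted_abundant + config.n_planted_rare
    if n_planted > config.n_taxa:
        raise ValueError("more planted taxa than taxa")
    planted = rng.choice(config.n_taxa, size=n_planted, replace=False)
    intent[planted[: config.n_planted_abundant]] = "abundant"
    intent[planted[config.n_planted_abundant:]] = "rare"
    # planted taxa get the median copy number so area selection cannot
    # move them across the abundance thresholds
    if n_planted and config.copy_number_constant is None:
        copies[planted] = np.median(copies)

    traits = pd.DataFrame(
        {
            "copy_number": copies,
            "guild": guilds,
            "phylum": phyla,
            "strategy_class": strategy,
            "intent": intent,
        },
        index=pd.Index(ids, name="taxon_id"),
    )
    taxonomy = pd.DataFrame(index=traits.index, columns=list(RANKS), dtype=object)
    taxonomy["kingdom"] = "Bacteria"
    taxonomy["phylum"] = traits["phylum"]
    taxonomy["genus"] = [f"Genus{i % 50:02d}" for i in range(config.n_taxa)]
    return traits, taxonomy


def _island_frame(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.area_range
    areas = 10 ** rng.uniform(np.log10(lo), np.log10(hi), config.n_islands)
    iso = rng.uniform(*config.isolation_range, config.n_islands)
    ids = [f"TK{i:02d}" for i in range(config.n_islands)]
    return pd.DataFrame({"area": areas, "isolation": iso}, index=pd.Index(ids, name="island_id"))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_counts(
    config: ScenarioConfig, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Counts, metadata and ground truth under area-dependent selection.

    Selection: taxon fitness w_i = base_i * exp(beta * z_area * z(c_i)),
    normalised to island compositions; samples are
    Dirichlet(concentration * p_island) draws with multinomial counts at
    the configured depth. The soil mediator TP follows
    a * z(log10 area) + sqrt(1-a^2) * noise. Ground truth stores the
    exact (infinite-depth) island CWM expectations.
    """
    rng = config.rng(stream=2)
    islands = _island_frame(config, rng)
    z_area = _zscore(np.log10(islands["area"].to_numpy()))

    copies = traits["copy_number"].to_numpy(dtype=float)
    z_c = _zscore(copies)
    intent = traits["intent"].to_numpy()
    free = intent == "free"

    base = np.zeros(config.n_taxa)
    base[free] = rng.lognormal(0.0, config.base_abundance_log_sd, free.sum())
    if free.any():
        planted_mass = (
            config.planted_abundant_share * (intent == "abundant").sum()
            + config.planted_rare_share * (intent == "rare").sum()
        )
        base[free] *= (1 - planted_mass) / base[free].sum()
    base[intent == "abundant"] = config.planted_abundant_share
    base[intent == "rare"] = config.planted_rare_share

    a = config.mediation_a
    soil = a * z_area + np.sqrt(max(0.0, 1 - a**2)) * rng.standard_normal(config.n_islands)

    sample_rows, meta_rows, counts = [], [], []
    expected_cwm = np.zeros(config.n_islands)
    for k, island in enumerate(islands.index):
        w = base * np.exp(config.beta * z_area[k] * z_c)
        p_island = w / w.sum()
        expected_cwm[k] = float((p_island * copies).sum())
        for s in range(config.samples_per_island):
            alpha = np.maximum(config.concentration * p_island, 1e-8)
            p_sample = rng.dirichlet(alpha)
            counts.append(rng.multinomial(config.depth, p_sample))
            sample_rows.append(f"{island}_S{s}")
            meta_rows.append(
                {
                    "sample_id": f"{island}_S{s}",
                    "island_id": island,
                    "area": islands.loc[island, "area"],
                    "isolation": islands.loc[island, "isolation"],
                    "TP": soil[k],
                }
            )
    table = pd.DataFrame(
        np.array(counts), index=pd.Index(sample_rows, name="sample_id"), columns=traits.index
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    island_truth = islands.assign(expected_cwm=expected_cwm, TP=soil)
    truth = GroundTruth(
        traits=traits,
        island_table=island_truth,
        beta=config.beta,
        mediation={"a": config.mediation_a, "b": config.mediation_b, "c": config.mediation_c},
    )
    return table, metadata, truth


def generate_planted_network_data(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """A counts table with planted correlation blocks (and optional hubs).

    Taxa in a block share a latent per-sample factor with loading
    sqrt(rho_within), so their pairwise latent correlation is
    rho_within; hub taxa load equally on two blocks. Background taxa are
    independent. Counts are a strictly monotone transform of the latent
    values, so Spearman structure survives discretisation. Ground truth
    carries the expected within-block edge set, block membership and hub
    linkage.
    """
    if not 0 <= config.rho_within < 1:
        raise ValueError("rho_within must be in [0, 1)")
    rng = config.rng(stream=3)
    n_block_taxa = config.n_blocks * config.block_size
    if n_block_taxa + config.n_hubs > config.n_taxa:
        raise ValueError("block structure does not fit into n_taxa")
    n = config.n_samples
    ids = _taxon_ids(config.n_taxa)
    factors = rng.standard_normal((n, config.n_blocks))
    latent = np.empty((n, config.n_taxa))
    blocks: dict[str, int] = {}
    load = np.sqrt(config.rho_within)
    resid = np.sqrt(1 - config.rho_within)
    pos = 0
    for b in range(config.n_blocks):
        for _ in range(config.block_size):
            latent[:, pos] = load * factors[:, b] + resid * rng.standard_normal(n)
            blocks[ids[pos]] = b
            pos += 1
    hubs: dict[str, tuple] = {}
    for h in range(config.n_hubs):
        b1, b2 = h % config.n_blocks, (h + 1) % config.n_blocks
        # a pure bridge: loads fully and equally on both block factors, so
        # its latent correlation with members of either block is
        # sqrt(rho_within / 2)
        latent[:, pos] = (factors[:, b1] + factors[:, b2]) / np.sqrt(2)
        hubs[ids[pos]] = (b1, b2)
        pos += 1
    latent[:, pos:] = rng.standard_normal((n, config.n_taxa - pos))

    counts = np.rint(1000.0 * np.exp(0.5 * latent)).astype(int)
    table = pd.DataFrame(
        counts,
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id"),
        columns=pd.Index(ids, name="taxon_id"),
    )
    expected_edges = {
        frozenset((a, b))
        for a in blocks
        for b in blocks
        if a < b and blocks[a] == blocks[b] and config.rho_within > 0
    }
    truth = GroundTruth(expected_edges=expected_edges, blocks=blocks, hubs=hubs)
    return table, truth


def generate_island_strategy(
    n_islands: int = 14,
    slope: float = 0.8,
    noise_sd: float = 0.1,
    intercept: float = 2.0,
    area_range: tuple = (1e3, 1e6),
    seed: int = 0,
) -> pd.DataFrame:
    """Island-level strategy index with a planted log10(area) slope.

    index = intercept + slope * log10(area) + N(0, noise_sd); the direct
    channel for regression-recovery checks where the island-level noise
    level is itself the stated quantity.
    """
    rng = np.random.default_rng([seed, 4])
    lo, hi = area_range
    areas = 10 ** rng.uniform(np.log10(lo), np.log10(hi), n_islands)
    index = intercept + slope * np.log10(areas) + rng.normal(0, noise_sd, n_islands)
    ids = [f"TK{i:02d}" for i in range(n_islands)]
    return pd.DataFrame(
        {"area": areas, "index": index}, index=pd.Index(ids, name="island_id")
    )


def generate_mediation_data(
    a: float = 0.6,
    b: float = 0.5,
    c: float = 0.0,
    n: int = 500,
    seed: int = 0,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Observed-variable mediation chain area -> soil -> strategy (+ direct).

    Structural equations on standardized scales:
    soil = a*z(log area) + e1, strategy = b*soil + c*z(log area) + e2,
    with unit-variance construction (residual sds sqrt(1-a^2) and
    sqrt(1 - b^2 - c^2 - 2abc)). ``noiseless`` drops both residuals for
    exact-coefficient checks.
    """
    rng = np.random.default_rng([seed, 5])
    log_area = rng.uniform(3, 6, n)
    z_area = _zscore(log_area)
    resid_soil = 1 - a**2
    resid_strat = 1 - b**2 - c**2 - 2 * a * b * c
    if min(resid_soil, resid_strat) < 0:
        raise ValueError("mediation coefficients imply negative residual variance")
    e1 = 0.0 if noiseless else np.sqrt(resid_soil) * rng.standard_normal(n)
    e2 = 0.0 if noiseless else np.sqrt(resid_strat) * rng.standard_normal(n)
    soil = a * z_area + e1
    strategy = b * soil + c * z_area + e2
    return pd.DataFrame(
        {"area": 10**log_area, "log_area": log_area, "soil": soil, "strategy": strategy}
    )
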