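# microstrat

Trait-based microbial life-strategy biogeography for habitat-island
systems.

Giant karst collapse dolines (tiankengs), oceanic islands, forest
fragments and similar cliff- or matrix-bounded habitats behave as
islands for their soil microbiota. Beyond the classical species–area
relationship, the *functional* composition of these communities shifts
with island area and isolation: larger, wetter, nutrient-richer islands
favour fast-growing copiotrophs (r-strategists), smaller and more
stressed islands favour slow-growing oligotrophs (K-strategists).
`microstrat` packages the full analysis chain used to test that idea on
amplicon (ASV) data, for microbial ecologists who have a processed
feature table and want reproducible, testable strategy-level inference:

- **partition** taxa into abundant (mean relative abundance > 0.05%),
  rare (< 0.01%) and intermediate classes, with shared/unique set
  algebra across islands;
- **strategy indices**: the community-weighted mean (CWM) rrn operon
  copy number for bacteria, CWM = Σᵢ pᵢcᵢ / Σᵢ pᵢ over taxa with known
  copy number cᵢ (annotation coverage Σᵢ pᵢ always reported); the
  ectomycorrhizal/saprotroph abundance ratio E/S for fungi; and
  oligotroph/eutroph phylum ratios for either kingdom;
- **co-occurrence networks**: Spearman |ρ| thresholding (0.7 for
  bacteria, 0.5 for fungi) with Benjamini–Hochberg-controlled
  significance, greedy-modularity modules, within-module degree z-score
  Zᵢ and participation coefficient Pᵢ = 1 − Σₜ(kᵢₜ/kᵢ)², and keystone
  classification (module hubs Zᵢ > 2.5, connectors Pᵢ > 0.62, network
  hubs both) — plus bipartite function–host networks;
- **biogeography**: log-linear regressions y = a + b·log₁₀(area) with
  the solid/dashed significance bands (P < 0.05 / P < 0.10), seeded
  Mantel permutation tests, PCoA by Gower double-centering, and
  observed-variable mediation path analysis
  (area → soil → strategy, plus a direct path) via per-equation OLS on
  standardized variables;
- **simulation**: a fully seeded generator planting copy-number–area
  selection, guild composition, correlation blocks with hubs, abundance
  classes and a mediation chain, so every stage has ground truth to
  recover.

The statistical estimators follow scikit-learn conventions
(`fit`, fitted attributes with trailing underscores, `get_params`) and
compose with sklearn tooling; module-level functions wrap them for
one-liners, and a thin `microstrat` CLI wraps the common steps.

## Worked example

```python
import microstrat as ms
from microstrat import simulate as sim

config = sim.ScenarioConfig(seed=42)           # 14 islands x 3 samples, beta = 1
traits, taxonomy = sim.generate_taxa(config)
table, metadata, truth = sim.generate_counts(config, traits)

clf = ms.AbundanceClassifier().fit(table)
print(clf.labels_.value_counts().to_dict())

indices = ms.strategy_indices(table, copy_map=traits["copy_number"])
per_island = ms.island_aggregate(indices, metadata)
fit = ms.fit_loglinear(per_island["area"], per_island["cwm_copy_number"])
print(f"slope={fit.slope_:.2f}  R2={fit.r_squared_:.2f}  p={fit.p_value_:.2g}  ({fit.significance_})")
```

prints

```
{'abundant': 172, 'rare': 88, 'intermediate': 40}
slope=2.13  R2=0.86  p=2e-06  (significant)
```

The generator planted positive selection (β = 1) of log₁₀ area on copy
number, so island-level CWM rises significantly with area: the fitted
slope of 2.13 copies per decade of area, with R² = 0.86 and
P = 2 × 10⁻⁶, lands in the "significant" band — the r-strategist shift
the index is designed to detect. Setting `beta=0` makes the same
regression non-significant at the nominal rate.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on the default synthetic
scenario for the given seed — generation, abundance partition, strategy
indices, the CWM–area regression, the thresholded co-occurrence network
with keystones, the Mantel test against the soil mediator, PCoA and the
mediation path model — printing a run summary and writing the result
JSON to `--out`.
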