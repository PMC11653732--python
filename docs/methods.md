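# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.
It states no empirical result that the test suite does not itself
compute.

## Abundance partitioning

Taxa are classified by the unweighted mean of their per-sample
relative abundances, zeros included: strictly above 0.05% → abundant,
strictly below 0.01% → rare, intermediate otherwise. The mean over
per-sample proportions (rather than pooled counts) makes the
classification invariant to per-sample sequencing depth; thresholds
are recorded in the output for auditability, and boundary values fall
in the intermediate class because both inequalities are strict. The
scope of the mean (which samples are pooled) is whatever table the
caller passes, so per-group classifications are obtained by subsetting
first.

## Life-strategy indices

**Community-weighted copy number.** The rrn operon copy number is a
growth-rate proxy: few copies indicate oligotrophic K-strategists,
many copies copiotrophic r-strategists. The community value is the
abundance-weighted mean over taxa with a known copy number,
renormalised to the annotated fraction:

    CWM = sum(p_i * c_i) / sum(p_i),   coverage = sum(p_i)  (over known c_i)

Coverage is always reported, so a sample whose annotation covers only
a sliver of the community is visible rather than silently wrong. Taxa
missing from the copy-number map are retained in the coverage
accounting, never dropped; lookup falls back from taxon id to genus
when a taxonomy is supplied, because copy-number references are keyed
by named taxa rather than ASVs. An unweighted ("presence") average
over annotated taxa is available as an alternative weighting; the
abundance-weighted form is the default because the index is meant to
describe where the community's biomass sits on the r–K axis, not its
species list.

**Ectomycorrhizal/saprotroph ratio (E/S).** Fungal guild annotations
are free-form and frequently compound, so labels are matched
case-insensitively on substrings: anything containing
"ectomycorrhizal" counts as E (K-strategists), anything containing
"saprotroph"/"saproph" as S (r-strategists), and compound labels
containing both are excluded — the conservative reading of a
multi-guild annotation. The ratio is the summed relative abundance of
E over S; a zero saprotroph sum makes it undefined and the result is
flagged with the reason instead of returning an infinity.

**Phylum strategy ratios.** Fixed phylum sets define
oligotroph/eutroph membership: for bacteria K =
{Acidobacteria, Actinobacteria, Planctomycetes, Chloroflexi} and r =
{Bacteroidetes, Gemmatimonadetes, Firmicutes}; for fungi K =
{Basidiomycota}, r = {Ascomycota}. Name matching tolerates the newer
-ota nomenclature (Acidobacteriota ≡ Acidobacteria, Bacteroidota ≡
Bacteroidetes, …) through an explicit alias table rather than suffix
stripping, which would risk collisions.

**Island aggregation** is the unweighted mean of defined sample values
within each island, with the contributing n recorded per index;
regressions and path models operate on these island-level values.

## Co-occurrence networks and Zi-Pi roles

Networks are built from all-pairs Spearman correlations (average-rank
ties; p from the t approximation). An edge requires |ρ| above a
kingdom-level threshold (defaults 0.7 bacteria / 0.5 fungi) *and* a
Benjamini–Hochberg-corrected p < 0.05 over all candidate pairs; a
|ρ|-only rule is selectable (`correction="none"`, `alpha=None`)
but FDR-uncontrolled thresholding over thousands of pairs is not a
defensible default. A prevalence pre-filter (default: present in ≥ 20%
of samples) removes the double-zero-dominated taxa whose rank
correlations are mostly artefactual. Constant taxa have undefined
correlations; their pairs are excluded and the taxa recorded on the
graph. Isolated nodes are dropped.

Modules come from greedy Newman-modularity agglomeration over a graph
rebuilt with lexicographically sorted nodes, which makes the partition
deterministic; the `seed` argument is accepted and recorded for
interface stability but the algorithm draws no random numbers. The
partition used is stored with the network, since Zi and Pi are defined
relative to a partition, not an algorithm.

For node i in module s: Zi = (k_is − mean_s)/sd_s with the population
standard deviation over s's members and Zi ≡ 0 when sd_s = 0 (all
members interchangeable — NaN would poison downstream role calls);
Pi = 1 − Σ_t (k_it/k_i)². Roles use the conventional cutoffs: module
hub Zi > 2.5, connector Pi > 0.62, network hub both, peripheral
otherwise, with strict inequalities so boundary nodes stay peripheral.
Keystones are the non-peripheral nodes. Bipartite function–host
networks use the same machinery with candidate pairs restricted to
taxon × function, and BH correction applied over those pairs only.

## Biogeography

**Regressions.** Strategy/diversity indices are fit by OLS on
log₁₀(area) (or depth); p-values use the exact t distribution, which
matters at island-group sizes of 12–14. Significance bands follow the
display convention: significant P < 0.05, marginal 0.05 ≤ P < 0.10. A
constant response returns slope 0, R² 0, p 1 explicitly (the
correlation is otherwise 0/0).

**Mantel.** Pearson (default) or Spearman correlation of the
vectorized upper triangles; the null jointly permutes rows and columns
of the second matrix; two-sided inclusive p = (1 + #{|r*| ≥ |r|}) /
(1 + n_perm); 999 permutations by default and a mandatory seed. For
the Spearman variant the off-diagonal values are rank-transformed once
before permuting — a joint row/column permutation only rearranges the
off-diagonal multiset, so ranking and permuting commute. Environmental
distance is Euclidean on z-standardized variables (absolute difference
for a single variable).

**PCoA.** Gower double-centering of −d²/2, symmetric
eigendecomposition, axes scaled by √eigenvalue. Negative eigenvalues
(non-Euclidean dissimilarities such as Bray–Curtis) are reported
unchanged rather than corrected, and proportions explained are taken
over the positive spectrum only.

**Path analysis.** The mediation model (area → soil properties →
strategy index, plus a direct path) is a recursive DAG over observed
variables, fit as one OLS per endogenous variable on z-standardized
data. With no latent variables these per-equation estimates coincide
with the maximum-likelihood SEM path estimates, so the heavier SEM
machinery (and its fit indices) is deliberately out of scope. Indirect
effects are products of edge coefficients along each directed path;
total = direct + Σ indirect. Guards: acyclicity, complete-case
n ≥ max-parents + 2, and a condition-number limit (10⁸) on each parent
block to fail loudly on collinear mediators. All specified paths are
reported with their p-values and significance bands; no pruning.

## Synthetic data

The generator emulates the *processed* data layer of an island survey
— never reads, chimeras or denoising. The stated world: 14 islands
(two surveyed groups had 12 and 14), 3 samples per island (field
protocol was 2–6 plots), areas log-uniform over 10³–10⁶ m², isolation
50–300 m, 300 taxa, depth 10⁴ reads. Copy numbers are a discretized
log-normal on [1, 15] with median ≈ 3, matching genomic surveys; 15%
of taxa are ectomycorrhizal and 35% saprotrophic, a realistic soil
split; 35%/25% of taxa sit in oligotroph/eutroph phyla.

Selection acts multiplicatively on log fitness,
w_i = base_i·exp(β·z(log₁₀ area)·z(c_i)), so the expected island CWM
is strictly increasing in area for β > 0 and the planted CWM–area
relationship is approximately linear on the log₁₀ axis. Sample
compositions are Dirichlet(concentration × p_island) perturbations
with multinomial counts, so totals equal the depth exactly. The
concentration default (15) was calibrated once so the within-island CV
of sample CWM is ≈ 10%, and not revisited. Soil mediators follow
soil = a·z(log₁₀ area) + √(1−a²)·ε.

Planted abundance classes put taxa at fixed composition shares (1%
per abundant taxon; 10⁻⁸ per rare taxon) with median copy number, so
selection cannot move them across the class thresholds. The rare share
sits far below the rare band on purpose: any share under 1/depth is
observationally equivalent (zero expected reads), while the
heavy-tailed Beta marginal of a low-concentration Dirichlet at larger
shares can occasionally spike a planted-rare taxon past a threshold —
which would make exact-recovery checks flaky by construction rather
than informative.

Correlation blocks share a latent factor with loading √ρ (pairwise
latent correlation ρ); hubs load fully and equally on two block
factors (correlation √(ρ/2) to either block's members). Counts are a
strictly monotone transform of the latents, so the Spearman structure
survives discretisation. Direct island-level and mediation-chain
generators exist alongside the count-level one, because planting an
exact island-level slope or exact structural coefficients *through*
the multinomial channel would confound the stated noise levels.

What a green test does and does not establish: recovery tests show the
estimators invert this generative model at the stated sizes; they do
not show robustness to compositional artefacts, phylogenetic
correlation among traits, spatial autocorrelation between islands, or
guild/copy-number annotation error, none of which the generator
emulates. The fungal null scenario (guild composition independent of
area) checks the false-positive rate of the E/S–area regression, not
power.

## Numerical conventions and degenerate inputs

- Proportions: rows of the relative-abundance table sum to 1 within
  1e-12; samples with zero total are an error listing the offenders.
- Bray–Curtis between two all-zero samples is undefined → error; one
  all-zero sample yields distance 1 to any non-empty sample (warned).
- Shannon uses natural log; 0·log 0 ≡ 0.
- Zi with zero within-module variance is 0, not NaN (logged above).
- Classification, role and significance boundaries are strict
  inequalities throughout.
- All randomness flows through numpy Generators seeded from explicit
  integers; generator stages use independent `[seed, stream]` spawns
  so adding a stage never perturbs earlier draws.

## Known limitations

- Spearman co-occurrence ignores compositionality; SparCC-style
  inference is out of scope by design.
- Rarefaction, UniFrac and BIOM-HDF5 input are not supported; tables
  are plain TSV.
- The path model covers observed variables only — no latent
  constructs, no fit indices, no model selection.
- Copy-number and guild maps are consumed as user-supplied tables; the
  package does not re-implement the reference databases behind them.
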