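# Methods

This note records the models, conventions and numerical choices behind
`secretomics`, and what the synthetic ground-truth tests do and do not
establish about real data.

## Spectral-count proteomics

**aPSM construction.** Per-run PSM tables are aligned on the union of
identified proteins (missing entries are true zeros for counting
purposes). Normalization scales each run so its total spectral count
equals the mean total of the comparison set — the standard total-count
normalization for spectral counting; a median-ratio alternative is
available (`normalize_runs(..., method="median_ratio")`). Averaging
happens after normalization: aPSM[p, c] is the arithmetic mean of the
normalized counts of protein p over all runs of condition c, including
runs where it was not detected. Normalizing within the analysed run set
(rather than against any external reference) is an assumption; the
comparison set is whatever set of runs is passed in.

**Detection frequency.** A protein's frequency in a condition counts the
runs (biological × technical) with PSM > 0. The overlap (Venn) analyses
use frequency ≥ 2 by default. A `collapse_bio` flag counts biological
replicates with ≥ 1 detection instead; the default counts all runs
because the run is the unit in which identification happens.

**DAve and DCI.** DAve is read as (X − Y) divided by half the sum, i.e.
2(X − Y)/(X + Y). This is the only reading of the index that makes its
printed selection threshold (0.4) exactly equivalent to the printed
fold-change criterion (1.5) — solve |2(r − 1)/(r + 1)| = 0.4 to get
r = 1.5 — and that bounds the index in [−2, 2]. Both indices are defined
as 0 at X = Y = 0, so proteins absent from both conditions are never
selected. Thresholds act on absolute values; the sign carries direction
(positive = up in the first condition, which is by construction down in
the second).

**F-ratio screen.** The multi-condition feature screen is the per-protein
one-way fixed-effects ANOVA F (model mean square over error mean square)
on normalized per-run values, with p from the F distribution at
(k − 1, N − k) degrees of freedom, retaining F ≥ 4.5 and p ≤ 0.001. It is
deliberately a univariate screen, not a discriminant projection: its role
is to pick features for clustering. Constant profiles get F = 0, p = 1.

**Clustering.** Agglomerative clustering under Ward's criterion with
Euclidean distance (scipy linkage); merge ties resolve by scipy's
lowest-index convention so leaf order is reproducible. The reported
two-branch top split is the membership on either side of the final merge.

**Enrichment.** One-sided upper-tail hypergeometric p per term,
P(X ≥ k), with Bonferroni correction over the terms actually tested
(those with ≥ 1 member in the universe). The universe is the
dataset-specific background — by default the union of proteins passing
the frequency filter — because an external database background is neither
shippable nor appropriate for a closed synthetic experiment. Depletion is
out of scope.

## miRNA cargo

**QC and UMI collapse.** A read survives iff the adapter was found, the
insert is ≥ 16 nt and the UMI ≥ 10 nt; discards are tallied by the first
failing rule in that order. Unique molecules are counted by exact-match
distinct UMIs per (species, sample); no edit-distance collapsing of UMIs
is attempted, matching the simple aggregation the counting describes.
RPM uses the post-collapse unique-molecule library size.

**Differential enrichment.** The per-species test is a seeded two-sided
permutation test on the difference of group means of log2(RPM + 0.5):
exact enumeration when the number of group assignments is ≤ 20 (e.g.
3 + 3), otherwise 10,000 seeded permutations with the +1 correction;
Benjamini–Hochberg q-values; modulated = {q ≤ 0.05}. This in-repo test
replaces external count-model packages so the pipeline is self-contained;
it is conservative — at 3 + 3 the smallest attainable two-sided p is
2/20 = 0.1, so genome-wide FDR calls require the full donor ×
preconditioning layout (6 vs 6 per gestational stage) that the stage
contrast actually has. Species below 5 mean unique molecules across the
contrast are excluded by default: permutation tests have no resolution
there and their inclusion only inflates the multiple-testing burden.

**Stability.** "Variability" is fixed as the coefficient of variation of
RPM across all samples of a gestational stage (donors × preconditioning).
Species are stratified into low/dim/high enrichment by terciles of mean
log10 RPM; a species is stable when its CV is in the lowest quartile of
its stratum; the shared core is the intersection of stable sets across
stages. All four choices (metric, strata count, cut points, quantile) are
arguments and recorded in the output records.

## Bioenergetics

Rates are OLS slopes per minute, normalized per 1e6 cells; the default
fit window skips the first 60 s (equilibration) unless the trace would
drop below 3 points. ATP calibration is a linear fit over standards
(1e−10–1e−7 M by default); non-monotone standards are rejected and
responses outside the standard range are flagged as extrapolation (the
zero-ATP start of a synthesis trace is typically flagged, harmlessly —
it carries no slope information). P/O is computed per oxygen **atom**:
a molecular-O2 rate is doubled first. This is the convention under which
the coupled-mitochondria reference values are 2.5 (NADH-linked) and 1.5
(FADH2-linked). Inhibition percentages are clamped at 0 with the raw
value retained. Glucose/lactate use Beer–Lambert with the NAD(P)H
extinction coefficient 6.22 mM⁻¹cm⁻¹ (a literature constant, here
configurable); glycolytic yield is lactate released / glucose consumed,
2.0 for fully fermentative metabolism. Negative computed consumptions
are flagged, never clamped: they indicate an assay problem.

## Synthetic data: what it emulates, and what it does not

**Proteome generator.** 8 conditions ({fetal, perinatal} × {CM, EV} ×
{normoxia, hypoxia}) × 3 biological replicates × technical duplicates =
48 runs of ~20,000 PSMs (1000 proteins, mean 20 PSMs, log-normal spread
σ = 0.5 — per-run depth is a free parameter, not a measured one). Counts
are negative-binomial with var = m + φm², φ = 0.02 by default, i.e. a
per-run CV of ≈ 26% at the median protein — at the clean end of what
technical-duplicate spectral counting achieves. The choice is a power
calculation: with 6 runs per condition the sd of the log aPSM ratio is
≈ sqrt(2(1/m + φ)/6); at φ = 0.02 a fold-2 spike passes the 1.5-fold
(DAve 0.4) cut ≈ 94% of the time while a null protein passes ≈ 3–4%,
matching the generator's contract that default-design selection attains
≥ 90% sensitivity and ≤ 5% false selections. At φ ≥ 0.1 (common in noisy
biological material) no threshold on these indices achieves that
operating point — passing tests on the synthetic default therefore says
the implementation is correct, not that real secretome data is this
clean. Detection dropout is Bernoulli per protein-run (0.98), abundance-
independent by default with an abundance-linked option. A per-protein
log-normal CM↔EV factor (shift 0.2, σ = 0.4) gives the two compartments
distinct profiles, so Ward's top split separates CM from EV; it cancels
in within-compartment contrasts. Spiked proteins (10%, fold 2) are each
up in one gestational stage of one (compartment, oxygen) cell.

**miRNA generator.** 12 samples (2 stages × 2 preconditioning × 3
donors), 50,000 reads each, mean 1.5 reads per molecule (geometric
multiplicities), 12-nt UMIs unique per molecule within a species-sample,
fixed per-species insert sequences, exact-match adapter. Class mix
miRNA 35.5% / rRNA 36% / tRNA 10% / other 18.5%. The top 15 species
carry 64% of miRNA mass (geometric weights), the tail is Zipf-like;
8 core species just below the top block are generated with pure sampling
noise (the low-variability core), 24 mid-abundance species differ 4-fold
between stages, and all other species get log-normal σ = 0.1
sample-to-sample jitter. Planted QC violations: 5% no adapter, 3% short
insert, 2% short UMI. No sequencing-error or isomiR structure is
simulated; UMI collisions are avoided by construction, so collapse
counts are exact molecule counts.

**Respiration generator.** Linear O2 decline (1 nmol O2/min per 1e5
cells) and ATP growth at the preset stoichiometry × 2 × O2 rate, sampled
every 30 s over 9 points; luminescence through a linear calibration whose
standards span 1e−10–1e−7 M; additive Gaussian noise scaled to the
dynamic range of each trace (noise_cv). Presets: 2.5 (pyruvate+malate),
1.5 (succinate), 0.4 (uncoupled).

## Problem sizes and determinism

All stochastic tests fix seeds; every generator draws from one
`numpy.random.Generator` per design, so equal designs give byte-identical
outputs. Test and acceptance runs use the default designs above (48 runs
× 1000 proteins; 12 samples × 50k reads; 4 respiration replicates × 9
points), which the package processes in seconds; larger designs scale
linearly. The pipeline's summary JSON is schema-versioned and written
with sorted keys so reruns at one seed are byte-identical.

## Known limitations

- DAve/DCI have no variance model; the indices are faithful to their
  definitions, and no moderated or count-model alternative is offered by
  design.
- The permutation differential test is underpowered below ~6 samples per
  group at genome-wide FDR (see above).
- The stability strata (terciles, lowest-quartile CV) are a stated
  convention, not a recovered parameter of any external analysis.
- Reference-catalogue overlap fractions depend entirely on the supplied
  catalogue snapshot.
- The glycolytic yield definition (lactate/glucose) is a documented
  choice among reasonable normalizations.
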