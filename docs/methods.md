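# Methods

This note records the scientific and numerical choices behind `langnet`:
the analysis conventions, the synthetic generative model and what it does
and does not emulate, and the places where the design was genuinely open.

## Analysis conventions

**Region definition.** A region joins a network when the fraction of its
voxels carrying suprathreshold evidence strictly exceeds the overlap
threshold ("more than half" is read as `>`, applied uniformly to any
fraction such as 1/4 or 3/4).  Consistency maps count subjects whose
statistic strictly exceeds the map threshold (default t = 2.3) and
probability maps binarize inclusively at 0.5 by default (the threshold
names the cut, not an exclusion; both conventions are configurable).
Before any matrix is built, regions are excluded when they have fewer
than 150 voxels, fewer than 2 expression sampling sites summed across
donors, or appear on an explicit drop list (anatomical exclusions are
dataset-specific and therefore configured, not inferred).  Region ids are
kept in ascending order everywhere, so connectivity, similarity and
distance vectors over the same region set are always aligned.

**Expression aggregation.** Probe-level values are averaged per gene per
site per donor.  Sites are mapped to atlas labels through the volume
affine; sites on background are snapped to the nearest labeled voxel
within 2 mm (configurable), else left unassigned.  The default regional
value pools all sites of all donors ("averaged per gene and across
donors"); a donor-first mode (mean of donor means) is retained because
the phrase is ambiguous.  Differential stability (DS) of a gene is the
mean Pearson correlation of its regional profile over all donor pairs,
using pairwise-complete regions (at least 3 shared regions per pair).
The stability filter keeps the top 5% of genes by default, with
lexicographic tie-breaking so the count is exact; an absolute-cutoff
mode (`DS > c`) and a bottom-tail negative control are also provided.

**Connectivity.** Per subject, pairwise Pearson correlations of the
regional time courses are Fisher-transformed, with |r| clipped at
1 − 1e−7 so the transform stays finite (arctanh of the clip point is
≈ 8.406).  The diagonal is stored as zero and never vectorized.  Two
negative-edge conventions are implemented because the two cohorts of the
original design used different orders of operations: average signed
matrices then zero negative group edges, or zero per subject then
average.  Both yield symmetric nonnegative matrices; the factorial
pipeline runs one mode per cohort.

**Matrix correlation.** The match statistic is the average-rank Spearman
correlation of strict upper triangles (row-major; length R(R−1)/2).  The
distance-corrected variant rank-transforms both vectors and the
inter-center Euclidean distance, residualizes the two rank vectors on
the ranked distance by least squares with intercept, and reports the
Pearson correlation of residuals with a two-sided p on n − 3 df.  (The
original description names neither the rank nor the residualization
convention; Pearson-partial on average ranks is the standard choice.)
The random-gene-set null redraws equal-sized sets without replacement,
rebuilds similarity each time, and uses the add-one one-sided estimator
p = (#{null ≥ observed} + 1)/(B + 1); the observed statistic is computed
through the identical code path as the nulls so exact ties compare
exactly.

**Gene contribution.** GCI(g) = ρ(full set) − ρ(set − g), with removal
at the similarity-construction step.  The scan downdates per-region sums
and cross-products (O(R²) per gene instead of O(R²·|G|)); region
profiles are mean-centered first, which correlations ignore but which
keeps the sum-of-products arithmetic well conditioned.  Equivalence with
the naive rebuild-from-scratch definition is enforced in the test suite
to 1e−12.  Consensus requires strictly positive GCI in every analysis
(zeros excluded).  Cross-analysis GCI agreement uses Pearson r (Spearman
exposed); consensus-vs-rest contrasts use Welch's t with
Welch–Satterthwaite df.

**Downstream statistics.** The expression-specificity contrast is a
per-gene Welch t between disjoint region groups with a 95% CI of the
mean difference; the BH-FDR family is exactly the gene list supplied to
the call.  Cell-type specificity calls a gene for type c when its
expression is at least 1.5× the maximum over all other types (inclusive
ratio; ties and all-zero rows yield no call).

## The synthetic generative model

The generator's defaults are the study conditions of the package: 20
regions, 200 genes of which 20 are planted drivers, 6 donors with 2–5
sampling sites per region each, and two independent cohorts of 30
subjects × 240 timepoints.

A latent K-factor model (K = 3) couples the two data modalities.
Region loadings L (R × K, standard normal) define the ground-truth
connectivity Σ = cov2corr(LLᵀ/K + 0.3·I).  Driver genes' regional mean
profiles put a `coupling_strength` fraction (default 0.8) of their
variance on random directions in the same factor space; non-driver genes
carry independent Gaussian regional profiles.  This is the simplest
model under which "similar expression ⇒ stronger connectivity" is
literally true for drivers and exactly false at zero coupling.

**Spatial confound.** Region centers come from the atlas blocks (2 mm
voxels).  With `distance_confound_weight` w > 0, an exponential kernel
D = exp(−d/λ) (λ = `region_extent_mm`, 40 mm) is mixed into Σ with share
w/(1+w), and every gene's profile receives the same share of a smooth
spatial field drawn from N(0, D).  Both sides of the analysis then carry
a distance-driven component — which is precisely what the
distance-partialling stage exists to remove.  The kernel is positive
definite, so Σ remains a valid correlation matrix without projection.

**Donor noise and stability.** A donor's regional profile is the gene's
mean profile plus a donor-by-region Gaussian effect whose variance is
solved analytically from the gene's stability target: with unit-variance
profiles, the expected inter-donor correlation is
1/(1 + σ² + σ²_site/n̄), inverted for σ².  Drivers default to target
0.9; non-drivers draw targets uniformly between `stability_low` (0.05)
and `stability_high` (a "two_level" spectrum is available for planting
exactly two groups).  Targets ≤ 0 are clamped to a small positive value:
this additive model cannot produce negative stability.

**Gene baseline.** Each gene has a baseline level with SD 5 across
genes, shared by all regions.  This reproduces a salient feature of real
cortical microarray data: regional expression profiles over a large gene
panel correlate above 0.9 for every region pair, because between-gene
level differences dwarf regional modulation.  The floor is a large-panel
property — on the full 200-gene panel it holds; a 10-gene subset (5% of
200) cannot exhibit it because a sample correlation over 10 points is
too noisy, whereas the real analysis's selected panels (hundreds of
genes) can.

**Time series.** Subjects draw i.i.d.-in-time samples from N(0, Σ) plus
white noise (SD 0.5), which attenuates all observed correlations by a
common factor and leaves their ranking intact.  A non-PSD covariance is
rejected with a clear error.  All randomness flows from one master seed
through named spawned substreams (atlas, truth, expression, each
cohort), so every artifact is independently reproducible.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: hemodynamic autocorrelation and head
motion, microarray batch effects, spatial autocorrelation beyond the
single exponential distance term, hemispheric asymmetries, and the
text-mining noise of meta-analytic activation maps.  Synthetic evidence
masks for the region variants cover ~80% "core" regions at 60–100%
voxel coverage and the rest at 0–40%, producing overlapping but distinct
network definitions, as alternative definitions of the same functional
network do.

## Simulation sizes and calibration checks

Problem sizes used by the test suite were chosen to keep each check
statistically decisive at desk scale: the null-calibration experiment
uses 200 zero-coupling datasets with B = 200 null draws and checks the
5% rejection rate against the 95% binomial band; driver recovery uses 20
replicate studies at the default conditions and requires median AUC
≥ 0.9 for mean-GCI ranking plus hypergeometric consensus enrichment; the
distance-correction experiment uses 30 regions because the null floor of
mean |Spearman ρ| is √(2/(π·n_pairs)) — about 0.058 at 20 regions (190
pairs) and 0.038 at 30 regions (435 pairs), so 30 regions is the
smallest default-shaped problem on which "partial ρ centered near zero"
is distinguishable from the plain ρ inflation at the 0.05 level.  The
cross-cohort reproducibility simulation (the quantity
`scripts/acceptance.py` reports) uses 20 master seeds.

## Known limitations

The pipeline consumes cleaned region-level time series; fMRI
preprocessing is out of scope.  Laterality-based region definitions
(homotopic-pair asymmetry tests) are consumed as precomputed lists, not
derived.  Leave-one-out contributions are single-gene only — no
leave-k-out or Shapley-style attribution.  Spatial-autocorrelation-
preserving nulls (spin/variogram) are not implemented; the random-gene
null permutes gene identity, not space.  DS is computed on the supplied
region set, which may differ from the native structures of a given
donor atlas.
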