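# Methods

`leafscape` implements a complete leaf-shape quantitative-genetics analysis:
binary leaf silhouettes are quantified three ways (linear traits, normalized
elliptical Fourier descriptors, and an orientation-invariant
persistent-homology annulus descriptor), tree-level phenotypes are adjusted
for orchard position with a REML mixed model, and the adjusted phenotypes are
linked to genome-wide SNPs through mixed-model GWAS, GREML SNP heritability,
and rrBLUP genomic prediction.  A synthetic-data layer generates all inputs
with known structure, so every stage is testable without external data.  This
note records the models, the parameter choices that matter, and the limits of
what the synthetic validation shows.

## Linear traits

A silhouette's largest 8-connected component is measured for surface area
(foreground pixels x scale^2, cm^2), bounding-box length and width (petiole
included), and the full major/minor axes of the moment-matched ellipse of the
*blade* (petiole removed by morphological opening with a disk, radius
defaulting to 1.5% of the leaf's larger image extent, or by an explicit
petiole mask).  Aspect ratio is major/minor.  Leaf mass per area (g/cm^2) is
computed per tree only when all 10 leaves contributed surface area.  Within-
tree variability is the coefficient of variation, 100·sd/mean with the n-1
denominator.  Trees with fewer than 8 or more than 10 leaves are excluded.
The default scale is 118.11 px/cm (300 DPI flatbed scanning); it is a
parameter everywhere.

Contours are traced with Moore-neighbor following and Jacob's stopping
criterion from the topmost-then-leftmost boundary pixel, so consecutive
pixels are 8-adjacent and the trace is losslessly expressible as a Freeman
chain code.

## Elliptical Fourier descriptors

The closed boundary is decomposed into per-harmonic quadruples
(a_n, b_n, c_n, d_n) by evaluating the elliptic Fourier integrals over the
piecewise-linear traversal.  Two parameterizations are supported: chord
length (the chain-code convention, default) and uniform per-vertex steps.
The distinction matters: for an analytic ellipse sampled evenly in its own
angle parameter, the uniform parameterization reproduces (a1, d1) = (A, B)
exactly, while the arc-length parameterization of a 2:1 ellipse yields
a1 ≈ 1.83 — not an implementation error but a property of the integral.
Correctness tests against closed forms therefore use the uniform mode;
pipeline data uses the chord convention.

Normalization removes translation (DC terms zeroed), scale (a1 = 1),
rotation, and starting point via the first-harmonic ellipse, and
canonicalizes traversal to counter-clockwise (d1 >= 0).  Two ambiguities
remain in the first-harmonic frame: which axis is "major" and which end of
it leads.  All four quarter-turn candidates are generated; those with the
major axis on x (|d1| <= 1) are kept, and the candidate placing the larger
reconstructed area at positive x wins (leaves are ovate, so the wider
blade base lands on a consistent side).  Exact ties fall back to a
lexicographic comparison of coefficients, which is input-invariant.
Setting every b_n and c_n to zero removes bilaterally asymmetric variation;
reconstructions from the symmetric coefficients are mirror-symmetric about
the major axis.  Reconstruction accepts a per-harmonic amplification factor
(0 deletes a harmonic, 1 is neutral, >1 exaggerates it).  Feature matrices
for PCA are per-tree means of the flattened (a, d) series — 40 features at
the default 20 harmonics.

## Persistent-homology annulus descriptor

The contour is resampled to exactly 500 points at uniform arc length,
centered, and scaled.  Shape size is removed by centroid-size normalization;
internally the cloud is expressed in units of its RMS radius (centroid size
divided by sqrt(n)), in which the geometry of a closed outline is
resolution-independent: typical point radii are O(1) regardless of how many
points represent the contour.  All kernel parameters below are in these
units.

Each point receives a Gaussian neighbor density (bandwidth 0.05, self term
included).  Sixteen concentric Gaussian annulus kernels with centers
r_i = i/16 x 1.5 and width equal to the ring spacing multiply the density;
1.5 is the largest point radius observed over a calibration set of synthetic
leaves, so the outermost ring sits at the leaf tips.  Ring weights depend
only on the distance from the centroid, making the construction invariant to
rotation and reflection — for exact polygon inputs the descriptor is
bit-identical under rotation, a property the test suite asserts.

For each ring, a plane descends through 500 uniform levels from the ring's
maximum weighted density to zero; at each level the connected components of
the points strictly above the plane are counted (epsilon-neighbor graph,
epsilon = 2x the median nearest-neighbor distance; counts maintained
incrementally with union-find and verified against exhaustive
depth-first search on hundreds of random clouds).  The concatenated
16 x 500 = 8,000 integer curve is the descriptor; per-tree descriptors are
leaf means.

Two numerical guards make raster inputs behave like their underlying
polygons: traced contours are smoothed with a circular moving average whose
window is 1/250 of the contour length (resolution-proportional, so it
removes pixel jaggedness without eroding shape), and ring weights below 1%
of the peak density are clamped to zero, since values that small are
dominated by discretization noise and would otherwise seed spurious
components on near-empty rings.  With these guards, descriptors of the same
leaf rasterized at 1x and 2x resolution correlate above 0.99 for smooth
blades.  Finely serrated margins remain genuinely resolution-sensitive —
teeth are ~10 px at 300 DPI, and their density peaks change with resolution
(correlation ~0.97); this is a property of any density-based topological
summary at fixed physical tooth size, not of this implementation.

## Morphospaces and phenomic statistics

PCA centers but does not scale, uses the SVD, and fixes signs by making the
largest-magnitude loading of each component positive, so the identity of
per-PC extreme accessions is reproducible.  Trait correlation matrices are
Pearson with Bonferroni correction over the unique trait pairs displayed.
Allometry between log blade width and log blade length is tested with
standardized major axis (SMA) regression: slope = sign(r)·sd(y)/sd(x), CI by
inversion of the F statistic of the residual-fitted correlation, and the
slope = 1 (isometry) null tested via the correlation between y - x and
y + x.  Under bivariate normality with equal variances that correlation is
exactly zero, so the test holds its nominal size — the suite measures a
~5% rejection rate over 1,000 isometric simulations at n = 200.  Species
contrasts use the Mann-Whitney U test (exact permutation null when both
groups have <= 20 untied observations; normal approximation with tie
correction otherwise).

## Orchard simulation and REML adjustment

The synthetic orchard is an incomplete block design on an
n_rgrid x n_cgrid grid: every cell receives one of three replicated control
accessions (cycling), and the unreplicated accessions are dealt across
cells.  Observations add independent Gaussian row, column, cell, and
residual effects (variances var_r, var_c, var_rc, var_resid) to each
accession value, drawn per trait.

Phenotypes are adjusted with the mixed model

    phenotype ~ accession + (1 | rGrid) + (1 | cGrid) + (1 | rGrid:cGrid)

with accession fixed (cell-means coding).  The restricted likelihood is
maximized over the three variance ratios sigma_k^2/sigma_e^2 on the log
scale by bounded quasi-Newton with the residual variance profiled out;
tolerance 1e-13 on the objective.  Because every replicated tree occupies
its own grid cell in this design, the cell-interaction variance is exactly
confounded with the residual — the restricted likelihood is flat along
their sum.  The fitter resolves such ridges by a parsimony collapse: each
component is tentatively fixed at zero with the others re-optimized, and
the boundary is kept whenever it costs less than 1e-4 of -2 log-likelihood.
This makes estimates deterministic and collapses correctly to ordinary
accession means when no positional variance exists.  Least-squares means
are the GLS accession effects with random effects at their zero mean: one
adjusted value per accession regardless of tree count.  Singleton
accessions' adjusted values depend on grid-effect BLUPs learned from the
controls — the mechanism by which the adjustment beats raw means, which it
does in ~100% of simulation replicates at realistic positional variance.
The collapse check (no grid effects implies adjusted = raw means) is run
with near-noiseless replicate observations (residual variance 1e-6 of the
accession variance), because spurious boundary variance estimates scale
with the residual noise for any REML fitter.  The implementation is
cross-checked against lme4 + emmeans in the test suite.

## Genetics

Genotypes are additive codes {0, 1, 2}; missing values are mean-imputed per
SNP before matrix computations.  The synthetic architecture draws a shared
allele frequency per LD block (uniform in [maf_low, maf_high]) and builds
haplotypes by copy-with-mutation along the block (copy probability 0.9),
giving adjacent-SNP correlation ~0.9 within blocks and independence across
blocks.  The default block size is 10, mirroring the strong local LD of
dense genotyping-by-sequencing panels; it also sets the effective number of
independent segments that genomic prediction can exploit (with 2,000
independent markers and n = 500 the theoretical accuracy ceiling
sqrt(h^2 n/(n + Me)) would sit near 0.35 even at h^2 = 0.7).  Phenotypes
are y = sum beta_j g_j + e with Gaussian effects at 200 causal SNPs and the
residual scaled to the target heritability.

QC removes SNPs with MAF < 0.05 or > 90% heterozygous calls.  LD pruning
slides a 10-SNP window in steps of 3, removing the later SNP of any
still-retained pair with r^2 > 0.5 — deterministic, and verified against an
independent brute-force re-implementation.  Kinship is the VanRaden genomic
relationship matrix ZZ'/(2 sum p(1-p)); population structure is the top
PCs of the centered genotype matrix.

All mixed-model genetics share one eigendecomposition REML core: with a
single relationship matrix K = U S U', the covariance is diagonal in the
rotated basis and the restricted likelihood reduces to a 1-D profile over
the genetic-to-residual variance ratio, optimized by bounded scalar search
with both boundaries checked.  GREML heritability is
h^2 = Vg/(Vg + Ve), clamped to [0, 1] at boundary fits and flagged; its
standard error comes from the inverse expected information of (Vg, Ve) with
a delta-method transform.  GWAS fits the covariate-only null model once and
reuses its variance components for every SNP (the P3D approximation;
exact per-SNP REML is available behind a flag), testing each SNP by a
t-statistic from the generalized least squares fit with kinship plus the
top 3 genotype PCs as structure control.  Under a polygenic null in which
no tested SNP is causal, the empirical type-I error at alpha = 0.05 is
0.05 +/- 0.02.  The significance threshold is 0.05/Meff with Meff from
simpleM: the smallest number of leading eigenvalues of the SNP correlation
matrix reaching 99.5% of the total, computed blockwise (default 5,000
SNPs) and summed for large panels.

Genomic prediction is GBLUP with the VanRaden kinship — algebraically
identical to ridge-regression BLUP of marker effects, an identity the test
suite verifies numerically to 1e-6 by running both routes on the same
split.  Cross-validation is seeded k-fold (default 5 folds x 3 repeats);
accuracy is the Pearson correlation between predicted and observed
phenotypes on held-out folds.  A random-phenotype null (standard-normal
phenotypes pushed through the identical CV machinery) quantifies the
accuracy expected by chance; it centers on zero.

## Synthetic study population

`simulate_leaf_population` generates the default validation population:
80-100 trees, 8-10 leaves each, per-tree aspect ratios lognormal with
median 1.8 and sd(log AR) = 0.10 (a realistic between-accession spread for
an orchard collection), within-tree jitter 0.03 on the log scale, blade
scale jitter 5%, petioles attached, serration off by default (it is a
parameter).  On this population both descriptor PC1s track aspect ratio
(|r| ~ 0.95-0.99) and agree with each other (|r| ~ 0.93-0.97), with PH PC1
explaining ~60% of descriptor variance.  A structural point discovered
during design: EFD PC1 is driven by the d1 coefficient and is therefore
nearly linear in 1/AR, while PH PC1 responds nearly linearly in AR; over a
wide lognormal AR spread their mutual correlation is bounded by
cor(X, 1/X) < 1, so very diverse populations necessarily show weaker PC1
agreement no matter how precise the descriptors are.

What passing these tests does *not* show: synthetic blades are smooth
parametric ovals — real leaves carry venation shadows, scanning artifacts,
torn margins, and lobe-level shape variation that no parameter here
emulates; the genotype simulator has block-uniform LD and no relatedness
structure beyond drift; and positional effects are exchangeable Gaussians
rather than spatially smooth field gradients.  Results on real data depend
on those factors.

## Numerical choices and degenerate inputs

- Contour tracing returns a single pixel for one-pixel components and
  raises on empty images or tied largest components.
- Degenerate (collinear) blade masks, zero-perimeter contours, zero-variance
  phenotypes, non-PSD kinship matrices, and single-level random terms are
  rejected with typed errors (or a warning plus term drop, for the latter).
- PH curves start at 0 (nothing lies strictly above the maximum) and use
  strict inequality throughout, so zero-weight points never activate and an
  empty ring yields an all-zero curve.
- LD-pruning ties are broken by removing the downstream SNP; PCA signs,
  CV fold assignment, and all generators are deterministic given seeds.
- Pipeline runs are cached by content hash of (stage, config, inputs);
  reruns with unchanged configuration skip all stages.

## Problem sizes used in the validation suite

Simulations run at n = 500 individuals x 2,000 SNPs (20 replicates per
heritability level), 80-tree leaf populations with 8-10 leaves per tree,
1,000 replicates for test-size checks, and 50 replicates for the
positional-adjustment comparison — sizes at which every recovery property
stabilizes while the full suite completes in minutes on one CPU.
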