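# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `pericolor`, and what the synthetic-data tests do and do
not demonstrate.

## Image analysis

**Thresholding.** Scans are converted to luminance as the mean of R, G, B
scaled to [0, 1] (the simplest grayscale; the choice only needs to be
monotone in brightness). A plane `luminance ~ x + y` is fit by least
squares to a seeded random subsample (default 3,000 pixels, seed 0) to
capture smooth illumination trends; Otsu's split point on the de-trended
residuals of the whole image sets the offset, and a pixel is foreground
when its luminance exceeds **both** the fixed minimum (default 0.4) and
the trend surface. The two criteria are intersected because each guards a
different failure: the fixed minimum rejects dark debris under a bright
trend, the trend surface rejects bright background under a gradient. A
constant image has no split point; the threshold falls back to the global
mean and the result is flagged degenerate.

**Cleaning.** Opening with a radius-1 disk removes speckles, closing with
a radius-7 disk plus hole filling repairs interior gaps, and a final
radius-5 opening strips residual debris. The magnitudes (1, 7, 5) are
structuring-element radii in pixels, exposed in configuration; they suit
kernels tens of pixels wide.

**Splitting touching kernels.** Each connected component is examined on
its Euclidean distance transform. Markers are the h-maxima rising at
least `h_fraction` (default 0.2) of the component's distance maximum; a
watershed floods the inverted distance transform from them; finally,
adjacent regions are re-merged when the distance value at their shared
saddle reaches `merge_ratio` (default 0.92) of the shallower region's own
maximum — a ridge plateau inside one convex kernel produces saddles nearly
as deep as its maxima (merged), while two kernels joined by a thinner neck
do not (kept split). Kernel pairs fused more deeply than that neck
criterion stay merged; such blobs then fail the shape QC, which is also
what happens with real clumps.

**Landmarks.** The contour comes from marching squares at the 0.5 level;
kernels with fewer than 100 contour points are removed. The center of
mass is the mean of the contour coordinates (a mask-centroid alternative
is available behind a flag). The tip/base pair maximizes pairwise contour
distance (exact on the convex hull; ties broken by lowest contour index).
Which end is the base is decided by color — the endpoint whose 15% axial
slice is more yellow ((R+G)/2 − B larger by ≥ 3) carries the endosperm
cap — with a geometric fallback (the blunter end, i.e. the larger
end-slice, is the base) when color is uninformative. The width chord runs
from the contour point whose angle tip–center–point is within 5° of 90°
(closest to exactly 90° wins) through the center to the opposite contour
intersection. Kernels with no admissible width point, an empty sampling
region, or width exceeding length are flagged and removed rather than
measured.

**Color.** The sampling region keeps pixels whose normalized position
along the tip→base axis lies in [0.30, 0.85], excluding the tip zone and
the basal cap. Hue is the standard RGB→HSV sector formula on the mean
region RGB, scaled to [0, 360) degrees; achromatic means (R = G = B)
return 0 with a flag. Pericarp hues live around 24–42°, far from the
0/360 wrap, so plain arithmetic averaging is used — a documented
limitation if the package were pointed at hues near the wrap. Quality
control applies a per-image 1.5×IQR fence on length:width ratio and a
pooled 1.5×IQR fence on each of the mean R, G, B channels; both
multipliers are configurable.

## Qualitative genetics

A genetic model is a boolean expression over loci; in a DH population
each unlinked locus carries the functional allele with probability 1/2,
so the expected pigmented proportion is the exact rational fraction of
the 2^L equiprobable multilocus classes satisfying the expression. The
six standard models are 1:1 (`A`), 3:1 (`A or B`, the "two additive
genes" model), 1:3 (`A and B`), 1:7 (`A and B and C`), 5:3
(`A or (B and C)`) and 3:5 (`A and (B or C)`). Observed counts are tested
by one-way Pearson chi-square with df = 1 and no continuity correction
(the goodness-of-fit form applies none, and published p-values computed
this way confirm it). Model selection maximizes the p-value across
candidates; ties within 1e-6 are reported jointly. All six p-values are
always emitted so the ranking is auditable.

## Phenotypic analysis

BLUEs come from `y_ij = g_i + r_j + e_ij` with fixed lines and a random
replicate effect, fit by REML. The implementation profiles the variance
ratio λ = σ_rep²/σ_e² and exploits the design's structure — X'W⁻¹X is a
diagonal matrix minus a rank-r update, so each evaluation is
O(n + p·r²) — making ~1,300 lines essentially instantaneous where a
generic mixed-model routine with 1,300 fixed-effect columns is not.
`avsed` is the mean over all line pairs of the standard error of the BLUE
difference, from the full GLS covariance at the REML ratio.

Cullis heritability `h² = 1 − avsed²/(2σ_g²)` needs a line variance,
which a fixed-line model does not have; σ_g² comes from a companion REML
fit of the same data with the line effect random (two variance ratios,
optimized by Nelder–Mead on their logs, same low-rank algebra). Both fits
were validated against the balanced-ANOVA closed forms and statsmodels
MixedLM. Lines harvested in a single replicate are retained; with only
one replicate level in the whole data the model degenerates to per-line
means and is flagged.

Tukey letter displays use statsmodels' studentized-range pairwise test
with an insert-and-absorb compact-letter construction; groups of size 1
are excluded with a warning. The Spearman validation against 1–5 visual
darkness ratings uses midranks and is expected negative (darker = lower
hue = higher rating).

## QTL scan

QC removes markers with > 75% missing calls, minor allele frequency
< 5%, or monomorphism, then individuals with > 200 apparent crossovers
(allele switches between consecutive non-missing calls on ordered
markers) or > 15% missing data. Genotype probabilities come from a
two-state forward–backward HMM per chromosome: uniform prior, Haldane
transitions from map distances, symmetric genotyping-error emissions
(default 0.002), uninformative emissions at missing calls. Physical maps
are converted at a configurable 1 cM/Mbp.

The scan regresses the phenotype on P(A) at each marker (Haley–Knott);
with one regressor, `LOD = −(n/2) log10(1 − r²)`. Monomorphic positions
score 0; numerically perfect fits are capped at LOD 50 and flagged.
Thresholds are the (1 − α) quantile of genome-wide maximum LOD over
seeded phenotype permutations (default 1,000, evaluated as one matrix
product). Peaks are per-chromosome maxima above threshold; the default
95% Bayes credible interval is the smallest contiguous run holding 95% of
the normalized 10^LOD mass, with a LOD-drop interval also available. The
allele effect at a peak treats the genotype coefficient as random: REML
estimates the variance ratio and the BLUP shrinks the OLS slope by
λS/(1 + λS). The effect is the full A-versus-B contrast in hue degrees;
negative means the first parent's allele darkens, and that parent is
reported as the donor. Scanning is at marker positions only (no
pseudomarker grid), matching marker-resolution peak reporting.

LD r² is the squared Pearson correlation of dosage vectors
(pairwise-complete over missing; monomorphic markers yield NaN), and
variance explained is the adjusted R² of a BLUE-on-dosage simple
regression.

## Synthetic data: what it emulates

Kernel scans: ovoid kernels as piecewise superellipses (pointed tip
exponent 1.35, blunt base 3.2) on a near-black background (default RGB
(16, 15, 18), Gaussian pixel noise SD 2), with a yellow endosperm-cap
dome over the basal 12% of the length and a darker tip dome over the
apical 8%; body colors are exact-hue browns (R = 200, B = 50, G set by
the target hue, mean luminance ≈ 0.47 so the 0.4 threshold retains them).
Optional touching pairs place outlines in contact so the cleaning stage
joins them with a thin neck; debris blobs are ≤ 4 px; damaged kernels
lose a chord-cut chunk with exposed yellow endosperm along the face —
large enough that cleaning cannot repair it, as with real broken kernels.
Background brightness is a parameter, since scanner-to-scanner lighting
is not modeled physically.

DH populations: per chromosome, each line is a two-state Markov chain
over ordered markers with Haldane transition probabilities (start allele
fair coin), giving 1:1 marker segregation and map-consistent crossover
counts. The qualitative pigment class evaluates the genetic model at
designated causal markers; quantitative hue is baseline − Σ(carried QTL
effects) + replicate effect + residual, with defaults baseline 34°,
replicate SD 0.5°, residual SD 1°, genotyping-error rate 0.002,
missingness 0.02, two replicates with 33% of lines harvested in both
(the remainder only in replicate 1). A 1–5 visual rating is generated as
a monotone decreasing function of true hue with scorer noise (SD 0.3).

What passing tests show — and do not. The simulations demonstrate that
the measurement chain is unbiased and calibrated **under the generator's
assumptions**: convex single-cut kernels, spatially uniform per-kernel
color, additive unlinked QTL, Gaussian noise, Haldane recombination
without interference. They do not certify performance on real scans with
specular highlights, dust films, strongly non-convex or overlapping
kernel heaps, segregation distortion, or linked/epistatic QTL. Simulation
sizes used by the test suite and acceptance script (100 scans of 12
kernels; 30–100 populations of 150 lines; one 1,300-line design-scale
fit; 400–1,000 permutations) were chosen as the smallest sizes at which
the binomial/simulation error of each check is comfortably below its
tolerance.

## Numerical choices and degenerate inputs

Seeds are explicit everywhere randomness exists (subsampling, generators,
permutations); identical seeds give bit-identical outputs. Maximal-
distance ties break to the lowest contour index; width candidates break
to the angle closest to 90°; quantiles use numpy's default linear
interpolation. The REML ratio searches log-space within e^±25 (bounded),
and zero residual variance (noiseless data) yields avsed 0 rather than a
failure. Empty foregrounds, zero-kernel images, scans with no significant
peak, and constant permutation phenotypes are all valid results, not
errors; impossible kernel placement, causal loci absent from the map,
all-markers-removed QC and constant-rating correlations raise
immediately with named reasons.

## Known limitations

- Deeply fused kernel pairs (saddle ≥ 0.92 of the kernel half-width) are
  not split; they are removed by shape QC instead of being measured.
- Arithmetic hue averaging assumes hues far from the 0/360 wrap.
- The binary cob-glume trait can be scanned with the same LOD machinery,
  but LOD values for a 0/1 trait are approximate (linear-model
  likelihood on a binary response).
- VCF input is not implemented; genotypes are CSV matrices as produced
  by the generator.
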