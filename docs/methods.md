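# Methods

## Scope and model

`myophen` quantifies the muscle phenotype of a dystrophic mouse model
along six axes: fiber-size morphometry, internal-nuclei counts,
basal-lamina intensity ratios, endomysial fibrosis, respiratory
mechanics and body-weight growth, with a statistics layer that gates
significance by practical relevance. Segmentation itself is an input:
the pipeline consumes instance label masks (e.g. produced by a neural
segmenter) and provides only a classical watershed fallback so the
pipeline runs end-to-end without external model weights.

## Fiber morphometry

**Minimum Feret diameter.** The region outline is taken as the four
corner points of every member pixel, so an axis-aligned square of k
pixels measures exactly k pixel-widths. On the convex hull of these
points the minimal width over orientations is attained with a supporting
line flush with a hull edge; the implementation therefore minimizes,
over hull edges, the farthest vertex distance from the edge line
(rotating-calipers equivalent, exact — no angular discretization).
Lengths are reported in µm via the pixel size; tests compare against an
independent 0.05°-step projection-sweep oracle (agreement within 0.5%).

**QC filter.** A fiber is retained when it does not touch the image
border, is not isolated, and satisfies area ≥ 50 µm², solidity ≥ 0.85
and boundary roughness (Crofton perimeter of the region over that of its
convex image, clamped at 1) ≤ 1.25. All thresholds are configurable;
they are conservative defaults meant to remove segmentation artifacts
without biasing the size distribution. *Isolated* means no other
retained fiber centroid within 60 µm; isolation is pruned to a fixed
point, which makes the filter idempotent (a second pass removes
nothing). A non-finite radius disables the rule. The report lists every
removed fiber and the first rule it failed (border → isolation handled
last; area → solidity → roughness in between).

**Internal nuclei.** Within a fiber's bounding box the DAPI channel is
thresholded (Otsu by default); connected components of at least 8 µm²
count as nuclei, and a nucleus is *internal* iff its centroid lies
deeper than a 2 µm erosion margin inside the fiber (sub-sarcolemmal
nuclei sit at the membrane; 2 µm matches the lamina width scale).
Depth is a Euclidean distance transform computed with a one-pixel
background pad so the fiber's own bounding box never masquerades as
interior. Both the count and count/area are emitted, since "nuclear
density" can mean either.

**Patches.** Fibers are assigned to patches (512 px default) by
centroid for bookkeeping; every measurement is made on the full-frame
region, so patching cannot change any value (tested).

## Basal-lamina band intensity

The measurement band is *outside* the fiber mask — the basal lamina
surrounds the sarcolemma — with width 2 µm, excluding pixels interior to
any fiber; where bands of abutting fibers overlap, shared interstitial
pixels contribute to both. Band membership uses the EDT to fiber pixels
with a net −0.25 px sub-pixel correction (half a pixel for the region
edge beyond the outermost pixel centers, minus the ~quarter-pixel
oversampling of a curved boundary by center-to-center distances); this
reproduces ideal annulus areas to ~1% on rasterized disks.

Background is estimated per channel from tissue pixels belonging to no
fiber and no band: the mode of a 64-bin histogram, or the median when
fewer than 1000 such pixels exist (sparse interstitium). Subtraction is
clipped at zero; the collagen-VI/perlecan ratio is computed per fiber
from subtracted means and marked undefined when the subtracted perlecan
mean is not positive. Ratios are aggregated per fiber first (never as a
ratio of group means), matching the automated per-fiber measurement
workflow.

## Fibrosis

The RGB Picro-Sirius-Red image is collapsed to a scalar *red-excess*
signal, `max(R − (G+B)/2, 0)` — bright on fibrillar collagen, near zero
on pale tissue, invariant to overall illumination. (A precomputed scalar
signal can be passed with `transform="identity"`.) Within each
500×500-px ROI, Li's minimum-cross-entropy threshold is fitted to the
ROI's own histogram and the percent of above-threshold pixels over the
*full* ROI area is reported.

**Li threshold.** The standard fixed-point iteration on the
(min-shifted) intensities with convergence tolerance 0.5; on
integer-valued images the converged value is snapped to the integer cut
minimizing the cross-entropy objective and canonicalized to the smallest
cut attaining the minimum (the objective is exactly flat across
histogram gaps, where any cut yields the same partition). On bimodal
integer images the result equals an exhaustive scan over all cuts
(tested exactly, 50 random images).

**Degenerate-ROI guard.** An ROI whose dynamic range is below 5% of the
whole-raster range, or below 16 intensity units outright (≈6% of the
8-bit scale), contains no stain to threshold; it is reported as 0% with
a `below_signal` flag rather than letting Li split noise into ~50%
"fibrosis". ROI placement is either a user-supplied origin list
(mirroring manual window movement) or automatic tiling (stride = ROI
size, optionally restricted to a tissue mask).

## Respiratory indices

Per breath, `pause = (Te − tR)/tR` and `Penh = (PEP/PIP)·pause`; both
dimensionless (invariant to common rescaling of times and of pressures
respectively). Sessions (nominally 60 × 5 s) are reduced to arithmetic
means; session pause/Penh are computed *from the session-mean
constituents*, matching the instrument's "average" parameter naming,
with per-breath-then-average variants also emitted. TV/weight divides
the mean tidal volume by body weight; log(Penh) is the natural log,
undefined (flagged) for Penh ≤ 0. End-inspiratory/expiratory pauses are
parsed but excluded from modelling by default (outlier-prone).

The longitudinal model is a linear mixed model of one parameter against
categorical age (time point), sex and genotype plus all two-way
interactions, with a random intercept per mouse (REML); with a single
age per mouse it falls back to OLS with a warning. Holm adjustment runs
over all non-intercept coefficients of one parameter's model. Residual
diagnostics (Shapiro normality; Spearman |residual|-vs-fitted) are
emitted; when either fails at α = 0.01 the model is refit on a 1%/99%
winsorized response and flagged robust — a pragmatic stand-in for a
robust mixed model, which the Python stack does not provide.

## Growth

The two-phase model is `weight = b0 + b1·age + b2·(age − bp)⁺`,
continuous at the breakpoint. The breakpoint is profiled on a 0.05-month
grid over candidates keeping at least two distinct ages on each side
(the minimum for identifiable phase slopes), with the profile assembled
from per-unique-age sufficient statistics (cost O(grid × ages),
independent of row count) and the minimum refined by parabolic
interpolation — without refinement the estimate is quantized to the
grid, which distorts bootstrap coverage whenever the truth lies near a
grid point. The response is mean-centered for numerical shift
invariance. The CI is a seeded case-resampling bootstrap over animals
(500 reps default, percentile method). A profile whose hinge buys
essentially nothing over a single line, or whose minimum sits on the
grid boundary, raises a `no_breakpoint` flag.

Phase-wise models regress weight on Age × Genotype within each phase
(closed on the left: phase 1 is [min, bp]), per sex and pooled, with
cluster-robust standard errors by mouse and Holm adjustment over the
genotype-involving terms. Grip strength is the mean of the (ten) force
readings divided by body weight; relative organ weights are organ/body
and organ/brain.

## Effect-size-gated statistics

Kruskal–Wallis (tie-corrected; H = 0, p = 1 on constant data) compares
all genotypes; pairwise Mann–Whitney tests use the tie-corrected normal
approximation **without** continuity correction, so `r = |z|/√N` is the
standard rank effect size (r ≈ 0.80 on the disjoint 3-vs-3 example).
Holm adjustment runs across the pairs of one family (one muscle × sex ×
metric). A comparison is *significant* when Holm-adjusted p < 0.05,
*relevant* when r > 0.1, and a *conclusion* only when both — the gate
that keeps per-fiber sample sizes in the thousands from promoting
trivial shifts. The coefficient of variation (SD/mean) carries a seeded
percentile-bootstrap 95% CI (2000 reps); groups are called different
when CIs are disjoint. Internal-nuclei category distributions (0/1/2+)
are compared pairwise by chi-square with the √(χ²/N) effect-size
analogue gated at the same 0.1; a seeded Monte-Carlo permutation p
replaces the asymptotic one when any expected cell is below 1.

## Synthetic data: what it emulates, and what it does not

Sections are a multiplicatively weighted centroidal Voronoi tessellation
(2 Lloyd iterations) of uniformly sampled seeds; weights follow the
log-normal size law (median `feret_median`, log-sd `feret_sigma`) so
fiber sizes disperse realistically. The canvas is auto-sized from the
sampled cell widths through a packing model `A ≈ 0.992·w²` (hexagonal
√3/2 with a fixed empirical correction measured on the generator); the
defaults (150 fibers, 40 µm median, 0.5 µm/px) give ≈1024 px. Cells are
shrunk by cutting the boundary-distance transform at the value whose
realized interstitial fraction is closest to the request; the reported
truth fraction is always the rasterized count. An unlucky layout that
squeezes a cell into a sliver is redrawn deterministically (same stream,
up to 5 attempts) before a tessellation failure is raised. Truth
minimum-Feret values come from a 0.5° projection sweep on the pixel
outline — independent of the calipers implementation they are used to
check.

Peripheral nuclei are placed with centroids within 1.8 µm of the
boundary, internal nuclei at ≥ 4.5 µm depth (making the internal /
peripheral distinction unambiguous relative to the 2 µm margin), with
≥ 8 µm centroid separation; nuclei are 2.5 µm-radius disks. Matrix
channels carry amplitude wherever the distance to the nearest fiber
boundary is within the lamina width; all channels add a 500 a.u. camera
offset and Gaussian noise (sd 150 a.u. default) and are clipped to
16-bit. PSR images cut a Gaussian-smoothed noise field at the matching
quantile, render fibrotic pixels in a red tone against a pale
blue-grey tissue tone, and return the rasterized truth fraction.

Breath tables draw each parameter around its design-cell mean with 10%
CV, with tR generated as a fraction of the same breath's Te so tR ≤ Te
always holds; 60 records per session, ages 6 and 12 months, 8 mice per
genotype × sex by default. Growth tables are exactly continuous
piecewise-linear per animal (breakpoint 2.2 months by default; male
wild-type 8.0 g/month juvenile slope versus 5.5 for mutants — a
deliberately unambiguous juvenile deficit — and ~0.5 g/month adult
slopes), plus per-animal intercepts (sd 1 g) and residual noise (sd 1 g).

Not emulated: optics (no point-spread function, no uneven illumination,
no chromatic effects), segmentation errors (truth masks are perfect),
staining artifacts and autofluorescence gradients, fiber typing, 3-D
structure, and real breath-to-breath autocorrelation. Passing tests
therefore demonstrate that the *computations* recover known ground truth
under the stated noise model — not that any particular real acquisition
meets that model.

## Numerical choices and degenerate inputs

- Seeds: every stochastic routine takes an explicit seed; identical
  inputs and seeds reproduce outputs bit-for-bit.
- Simulation sizes (200 replicates for calibration checks, 500-rep
  bootstraps, 10-seed recovery runs) balance Monte-Carlo error against
  runtime on a single core.
- Constant images raise for Li (no threshold exists); empty masks yield
  empty reports; single-pixel regions return one pixel-width with a
  warning; margins larger than the fiber yield 0 internal nuclei with a
  warning; sessions with ≠ 60 records warn (configurable to fail).
- Mann–Whitney U is cross-checked against scipy; the z and p are
  computed in-package because scipy's asymptotic variant applies a
  continuity correction that the closed-form effect size excludes.

## Known limitations

- The watershed fallback segmenter reaches ~90–95% one-to-one truth
  matching (IoU ≥ 0.7) on clean synthetic sections; it is a testing
  stand-in, not a replacement for a learned segmenter on real images.
- Per-fiber statistics pool fibers across animals; animal-level
  clustering is noted in reports but not modelled (a per-animal
  aggregation option exists upstream of the gate).
- The red-excess PSR transform assumes an approximately neutral
  non-fibrotic tone; strongly counterstained slides may need the
  hue-based alternative or a custom signal.
- The robust mixed-model fallback (winsorization) reduces, but does not
  eliminate, sensitivity to heavy-tailed residuals.
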