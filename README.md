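# myophen

Quantitative muscle phenotyping for mouse models of muscular dystrophy —
in particular collagen-VI-related disease, where the readouts are fiber
size and shape, internal (centralized) myonuclei, basal-lamina
collagen-VI intensity, endomysial fibrosis, respiratory mechanics and
body-weight growth.

`myophen` implements the full quantitative pipeline as a tested Python
library:

- **Fiber morphometry** — QC filtering of instance segmentations
  (border-clipped, isolated and irregular fibers removed), per-fiber
  **minimum Feret diameter** (exact rotating-calipers width of the convex
  hull of the pixel outline) and **internal-nuclei counts** (DAPI
  components whose centroid lies deeper than a 2 µm margin inside the
  fiber).
- **Basal-lamina intensity** — collagen VI and perlecan means in a 2-µm
  peripheral band around each fiber, background-subtracted, and their
  per-fiber ratio (collagen-VI deficiency lowers this ratio against the
  perlecan reference).
- **Fibrosis** — percent Sirius-red-positive area per 500×500-px ROI,
  thresholded with **Li's minimum-cross-entropy** method on a red-excess
  signal.
- **Respiratory indices** — whole-body plethysmography sessions reduced
  to means; `pause = (Te − tR)/tR` and `Penh = (PEP/PIP)·pause`; linear
  mixed models (age, sex, genotype + interactions; random intercept per
  mouse) with Bonferroni–Holm adjustment.
- **Growth** — continuous two-segment regression of body weight on age
  with a profiled breakpoint and case-resampling bootstrap CI; phase-wise
  Age×Genotype models; grip-strength normalization and relative organ
  weights.
- **Effect-size-gated statistics** — Kruskal–Wallis and pairwise
  Mann–Whitney tests with Holm adjustment, each carrying the rank effect
  size `r = |z|/√N`; a comparison *counts* only when it is both
  significant and relevant (`r > 0.1`), which matters when n is
  thousands of fibers.
- **Synthetic ground truth** (`myophen.synth`) — seeded generators for
  sections (weighted centroidal Voronoi fiber packing with calibrated
  interstitium, stained lamina bands, peripheral/internal nuclei), PSR
  images, breath tables and growth tables, with truths computed from the
  rasterized geometry. Every stage is testable with no real data.

## Worked example

```sh
python examples/05_growth_breakpoint.py
```

prints

```
breakpoint 2.21 months (95% CI 2.16-2.27); slopes 5.9 -> 0.5 g/month
phase 1, males: Age x HET slope difference -3.25 g/month (designed -2.5), Holm-adjusted p 4.3e-07
```

The generator built a cohort whose weights follow a continuous two-phase
trajectory kinked at 2.2 months; the profiled fit recovers the breakpoint
(2.21, CI covering truth) and the slowdown from ~6 g/month juvenile
growth to ~0.5 g/month adult growth. The phase-1 model then detects the
designed heterozygote growth deficit with a Holm-adjusted p-value.

Each script in `examples/` exercises one capability the same way
(morphometry, lamina ratios, fibrosis, plethysmography, gated
statistics). A thin CLI mirrors the library:

```sh
myophen simulate section --seed 7 --out-dir demo
myophen morphometry --image demo/section.ome.tif --mask demo/labels.tif --out fibers.csv
myophen compare --csv fibers.csv --metric min_feret_um
```

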