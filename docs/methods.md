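# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitopattern`, and what the synthetic generator does and does not
emulate.

## Coordinate system and radial profiling

The circular cancer island defines a normalized radial coordinate:
r = (distance to island center)/(island radius), with r = 0 the center,
r = 1 the tumor–stromal interface and r > 1 the stroma. The island is
detected as the largest connected component of the (Otsu-)thresholded
epithelial-marker channel, hole-filled; the center is its centroid and the
radius the equivalent-circle radius √(area/π). Coordinates are 0-based with
pixel centers at integers; physical lengths come from the pixel size in µm.

Radial profiles bin pixel intensities in half-open bins [lo, hi) of width
0.02 over [0, 1.2] (~50 bins inside the island, stroma visible to r = 1.2).
Empty bins carry NaN means. Before peak-finding the profile is smoothed by a
centered moving average over 5 bins (configurable); this suppresses
single-bin noise spikes at the cost of slightly flattening peaks that sit
within two bins of the island edge.

**Crossover radius.** The radius beyond which the untreated (NTX) profile is
significantly above uncoupled (FCCP) controls is the smallest bin center r\*
such that every bin from r\* to r = 1 rejects a one-sided Welch test
(NTX > control) at α = 0.05, computed from the per-bin summary statistics
(mean, SD, pixel count); replicate control profiles are pooled per bin. No
multiple-testing correction is applied across bins — the method reports a
single radius, and a correction would only shift it outward; this is a
deliberate, documented choice.

**Peak metrics.** The high-ΔΨm band is the contiguous radial run around the
smoothed peak where the mean exceeds baseline + 0.5·(peak − baseline)
(half-prominence, hence invariant to global intensity scaling). The baseline
is the control-profile island mean when a control is available, else the
minimum of the smoothed profile inside r ≤ 0.5. The normalized peak area of
a run [r₁, r₂] is r₂² − r₁², which is exactly the annulus area divided by
the island area. A flat profile is flagged degenerate with area 0.

## Regions and per-cell measurements

Default regions (configurable, reported in output metadata): center disc
r < 0.4, edge annulus 0.8 ≤ r ≤ 1.0, stroma r > 1; radii between are
"intermediate". Region areas for densities are computed analytically from
the fitted island radius, not by pixel counting.

Nuclei are segmented from smoothed DAPI (Gaussian σ = 1 px) by Otsu
thresholding and a distance-transform watershed seeded at distance peaks;
components below 30 px (at the default 2 µm/px; scale with the pixel area
for other resolutions) are discarded as debris. Cells are classified cancer
vs stroma by comparing mean pan-cytokeratin and vimentin in the nucleus
neighborhood (nearest-label expansion by 4 px, which cannot merge
neighbors). Per-cell nuclear means use the nucleus mask; cytoplasmic means
use a 3 px ring around the nucleus excluding all segmented nuclei.

Fold differences are (edge mean − background)/(center mean − background);
the background is the modal intensity (256-bin histogram peak) beyond
r = 1.2, which is robust to the stromal cells occupying a minority of that
area. The fold is therefore invariant to additive offsets and positive
scaling.

## Optical redox ratio

ORR = FAD/(FAD + NAD(P)H) per pixel where the sum is positive; undefined
pixels are masked and never enter statistics. Mitochondria are segmented
per cell by Otsu on FAD within the cell's neighborhood, restricted to
pixels above a background floor (3 robust noise SDs); Otsu operates on the
relative histogram, so the mask is invariant to global rescaling. Cells
with uniform FAD are flagged and excluded. Per-cell mitochondrial ORR
requires ≥ 10 mitochondrial pixels. ORR is computed on raw intensities by
default (background subtraction is exposed as an option via the fold
machinery but not applied), since bleed-through and background handling are
acquisition-specific.

## YAP/TAZ scoring

A cell is called "nuclear" when its nuclear/cytoplasmic-ring mean ratio is
≥ 1.0 — the symmetric cut, chosen because no operational threshold is
standard; it is exposed as `nc_threshold`. Percent-nuclear per region uses
Clopper–Pearson 95% intervals and flags regions with < 20 scored cells.
The percent-nuclear vs TMRM association is ordinary least squares over
sampled locations with the two-sided zero-slope t-test.

## Confinement growth model

Island growth follows Y = Y₀·e^{k(s)t}; with growth time fixed (t = 4 days,
matching the assay's readout day) and k(s) = −k′s linear in stromal density,
the observable is a single exponential decay Y(s) = Y₀·e^{−k′st}. Y₀ and k′
are the only free parameters. Fitting is Levenberg–Marquardt least squares
on the original scale (parameter/function tolerances 1e-12), initialized
from the log-linear OLS of ln Y on s (a convex surrogate that gives a
reliable start). R² is reported on the original scale, the convention for
nonlinear regression of such measurements. Flat data (all Y equal) are
flagged: k′ = 0, R² undefined. Units: with s in cells/mm² and t in days,
k′ is in mm²·cell⁻¹·day⁻¹; using densities per pattern instead rescales k′
by exactly the pattern area (verified as an invariance test).

## Statistical tests

Welch's t (samples or summary statistics, Welch–Satterthwaite df), one-way
ANOVA, Kruskal–Wallis and OLS delegate to scipy behind the package's result
types. Mann–Whitney U is implemented in-package: midrank ties; exact
p-values by full enumeration of all C(n₁+n₂, n₁) group assignments when
n₁+n₂ ≤ 12 (enumeration is cheap there; the cutoff is configurable);
otherwise the tie-corrected normal approximation with continuity
correction. Two-sided p-values double the smaller tail, capped at 1.
Pairwise p-values are reported unadjusted by default (a Holm option
exists), matching the convention of reporting per-panel tests.

## Synthetic µTSA generator

The generator emulates the study conditions so that every downstream stage
has a ground-truth oracle:

* **Geometry** — a 2 mm circular island (radius 1000 µm) in a field 2.4
  island-radii wide. Under stromal density s the island area is scaled by
  exp(−k′st) exactly (the confinement law holds to machine precision in
  ground truth).
* **Cells** — nuclei (8 µm radius, ±15% jitter) inside cytoplasm disks
  (16 µm), placed by sequential dart-throwing with a 2.6-nucleus-radius
  minimum separation (keeps jittered nuclei from touching, which the
  segmentation recall contract assumes). Cancer density rises linearly from
  800 (center) to 1200 cells/mm² (edge; the edge value grows with s);
  stroma is uniform at s outside r = 1.05.
* **TMRM/TOM20** — smooth radial fields baseline + amplitude·g(r) inside
  the island (the island is confluent at day 4, so the field is rendered
  per-pixel, not per-cell), a low constant (20 a.u.) outside. g is a
  Gaussian bump (peak position/width per condition), truncated at the
  island edge; a ramp kernel with a hard onset exists for
  separation-onset experiments. Amplitudes for the co-culture presets are
  calibrated so the background-subtracted edge/center folds equal the
  measured 3.1 (TMRM) and 1.7 (TOM20).
* **Condition presets** — `open_edge` (s = 0, peak r = 0.67, width 0.18),
  `coculture_25k/50k/100k` (s = 221/442/884 cells/mm², peaks
  0.85/0.91/0.92, narrowing widths), `pdms_confined` (uniformly low with a
  thin rim), `fccp_pair` (apply `apply_fccp` for the uncoupled control,
  which multiplies the expected TMRM by the residual fraction, default 0.1,
  and re-applies noise). The density-series generator maps s smoothly to
  peak position 1 − 0.33·e^{−0.0036s} and width 0.18·e^{−0.00145s},
  consistent with the preset anchors.
* **Metabolic channels** — each cell's true ORR is linear in radius (0.35
  at the center to 0.50 at the edge; stroma 0.30). Mitochondrial pixels
  (35% of the cytoplasm) carry FAD = M·ORR and NAD(P)H = M·(1 − ORR) at
  M = 200 a.u.; non-mitochondrial cytoplasm is 5× dimmer, so the pixelwise
  ratio equals the true ORR everywhere in the cell while FAD segmentation
  has 5:1 contrast.
* **YAP/TAZ** — per-cell nuclear fraction = clamp(0.19 + 0.0016·E[TMRM] +
  ε, 0, 1) with cell-level jitter ε ~ N(0, 0.12). Nucleus pixels get
  total·fraction, cytoplasm total·(1 − fraction), so the measured N/C ratio
  is fraction/(1 − fraction) and the ≥ 1.0 call corresponds exactly to
  fraction ≥ 0.5.
* **Noise** — per pixel, Poisson shot noise at `noise_gain` photons per
  a.u. (default 1; ∞ disables it) plus Gaussian read noise (default SD
  2 a.u.), clipped at zero. Absolute intensity units are nominal a.u.; the
  assay reports no camera calibration, so all intensity-scale defaults are
  arbitrary but fixed.
* **Determinism** — all randomness flows from one seed through named
  substreams (placement, noise, per-cell draws, uncoupler re-noise);
  identical parameters give bit-identical images and tables.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optics (no PSF, no depth sectioning, no
vignetting or flat-field error), cell morphology (disks, not real shapes;
no mitosis figures or debris), channel bleed-through, autofluorescence
background structure, cell motility/time-lapse, and the 3-D character of
clumped edges. Results on real micrographs additionally depend on staining
quality and the cancer/stroma marker contrast.

## Problem sizes used in tests and the acceptance script

Radial statistics run on the full 2 mm pattern at 8 µm/px (300² px);
cell-level analyses on 0.6–1.5 mm patterns at 2 µm/px, which resolves
nuclei (≥ 36 px) while keeping a single image under ~1 s to generate. The
confinement-recovery study uses 200 simulated experiments of 4 densities ×
3 replicates at 5% multiplicative noise; the type-I calibration of the
zero-slope test uses 1000 null draws at n = 50. These sizes were chosen to
make the Monte-Carlo bounds in the tests sharp while keeping the whole
suite fast on a laptop.

## Known limitations

* The crossover search uses per-bin summary statistics; with very large
  pixel counts per bin, minute systematic differences become "significant",
  so the estimated radius is a detection boundary, not an effect-size
  boundary.
* The peak-area threshold (half-prominence) is a convention; reported areas
  are comparable across conditions under a common threshold but are not
  absolute band widths.
* Watershed splitting assumes roughly convex nuclei; heavily overlapping
  nuclei (> ~30% area) merge.
* The growth model treats island area as the growth readout and ignores
  density changes inside the island; k′ is a lumped confinement constant,
  not a mechanistic parameter.
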