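# mitopattern

Quantitative image analysis for **micropatterned tumor–stromal assays
(µTSA)** — circular cancer-cell islands (≈2 mm) surrounded by stromal cells —
with a synthetic image generator that provides full ground truth for every
analysis stage.

Cancer cells at the tumor–stromal interface differ metabolically from those
at the island center: their mitochondrial membrane potential (ΔΨm, reported
by the TMRM dye), oxidative metabolism (optical redox ratio from NAD(P)H/FAD
autofluorescence), and mechanotransduction state (nuclear YAP/TAZ) are all
elevated at the interface, and the width of the high-ΔΨm band depends on how
strongly the surrounding stroma confines the island. `mitopattern` is for
researchers who need to quantify these spatial patterns from multi-channel
fluorescence micrographs — or to validate such a pipeline end-to-end on
simulated data.

## What it computes

* **Radial profiling** — island detection, normalized-radius maps
  (r = 0 center, r = 1 interface), binned radial intensity profiles, the
  significance **crossover radius** against FCCP-uncoupled controls
  (per-bin one-sided Welch tests), and the **normalized peak area** of the
  high-ΔΨm interface band (half-prominence rule; for a radial run
  [r₁, r₂] the island-area fraction is exactly r₂² − r₁²).
* **Region statistics** — DAPI watershed nucleus segmentation,
  cancer/stroma classification (pan-cytokeratin vs vimentin), center-disc /
  edge-annulus cell densities, and background-subtracted **edge/center fold
  differences** of any channel.
* **Optical redox ratio** — pixelwise ORR = FAD/(FAD + NAD(P)H), per-cell
  mitochondrial segmentation (per-cell Otsu on FAD), per-cell mitochondrial
  ORR and Welch comparison of edge vs center populations.
* **YAP/TAZ localization** — per-cell nuclear/cytoplasmic-ring intensity
  ratio, percent-nuclear per region with binomial CIs, and the regression
  of percent-nuclear against regional TMRM.
* **Confinement growth model** — island growth Y = Y₀·e^{k(s)t} with
  k(s) = −k′s, i.e. a single exponential decay in stromal density s:

      Y(s) = Y₀ · exp(−k′ · s · t)

  fitted by nonlinear least squares (`ConfinementDecayModel(...).fit()`,
  statsmodels-style Model/Results with `summary()`), plus the linear
  regression of normalized peak area against interfacial cell density.
* **Statistics** — Welch's t (samples or summary stats), Mann–Whitney U
  (exact enumeration for combined n ≤ 12, tie-corrected normal
  approximation above), one-way ANOVA, Kruskal–Wallis, OLS with the
  zero-slope t-test.
* **Synthetic µTSA generator** — seeded, fully deterministic multi-channel
  images (DAPI, panCK, vimentin, TMRM, TOM20, NAD(P)H, FAD, YAP) with
  Poisson + Gaussian noise and a `GroundTruth` object carrying per-cell
  records, geometry and the analytic radial profile.

## Worked example

```python
import mitopattern as mp
from mitopattern import simulate as sim, redox, yap as ym

params = sim.preset("coculture_50k", seed=1, island_radius_um=400.0, pixel_size_um=2.0)
image, truth = mp.generate_micropattern(params)
geom = mp.detect_island(image)

profile = mp.radial_profile(image, "TMRM", geom)
pm = mp.peak_metrics(profile)
print(f"TMRM peak at r = {pm.peak_radius:.2f}, normalized peak area {pm.normalized_peak_area:.3f}")
print(f"edge/center fold: TMRM {mp.fold_difference(image, 'TMRM', geom):.2f}, "
      f"TOM20 {mp.fold_difference(image, 'TOM20', geom):.2f}")

spec = mp.RegionSpec()
cells = mp.segment_nuclei(image)
cells = mp.annotate_regions(cells, geom, spec)
cells = mp.classify_cell_types(cells, image)
orr = redox.compute_orr(image["NADPH"], image["FAD"])
mito, _ = redox.segment_mitochondria(image, cells)
cells = redox.per_cell_orr(orr, cells, mito)
print(redox.compare_regions_orr(cells, spec).pvalue)

cells = ym.score_nc_ratio(image, cells)
for q in ym.percent_nuclear(cells, spec):
    print(f"nuclear YAP/TAZ {q.region}: {q.percent:.1f}% (n={q.n_scored})")
```

prints

```
TMRM peak at r = 0.91, normalized peak area 0.320
edge/center fold: TMRM 3.08, TOM20 1.69
5.8e-95
nuclear YAP/TAZ center: 5.3% (n=95)
nuclear YAP/TAZ edge: 84.3% (n=230)
```

The `coculture_50k` preset encodes a 442 cells/mm² stromal co-culture: the
ΔΨm band peaks near the interface (r = 0.91), the membrane potential is
~3.1-fold higher at the edge than the center while mitochondrial mass is
only ~1.7-fold higher (so the ΔΨm gradient is not a mass effect), the
mitochondrial redox ratio is higher in edge cells, and YAP/TAZ is nuclear in
most interfacial cells but few central ones.

Fitting the confinement model to a simulated stromal-density series:

```python
densities = [0.0, 221.0, 442.0, 884.0]
members = sim.generate_density_series(mp.GeneratorParams(pixel_size_um=8.0, seed=1), densities)
obs = [(s, mp.detect_island(img).area_mm2) for s, (img, _) in zip(densities, members)]
print(mp.fit_exponential_decay(obs, t_days=4.0).summary())
```

```
Confinement decay fit: Y = Y0 * exp(-k' s t)
  n obs            : 4
  t (fixed, days)  : 4
  Y0               : 3.14092 (SE 0.000502)
  k' (mm²/cell/day): 0.000199967 (SE 1.1e-07)
  R² (orig. scale) : 1.0000
  converged        : True
```

A command-line interface mirrors the library
(`mitopattern simulate|radial|regions|orr|yap|fit-confinement|run`);
see `mitopattern --help`.

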