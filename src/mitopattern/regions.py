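"""Nucleus segmentation, center/edge region assignment and region statistics.

The assay contrasts cancer cells at the island center with those at the
tumor-stromal interface.  This module segments nuclei from the DAPI channel,
classifies each cell as cancer or stroma by its epithelial vs mesenchymal
marker signal, assigns radial regions (center disc, edge annulus, stroma),
and computes the region-level quantities: per-region cell densities,
background-subtracted edge/center fold differences, and treatment
time-courses compared by one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .image import MicropatternImage
from .geometry import IslandGeometry, radius_map
from .stats import one_way_anova, TestResult


class RegionError(ValueError):
    """Region specification or region contents invalid for the computation."""


@dataclass(frozen=True)
class RegionSpec:
    """Radial definition of the analysis regions in normalized radius.

    ``center`` is the disc [0, center_rmax); ``edge`` the annulus
    [edge_rlo, edge_rhi]; radii between the two are ``intermediate``;
    anything beyond 1 is ``stroma``.
    """

    center_rmax: float = 0.4
    edge_rlo: float = 0.8
    edge_rhi: float = 1.0

    def __post_init__(self):
        if not (0 < self.center_rmax < self.edge_rlo < self.edge_rhi <= 1.0):
            raise RegionError(
                f"need 0 < center_rmax < edge_rlo < edge_rhi <= 1, got {self}"
            )

    def label_of(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.full(r.shape, "intermediate", dtype=object)
        out[r < self.center_rmax] = "center"
        out[(r >= self.edge_rlo) & (r <= self.edge_rhi)] = "edge"
        out[r > 1.0] = "stroma"
        return out

    def area_mm2(self, region: str, radius_um: float) -> float:
        """Analytic region area from the island radius."""
        R_mm = radius_um / 1000.0
        if region == "center":
            return float(np.pi * (self.center_rmax * R_mm) ** 2)
        if region == "edge":
            return float(np.pi * R_mm**2 * (self.edge_rhi**2 - self.edge_rlo**2))
        if region == "intermediate":
            return float(np.pi * R_mm**2 * (self.edge_rlo**2 - self.center_rmax**2))
        raise RegionError(f"no analytic area for region {region!r}")


@dataclass
class CellTable:
    """Per-cell records plus the nucleus label raster they came from.

    ``df`` has one row per segmented nucleus: cell_id, centroid (x, y),
    nucleus_area_px, r_norm, region, cell_type, and measurement columns
    appended by later stages (per-channel nuclear/cytoplasmic means, N/C
    ratios, mitochondrial ORR).
    """

    df: pd.DataFrame
    labels: np.ndarray                  # 0 background, cell_id elsewhere
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cancer(self) -> pd.DataFrame:
        return self.df[self.df["cell_type"] == "cancer"]

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        return self.labels == cell_id

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")


# ------------------------------------------------------------- segmentation


def segment_nuclei(
    image: MicropatternImage,
    dapi_channel: str = "DAPI",
    min_area_px: int = 30,
    smooth_sigma: float = 1.0,
    threshold: float | None = None,
) -> CellTable:
    """Segment nuclei from the DAPI channel.

    Smoothed DAPI is thresholded (Otsu unless given), touching nuclei are
    split by a distance-transform watershed seeded at local maxima, and
    components below ``min_area_px`` are discarded.  An empty result is a
    warning-level outcome (empty table), not an error.
    """
    data = image[dapi_channel].astype(float)
    sm = gaussian(data, sigma=smooth_sigma, preserve_range=True)
    if threshold is None:
        if np.ptp(sm) == 0:
            return _empty_cell_table(image)
        threshold = threshold_otsu(sm)
    fg = sm > threshold
    if not fg.any():
        return _empty_cell_table(image)
    dist = ndimage.distance_transform_edt(fg)
    # seeds: distance-transform peaks, one per prospective nucleus; the
    # min_distance scales with the smallest admissible nucleus radius
    min_dist = max(2, int(round(np.sqrt(min_area_px / np.pi) * 0.8)))
    peaks = peak_local_max(dist, min_distance=min_dist, threshold_abs=1.0, labels=fg)
    maxi = np.zeros(fg.shape, dtype=bool)
    maxi[tuple(peaks.T)] = True
    seeds, _ = ndimage.label(maxi, structure=np.ones((3, 3)))
    labels = watershed(-dist, seeds, mask=fg)
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        keep[prop.label] = next_id
        cy, cx = prop.centroid
        rows.append((next_id, float(cx), float(cy), int(prop.area)))
        next_id += 1
    labels = keep[labels]
    df = pd.DataFrame(rows, columns=["cell_id", "x", "y", "nucleus_area_px"])
    return CellTable(df, labels, image.pixel_size_um)


def _empty_cell_table(image: MicropatternImage) -> CellTable:
    df = pd.DataFrame(columns=["cell_id", "x", "y", "nucleus_area_px"])
    return CellTable(df, np.zeros(image.shape, dtype=np.int32), image.pixel_size_um)


def annotate_regions(
    cells: CellTable, geometry: IslandGeometry, spec: RegionSpec
) -> CellTable:
    """Add normalized radius and radial region label per cell."""
    cx, cy = geometry.center_xy
    r = np.hypot(cells.df["y"] - cy, cells.df["x"] - cx) / geometry.radius_px
    cells.df["r_norm"] = r
    cells.df["region"] = spec.label_of(r.to_numpy())
    return cells


def classify_cell_types(
    cells: CellTable,
    image: MicropatternImage,
    panck_channel: str = "panCK",
    vimentin_channel: str = "vimentin",
    dilate_px: int = 4,
) -> CellTable:
    """Cancer vs stroma call per cell: mean pan-cytokeratin versus mean
    vimentin in the dilated nucleus neighborhood (epithelial beats
    mesenchymal)."""
    panck = image[panck_channel]
    vim = image[vimentin_channel]
    if len(cells) == 0:
        cells.df["cell_type"] = pd.Series(dtype=object)
        return cells
    grown = _dilated_labels(cells.labels, dilate_px)
    ids = cells.df["cell_id"].to_numpy()
    mean_ck = ndimage.labeled_comprehension(panck, grown, ids, np.mean, float, np.nan)
    mean_vim = ndimage.labeled_comprehension(vim, grown, ids, np.mean, float, np.nan)
    cells.df["panck_mean"] = mean_ck
    cells.df["vimentin_mean"] = mean_vim
    cells.df["cell_type"] = np.where(mean_ck > mean_vim, "cancer", "stroma")
    return cells


def _dilated_labels(labels: np.ndarray, dilate_px: int) -> np.ndarray:
    """Grow nucleus labels outward by ``dilate_px`` without merging
    neighbors (nearest-label expansion within the dilation distance)."""
    dist, (iy, ix) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    grown = labels[iy, ix]
    grown[dist > dilate_px] = 0
    return grown


def measure_channel(
    cells: CellTable,
    image: MicropatternImage,
    channel: str,
    ring_width_px: int = 3,
    prefix: str | None = None,
) -> CellTable:
    """Per-cell nuclear mean and cytoplasmic-ring mean of one channel.

    The cytoplasmic ring is the annulus of ``ring_width_px`` around each
    nucleus, excluding every segmented nucleus (neighbors included).  Cells
    whose ring is fully occluded get NaN ring means.
    """
    data = image[channel]
    prefix = prefix or channel.lower()
    if len(cells) == 0:
        cells.df[f"{prefix}_nuc_mean"] = pd.Series(dtype=float)
        cells.df[f"{prefix}_ring_mean"] = pd.Series(dtype=float)
        return cells
    ids = cells.df["cell_id"].to_numpy()
    nuc_mean = ndimage.labeled_comprehension(data, cells.labels, ids, np.mean, float, np.nan)
    grown = _dilated_labels(cells.labels, ring_width_px)
    ring = np.where(cells.labels > 0, 0, grown)  # exclude all nuclei
    ring_mean = ndimage.labeled_comprehension(data, ring, ids, np.mean, float, np.nan)
    cells.df[f"{prefix}_nuc_mean"] = nuc_mean
    cells.df[f"{prefix}_ring_mean"] = ring_mean
    return cells


# ----------------------------------------------------------------- measures


def cell_density(
    cells: CellTable,
    geometry: IslandGeometry,
    spec: RegionSpec,
    regions: tuple[str, ...] = ("center", "edge"),
    cancer_only: bool = True,
) -> pd.DataFrame:
    """Cancer-cell count per region divided by the analytic region area.

    Returns a frame of (region, n_cells, area_mm2, density_cells_per_mm2).
    """
    df = cells.cancer if (cancer_only and "cell_type" in cells.df) else cells.df
    rows = []
    for region in regions:
        area = spec.area_mm2(region, geometry.radius_um)
        if area <= 0:
            raise RegionError(f"region {region!r} has zero area")
        n = int((df["region"] == region).sum())
        rows.append((region, n, area, n / area))
    return pd.DataFrame(rows, columns=["region", "n_cells", "area_mm2", "density_cells_per_mm2"])


def estimate_background(
    image: MicropatternImage,
    channel: str,
    geometry: IslandGeometry,
    r_min: float = 1.2,
    n_bins: int = 256,
) -> float:
    """Modal intensity outside normalized radius ``r_min`` (robust to the
    stromal cells themselves, which occupy a minority of that area)."""
    data = image[channel]
    rmap = radius_map(geometry, data.shape)
    vals = data[rmap > r_min]
    if vals.size == 0:
        raise RegionError(f"no pixels beyond r = {r_min} to estimate background")
    hist, edges = np.histogram(vals, bins=n_bins)
    i = int(hist.argmax())
    return float(0.5 * (edges[i] + edges[i + 1]))


def fold_difference(
    image: MicropatternImage,
    channel: str,
    geometry: IslandGeometry,
    spec: RegionSpec = RegionSpec(),
    background: float | None = None,
) -> float:
    """Background-subtracted edge/center mean-intensity ratio.

    Invariant to adding a constant to the whole image (the background
    estimate absorbs it) and to positive global scaling.
    """
    data = image[channel]
    rmap = radius_map(geometry, data.shape)
    if background is None:
        background = estimate_background(image, channel, geometry)
    center = data[rmap < spec.center_rmax]
    edge = data[(rmap >= spec.edge_rlo) & (rmap <= spec.edge_rhi)]
    if center.size == 0 or edge.size == 0:
        raise RegionError("center or edge region holds no pixels")
    denom = float(center.mean()) - background
    if denom <= 0:
        raise RegionError("center mean does not exceed background; fold undefined")
    return (float(edge.mean()) - background) / denom


def region_timecourse(
    timepoints: list[tuple[float, MicropatternImage]],
    channel: str,
    geometry_channel: str = "panCK",
    spec: RegionSpec = RegionSpec(),
    subtract_background: bool = True,
) -> pd.DataFrame:
    """Per-timepoint region means of a channel across replicate images.

    Each (time, image) contributes one mean per region; replicate images at
    the same nominal time become replicate rows.  Geometry is re-detected
    per image (treatments change island appearance over time).
    """
    from .geometry import detect_island

    if not timepoints:
        raise ValueError("need at least one timepoint")
    rows = []
    for t, img in timepoints:
        geom = detect_island(img, geometry_channel)
        rmap = radius_map(geom, img.shape)
        data = img[channel].astype(float)
        bg = estimate_background(img, channel, geom) if subtract_background else 0.0
        for region, sel in (
            ("center", rmap < spec.center_rmax),
            ("edge", (rmap >= spec.edge_rlo) & (rmap <= spec.edge_rhi)),
        ):
            vals = data[sel] - bg
            rows.append((float(t), region, float(vals.mean()), float(vals.std(ddof=1))))
    return pd.DataFrame(rows, columns=["time", "region", "mean", "sd"])


def timecourse_anova(timecourse: pd.DataFrame, region: str) -> TestResult:
    """One-way ANOVA of the replicate region means across timepoints."""
    sub = timecourse[timecourse["region"] == region]
    groups = [g["mean"].to_numpy() for _, g in sub.groupby("time")]
    return one_way_anova(groups)
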