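"""Optical redox ratio (ORR) imaging.

The ORR is FAD / (FAD + NAD(P)H) computed pixelwise from the two
autofluorescence channels; higher values indicate more oxidative
metabolism.  Mitochondrial regions are segmented per cell from the FAD
channel (bright subcellular hotspots) so the per-cell ratio is measured
over mitochondria only, and center vs edge populations are compared with
Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image import MicropatternImage, ShapeError
from .regions import CellTable, RegionSpec, _dilated_labels
from .stats import TestResult, welch_t, InsufficientDataError


@dataclass
class ORRMap:
    """Pixelwise redox ratio with validity and mitochondrial masks.

    ``ratio`` is defined (and lies in [0, 1]) only where ``valid`` is True
    (channel sum > 0); elsewhere it is NaN and must never enter statistics.
    """

    ratio: np.ndarray
    valid: np.ndarray
    mito_mask: np.ndarray | None = None

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.ratio, mask=~self.valid)


def compute_orr(nadph: np.ndarray, fad: np.ndarray) -> ORRMap:
    """FAD / (FAD + NAD(P)H) where the sum is positive; masked elsewhere."""
    nadph = np.asarray(nadph, dtype=float)
    fad = np.asarray(fad, dtype=float)
    if nadph.shape != fad.shape:
        raise ShapeError(f"channel shapes differ: {nadph.shape} vs {fad.shape}")
    if (nadph < 0).any() or (fad < 0).any():
        raise ValueError("autofluorescence intensities must be non-negative")
    total = nadph + fad
    valid = total > 0
    ratio = np.full(nadph.shape, np.nan)
    np.divide(fad, total, out=ratio, where=valid)
    return ORRMap(ratio=ratio, valid=valid)


def segment_mitochondria(
    image: MicropatternImage,
    cells: CellTable,
    fad_channel: str = "FAD",
    neighborhood_px: int = 6,
    background_floor: float | None = None,
    cancer_only: bool = True,
) -> tuple[np.ndarray, list[int]]:
    """Bright-FAD mitochondrial mask per cell.

    Within each cell's neighborhood (nucleus dilated by ``neighborhood_px``,
    restricted to pixels above a background floor), an Otsu threshold on the
    FAD intensity selects the mitochondrial hotspots.  Otsu operates on the
    relative histogram, so a global intensity rescaling leaves the mask
    unchanged.  Cells whose neighborhood FAD is uniform (no threshold) are
    flagged and excluded.

    Returns the boolean mask and the list of flagged cell ids.
    """
    fad = image[fad_channel].astype(float)
    if len(cells) == 0:
        raise ValueError("cell table is empty")
    if background_floor is None:
        # exclude extracellular pixels: anything within a few read-noise
        # widths of zero cannot be cytoplasm
        background_floor = max(1e-9, 3.0 * _robust_noise_sd(fad))
    grown = _dilated_labels(cells.labels, neighborhood_px)
    mask = np.zeros(fad.shape, dtype=bool)
    flagged: list[int] = []
    df = cells.cancer if (cancer_only and "cell_type" in cells.df) else cells.df
    for cell_id in df["cell_id"]:
        sel = (grown == cell_id) & (fad > background_floor) & (cells.labels == 0)
        vals = fad[sel]
        if vals.size < 2 or np.ptp(vals) == 0:
            flagged.append(int(cell_id))
            continue
        try:
            thr = threshold_otsu(vals)
        except ValueError:
            flagged.append(int(cell_id))
            continue
        sub = np.zeros_like(mask)
        sub[sel] = fad[sel] > thr
        if not sub.any():
            flagged.append(int(cell_id))
            continue
        mask |= sub
    return mask, flagged


def _robust_noise_sd(data: np.ndarray) -> float:
    """MAD-based noise scale of the dim background (lowest-decile pixels)."""
    low = data[data <= np.quantile(data, 0.1)]
    if low.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(low - np.median(low))))


def per_cell_orr(
    orr: ORRMap,
    cells: CellTable,
    mito_mask: np.ndarray,
    neighborhood_px: int = 6,
    min_mito_pixels: int = 10,
) -> CellTable:
    """Mean mitochondrial ORR per cell.

    A cell's mitochondrial pixels are the mask pixels within its
    neighborhood; cells with fewer than ``min_mito_pixels`` valid pixels get
    NaN (excluded from downstream comparisons).
    """
    grown = _dilated_labels(cells.labels, neighborhood_px)
    good = mito_mask & orr.valid
    means, counts = [], []
    for cell_id in cells.df["cell_id"]:
        sel = (grown == cell_id) & good
        n = int(sel.sum())
        counts.append(n)
        means.append(float(orr.ratio[sel].mean()) if n >= min_mito_pixels else np.nan)
    cells.df["mito_pixels"] = counts
    cells.df["orr_mito_mean"] = means
    return cells


def compare_regions_orr(
    cells: CellTable,
    spec: RegionSpec = RegionSpec(),
    regions: tuple[str, str] = ("edge", "center"),
) -> TestResult:
    """Welch's t-test of per-cell mitochondrial ORR, edge vs center."""
    df = cells.cancer if "cell_type" in cells.df else cells.df
    df = df.dropna(subset=["orr_mito_mean"])
    a = df.loc[df["region"] == regions[0], "orr_mito_mean"].to_numpy()
    b = df.loc[df["region"] == regions[1], "orr_mito_mean"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >= 2 scored cells per region, have {regions[0]}={a.size}, {regions[1]}={b.size}"
        )
    return welch_t(a, b)
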