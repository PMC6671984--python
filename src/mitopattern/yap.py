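"""YAP/TAZ nuclear-translocation scoring.

Nuclear localization of the mechanosensitive co-activators YAP/TAZ reports
the physical constraint a cell experiences.  Each segmented cell is scored
by the nuclear-to-cytoplasmic (N/C) mean-intensity ratio of the YAP/TAZ
channel; a cell is called "nuclear" when the ratio reaches a threshold
(default 1.0, the symmetric cut).  Per-region percentages carry binomial
confidence intervals, and the percent-nuclear values are regressed against
regional TMRM intensity to quantify the membrane-potential association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image import MicropatternImage
from .regions import CellTable, RegionSpec, measure_channel
from .stats import LinearFit, linear_regression, InsufficientDataError

#: N/C ratio at or above which a cell is called nuclear
NC_THRESHOLD = 1.0


def score_nc_ratio(
    image: MicropatternImage,
    cells: CellTable,
    yap_channel: str = "YAP",
    ring_width_px: int = 3,
    nc_threshold: float = NC_THRESHOLD,
) -> CellTable:
    """Per-cell nuclear and cytoplasmic-ring means, N/C ratio and the
    nuclear/cytoplasmic call.

    Cells with an occluded ring or zero signal in both compartments are
    excluded (NaN ratio).  The ratio is invariant to global multiplicative
    intensity changes.
    """
    cells = measure_channel(cells, image, yap_channel, ring_width_px, prefix="yap")
    nuc = cells.df["yap_nuc_mean"].to_numpy()
    ring = cells.df["yap_ring_mean"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((ring > 0) & np.isfinite(ring), nuc / ring, np.nan)
    # zero everywhere -> undefined, not "cytoplasmic"
    ratio = np.where((nuc == 0) & (ring == 0), np.nan, ratio)
    cells.df["yap_nc_ratio"] = ratio
    cells.df["yap_is_nuclear"] = np.where(
        np.isfinite(ratio), ratio >= nc_threshold, np.nan
    )
    return cells


@dataclass
class RegionPercentNuclear:
    region: str
    n_scored: int
    n_nuclear: int
    percent: float
    ci_low: float
    ci_high: float
    insufficient: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def percent_nuclear(
    cells: CellTable,
    spec: RegionSpec = RegionSpec(),
    regions: tuple[str, ...] = ("center", "edge"),
    min_cells: int = 20,
) -> list[RegionPercentNuclear]:
    """Percentage of scored cancer cells called nuclear per region, with a
    Clopper-Pearson 95% interval.  Regions with fewer than ``min_cells``
    scored cells are flagged insufficient (percentage still reported)."""
    df = cells.cancer if "cell_type" in cells.df else cells.df
    df = df.dropna(subset=["yap_is_nuclear"])
    out = []
    for region in regions:
        sub = df[df["region"] == region]
        n = len(sub)
        k = int(sub["yap_is_nuclear"].sum())
        if n == 0:
            out.append(RegionPercentNuclear(region, 0, 0, float("nan"), float("nan"),
                                            float("nan"), insufficient=True))
            continue
        pct = 100.0 * k / n
        lo = 0.0 if k == 0 else float(sps.beta.ppf(0.025, k, n - k + 1)) * 100
        hi = 100.0 if k == n else float(sps.beta.ppf(0.975, k + 1, n - k)) * 100
        out.append(RegionPercentNuclear(region, n, k, pct, lo, hi, insufficient=n < min_cells))
    return out


def regress_percent_nuclear_vs_tmrm(points) -> LinearFit:
    """OLS of percent-nuclear YAP/TAZ against regional TMRM intensity.

    ``points`` is a sequence of (tmrm_mean, percent_nuclear) pairs, one per
    sampled location; returns slope/intercept/R² and the two-sided
    zero-slope p-value.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (tmrm_mean, percent_nuclear) pairs")
    if pts.shape[0] < 3:
        raise InsufficientDataError("regression needs at least 3 locations")
    return linear_regression(pts[:, 0], pts[:, 1])
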