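"""Island detection, normalized-radius mapping and radial profiling.

The circular cancer island defines the coordinate system of the whole
analysis: normalized radius 0 is the island center, 1 the tumor-stromal
interface, and values above 1 the surrounding stroma.  This module fits that
geometry from the epithelial-marker channel, bins pixel intensities by
normalized radius, finds the radius beyond which the potentiometric signal
is significantly above the uncoupled control (the significance crossover),
and measures the normalized area of the high-potential annulus at the
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .image import MicropatternImage
from .stats import welch_t_from_stats


class DetectionError(ValueError):
    """No island-like component found in the detection channel."""


class BinningError(ValueError):
    """Profiles to be compared do not share bin edges."""


@dataclass
class IslandGeometry:
    """Fitted center and radius of the circular cancer island.

    Coordinates are 0-based with pixel centers at integer positions.
    """

    center_xy: tuple[float, float]      # (x, y) in pixels
    radius_px: float
    radius_um: float
    mask: np.ndarray                    # hole-filled island component
    touches_border: bool = False

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValueError("island radius must be positive")

    @property
    def area_mm2(self) -> float:
        return float(np.pi * (self.radius_um / 1000.0) ** 2)

    def to_dict(self) -> dict:
        return {
            "center_xy": [float(self.center_xy[0]), float(self.center_xy[1])],
            "radius_px": float(self.radius_px),
            "radius_um": float(self.radius_um),
            "area_mm2": self.area_mm2,
            "touches_border": bool(self.touches_border),
        }


@dataclass
class RadialProfile:
    """Binned mean/SD intensity versus normalized radius.

    Bins are half-open ``[lo, hi)``; ``mean`` is NaN where a bin holds no
    pixels.  ``normalization`` tags how the intensities were scaled.
    """

    bin_edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_pixels: np.ndarray
    channel: str
    normalization: str = "raw"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def smoothed(self, window: int = 5) -> np.ndarray:
        """Centered moving average of the mean, ignoring empty bins."""
        m = self.mean.copy()
        valid = np.isfinite(m)
        out = np.full_like(m, np.nan)
        half = window // 2
        for i in range(m.size):
            lo, hi = max(0, i - half), min(m.size, i + half + 1)
            seg = m[lo:hi][valid[lo:hi]]
            if seg.size:
                out[i] = seg.mean()
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean": self.mean,
                "sd": self.sd,
                "n_pixels": self.n_pixels,
            }
        )

    def plot(self, ax=None, show_sd: bool = True, **kwargs):
        """Plot mean intensity vs normalized radius (SD as a band)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.bin_centers
        ax.plot(c, self.mean, **kwargs)
        if show_sd:
            ax.fill_between(c, self.mean - self.sd, self.mean + self.sd, alpha=0.2)
        ax.set_xlabel("normalized radius")
        ax.set_ylabel(f"{self.channel} intensity ({self.normalization})")
        return ax


@dataclass
class PeakMetrics:
    """Location and normalized area of the high-potential interface band."""

    peak_radius: float
    peak_height: float
    run_radii: tuple[float, float]      # [r1, r2] of the above-threshold run
    normalized_peak_area: float         # (r2² - r1²): annulus area / island area
    baseline: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "peak_radius": float(self.peak_radius),
            "peak_height": float(self.peak_height),
            "run_radii": [float(self.run_radii[0]), float(self.run_radii[1])],
            "normalized_peak_area": float(self.normalized_peak_area),
            "baseline": float(self.baseline),
            "degenerate": bool(self.degenerate),
        }


# ------------------------------------------------------------------- detect


def detect_island(
    image: MicropatternImage,
    channel: str = "panCK",
    threshold: float | None = None,
) -> IslandGeometry:
    """Locate the circular island as the largest bright connected component.

    The channel is thresholded globally (Otsu unless a threshold is given),
    the largest component is hole-filled, and the equivalent-circle radius
    ``sqrt(area / pi)`` with the component centroid define the geometry.
    A component touching the image border is flagged, not rejected.
    """
    data = image[channel]
    if threshold is None:
        if np.ptp(data) == 0:
            raise DetectionError(f"channel {channel!r} is constant; nothing to detect")
        threshold = threshold_otsu(data)
    fg = data > threshold
    if not fg.any():
        raise DetectionError(f"no pixels above threshold in channel {channel!r}")
    lab = label(fg)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    comp = lab == biggest
    comp = ndimage.binary_fill_holes(comp)
    area = float(comp.sum())
    cy, cx = ndimage.center_of_mass(comp)
    radius_px = float(np.sqrt(area / np.pi))
    touches = bool(
        comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any()
    )
    return IslandGeometry(
        center_xy=(float(cx), float(cy)),
        radius_px=radius_px,
        radius_um=radius_px * image.pixel_size_um,
        mask=comp,
        touches_border=touches,
    )


def radius_map(geometry: IslandGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Normalized radius of every pixel (Euclidean distance to the island
    center over the island radius; > 1 in the stroma)."""
    if geometry.radius_px <= 0:
        raise ValueError("island radius must be positive")
    cy, cx = geometry.center_xy[1], geometry.center_xy[0]
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return np.hypot(yy - cy, xx - cx) / geometry.radius_px


# ------------------------------------------------------------------ profile


def radial_profile(
    image: MicropatternImage,
    channel: str,
    geometry: IslandGeometry,
    bin_width: float = 0.02,
    r_max: float = 1.2,
    restrict_mask: np.ndarray | None = None,
    normalization: str = "raw",
) -> RadialProfile:
    """Per-bin mean/SD/count of pixel intensities by normalized radius.

    Bins are half-open ``[lo, hi)`` spanning ``[0, r_max]``.  An optional
    boolean mask restricts the pixels (e.g. to cancer cells only).
    ``normalization='minmax'`` rescales the binned means to [0, 1].
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    data = image[channel]
    rmap = radius_map(geometry, data.shape)
    sel = rmap < r_max
    if restrict_mask is not None:
        sel &= restrict_mask.astype(bool)
    if not sel.any():
        raise ValueError("no pixels fall inside the profile support and mask")
    r = rmap[sel]
    v = data[sel].astype(float)
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((r / bin_width).astype(int), n_bins - 1)
    n = np.bincount(idx, minlength=n_bins).astype(int)
    s1 = np.bincount(idx, weights=v, minlength=n_bins)
    s2 = np.bincount(idx, weights=v * v, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (s2 - s1**2 / np.maximum(n, 1)) / np.maximum(n - 1, 1), 0.0)
    sd = np.sqrt(np.clip(var, 0.0, None))
    sd[n == 0] = np.nan
    if normalization == "minmax":
        finite = np.isfinite(mean)
        lo, hi = np.nanmin(mean), np.nanmax(mean)
        if hi > lo:
            mean = np.where(finite, (mean - lo) / (hi - lo), np.nan)
            sd = np.where(finite, sd / (hi - lo), np.nan)
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return RadialProfile(edges, mean, sd, n, channel, normalization)


# ---------------------------------------------------------------- crossover


def _combine_profiles(profiles: list[RadialProfile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool replicate profiles per bin (combined mean/SD/count from the
    per-bin summary statistics)."""
    ns = np.stack([p.n_pixels for p in profiles])
    means = np.stack([np.where(p.n_pixels > 0, p.mean, 0.0) for p in profiles])
    sds = np.stack([np.where(p.n_pixels > 0, p.sd, 0.0) for p in profiles])
    n_tot = ns.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = (ns * means).sum(axis=0) / np.maximum(n_tot, 1)
        ss_within = (np.maximum(ns - 1, 0) * sds**2).sum(axis=0)
        ss_between = (ns * (means - grand) ** 2).sum(axis=0)
        var = (ss_within + ss_between) / np.maximum(n_tot - 1, 1)
    return grand, np.sqrt(np.clip(var, 0, None)), n_tot


def crossover_radius(
    profile_ntx: RadialProfile,
    profiles_fccp: list[RadialProfile],
    alpha: float = 0.05,
) -> float | None:
    """Smallest bin center r* such that the untreated profile is
    significantly above the uncoupled controls at every bin from r* to the
    island edge (one-sided Welch test per bin at level ``alpha``; no
    multiple-testing correction, matching the single reported radius).

    Returns None when no such contiguous run reaches r = 1.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not profiles_fccp:
        raise ValueError("need at least one control profile")
    for pf in profiles_fccp:
        if pf.bin_edges.shape != profile_ntx.bin_edges.shape or not np.allclose(
            pf.bin_edges, profile_ntx.bin_edges
        ):
            raise BinningError("control profile bins differ from the NTX profile")
    f_mean, f_sd, f_n = _combine_profiles(profiles_fccp)
    centers = profile_ntx.bin_centers
    in_island = centers <= 1.0
    sig = np.zeros(centers.size, dtype=bool)
    for i in np.flatnonzero(in_island):
        n1, n2 = int(profile_ntx.n_pixels[i]), int(f_n[i])
        if n1 < 2 or n2 < 2:
            continue
        res = welch_t_from_stats(
            float(profile_ntx.mean[i]), float(profile_ntx.sd[i]), n1,
            float(f_mean[i]), float(f_sd[i]), n2,
            sided="greater",
        )
        sig[i] = res.pvalue < alpha
    island_idx = np.flatnonzero(in_island)
    last = island_idx[-1]
    # walk inward from the edge while every bin stays significant
    run_start = None
    for i in island_idx[::-1]:
        if sig[i]:
            run_start = i
        else:
            break
    if run_start is None or not sig[last]:
        return None
    return float(centers[run_start])


# ------------------------------------------------------------- peak metrics


def peak_metrics(
    profile: RadialProfile,
    baseline: RadialProfile | float | None = None,
    smooth_window: int = 5,
    threshold_factor: float = 0.5,
) -> PeakMetrics:
    """Peak position and normalized area of the high-potential band.

    The profile is smoothed (centered moving average), the peak is the
    maximum within r <= 1, and the band is the contiguous radial run around
    the peak where the smoothed mean exceeds
    ``baseline + threshold_factor * (peak - baseline)`` (half-prominence by
    default, hence invariant to global intensity scaling).  The area is the
    annulus area in normalized-radius units, ``r2² - r1²``, which is already
    the fraction of island area.

    ``baseline`` may be a control profile (its island-interior mean is
    used), a scalar, or None (minimum of the smoothed profile inside
    r <= 0.5).
    """
    centers = profile.bin_centers
    sm = profile.smoothed(smooth_window)
    inside = (centers <= 1.0) & np.isfinite(sm)
    if not inside.any():
        raise ValueError("profile empty inside the island")
    if isinstance(baseline, RadialProfile):
        b_in = (baseline.bin_centers <= 1.0) & np.isfinite(baseline.mean)
        base = float(
            np.average(baseline.mean[b_in], weights=np.maximum(baseline.n_pixels[b_in], 1))
        )
    elif baseline is None:
        core = inside & (centers <= 0.5)
        base = float(np.nanmin(sm[core])) if core.any() else float(np.nanmin(sm[inside]))
    else:
        base = float(baseline)
    idx_inside = np.flatnonzero(inside)
    i_pk = idx_inside[int(np.nanargmax(sm[inside]))]
    peak = float(sm[i_pk])
    if peak <= base:
        return PeakMetrics(float(centers[i_pk]), peak, (0.0, 0.0), 0.0, base, degenerate=True)
    cut = base + threshold_factor * (peak - base)
    above = np.zeros(centers.size, dtype=bool)
    above[inside] = sm[inside] > cut
    lo = i_pk
    while lo - 1 in idx_inside and above[lo - 1]:
        lo -= 1
    hi = i_pk
    while hi + 1 in idx_inside and above[hi + 1]:
        hi += 1
    r1 = float(profile.bin_edges[lo])
    r2 = float(min(profile.bin_edges[hi + 1], 1.0))
    return PeakMetrics(
        peak_radius=float(centers[i_pk]),
        peak_height=peak,
        run_radii=(r1, r2),
        normalized_peak_area=float(r2**2 - r1**2),
        baseline=base,
    )
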