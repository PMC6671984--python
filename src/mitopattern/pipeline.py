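"""End-to-end analysis pipeline.

One call runs: simulate (or load) -> island detection -> radial profile /
crossover / peak metrics -> segmentation, region assignment, densities and
fold differences -> per-cell redox ratio -> YAP/TAZ scoring -> confinement
fits (when a density series is requested).  Every output file carries the
seed and a hash of the configuration, and a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry as geo
from . import regions as reg
from . import redox, simulate, yap
from .growth import fit_exponential_decay, fit_peak_area_decay, linreg_peak_area_vs_density
from .image import MicropatternImage, read_image

log = logging.getLogger("mitopattern")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``preset`` (simulated input) or ``image_path`` must be set.
    ``density_series`` switches to the multi-density experiment and enables
    the confinement fits.
    """

    preset: str | None = "coculture_50k"
    image_path: str | None = None
    pixel_size_um: float | None = None          # override for loaded images
    density_series: list[float] | None = None   # e.g. [0, 221, 442, 884]
    seed: int = 0
    out_dir: str = "mitopattern_out"

    # analysis knobs
    bin_width: float = 0.02
    r_max: float = 1.2
    center_rmax: float = 0.4
    edge_rlo: float = 0.8
    edge_rhi: float = 1.0
    nc_threshold: float = 1.0
    threshold_factor: float = 0.5
    min_mito_pixels: int = 10
    alpha: float = 0.05
    t_days: float = 4.0
    write_images: bool = True
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**data)

    @property
    def region_spec(self) -> reg.RegionSpec:
        return reg.RegionSpec(self.center_rmax, self.edge_rlo, self.edge_rhi)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not change the analysis, so reruns into different directories
        stay comparable)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> str:
    return f"config_hash={config.config_hash()} seed={config.seed}"


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    payload = {"_provenance": _stamp(config), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_csv(path: Path, df: pd.DataFrame, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_stamp(config)}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def analyze_image(
    image: MicropatternImage,
    config: PipelineConfig,
    out: Path,
    tag: str = "",
    fccp_image: MicropatternImage | None = None,
) -> dict:
    """Single-image analysis; returns the report fragment and writes files."""
    spec = config.region_spec
    suffix = f"_{tag}" if tag else ""
    report: dict = {}

    geom = geo.detect_island(image, "panCK")
    report["geometry"] = geom.to_dict()
    _write_json(out / f"geometry{suffix}.json", geom.to_dict(), config)

    profile = geo.radial_profile(image, "TMRM", geom, config.bin_width, config.r_max)
    _write_csv(out / f"radial_tmrm{suffix}.csv", profile.to_frame(), config)

    baseline = None
    if fccp_image is not None:
        fccp_profile = geo.radial_profile(fccp_image, "TMRM", geom, config.bin_width, config.r_max)
        _write_csv(out / f"radial_tmrm_fccp{suffix}.csv", fccp_profile.to_frame(), config)
        r_star = geo.crossover_radius(profile, [fccp_profile], alpha=config.alpha)
        report["crossover_radius"] = r_star
        baseline = fccp_profile

    pm = geo.peak_metrics(profile, baseline, threshold_factor=config.threshold_factor)
    report["peak_metrics"] = pm.to_dict()
    _write_json(out / f"peak_metrics{suffix}.json", pm.to_dict(), config)

    # region-level quantities
    folds = {}
    for channel in ("TMRM", "TOM20"):
        if channel in image:
            try:
                folds[channel] = reg.fold_difference(image, channel, geom, spec)
            except reg.RegionError as err:
                folds[channel] = None
                log.warning("fold_difference(%s) failed: %s", channel, err)
    report["fold_difference"] = folds

    cells = reg.segment_nuclei(image)
    cells = reg.annotate_regions(cells, geom, spec)
    cells = reg.classify_cell_types(cells, image)
    report["n_cells"] = int(len(cells))

    density = reg.cell_density(cells, geom, spec)
    _write_csv(out / f"cell_density{suffix}.csv", density, config)
    report["cell_density"] = {
        row.region: row.density_cells_per_mm2 for row in density.itertuples()
    }

    # redox
    if "FAD" in image and "NADPH" in image:
        orr_map = redox.compute_orr(image["NADPH"], image["FAD"])
        mito, flagged = redox.segment_mitochondria(image, cells)
        cells = redox.per_cell_orr(orr_map, cells, mito, min_mito_pixels=config.min_mito_pixels)
        report["orr_flagged_cells"] = len(flagged)
        try:
            orr_test = redox.compare_regions_orr(cells, spec)
            report["orr_edge_vs_center"] = orr_test.to_dict()
        except Exception as err:
            report["orr_edge_vs_center"] = None
            log.warning("ORR region comparison failed: %s", err)

    # YAP/TAZ
    if "YAP" in image:
        cells = yap.score_nc_ratio(image, cells, nc_threshold=config.nc_threshold)
        pcts = yap.percent_nuclear(cells, spec)
        report["percent_nuclear"] = {p.region: p.to_dict() for p in pcts}

    cells.df.insert(0, "image_tag", tag or "main")
    _write_csv(out / f"cells{suffix}.csv", cells.df, config)
    if config.write_images:
        image.write_tiff(out / f"image{suffix}.tif")
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis; returns the full report dict.

    For a density series, each member is analyzed individually, then the
    island areas and normalized peak areas are fitted with the confinement
    decay and the peak-area-vs-edge-density regression is run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    if config.image_path is not None:
        image = read_image(config.image_path, pixel_size_um=config.pixel_size_um)
        report["input"] = str(config.image_path)
        report["image"] = analyze_image(image, config, out)
    elif config.density_series is not None:
        base = simulate.preset(
            config.preset or "coculture_50k", seed=config.seed, **config.generator_overrides
        )
        members = simulate.generate_density_series(base, config.density_series)
        obs_area, obs_peak, dens_points = [], [], []
        report["series"] = {}
        for s, (img, truth) in zip(config.density_series, members):
            tag = f"s{int(s)}"
            frag = analyze_image(img, config, out, tag=tag)
            report["series"][tag] = frag
            obs_area.append((s, frag["geometry"]["area_mm2"]))
            obs_peak.append((s, frag["peak_metrics"]["normalized_peak_area"]))
            edge_density = frag["cell_density"].get("edge")
            if edge_density is not None:
                dens_points.append((edge_density, frag["peak_metrics"]["normalized_peak_area"]))
        area_fit = fit_exponential_decay(obs_area, t_days=config.t_days)
        report["area_decay_fit"] = area_fit.to_dict()
        _write_json(out / "area_decay_fit.json", area_fit.to_dict(), config)
        if all(y > 0 for _, y in obs_peak):
            peak_fit = fit_peak_area_decay(obs_peak, t_days=config.t_days)
            report["peak_area_decay_fit"] = peak_fit.to_dict()
            _write_json(out / "peak_area_decay_fit.json", peak_fit.to_dict(), config)
        if len(dens_points) >= 3:
            lin = linreg_peak_area_vs_density(dens_points)
            report["peak_area_vs_edge_density"] = lin.to_dict()
            _write_json(out / "peak_area_vs_edge_density.json", lin.to_dict(), config)
    else:
        params = simulate.preset(config.preset, seed=config.seed, **config.generator_overrides)
        image, truth = simulate.generate_micropattern(params)
        fccp_image = None
        if config.preset == "fccp_pair":
            fccp_image, _ = simulate.apply_fccp(image, truth)
        report["preset"] = config.preset
        report["image"] = analyze_image(image, config, out, fccp_image=fccp_image)

    _write_json(out / "report.json", report, config)
    return report
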