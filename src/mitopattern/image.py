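"""Multi-channel micropattern image container and TIFF interchange.

A :class:`MicropatternImage` is the unit of analysis: a stack of co-registered
2-D fluorescence channels (nuclei, epithelial/stromal markers, potentiometric
and metabolic dyes) with a physical pixel size.  Images round-trip through
multi-page TIFF with one page per channel and the channel name plus pixel
size stored as JSON in each page description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile

#: canonical channel order used when writing stacks
CHANNELS = ("DAPI", "panCK", "vimentin", "TMRM", "TOM20", "NADPH", "FAD", "YAP")


class ChannelError(KeyError):
    """A required fluorescence channel is absent from the image."""


class ShapeError(ValueError):
    """Channel rasters do not share a common 2-D shape."""


@dataclass
class MicropatternImage:
    """Co-registered multi-channel fluorescence image of one micropattern.

    Parameters
    ----------
    channels
        Mapping of channel name to 2-D float array (arbitrary intensity
        units).  All channels must share one shape.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    metadata
        Free-form acquisition metadata (condition, treatment, timepoint,
        generator parameters...).  Serialized alongside the pixels.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ShapeError(f"channels have mixed shapes: {shapes}")
        for ch, a in self.channels.items():
            if a.ndim != 2:
                raise ShapeError(f"channel {ch!r} is not 2-D (shape {a.shape})")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels

    def __getitem__(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel]
        except KeyError:
            raise ChannelError(
                f"channel {channel!r} not present; have {sorted(self.channels)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def with_channel(self, channel: str, data: np.ndarray) -> "MicropatternImage":
        """Return a copy with one channel replaced (other arrays shared)."""
        if data.shape != self.shape:
            raise ShapeError(f"replacement shape {data.shape} != image shape {self.shape}")
        channels = dict(self.channels)
        channels[channel] = data
        return MicropatternImage(channels, self.pixel_size_um, dict(self.metadata))

    # ------------------------------------------------------------------ I/O

    def write_tiff(self, path: str | Path) -> Path:
        """Write one page per channel; names and pixel size go in the page
        descriptions so the file is self-describing."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with tifffile.TiffWriter(path) as tif:
            for ch in self.channels:
                desc = json.dumps(
                    {
                        "channel": ch,
                        "pixel_size_um": self.pixel_size_um,
                        "metadata": _jsonable(self.metadata),
                    }
                )
                tif.write(
                    self.channels[ch].astype(np.float32),
                    description=desc,
                    contiguous=False,
                )
        return path

    @classmethod
    def read_tiff(
        cls, path: str | Path, pixel_size_um: float | None = None
    ) -> "MicropatternImage":
        """Read a multi-page TIFF written by :meth:`write_tiff` (or any TIFF
        whose page descriptions carry ``{"channel": name}`` JSON).

        ``pixel_size_um`` overrides the file metadata when given; the
        override wins by documented precedence.
        """
        path = Path(path)
        channels: dict[str, np.ndarray] = {}
        file_px: float | None = None
        metadata: dict = {}
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                desc = page.description or ""
                try:
                    info = json.loads(desc)
                except (json.JSONDecodeError, TypeError):
                    info = {}
                name = info.get("channel")
                if name is None:
                    raise SchemaError(
                        f"page {i} of {path} has no channel name in its description"
                    )
                channels[name] = page.asarray().astype(np.float64)
                if file_px is None and "pixel_size_um" in info:
                    file_px = float(info["pixel_size_um"])
                if not metadata and info.get("metadata"):
                    metadata = info["metadata"]
        px = pixel_size_um if pixel_size_um is not None else file_px
        if px is None:
            raise SchemaError(f"{path}: pixel size neither in file nor overridden")
        return cls(channels, px, metadata)


class SchemaError(ValueError):
    """Image file does not follow the expected channel-manifest layout."""


def read_image(
    path: str | Path, pixel_size_um: float | None = None
) -> MicropatternImage:
    """Load a micropattern image.

    Accepts a multi-page TIFF with channel names in page descriptions, or a
    directory of single-channel TIFFs accompanied by a ``manifest.json``
    mapping channel names to file names (and optionally a pixel size).
    """
    path = Path(path)
    if path.is_dir():
        manifest = path / "manifest.json"
        if not manifest.exists():
            raise SchemaError(f"directory {path} has no manifest.json")
        spec = json.loads(manifest.read_text())
        channels = {
            ch: tifffile.imread(path / fname).astype(np.float64)
            for ch, fname in spec["channels"].items()
        }
        px = pixel_size_um if pixel_size_um is not None else spec.get("pixel_size_um")
        if px is None:
            raise SchemaError(f"{manifest}: pixel_size_um missing and not overridden")
        return MicropatternImage(channels, float(px), spec.get("metadata", {}))
    return MicropatternImage.read_tiff(path, pixel_size_um=pixel_size_um)


def _jsonable(obj):
    """Coerce nested metadata to JSON-safe types (numpy scalars -> python)."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
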