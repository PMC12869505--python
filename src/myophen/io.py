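"""File formats and containers: multi-channel sections, label masks, tables.

Sections are held as a (C, Y, X) raster with named channels (DAPI, COL6,
PERLECAN) and a physical pixel size in µm/px.  On disk they are OME-TIFF;
instance label masks are 16-bit label TIFFs with 0 as background.  Pixel
size resolution precedence is explicit override > file metadata > error —
never a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "SectionImage",
    "read_section",
    "write_section",
    "read_label_mask",
    "write_label_mask",
    "write_manifest",
]

DEFAULT_CHANNELS = ("DAPI", "COL6", "PERLECAN")


@dataclass
class SectionImage:
    """Multi-channel fluorescence section with physical pixel size."""

    channels: np.ndarray  # (C, Y, X)
    channel_names: tuple = DEFAULT_CHANNELS
    pixel_size: float = field(default=None)  # µm/px

    def __post_init__(self):
        self.channels = np.asarray(self.channels)
        if self.channels.ndim == 2:
            self.channels = self.channels[None]
        if self.channels.ndim != 3:
            raise ValueError("channels must be a (C, Y, X) array")
        self.channel_names = tuple(self.channel_names)[: self.channels.shape[0]]
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError("one name per channel required")
        if self.pixel_size is None or not self.pixel_size > 0:
            raise ValueError("pixel_size (µm/px) is required and must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.channels[i]


def write_section(path, image: SectionImage) -> None:
    """Write a section as OME-TIFF with channel names and pixel size."""
    tifffile.imwrite(
        str(path),
        image.channels,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": image.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": list(image.channel_names)},
        },
    )


def read_section(
    path,
    pixel_size: float | None = None,
    channel_names: tuple | None = None,
) -> SectionImage:
    """Read an OME-TIFF (or plain TIFF) section.

    Channel names and pixel size come from OME metadata when present;
    explicit arguments override metadata.  A file carrying no pixel size
    and no override is an error.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta_names, meta_ps = _parse_ome(tf)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a (C, Y, X) stack, got shape {arr.shape}")
    names = channel_names or meta_names or DEFAULT_CHANNELS[: arr.shape[0]]
    ps = pixel_size if pixel_size is not None else meta_ps
    if ps is None:
        raise ValueError(
            f"{path}: no pixel size in metadata and no override given; "
            "pass pixel_size explicitly"
        )
    return SectionImage(arr, tuple(names), float(ps))


def _parse_ome(tf: tifffile.TiffFile):
    """Best-effort (channel names, pixel size µm/px) from OME metadata."""
    names = None
    ps = None
    xml = tf.ome_metadata
    if xml:
        try:
            d = tifffile.xml2dict(xml)
            image = d.get("OME", {}).get("Image", {})
            if isinstance(image, list):
                image = image[0]
            pixels = image.get("Pixels", {})
            ps = pixels.get("PhysicalSizeX")
            chans = pixels.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            got = [c.get("Name") for c in chans]
            if got and all(got):
                names = tuple(got)
        except Exception:  # malformed metadata: fall back to overrides
            pass
    return names, (float(ps) if ps is not None else None)


def read_label_mask(path) -> np.ndarray:
    """Read an instance label mask (background 0)."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError("label mask must be 2-d")
    return arr.astype(np.int32)


def write_label_mask(path, mask: np.ndarray) -> None:
    m = np.asarray(mask)
    if m.min() < 0:
        raise ValueError("labels must be non-negative")
    tifffile.imwrite(str(path), m.astype(np.uint16), photometric="minisblack")


def write_manifest(path, payload: dict) -> None:
    """Write a YAML manifest (params, seed, produced files)."""
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
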