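"""2-D count-image container and TIFF I/O.

All physical positions in this package are expressed in nanometres using a
pixel-centre convention: pixel (row ``i``, column ``j``) covers the square
``[j*p, (j+1)*p) x [i*p, (i+1)*p)`` nm and has its centre at
``((j+0.5)*p, (i+0.5)*p)`` nm, where ``p`` is the pixel size.  ``x`` runs
along columns, ``y`` along rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Image2D", "read_tiff", "write_tiff"]


@dataclass
class Image2D:
    """A single-channel photon-count raster with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite count values.
    pixel_size_nm
        Physical edge length of one pixel in nanometres (default 20 nm, the
        acquisition setting the analysis conventions assume).
    channel
        Free-text channel label (e.g. ``"DARPP-32"`` or ``"D1R"``).
    """

    pixels: np.ndarray
    pixel_size_nm: float = 20.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the field in nm."""
        h, w = self.pixels.shape
        return (w * self.pixel_size_nm, h * self.pixel_size_nm)

    def copy(self) -> "Image2D":
        return Image2D(self.pixels.copy(), self.pixel_size_nm, self.channel)


def write_tiff(image: Image2D, path: str | Path) -> None:
    """Write a 16-bit grayscale TIFF plus a JSON sidecar with the pixel size.

    Pixel size is also recorded in the TIFF resolution tags (pixels per cm).
    Counts are rounded and clipped to the uint16 range.
    """
    path = Path(path)
    data = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    px_per_cm = 1e7 / image.pixel_size_nm
    tifffile.imwrite(path, data, resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")
    sidecar = {"pixel_size_nm": image.pixel_size_nm, "channel": image.channel}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_tiff(path: str | Path, pixel_size_nm: float | None = None,
              channel: str | None = None) -> Image2D:
    """Read a grayscale TIFF written by :func:`write_tiff` or from elsewhere.

    Pixel size resolution order: explicit argument, JSON sidecar, TIFF
    resolution tags.  A missing pixel size is an error — analysis without
    physical units is meaningless here.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        if pixel_size_nm is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
                pixel_size_nm = float(meta["pixel_size_nm"])
                if channel is None:
                    channel = meta.get("channel")
            else:
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None and res.value[1] != 0 and res.value[0] != 0:
                    px_per_unit = res.value[0] / res.value[1]
                    unit_val = int(unit.value) if unit is not None else 3
                    unit_nm = {2: 2.54e7, 3: 1e7}.get(unit_val, 1e7)
                    pixel_size_nm = unit_nm / px_per_unit
    if pixel_size_nm is None:
        raise ValueError(f"{path}: pixel size not given and not recoverable from tags")
    return Image2D(np.asarray(data, dtype=float), pixel_size_nm, channel or "")
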