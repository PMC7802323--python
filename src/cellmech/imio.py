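"""TIFF stack I/O with pixel-size and channel metadata."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import MissingInputError


@dataclass
class ImageStack:
    """An image stack with provenance-tracked pixel size.

    ``axes`` is a subset of ``"TCYX"``; channels (if present) are
    addressable by name through :meth:`channel`.
    """

    data: np.ndarray
    axes: str
    pixel_size_um: float
    pixel_size_source: str  # "metadata" or "override"
    channel_names: list[str] | None = None

    def channel(self, name: str) -> np.ndarray:
        if self.channel_names is None or "C" not in self.axes:
            raise KeyError("stack has no named channels")
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}") from None
        return self.data.take(idx, axis=self.axes.index("C"))


def write_stack(
    path: str | Path,
    data: np.ndarray,
    pixel_size_um: float,
    axes: str = "TYX",
    channel_names: list[str] | None = None,
) -> None:
    """Write a float32 multi-page TIFF with pixel size and channel names."""
    data = np.asarray(data)
    if data.ndim != len(axes):
        raise ValueError(f"data has {data.ndim} dims but axes is {axes!r}")
    meta = {"axes": axes, "pixel_size_um": float(pixel_size_um)}
    if channel_names is not None:
        meta["channel_names"] = list(channel_names)
    tifffile.imwrite(
        str(path),
        data.astype(np.float32),
        photometric="minisblack",
        metadata=meta,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        resolutionunit="MICROMETER",
    )


def read_image_stack(path: str | Path, pixel_size_um: float | None = None) -> ImageStack:
    """Read a TIFF stack; pixel size from metadata unless overridden.

    Raises
    ------
    MissingInputError
        If the file is absent/unreadable, or no pixel size is available
        from either metadata or the override.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"image stack not found: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            meta = (tif.shaped_metadata or [{}])[0]
    except Exception as exc:  # unreadable / ragged pages
        raise MissingInputError(f"cannot read TIFF {path}: {exc}") from exc
    axes = meta.get("axes")
    if axes is None:
        axes = "TYX" if data.ndim == 3 else ("YX" if data.ndim == 2 else "TCYX")
    if pixel_size_um is not None:
        px, source = float(pixel_size_um), "override"
    elif "pixel_size_um" in meta:
        px, source = float(meta["pixel_size_um"]), "metadata"
    else:
        raise MissingInputError(
            f"{path}: no pixel-size metadata and no override given"
        )
    names = meta.get("channel_names")
    return ImageStack(
        data=data, axes=axes, pixel_size_um=px,
        pixel_size_source=source,
        channel_names=list(names) if names is not None else None,
    )
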