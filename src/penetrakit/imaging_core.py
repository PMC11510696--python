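"""Data model, image I/O, calibration and coordinate conventions.

Coordinate convention: row 0 is the top of the frame and lies *outside* the
tissue; depth below the tissue surface increases with row index.  All physical
distances are pixel counts multiplied by a user-supplied µm-per-pixel scale —
the scale is part of the acquisition metadata, never read from file tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

TISSUE_KINDS = ("skin", "cornea")


class UnsupportedDepthError(ValueError):
    """Raised for inputs that are not 8-bit (no silent rescale is performed)."""


@dataclass
class CalibratedImage:
    """An 8-bit RGB micrograph with its physical pixel scale and provenance.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), dtype uint8
        Raw intensities as acquired; never rescaled.
    scale_um_per_px : float
        Physical size of one pixel in µm; must be positive.
    tissue : {"skin", "cornea"}
    treatment : str
        Group label, e.g. ``"blank_initial"`` or ``"curcumin:cyclodextrins"``.
    replicate_id, section_id : str
        Biological replicate and section identifiers.
    metadata : dict
        Free-form acquisition notes (exposure, filter block, ...).
    """

    pixels: np.ndarray
    scale_um_per_px: float
    tissue: str
    treatment: str = ""
    replicate_id: str = ""
    section_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise UnsupportedDepthError(
                f"unsupported depth: expected uint8 pixels, got {px.dtype}"
            )
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be > 0")
        if self.tissue not in TISSUE_KINDS:
            raise ValueError(f"tissue must be one of {TISSUE_KINDS}, got {self.tissue!r}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the frame."""
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class Roi:
    """Half-open rectangular region [r0, r1) x [c0, c1) in pixel indices."""

    row_range: tuple[int, int]
    col_range: tuple[int, int]

    def __post_init__(self) -> None:
        r0, r1 = self.row_range
        c0, c1 = self.col_range
        if not (0 <= r0 < r1 and 0 <= c0 < c1):
            raise ValueError(f"invalid Roi: rows {self.row_range}, cols {self.col_range}")

    def clip_to(self, shape: tuple[int, int]) -> "Roi":
        h, w = shape
        r0, r1 = self.row_range
        c0, c1 = self.col_range
        if r1 > h or c1 > w:
            raise ValueError(f"Roi {self} exceeds image shape {shape}")
        return self

    def slices(self) -> tuple[slice, slice]:
        return slice(*self.row_range), slice(*self.col_range)


@dataclass
class ImageSet:
    """A collection of images with their treatment-group design.

    ``design`` maps each treatment label to the indices (into ``images``) of
    the images in that group; every image belongs to exactly one group.
    """

    images: list[CalibratedImage]
    design: Mapping[str, Sequence[int]]

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for label, idxs in self.design.items():
            if len(idxs) == 0:
                raise ValueError(f"treatment group {label!r} is empty")
            for i in idxs:
                if not 0 <= i < len(self.images):
                    raise ValueError(f"index {i} in group {label!r} out of range")
                if i in seen:
                    raise ValueError(
                        f"image {i} assigned to both {seen[i]!r} and {label!r}"
                    )
                seen[i] = label
        if len(seen) != len(self.images):
            missing = sorted(set(range(len(self.images))) - set(seen))
            raise ValueError(f"images {missing} belong to no treatment group")

    def group(self, label: str) -> list[CalibratedImage]:
        return [self.images[i] for i in self.design[label]]

    @property
    def labels(self) -> list[str]:
        return list(self.design)


def read_image(
    path: str | Path,
    scale_um_per_px: float,
    tissue: str,
    treatment: str = "",
    **ids,
) -> CalibratedImage:
    """Read an 8-bit RGB (or greyscale) TIFF/PNG as a :class:`CalibratedImage`.

    Greyscale input is promoted by channel replication.  16-bit input raises
    :class:`UnsupportedDepthError` — intensities are never silently rescaled.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        raise UnsupportedDepthError(
            f"unsupported depth in {path}: {arr.dtype} (only 8-bit is supported)"
        )
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha, keep RGB bit-exact
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected greyscale or RGB image, got shape {arr.shape}")
    return CalibratedImage(
        pixels=arr.copy(),
        scale_um_per_px=scale_um_per_px,
        tissue=tissue,
        treatment=treatment,
        **ids,
    )


def write_image(image: CalibratedImage, path: str | Path) -> None:
    """Write the raw pixel array to TIFF or PNG, bit-exactly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        iio.imwrite(path, image.pixels)


def to_grey(image: CalibratedImage) -> np.ndarray:
    """Unweighted grey conversion grey = (R + G + B) / 3, real-valued.

    Matches ImageJ's default "mean of RGB" used by the original macro rather
    than luminance weighting.
    """
    return np.asarray(image.pixels, dtype=np.float64).mean(axis=2)


def px_to_um(d_px: float, scale_um_per_px: float) -> float:
    """Convert a pixel distance to µm. Negative distances are a domain error."""
    if d_px < 0:
        raise ValueError(f"distance must be >= 0, got {d_px}")
    if not scale_um_per_px > 0:
        raise ValueError("scale_um_per_px must be > 0")
    return float(d_px) * float(scale_um_per_px)
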