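"""Autofluorescence removal via blank-derived per-channel RGB thresholds.

Untreated ("blank") sections characterise the tissue's intrinsic
fluorescence.  A :class:`ThresholdProfile` records, per RGB channel, the
empirical quantile (default 0.999) of all pooled blank pixels; applying it to
a treated section removes every pixel not *strictly* brighter than the blank
tissue, so the surviving pixels represent the exogenous fluorophore.

Low-autofluorescence tissue (cornea) can skip the step entirely: passing
``profile=None`` to :func:`apply_threshold` retains every pixel ("cornea
mode").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from penetrakit.imaging_core import CalibratedImage, Roi, to_grey

COMBINE_MODES = ("all_channels", "any_channel", "grey")


@dataclass
class ThresholdProfile:
    """Per-channel lower bounds derived from blank tissue, with provenance.

    ``low`` holds the (R, G, B) bounds in 8-bit units; a pixel survives only
    by exceeding them strictly, per ``combine_mode``:

    - ``all_channels`` (default, ImageJ colour-threshold semantics): every
      channel must exceed its bound,
    - ``any_channel``: at least one channel exceeds its bound,
    - ``grey``: the pixel's grey value must exceed the mean of the bounds.
    """

    low: tuple[float, float, float]
    quantile: float
    n_blank_images: int
    n_blank_pixels: int
    combine_mode: str = "all_channels"

    def __post_init__(self) -> None:
        if len(self.low) != 3 or any(not 0 <= v <= 255 for v in self.low):
            raise ValueError(f"low must be 3 values in [0, 255], got {self.low}")
        if not 0 < self.quantile <= 1:
            raise ValueError("quantile must be in (0, 1]")
        if self.n_blank_images < 1 or self.n_blank_pixels < 1:
            raise ValueError("profile requires >= 1 blank image and > 0 pixels")
        if self.combine_mode not in COMBINE_MODES:
            raise ValueError(f"combine_mode must be one of {COMBINE_MODES}")
        self.low = tuple(float(v) for v in self.low)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdProfile":
        d = json.loads(Path(path).read_text())
        d["low"] = tuple(d["low"])
        return cls(**d)


@dataclass
class RetainedMask:
    """Pixels surviving the threshold, and their grey values (0 elsewhere)."""

    mask: np.ndarray  # H x W bool
    retained_grey: np.ndarray  # H x W float, 0 where mask is False
    n_retained: int

    def __post_init__(self) -> None:
        if self.mask.shape != self.retained_grey.shape:
            raise ValueError("mask and retained_grey shapes differ")
        if int(self.mask.sum()) != self.n_retained:
            raise ValueError("n_retained inconsistent with mask")
        if np.any(self.retained_grey[~self.mask] != 0):
            raise ValueError("retained_grey must be 0 outside the mask")


def derive_threshold(
    blanks: Sequence[CalibratedImage],
    quantile: float = 0.999,
    roi: Optional[Roi] = None,
    combine_mode: str = "all_channels",
) -> ThresholdProfile:
    """Per-channel empirical quantile over all pooled blank pixels.

    Pixels from every blank replicate are pooled *before* taking the quantile
    (more stable than averaging per-image thresholds for small replicate
    counts).  ``roi`` restricts the pool to a rectangular region.
    """
    if len(blanks) == 0:
        raise ValueError("need at least one blank image")
    kinds = {b.tissue for b in blanks}
    if len(kinds) > 1:
        raise ValueError(f"blanks mix tissue kinds: {sorted(kinds)}")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if combine_mode not in COMBINE_MODES:
        raise ValueError(f"combine_mode must be one of {COMBINE_MODES}")

    pools = []
    for b in blanks:
        px = b.pixels
        if roi is not None:
            rs, cs = roi.clip_to(b.shape).slices()
            px = px[rs, cs]
        pools.append(px.reshape(-1, 3))
    pooled = np.concatenate(pools, axis=0)
    low = tuple(float(np.quantile(pooled[:, c].astype(np.float64), quantile)) for c in range(3))
    return ThresholdProfile(
        low=low,
        quantile=quantile,
        n_blank_images=len(blanks),
        n_blank_pixels=pooled.shape[0],
        combine_mode=combine_mode,
    )


def apply_threshold(
    image: CalibratedImage,
    profile: Optional[ThresholdProfile],
) -> RetainedMask:
    """Apply a blank-derived threshold; ``profile=None`` retains every pixel.

    Retention uses strict inequality: a pixel exactly at the bound is
    removed, so a blank thresholded with its own quantile-1.0 profile retains
    nothing.
    """
    grey = to_grey(image)
    if profile is None:
        mask = np.ones(grey.shape, dtype=bool)
        return RetainedMask(mask=mask, retained_grey=grey, n_retained=int(mask.sum()))

    px = image.pixels.astype(np.float64)
    low = np.asarray(profile.low, dtype=np.float64)
    if profile.combine_mode == "all_channels":
        mask = np.all(px > low[None, None, :], axis=2)
    elif profile.combine_mode == "any_channel":
        mask = np.any(px > low[None, None, :], axis=2)
    else:  # grey
        mask = grey > float(low.mean())
    retained = np.where(mask, grey, 0.0)
    return RetainedMask(mask=mask, retained_grey=retained, n_retained=int(mask.sum()))


def write_mask_png(mask: RetainedMask, path: str | Path) -> None:
    """Write the boolean mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))
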