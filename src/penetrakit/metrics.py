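"""The penetration readouts: MGV/px, MPD, SCT, Δ and derived comparisons.

All depths are measured from the tissue surface, detected per column as the
first row whose grey value rises above the exterior background.  MGV/px is
the frame-mean grey of threshold-surviving pixels (the semi-quantitative
amount of penetrated drug); MPD is the mean depth of the deepest surviving
pixels; SCT is the thickness of the bright stratum-corneum band measured on
the *original* (unthresholded) image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

from penetrakit.imaging_core import CalibratedImage, to_grey
from penetrakit.thresholding import RetainedMask


class SurfaceDetectionError(RuntimeError):
    """Raised when no tissue surface can be located in an image."""


@dataclass
class SurfaceLine:
    """Per-column exterior boundary of the tissue (the depth origin).

    ``row_by_col`` holds the surface row index per column (NaN on invalid
    columns); ``valid_cols`` marks columns where the surface criterion was
    met.  An image with fewer than 50% valid columns is rejected.
    """

    row_by_col: np.ndarray  # float per column, NaN where invalid
    valid_cols: np.ndarray  # bool per column
    method: str = "background-rise"

    def __post_init__(self) -> None:
        if self.row_by_col.shape != self.valid_cols.shape:
            raise ValueError("row_by_col and valid_cols shapes differ")
        if self.valid_cols.mean() < 0.5:
            raise SurfaceDetectionError(
                f"no surface found: only {int(self.valid_cols.sum())} of "
                f"{self.valid_cols.size} columns show a surface"
            )


class MpdResult(NamedTuple):
    """Mean penetration depth with its degenerate-input flag."""

    mpd_um: float
    no_signal: bool
    n_depths: int


@dataclass
class PenetrationMetrics:
    """Per-image (or per-group) penetration readouts.

    ``mgv_per_px`` is the semi-quantitative amount of penetrated drug;
    ``delta_um`` = SCT − MPD (negative ⇔ the drug crossed the stratum
    corneum).  ``sct_um`` is absent (None) for cornea.  ``rel_efficacy_pct``
    and ``rel_depth_pct`` stay None until a reference group is set.
    """

    mgv_per_px: float
    mpd_um: float
    sct_um: Optional[float] = None
    n_retained: int = 0
    n_images: int = 1
    rel_efficacy_pct: Optional[float] = None
    rel_depth_pct: Optional[float] = None
    flags: list[str] = field(default_factory=list)

    @property
    def delta_um(self) -> Optional[float]:
        if self.sct_um is None:
            return None
        return delta_mpd_sct(self.mpd_um, self.sct_um)


@dataclass
class GroupSummary:
    """Unweighted mean ± sample SD of per-image metrics within one group."""

    mean: PenetrationMetrics
    sd: dict[str, Optional[float]]
    n_images: int


def mgv_per_px(mask: RetainedMask) -> float:
    """Mean grey value per pixel: sum of retained greys over the frame area.

    Higher MGV/px ⇔ more penetrated drug.  The denominator is the full frame
    area, so images entering one comparison must share frame geometry.
    """
    return float(mask.retained_grey.sum() / mask.retained_grey.size)


def detect_surface(
    image: CalibratedImage,
    smooth_cols: int = 7,
    k_sigma: float = 5.0,
    bg_rows_frac: float = 0.10,
    t_min: float = 5.0,
) -> SurfaceLine:
    """Locate the tissue surface per column as the first above-background row.

    Background statistics come from the top ``bg_rows_frac`` of rows (the
    exterior region).  A column's surface is the first row whose grey value
    reaches ``max(bg_mean + k_sigma * bg_sd, t_min)``; the resulting line is
    median-filtered over ``smooth_cols`` columns to suppress isolated
    noise-triggered columns.  Columns never reaching the criterion are
    invalid; fewer than 50% valid columns raises
    :class:`SurfaceDetectionError`.
    """
    grey = to_grey(image)
    h, w = grey.shape
    n_bg = max(1, int(round(bg_rows_frac * h)))
    bg = grey[:n_bg, :]
    thresh = max(float(bg.mean()) + k_sigma * float(bg.std()), t_min)

    above = grey >= thresh
    first = np.argmax(above, axis=0).astype(np.float64)
    valid = above.any(axis=0)
    first[~valid] = np.nan

    if smooth_cols > 1:
        first = _nan_median_filter(first, smooth_cols)
        valid = ~np.isnan(first)
    return SurfaceLine(row_by_col=first, valid_cols=valid)


def _nan_median_filter(x: np.ndarray, size: int) -> np.ndarray:
    """Median filter ignoring NaNs; a window of all-NaN stays NaN."""
    half = size // 2
    n = x.size
    out = np.full(n, np.nan)
    for i in range(n):
        window = x[max(0, i - half): i + half + 1]
        vals = window[~np.isnan(window)]
        if vals.size:
            out[i] = np.median(vals)
    return out


def mpd(
    mask: RetainedMask,
    surface: SurfaceLine,
    scale_um_per_px: float,
    deep_fraction: float = 0.01,
) -> MpdResult:
    """Mean penetration depth: mean of the deepest retained-pixel depths.

    Depth of a retained pixel = (row − surface row of its column) × scale;
    pixels above the surface (negative depth) and pixels in invalid columns
    are discarded.  The "most distant pixels" are the deepest
    ``ceil(deep_fraction * N)`` depths (at least one), averaged — robust to a
    single stray pixel.  No retained pixel below the surface → MPD 0 with the
    ``no_signal`` flag.
    """
    if not 0 < deep_fraction <= 1:
        raise ValueError("deep_fraction must be in (0, 1]")
    rows, cols = np.nonzero(mask.mask)
    if rows.size:
        surf = surface.row_by_col[cols]
        ok = ~np.isnan(surf)
        depths = (rows[ok] - surf[ok]) * scale_um_per_px
        depths = depths[depths >= 0]
    else:
        depths = np.empty(0)
    if depths.size == 0:
        return MpdResult(mpd_um=0.0, no_signal=True, n_depths=0)
    k = max(1, math.ceil(deep_fraction * depths.size))
    deepest = np.partition(depths, depths.size - k)[-k:]
    return MpdResult(mpd_um=float(deepest.mean()), no_signal=False, n_depths=int(depths.size))


def sct(
    image: CalibratedImage,
    surface: SurfaceLine,
    scale_um_per_px: float,
    expected_sct_um: float = 60.0,
    rel_height: float = 0.5,
) -> float:
    """Stratum corneum thickness from the original (unthresholded) image.

    Per valid column the SC band is the contiguous run of rows from the
    surface whose grey stays at or above ``rel_height`` of the column's band
    peak (peak taken within 3 × ``expected_sct_um`` of the surface).  A
    column whose profile never drops below that level within the search
    window shows no distinct band and contributes 0.  SCT = median column
    band length × scale.  Only defined for skin.
    """
    if image.tissue != "skin":
        raise ValueError("SCT undefined for cornea (no stratum corneum)")
    grey = to_grey(image)
    h, _ = grey.shape
    window_px = max(1, int(round(3 * expected_sct_um / scale_um_per_px)))

    lengths = []
    for c in np.nonzero(surface.valid_cols)[0]:
        r0 = int(surface.row_by_col[c])
        r1 = min(h, r0 + window_px)
        profile = grey[r0:r1, c]
        if profile.size == 0:
            continue
        peak = profile.max()
        below = np.nonzero(profile < rel_height * peak)[0]
        lengths.append(int(below[0]) if below.size else 0)
    if not lengths:
        raise SurfaceDetectionError("no valid columns for SCT measurement")
    return float(np.median(lengths) * scale_um_per_px)


def delta_mpd_sct(mpd_um: float, sct_um: float) -> float:
    """Δ = SCT − MPD (µm); negative ⇔ the drug crossed the stratum corneum."""
    if not (math.isfinite(mpd_um) and math.isfinite(sct_um)):
        raise ValueError("MPD and SCT must be finite")
    if mpd_um < 0 or sct_um < 0:
        raise ValueError("MPD and SCT must be >= 0")
    return sct_um - mpd_um


def crossing_flags(
    mpd_um: float,
    sct_um: Optional[float],
    epidermis_um: float = 100.0,
) -> tuple[Optional[bool], bool]:
    """Barrier-crossing criteria.

    ``crossed_sc``: MPD > SCT ⇒ the drug passed the stratum corneum (None if
    SCT is absent, i.e. cornea).  ``reached_viable_dermis``: MPD exceeds the
    epidermis thickness (≈100 µm in the ex vivo skin model), i.e. the drug
    could reach systemic circulation.
    """
    if mpd_um < 0:
        raise ValueError("MPD must be >= 0")
    crossed = None if sct_um is None else bool(mpd_um > sct_um)
    return crossed, bool(mpd_um > epidermis_um)


def relative_to_reference(
    values: Mapping[str, float],
    reference_group: str,
) -> dict[str, float]:
    """Express per-group values as percent of a reference group (ref = 100)."""
    if reference_group not in values:
        raise KeyError(f"reference group {reference_group!r} not among {list(values)}")
    ref = values[reference_group]
    if ref == 0:
        raise ZeroDivisionError("undefined relative value: reference group value is 0")
    out = {g: 100.0 * v / ref for g, v in values.items()}
    out[reference_group] = 100.0
    return out


def sct_ratio(sct_a_um: float, sct_b_um: float) -> int:
    """SCT ratio a/b as an integer percent (reported rounded)."""
    if sct_b_um <= 0:
        raise ZeroDivisionError("undefined SCT ratio: denominator must be > 0")
    return int(round(100.0 * sct_a_um / sct_b_um))


def aggregate_group(per_image: Sequence[PenetrationMetrics]) -> GroupSummary:
    """Unweighted mean and sample SD (n−1) across images of one group.

    All images must agree on SCT presence (skin) or absence (cornea).  With a
    single image the SD is reported as absent (None).
    """
    if len(per_image) == 0:
        raise ValueError("cannot aggregate an empty group")
    has_sct = [m.sct_um is not None for m in per_image]
    if any(has_sct) and not all(has_sct):
        raise ValueError("group mixes SCT-present and SCT-absent images")

    def _stats(vals: list[float]) -> tuple[float, Optional[float]]:
        arr = np.asarray(vals, dtype=np.float64)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else None
        return mean, sd

    mgv_m, mgv_s = _stats([m.mgv_per_px for m in per_image])
    mpd_m, mpd_s = _stats([m.mpd_um for m in per_image])
    if all(has_sct):
        sct_m, sct_s = _stats([m.sct_um for m in per_image])
    else:
        sct_m, sct_s = None, None
    flags = sorted({f for m in per_image for f in m.flags})
    mean = PenetrationMetrics(
        mgv_per_px=mgv_m,
        mpd_um=mpd_m,
        sct_um=sct_m,
        n_retained=int(round(np.mean([m.n_retained for m in per_image]))),
        n_images=len(per_image),
        flags=flags,
    )
    return GroupSummary(
        mean=mean,
        sd={"mgv_per_px": mgv_s, "mpd_um": mpd_s, "sct_um": sct_s},
        n_images=len(per_image),
    )
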