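"""Config-driven orchestration of skin-mode and cornea-mode analyses.

Skin mode derives an RGB threshold from blank sections and applies it before
any readout.  Cornea mode computes MGV/px both ways — threshold-free (the
more discriminative readout for low-autofluorescence tissue) and thresholded
— while MPD always comes from the thresholded image, where the
drug/background contrast is unambiguous.

Also houses the small experimental-design arithmetic: finite-dose µL/cm² and
the section × position sampling plan.
"""

from __future__ import annotations

import glob as globmod
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from penetrakit.imaging_core import CalibratedImage, ImageSet, read_image
from penetrakit.thresholding import ThresholdProfile, apply_threshold, derive_threshold
from penetrakit.metrics import (
    PenetrationMetrics,
    SurfaceDetectionError,
    aggregate_group,
    detect_surface,
    mgv_per_px,
    mpd,
    relative_to_reference,
    sct,
)
from penetrakit.group_stats import ComparisonResult, compare_groups


def dose_per_area(volume_ul: float, area_diameter_cm: float) -> tuple[float, bool]:
    """Applied dose per treated area and the finite-dose flag.

    dose = volume / (π (d/2)²); a dose strictly below 10 µL/cm² is a finite
    dose, mimicking real-world topical application.
    """
    if volume_ul <= 0 or area_diameter_cm <= 0:
        raise ValueError("volume and diameter must be > 0")
    area_cm2 = math.pi * (area_diameter_cm / 2.0) ** 2
    dose = volume_ul / area_cm2
    return dose, dose < 10.0


def sampling_plan(n_sections: int, n_positions: int) -> int:
    """Total images per sample: sections × imaging positions per section."""
    if n_sections < 1 or n_positions < 1:
        raise ValueError("n_sections and n_positions must be >= 1")
    return int(n_sections) * int(n_positions)


@dataclass
class RunConfig:
    """Validated configuration of one analysis run."""

    tissue: str
    groups: dict[str, list[str]]  # label -> list of paths/globs
    scale_um_per_px: float
    blank_groups: list[str] = field(default_factory=list)
    quantile: float = 0.999
    combine_mode: str = "all_channels"
    cornea_threshold_free: bool = True
    deep_fraction: float = 0.01
    expected_sct_um: float = 60.0
    reference_group: Optional[str] = None
    control_group: Optional[str] = None
    alpha: float = 0.05
    seed: int = 0
    flip_vertical: bool = False  # for sections mounted tissue-side up
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tissue not in ("skin", "cornea"):
            raise ValueError("tissue must be 'skin' or 'cornea'")
        # the thresholded MPD variant is always computed, so blanks are always needed
        if not self.blank_groups:
            raise ValueError("blank_groups required: thresholding needs blank sections")
        for b in self.blank_groups:
            if b not in self.groups:
                raise ValueError(f"blank group {b!r} not among groups")
        for ref in (self.reference_group, self.control_group):
            if ref is not None and ref not in self.groups:
                raise ValueError(f"group {ref!r} not among groups")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ReportBundle:
    """Everything one analysis run produces."""

    per_image: pd.DataFrame
    group_summaries: dict
    relative_efficacy: Optional[dict]
    relative_depth: Optional[dict]
    comparisons: list[ComparisonResult]
    profile: Optional[ThresholdProfile]
    log: list[str]
    config: Optional[RunConfig] = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_image.to_csv(out / "per_image.csv", index=False)
        rows = []
        for label, gs in self.group_summaries.items():
            rows.append(
                {
                    "treatment": label,
                    "n_images": gs.n_images,
                    "mgv_per_px_mean": gs.mean.mgv_per_px,
                    "mgv_per_px_sd": gs.sd["mgv_per_px"],
                    "mpd_um_mean": gs.mean.mpd_um,
                    "mpd_um_sd": gs.sd["mpd_um"],
                    "sct_um_mean": gs.mean.sct_um,
                    "sct_um_sd": gs.sd["sct_um"],
                    "delta_um": gs.mean.delta_um,
                }
            )
        pd.DataFrame(rows).to_csv(out / "group_summary.csv", index=False)
        rel = {"relative_efficacy_pct": self.relative_efficacy, "relative_depth_pct": self.relative_depth}
        (out / "relative.json").write_text(json.dumps(rel, indent=2) + "\n")
        if self.comparisons:
            pd.concat([c.to_frame() for c in self.comparisons]).to_csv(
                out / "comparisons.csv", index=False
            )
        if self.profile is not None:
            self.profile.to_json(out / "threshold_profile.json")
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")
        if self.config is not None:
            (out / "config_used.json").write_text(json.dumps(asdict(self.config), indent=2) + "\n")


def _analyze_one(
    image: CalibratedImage,
    profile: Optional[ThresholdProfile],
    tissue: str,
    deep_fraction: float,
    expected_sct_um: float,
    cornea_threshold_free: bool,
    log: list[str],
) -> Optional[dict]:
    try:
        surface = detect_surface(image)
    except SurfaceDetectionError as exc:
        log.append(f"ERROR {image.section_id or image.treatment}: {exc}")
        return None
    thresholded = apply_threshold(image, profile)
    row: dict = {
        "treatment": image.treatment,
        "replicate": image.replicate_id,
        "section": image.section_id,
        "n_retained": thresholded.n_retained,
        "mgv_per_px_thresholded": mgv_per_px(thresholded),
    }
    flags = []
    # MPD always from the thresholded image (clear drug/background contrast)
    mres = mpd(thresholded, surface, image.scale_um_per_px, deep_fraction=deep_fraction)
    row["mpd_um"] = mres.mpd_um
    if mres.no_signal:
        flags.append("no penetration signal")
    if tissue == "skin":
        row["mgv_per_px"] = row["mgv_per_px_thresholded"]
        row["sct_um"] = sct(image, surface, image.scale_um_per_px, expected_sct_um=expected_sct_um)
        row["delta_um"] = row["sct_um"] - row["mpd_um"]
    else:
        free = apply_threshold(image, None)
        row["mgv_per_px_threshold_free"] = mgv_per_px(free)
        row["mgv_per_px"] = (
            row["mgv_per_px_threshold_free"] if cornea_threshold_free
            else row["mgv_per_px_thresholded"]
        )
        row["sct_um"] = None
        row["delta_um"] = None
    row["flags"] = ";".join(flags)
    return row


def analyze_imageset(
    imageset: ImageSet,
    tissue: str,
    blank_groups: list[str],
    quantile: float = 0.999,
    combine_mode: str = "all_channels",
    cornea_threshold_free: bool = True,
    deep_fraction: float = 0.01,
    expected_sct_um: float = 60.0,
    reference_group: Optional[str] = None,
    control_group: Optional[str] = None,
    alpha: float = 0.05,
    config: Optional[RunConfig] = None,
) -> ReportBundle:
    """Run the full analysis on an in-memory :class:`ImageSet`.

    Blank groups supply the threshold; every image contributes one row to
    the per-image table or one entry to the error log.  Group statistics run
    on the primary MGV/px of the non-blank groups.
    """
    log: list[str] = []
    blanks = [img for b in blank_groups for img in imageset.group(b)]
    if not blanks:
        raise ValueError("no blank images available for threshold derivation")
    profile = derive_threshold(blanks, quantile=quantile, combine_mode=combine_mode)
    log.append(
        f"threshold: low={tuple(round(v, 2) for v in profile.low)} "
        f"quantile={quantile} mode={combine_mode} from {len(blanks)} blanks"
    )

    rows = []
    per_group_metrics: dict[str, list[PenetrationMetrics]] = {}
    for label in imageset.labels:
        for img in imageset.group(label):
            row = _analyze_one(
                img, profile, tissue, deep_fraction, expected_sct_um,
                cornea_threshold_free, log,
            )
            if row is None:
                continue
            rows.append(row)
            per_group_metrics.setdefault(label, []).append(
                PenetrationMetrics(
                    mgv_per_px=row["mgv_per_px"],
                    mpd_um=row["mpd_um"],
                    sct_um=row["sct_um"],
                    n_retained=row["n_retained"],
                    flags=[f for f in row["flags"].split(";") if f],
                )
            )
    per_image = pd.DataFrame(rows)

    group_summaries = {
        label: aggregate_group(ms) for label, ms in per_group_metrics.items()
    }

    treatment_labels = [l for l in imageset.labels if l not in blank_groups and l in group_summaries]
    rel_eff = rel_depth = None
    if reference_group is not None and reference_group in group_summaries:
        eff = {l: group_summaries[l].mean.mgv_per_px for l in treatment_labels}
        dep = {l: group_summaries[l].mean.mpd_um for l in treatment_labels}
        try:
            rel_eff = relative_to_reference(eff, reference_group)
        except ZeroDivisionError as exc:
            log.append(f"relative efficacy skipped: {exc}")
        try:
            rel_depth = relative_to_reference(dep, reference_group)
        except ZeroDivisionError as exc:
            log.append(f"relative depth skipped: {exc}")

    comparisons: list[ComparisonResult] = []
    stat_labels = [l for l in treatment_labels if len(per_group_metrics[l]) >= 3]
    if len(stat_labels) >= 2:
        for metric_name in ("mgv_per_px", "mpd_um"):
            samples = [
                [getattr(m, metric_name) for m in per_group_metrics[l]] for l in stat_labels
            ]
            res = compare_groups(
                samples, stat_labels, alpha=alpha,
                control=control_group if control_group in stat_labels else None,
                metric=metric_name,
            )
            comparisons.append(res)
            log.append(f"stats[{metric_name}]: route={res.route} omnibus_p={res.omnibus_p:.4g}")
    else:
        log.append("stats skipped: fewer than two groups with n >= 3")

    return ReportBundle(
        per_image=per_image,
        group_summaries=group_summaries,
        relative_efficacy=rel_eff,
        relative_depth=rel_depth,
        comparisons=comparisons,
        profile=profile,
        log=log,
        config=config,
    )


def load_imageset(config: RunConfig) -> ImageSet:
    """Resolve the per-group path globs into a loaded, validated ImageSet."""
    images: list[CalibratedImage] = []
    design: dict[str, list[int]] = {}
    errors: list[str] = []
    for label, patterns in config.groups.items():
        paths: list[str] = []
        for pat in patterns:
            hits = sorted(globmod.glob(pat))
            paths.extend(hits if hits else [pat])
        idxs = []
        for p in paths:
            try:
                img = read_image(
                    p, config.scale_um_per_px, config.tissue, treatment=label,
                    section_id=str(p),
                )
            except OSError as exc:
                errors.append(str(exc))
                continue
            if config.flip_vertical:
                img.pixels = img.pixels[::-1].copy()
            idxs.append(len(images))
            images.append(img)
        if idxs:
            design[label] = idxs
    if errors:
        raise OSError("unreadable images:\n" + "\n".join(errors))
    return ImageSet(images=images, design=design)


def run_analysis(config: RunConfig) -> ReportBundle:
    """Load images per config, run the analysis, and write the report bundle."""
    imageset = load_imageset(config)
    bundle = analyze_imageset(
        imageset,
        tissue=config.tissue,
        blank_groups=config.blank_groups,
        quantile=config.quantile,
        combine_mode=config.combine_mode,
        cornea_threshold_free=config.cornea_threshold_free,
        deep_fraction=config.deep_fraction,
        expected_sct_um=config.expected_sct_um,
        reference_group=config.reference_group,
        control_group=config.control_group,
        alpha=config.alpha,
        config=config,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
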