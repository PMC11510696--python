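"""Seeded generator of skin-like and cornea-like cross-section images.

Each synthetic section emulates the features the analysis relies on:

* a dark exterior region above the tissue surface,
* a bright stratum-corneum (SC) band for skin (absent in cornea),
* diffuse tissue autofluorescence, much stronger in skin than in the
  water-rich cornea,
* an exogenous drug signal added at the surface that decays with depth and
  ends at a known true depth,
* per-pixel Gaussian noise and 8-bit clipping.

The generator returns the rendered image together with a :class:`GroundTruth`
record (surface line, SC thickness, drug depth, drug-pixel mask, mean added
grey), so every downstream readout can be checked against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy.ndimage import median_filter

from penetrakit.imaging_core import CalibratedImage, ImageSet

__all__ = [
    "TissueSpec",
    "DrugSpec",
    "GroundTruth",
    "generate_section",
    "generate_experiment",
    "skin_spec",
    "cornea_spec",
]


def _normalize_weights(w) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (3,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError(f"channel weights must be 3 non-negative reals, got {w}")
    # normalised so that the grey value (R+G+B)/3 of a weighted intensity I is I
    return 3.0 * w / w.sum()


@dataclass(frozen=True)
class TissueSpec:
    """Geometry and autofluorescence of one synthetic tissue section.

    Intensities are mean 8-bit values before noise; ``channel_weights`` give
    the autofluorescence colour and are normalised so the grey value of a
    region equals its nominal intensity.
    """

    height_px: int = 300
    width_px: int = 400
    scale_um_per_px: float = 1.0
    surface_row_px: int = 60
    surface_roughness_px: float = 1.5
    sct_um: float = 25.0
    sc_autofluor: float = 130.0
    tissue_autofluor: float = 48.0
    background_autofluor: float = 0.0
    noise_sd: float = 4.0
    channel_weights: tuple[float, float, float] = (0.9, 1.2, 0.9)

    def validate(self) -> None:
        for name in ("sc_autofluor", "tissue_autofluor", "background_autofluor"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.sct_um < 0:
            raise ValueError("sct_um must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.surface_roughness_px < 0:
            raise ValueError("surface_roughness_px must be >= 0")
        if self.height_px <= 0 or self.width_px <= 0 or self.scale_um_per_px <= 0:
            raise ValueError("height, width and scale must be positive")
        sct_px = self.sct_um / self.scale_um_per_px
        if self.surface_row_px + sct_px >= self.height_px:
            raise ValueError("frame height does not accommodate surface + SC band")
        _normalize_weights(self.channel_weights)


@dataclass(frozen=True)
class DrugSpec:
    """The exogenous fluorophore signal added below the tissue surface.

    The added grey signal starts at ``amplitude`` at the surface and decays to
    the signal floor ``max(2 * noise_sd, 1)`` exactly at ``true_depth_um``;
    below that depth no signal is added.  ``decay`` selects a linear ramp
    (default) or an exponential with the rate solved from the same endpoint
    condition.  ``lateral_fraction`` < 1 restricts the drug to a random subset
    of columns (a patchy film).
    """

    amplitude: float = 160.0
    true_depth_um: float = 50.0
    decay: str = "linear"
    lateral_fraction: float = 1.0
    drug_channel_weights: tuple[float, float, float] = (0.7, 1.5, 0.8)

    def validate(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.true_depth_um < 0:
            raise ValueError("true_depth_um must be >= 0")
        if not 0 < self.lateral_fraction <= 1:
            raise ValueError("lateral_fraction must be in (0, 1]")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"decay must be 'linear' or 'exponential', got {self.decay!r}")
        _normalize_weights(self.drug_channel_weights)


@dataclass
class GroundTruth:
    """Exact generator truth for one synthetic section."""

    surface_row_by_col: np.ndarray  # int, per column
    true_sct_um: float
    true_depth_um: float
    drug_pixel_mask: np.ndarray  # H x W bool
    true_mean_added_grey: float  # frame mean of the added drug grey signal


def skin_spec(**overrides) -> TissueSpec:
    """Default skin-like section: bright SC band, strong autofluorescence."""
    return replace(TissueSpec(), **overrides)


def cornea_spec(**overrides) -> TissueSpec:
    """Default cornea-like section: no SC band, weak autofluorescence.

    Tissue autofluorescence defaults to one quarter of the skin default,
    encoding the qualitative skin >> cornea contrast.
    """
    base = TissueSpec(
        sct_um=0.0,
        sc_autofluor=0.0,
        tissue_autofluor=12.0,
        noise_sd=3.0,
        channel_weights=(0.9, 1.1, 1.0),
    )
    return replace(base, **overrides)


def _surface_line(spec: TissueSpec, rng: np.random.Generator) -> np.ndarray:
    jitter = rng.normal(0.0, spec.surface_roughness_px, size=spec.width_px)
    rows = spec.surface_row_px + jitter
    # median smoothing over 5 columns: jagged but laterally coherent edge
    rows = median_filter(rows, size=5, mode="nearest")
    return np.clip(np.round(rows), 0, spec.height_px - 1).astype(np.intp)


def _added_profile(drug: DrugSpec, depth_um: np.ndarray, noise_sd: float) -> np.ndarray:
    """Added grey signal as a function of depth below the surface (µm)."""
    floor = max(2.0 * noise_sd, 1.0)
    amp = drug.amplitude
    d = drug.true_depth_um
    out = np.zeros_like(depth_um, dtype=np.float64)
    inside = (depth_um >= 0) & (depth_um <= d)
    if amp <= 0:
        return out
    if d == 0:
        out[depth_um == 0] = amp
        return out
    if amp <= floor:
        out[inside] = amp  # sub-floor amplitude: flat plug down to the end depth
    elif drug.decay == "linear":
        out[inside] = amp - (amp - floor) * depth_um[inside] / d
    else:
        k = np.log(amp / floor) / d
        out[inside] = amp * np.exp(-k * depth_um[inside])
    return out


def generate_section(
    tissue_spec: TissueSpec,
    drug_spec: Optional[DrugSpec],
    seed: int,
    tissue: str | None = None,
    treatment: str = "",
    replicate_id: str = "",
    section_id: str = "",
) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic cross-section and its exact ground truth.

    Deterministic for fixed (specs, seed).  ``drug_spec=None`` yields a blank
    (untreated) section.  The drug signal is *additive* on top of the
    autofluorescence, then the frame is noised and clipped to [0, 255].
    """
    tissue_spec.validate()
    if drug_spec is not None:
        drug_spec.validate()
    if tissue is None:
        tissue = "skin" if tissue_spec.sct_um > 0 else "cornea"

    h, w = tissue_spec.height_px, tissue_spec.width_px
    scale = tissue_spec.scale_um_per_px
    rng = np.random.default_rng(seed)

    surface = _surface_line(tissue_spec, rng)
    rows = np.arange(h)[:, None]  # H x 1
    depth_px = rows - surface[None, :]  # H x W, negative above surface
    depth_um = depth_px.astype(np.float64) * scale

    sct_px = tissue_spec.sct_um / scale
    grey = np.full((h, w), tissue_spec.background_autofluor, dtype=np.float64)
    in_sc = (depth_px >= 0) & (depth_px < np.ceil(sct_px)) & (sct_px > 0)
    in_tissue = (depth_px >= 0) & ~in_sc
    grey[in_sc] = tissue_spec.sc_autofluor
    grey[in_tissue] = tissue_spec.tissue_autofluor

    w_auto = _normalize_weights(tissue_spec.channel_weights)
    frame = grey[:, :, None] * w_auto[None, None, :]

    drug_mask = np.zeros((h, w), dtype=bool)
    added = np.zeros((h, w), dtype=np.float64)
    if drug_spec is not None and drug_spec.amplitude > 0:
        if drug_spec.lateral_fraction < 1.0:
            n_cols = max(1, int(round(drug_spec.lateral_fraction * w)))
            cols = np.sort(rng.choice(w, size=n_cols, replace=False))
            col_mask = np.zeros(w, dtype=bool)
            col_mask[cols] = True
        else:
            col_mask = np.ones(w, dtype=bool)
        profile = _added_profile(drug_spec, depth_um, tissue_spec.noise_sd)
        profile[:, ~col_mask] = 0.0
        added = profile
        drug_mask = added > 0
        w_drug = _normalize_weights(drug_spec.drug_channel_weights)
        frame = frame + added[:, :, None] * w_drug[None, None, :]

    if tissue_spec.noise_sd > 0:
        frame = frame + rng.normal(0.0, tissue_spec.noise_sd, size=frame.shape)
    pixels = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    image = CalibratedImage(
        pixels=pixels,
        scale_um_per_px=scale,
        tissue=tissue,
        treatment=treatment,
        replicate_id=replicate_id,
        section_id=section_id,
        metadata={"synthetic": True, "seed": seed},
    )
    truth = GroundTruth(
        surface_row_by_col=surface,
        true_sct_um=tissue_spec.sct_um,
        true_depth_um=(drug_spec.true_depth_um if drug_spec is not None else 0.0),
        drug_pixel_mask=drug_mask,
        true_mean_added_grey=float(added.mean()),
    )
    return image, truth


def generate_experiment(
    design: Mapping[str, tuple[TissueSpec, Optional[DrugSpec], int]],
    seed: int,
) -> tuple[ImageSet, list[GroundTruth]]:
    """Generate a grouped experiment; per-image seed = master seed + ordinal.

    ``design`` maps each treatment label to (tissue_spec, drug_spec | None,
    n_images).  The image ordinal runs over all groups in design order, so two
    groups with identical specs still receive different per-image seeds.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    labels = list(design)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate treatment labels in design")

    images: list[CalibratedImage] = []
    truths: list[GroundTruth] = []
    groups: dict[str, list[int]] = {}
    ordinal = 0
    for label, (tspec, dspec, n_images) in design.items():
        if n_images < 1:
            raise ValueError(f"group {label!r}: n_images must be >= 1")
        idxs = []
        for j in range(n_images):
            img, truth = generate_section(
                tspec,
                dspec,
                seed=seed + ordinal,
                treatment=label,
                replicate_id=f"r{j + 1}",
                section_id=f"{label}/{j + 1}",
            )
            idxs.append(len(images))
            images.append(img)
            truths.append(truth)
            ordinal += 1
        groups[label] = idxs
    return ImageSet(images=images, design=groups), truths
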