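# Methods

## Scope and model of the measurement

penetrakit quantifies the penetration of an inherently fluorescent drug into
skin or cornea from 8-bit RGB micrographs of vertical cryosections. The
measurement model is deliberately simple: tissue autofluorescence is a
stationary per-channel intensity distribution characterised by untreated
(blank) sections; any pixel of a treated section strictly brighter than the
blank distribution's upper quantile in every channel is attributed to the
drug. All spatial readouts are pixel counts scaled by a user-supplied
µm-per-pixel calibration; the scale is configuration, never read from image
tags (tag dialects vary across microscope vendors).

Coordinate convention: row 0 is the top of the frame and lies outside the
tissue; depth increases with row index. Sections mounted upside down must be
flipped at ingest (`flip_vertical` in the run config).

## Thresholding

* **Derivation.** Per-channel empirical quantile (default q = 0.999) over
  the pooled pixels of all blank replicates. Pooling before the quantile is
  more stable than averaging per-image thresholds when only 2–3 blanks per
  condition exist. The 0.999 default removes blanks essentially completely
  while tolerating isolated hot pixels; q is configurable, and an optional
  rectangular ROI restricts the pool.
* **Retention.** Strict inequality, so a blank thresholded with its own
  quantile-1.0 profile retains exactly zero pixels. Default combine mode is
  `all_channels` (ImageJ colour-threshold semantics: a pixel passes only if
  inside every channel window); `any_channel` and `grey` composites are also
  implemented because the original macro's rule is not recoverable.
* **Blank pooling across time points.** Blanks taken before and after
  incubation are pooled by default; the config can restrict to either.

## Grey conversion

grey = (R+G+B)/3, unweighted, real-valued — ImageJ's default "mean of RGB",
matching the macro lineage of the method, rather than luminance weighting.

## Surface detection

The tissue surface is the depth origin of MPD and SCT. Per column, the
surface is the first row whose grey value reaches
`max(bg_mean + k_sigma * bg_sd, t_min)`, with the background statistics
estimated from the top 10% of rows, `k_sigma = 5` and an absolute floor
`t_min = 5` (8-bit units). The floor makes the degenerate cases behave
sensibly: an all-zero frame has no surface (error), while a frame entirely
filled with tissue yields surface ≡ row 0 (the ≥ comparison admits the
boundary). The per-column line is then median-filtered over 7 columns, which
suppresses isolated noise-triggered columns; columns never reaching the
criterion are invalid, and an image with < 50% valid columns is rejected.
The criterion is evaluated on the raw column profile — row-smoothing before
detection would bias the crossing upward by half the window at sharp edges.

## MPD

Depths of threshold-surviving pixels below their column's surface (negative
depths discarded); MPD is the mean of the deepest ⌈1% · N⌉ depths (at least
one). Averaging the deepest fraction rather than taking the single deepest
pixel keeps the readout robust to isolated stray pixels, which is the
spirit of "most distant pixels" (plural) in the source method. An empty
below-surface set yields MPD = 0 with a `no penetration signal` flag rather
than an error, so blank controls flow through batch summaries.

## SCT

Measured on the original (unthresholded) image, skin only. Per valid
column: the band peak is the maximal grey within 3× the expected SCT
(default 60 µm) of the surface; the band is the contiguous run of rows from
the surface with grey ≥ 50% of that peak; a column whose profile never
drops below the 50% level within the window shows no distinct band and
contributes 0. SCT = median column band length × scale. The 50%-of-peak
edge is a standard full-width criterion; the original method measured SCT
manually and states no rule. When a drug film much brighter than the SC
band sits at the surface, the 50%-of-peak run extends into the drug signal
and overestimates SCT — a human measuring morphology would not be fooled;
treated-section SCT values should be read with that in mind. Cornea has no
stratum corneum and corneal
autofluorescence is too weak for reliable thickness segmentation, so the
operation refuses cornea input.

## Δ and barrier criteria

Δ = SCT − MPD, the sign convention that reproduces the published per-row Δ
column; Δ < 0 ⇔ the drug crossed the stratum corneum. (One published row,
nanocrystals, prints Δ = −7 where its own printed means give 27 − 33 = −6,
presumably computed from unrounded means; this implementation always
follows its own arithmetic.) `reached_viable_dermis` flags MPD above the
epidermis thickness, default 100 µm for the ex vivo skin model.

## Group statistics

Gate at α = 0.05: Shapiro–Wilk per group (all groups must pass — the
conservative reading) and mean-centred Levene. Routes: classic ANOVA
(+ Dunnett when a control group is designated, Games–Howell all-pairs
otherwise), Welch ANOVA + Games–Howell under heteroscedasticity,
Kruskal–Wallis + Dunn (Holm-adjusted — Dunn's customary companion; the
source names no adjustment) otherwise. Two samples: Student's t vs
Mann–Whitney by the same Shapiro gate. A zero-variance sample is treated as
maximally non-normal in the gate; all-identical data short-circuits to a
"no variance" result (p = 1) instead of crashing. Dunn's z statistics use
the tie-corrected variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`; for two groups
the unadjusted Dunn p equals the tie-corrected Kruskal–Wallis p, which the
test suite uses as an independent oracle. Star codes: * p<0.05, ** p<0.01,
*** p<0.001.

A consequence of the all-groups Shapiro gate worth knowing: for three
Gaussian groups the classic-ANOVA route is chosen at rate ≈ 0.95⁴ ≈ 0.81,
not ≈ 1 — the remainder goes to Kruskal–Wallis (≈ 14%) and Welch (≈ 4%).
The omnibus type-I error stays calibrated (≈ 0.04–0.05 in 2000-replicate
simulations) because every route is level-α.

The statistical unit defaults to the image; nesting of sections within
biopsies is not modelled (no mixed-effects machinery), matching the source
workflow.

## Synthetic-section generator

Emulates what the analysis depends on and nothing more: a dark exterior, a
per-column surface line (Gaussian jitter, SD 1.5 px, median-smoothed over 5
columns — cryosection-edge roughness without histology), a bright SC band
(skin), diffuse tissue autofluorescence, an additive drug signal, Gaussian
pixel noise, 8-bit clipping. Channel weights are normalised so a region's
grey value equals its nominal intensity.

Defaults (8-bit units, chosen as plausible for 50 ms / 50% LED exposures;
the source reports no intensity statistics): skin — SC band 130, tissue 48,
background 0, noise SD 4, SCT 25 µm; cornea — tissue 12 (= skin/4, encoding
the qualitative skin ≫ cornea autofluorescence contrast), noise SD 3, no SC
band. Frames are 300×400 px at 1 µm/px with the surface near row 60.

**Drug signal.** Additive on top of autofluorescence (fluorescence
intensities add below detector saturation), amplitude 160 at the surface,
with its own colour distinct from the autofluorescence colour. "Signal end"
is defined as the added signal reaching the floor `max(2·noise_sd, 1)`
exactly at the true depth; the default decay is a **linear ramp** to that
floor, with an exponential alternative whose rate is solved from the same
endpoint. The linear default is a deliberate design choice: an exponential
tail spends most of the depth range far below any realistic retention
bound, so the depth recoverable from thresholded pixels would
systematically undershoot the nominal true depth; the steep linear approach
makes true depth a well-defined estimand of the thresholded analysis.

Per-image seeds in `generate_experiment` are `master_seed + image_ordinal`
(ordinal global across groups), so identically-specified groups still get
distinct noise.

**What the generator does not emulate** — optical PSF and blur,
photobleaching, hair follicles and histological texture, animal-to-animal
autofluorescence variability, uneven illumination. Passing recovery tests
therefore shows the *algorithms* are correct on images satisfying the
stated model, not that the readouts are unbiased on real micrographs.

## Validation problem sizes

The ground-truth studies run on 300×400 px (acceptance grids 200×300 px)
sections at 1 µm/px: depth grid {20, 40, 60, 80} µm × 5 seeds (tolerance
10% of truth, ≥90% of cells), SCT grid {15, 25, 35} µm × 5 seeds (±2 px),
blank elimination over 10 seeds (held-out blank retains <0.5% of pixels),
and a 2000-replicate null calibration of the gated omnibus. These sizes
give stable pass/fail behaviour while keeping a full validation run in the
order of a minute on one CPU.

Depth recovery is validated on cornea-like sections with a blank-derived
threshold — the configuration in which thresholded MPD is the recommended
readout. In skin, the pooled blank quantile is dominated by the bright SC
band, so the retention bound sits far above the 2·noise floor and the
deepest decaying signal is unrecoverable in principle; that is a property
of the measurement, not of this implementation.

## Cornea mode

MGV/px is reported both threshold-free and thresholded for cornea; the
threshold-free variant is the default statistic (thresholding also removes
faint drug pixels and lowers contrast between weak formulations near the
bound), while MPD always uses the thresholded image, where the
drug/background contrast is unambiguous. Both columns appear in the
per-image output so the choice is auditable.

## Known limitations

* MGV/px divides by the full frame area, so images entering one comparison
  must share frame geometry.
* The threshold assumes blank and treated sections share an
  autofluorescence distribution; for cornea, where blanks come from
  different animals, that assumption is weaker and the threshold-free
  readout is preferred.
* 8-bit input only; 16-bit data must be converted upstream, deliberately
  not silently rescaled here.
* No absolute quantification (µg/cm²): MGV/px is comparative across
  formulations imaged under identical settings.
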