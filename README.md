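# penetrakit

Semi-quantitative image analysis of drug penetration into skin and cornea
from fluorescence micrographs of vertical tissue cross-sections.

## The problem

How deep, and how much of, a fluorescent drug (e.g. curcumin) penetrates into
tissue can be read off epifluorescence micrographs of cryosectioned
biopsies — if the tissue's own autofluorescence is removed first. The
workflow implemented here, developed for ex vivo porcine skin and
transferable to cornea, is:

1. **RGB thresholding** — untreated ("blank") sections characterise the
   tissue autofluorescence. Per RGB channel, an intensity bound is set at a
   high empirical quantile (default 0.999) of all pooled blank pixels; a
   pixel of a treated section survives only if it strictly exceeds the bound
   in every channel. Surviving pixels represent the penetrated drug.
2. **MGV/px** (mean grey value per pixel) — the frame-mean grey value,
   grey = (R+G+B)/3, of surviving pixels: the semi-quantitative amount of
   penetrated drug. Higher MGV/px ⇔ more drug.
3. **MPD** (mean penetration depth, µm) — the mean depth below the detected
   tissue surface of the deepest surviving pixels (deepest 1% by default).
4. **SCT** (stratum corneum thickness, µm) — thickness of the bright
   outermost skin band, measured on the *original* image; a proxy for skin
   hydration. Δ = SCT − MPD < 0 means the drug crossed the stratum corneum;
   MPD > ≈100 µm (epidermis) means it reached the viable dermis.
5. **Gated statistics** — groups are compared by ANOVA (+ Dunnett or
   Games–Howell), Welch ANOVA (+ Games–Howell) or Kruskal–Wallis (+ Dunn),
   chosen by Shapiro–Wilk and Levene gates at α = 0.05; two-sample cases use
   Student's t or Mann–Whitney.

Low-autofluorescence tissue (cornea) supports a **threshold-free mode** for
MGV/px — more discriminative because the threshold also eats faint drug
signal — while corneal MPD is still read from thresholded images.

Because the original micrographs are not deposited, the package ships a
seeded **synthetic-section generator** with exact ground truth (surface
line, band thickness, true drug depth, drug-pixel mask) used to validate
every stage: blank self-elimination, depth/SCT recovery, amplitude→MGV
ordering and statistical calibration.

## Worked example

```python
import penetrakit as pk
from penetrakit.synthetic_data import cornea_spec

spec = cornea_spec()  # 300x400 px cornea-like section, 1 µm/px
design = {
    "blank":         (spec, None, 3),
    "oily_solution": (spec, pk.DrugSpec(amplitude=40,  true_depth_um=30), 5),
    "cyclodextrins": (spec, pk.DrugSpec(amplitude=150, true_depth_um=60), 5),
}
imageset, truths = pk.generate_experiment(design, seed=11)
bundle = pk.analyze_imageset(imageset, tissue="cornea",
                             blank_groups=["blank"],
                             reference_group="oily_solution")
```

prints (via the loop in `examples` below):

```
blank           MGV/px =   9.83 ± 0.00   MPD =   0.0 µm
oily_solution   MGV/px =  12.22 ± 0.01   MPD =  26.0 µm
cyclodextrins   MGV/px =  25.70 ± 0.00   MPD =  57.1 µm
relative efficacy: {'oily_solution': 100, 'cyclodextrins': 210}
route: anova_dunnett  omnibus p = 1.20e-26
      group_a       group_b   p star_code
cyclodextrins oily_solution 0.0       ***
```

Reading: the blank group keeps no drug signal (MPD 0 with a "no penetration
signal" flag); the weak formulation's MPD (26 µm) sits below its true 30 µm
because sub-threshold signal near the depth limit is removed; the strong
formulation recovers its 60 µm depth well (57.1 µm) and carries ~2.1× the
penetrated amount of the reference, a difference the gated route flags at
p < 0.001.

The same pipeline runs from the shell on directories of TIFF/PNG images:

```bash
penetrakit simulate --config sim.yaml --out imgs/ --seed 3   # synthetic data
penetrakit analyze  --config run.yaml                        # full analysis
penetrakit stats    --metrics per_image.csv --metric mgv_per_px
```

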