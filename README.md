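# memfuse

Quantitative analysis of how **lateral membrane tension** controls
**SNARE-mediated fusion** of large unilamellar vesicles (LUVs) with target
bilayers, for the two assay geometries in which tension can be set
mechanically: isolated supported-bilayer patches on a dilatable elastomer
sheet, and sessile giant unilamellar vesicles (GUVs) stretched by adhesion.
It is aimed at membrane biophysicists who have two-channel fluorescence
stacks (a membrane dye and a vesicle dye) and want tensions, fusion
efficiencies and dose-response fits out the other end — plus a synthetic
scene generator with exact ground truth so every stage of the pipeline is
testable without microscope data.

## What it computes

**Tension from area dilatation.** For supported patches (undulations
suppressed) Hooke's law for membranes gives the tension difference

    σ − σ₀ = K_A · ΔA/A₀,        K_A = 0.28 N/m by default.

For vesicles, the excess area stored in thermal undulations adds an
entropic term,

    ΔA/A₀ = (σ − σ₀)/K_A + (k_B T / 8πκ) · ln(σ/σ₀),

which is inverted numerically (κ = 0.85×10⁻¹⁹ J ≈ 21 k_BT,
σ₀ = 9.7×10⁻⁵ N/m). A sessile GUV's dilatation comes from its
spherical-cap shape (cap radius R̃_V, contact radius R_i) under volume
conservation.

**Area change from images.** Patches are segmented by minimum
cross-entropy (Li–Tam) thresholding — implemented from scratch and checked
against an exhaustive oracle — with enclosed ruptured holes subtracted
from the area, matched across relaxed/stretched frames, and size-filtered
to 100–7000 µm².

**Fusion efficiency.** Lipid mixing is the background-corrected vesicle-dye
signal normalised to the brightest adhered vesicle,

    F_eff = (I_patch − I_back) / (I_max − I_back) · 100%,

with docked and hemifused vesicles excluded by spot detection plus a
median + 3·MAD intensity cap, and classified by membrane-dye
colocalisation.

**Dose response.** Pooled (σ, F_eff) pairs are binned and fitted with a
four-parameter Hill curve F(σ) = F_base + (F_max−F_base)·σⁿ/(σ_halfⁿ+σⁿ).
FRAP recovery curves (circular spot, Soumpasis form) yield diffusion
coefficients and immobile fractions.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a three-patch field (one patch per behaviour class is typical:
following the substrate, sliding, or rupturing) and analyse it blind:

```python
from memfuse import SceneConfig, generate_patch_scene, analyze_scene

scene = generate_patch_scene(SceneConfig(seed=7))
table = analyze_scene(scene.relaxed, scene.stretched, scene.post_incubation)
print(table[["patch_id", "A0_um2", "rel_change", "sigma_mN_per_m",
             "F_eff_percent", "n_docked", "n_hemifused"]].round(3).to_string(index=False))
```

```
 patch_id  A0_um2  rel_change  sigma_mN_per_m  F_eff_percent  n_docked  n_hemifused
        3 369.162       0.000           0.000          1.293         1            0
        2 349.020       0.017           4.711          3.557        10            4
        1 183.527       0.002           0.611          1.291         5            1
```

Patch 2 followed the substrate dilation (ΔA/A₀ = 1.7%, i.e. σ−σ₀ ≈ 4.7
mN/m) and sits above the fusion threshold: its lipid-mixing efficiency
(3.6%) is nearly triple the unstressed patches' baseline (~1.3%), and it
carries the most docked/hemifused vesicles. Patches 1 and 3 stayed near
zero tension and show only baseline mixing. The same conversion is
available directly:

```python
from memfuse.mechanics import tension_hooke
est = tension_hooke(0.012)          # the threshold dilatation of 1.2%
print(f"sigma - sigma0 = {est.sigma * 1e3:.2f} mN/m")   # -> 3.36 mN/m
```

The command line mirrors this: `memfuse simulate --seed 7 --out scene/`
writes TIFFs plus a ground-truth manifest, and `memfuse analyze
--scene-dir scene/ --out results/` writes the per-patch tension and fusion
tables (a directory containing `guv_stack.tif` is routed through the
sessile-GUV geometry instead). `memfuse frap`, `memfuse tension` and
`memfuse fit-response` handle FRAP tables, batch dilatation-to-tension
conversion and Hill fitting of pooled response tables.

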