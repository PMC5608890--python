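# Methods

`memfuse` quantifies how the lateral tension of a lipid bilayer controls
SNARE-mediated lipid mixing with added large unilamellar vesicles (LUVs).
It implements both experimental routes of the assay — supported bilayer
patches on a dilatable elastomer sheet, and sessile giant unilamellar
vesicles (GUVs) whose tension is set by adhesion — and ships a synthetic
scene generator so the entire chain can be validated against exact ground
truth.

## Mechanical model

Tension is never measured directly; it is inferred from the relative area
change ΔA/A₀ of the membrane.

**Hookean (supported patches).** For a bilayer firmly coupled to its
substrate thermal undulations are suppressed and

σ = σ₀ + K_A · ΔA/A₀

with area compressibility modulus K_A. Because the pre-stress σ₀ of a
freshly deposited patch is unknown, the package reports the *tension
difference* σ − σ₀ = K_A · ΔA/A₀ for this model, and the `model="hooke"`
tag on every `TensionEstimate` records that convention.

**Undulation-corrected (vesicles).** A weakly adhered vesicle stores excess
area in thermal undulations; pulling that reservoir flat contributes a
logarithmic entropic term:

ΔA/A₀ = (σ − σ₀)/K_A + (k_BT / 8πκ) · ln(σ/σ₀)

The forward map is strictly increasing in σ, so the inverse (tension from a
measured dilatation) is obtained by Brent root bracketing on
[10⁻⁹, 1] N/m at 10⁻¹⁰ relative tolerance; it reports absolute σ
(`model="undulation"`). Uncertainties propagate first-order: K_A·δ for the
Hookean model, and the delta method with
dσ/d(ΔA/A₀) = (1/K_A + k_BT/8πκσ)⁻¹ for the undulation model.

**Defaults** (the lipid composition of the assay, DOPC/DOPE/DOPS/cholesterol):
K_A = 0.28 N/m, κ = 0.85×10⁻¹⁹ J, σ₀ = 9.7×10⁻⁵ N/m. The temperature
default of 293 K is chosen so that κ corresponds to 21 k_BT, the value the
assay works with; a consistency check in the test suite pins this down.

**Sessile-GUV geometry.** A strongly adhered GUV takes a spherical-cap
shape characterised by the cap radius R̃_V and the contact radius R_i.
With cap height h = R̃_V ± √(R̃_V² − R_i²) (+ past the hemisphere), the
membrane area is A_m = 2πR̃_V h + πR_i² (free cap plus adhesion disc) and
the enclosed volume V = (πh²/3)(3R̃_V − h). Assuming the volume is
conserved from the free spherical state of radius R₀ = (3V/4π)^{1/3}, the
dilatation is ΔA/A₀ = A_m/(4πR₀²) − 1, which is ≥ 0 with equality only for
the free sphere. This volume-conserving reconstruction uses exactly the
two measurable radii; whether adhesion is truly iso-volume (no osmotic
flux) is an assumption of the method. The dilatation then feeds the
undulation model to give absolute tension.

## Segmentation and area measurement

Membrane patches are detected in the membrane-dye channel by minimum
cross-entropy thresholding (Li & Tam), implemented from scratch as an
exhaustive, vectorised minimisation of the cross-entropy criterion over all
candidate grey levels; a test compares it against an independent
brute-force oracle on random images and against scikit-image's iterative
implementation on bimodal data. The returned threshold is the midpoint of
the intensity gap at the optimal split: any value in the gap induces the
same partition, and the midpoint stays valid when the same threshold is
reused on later frames of the field whose foreground is slightly dimmer
(dye dilution upon stretch, photobleaching). Reusing one threshold per
field avoids a per-frame segmentation bias.

Components are 8-connected; the background (and therefore any hole) is
4-connected — the standard digital-topology pairing. Patches touching the
image border are discarded (censored area), components below a minimum size
are ignored, and fully enclosed sub-threshold holes are subtracted from
the patch area: holes are tension-relaxing ruptures and carry no membrane.
Dark notches open to the component boundary are background, not holes.
Areas are pixel counts × pixel_size²; the default pixel size is 0.132 µm.

Patch identity between the relaxed and stretched frame is established by
greedy one-to-one bounding-box-overlap matching (ties by centroid
distance). Only patches with initial area between 100 and 7000 µm² enter
the tension-response analysis; outside that window the relative area error
grows beyond ~1%.

## Fusion quantification

Lipid mixing is read from the LUV-dye channel as

F_eff = (I_patch − I_back) / (I_max − I_back) · 100%

* I_back — mean over patches of the median intensity in a 5–20 px annulus
  around each patch, excluding patch and vesicle pixels (median makes
  settled vesicles in the surround irrelevant);
* I_max — the mean intensity of the brightest detected vesicle spot (an
  adhered LUV on the bare substrate is the assay's internal reference);
  using a spot mean rather than the global maximum pixel is robust to
  single-pixel shot noise;
* I_patch — mean over patch pixels after removing detected-spot discs and
  capping at median + 3·MAD of the remaining pixels, so docked or
  hemifused vesicles sitting on the patch cannot masquerade as post-fusion
  signal. Negative efficiencies under noise are deliberately not clamped
  (clamping would bias pooled averages).

Vesicle spots are local maxima of a difference-of-Gaussian band-pass at the
expected spot scale; the prominence floor is the larger of 5·MAD of the
filtered image and a quarter of its strongest response, which suppresses
patch-edge ripple without losing genuine vesicles. Spots are classified by
colocalisation with the membrane dye: no membrane-dye excess above the
local baseline + 3 noise SD → docked; excess → hemifused. The full
time-series criteria (no shrinkage, no intensity loss) require multiple
frames; with one frame the call is recorded as a single-frame call. Event
counts are assigned to patches by centre-pixel membership.

For GUVs, I_patch is replaced by the adhesion-zone intensity at the
substrate slice (the lowest z-slice whose in-disc signal exceeds twice the
out-of-disc background). Spot exclusion is not applied there: vesicles
cannot dock inside the contact zone, so every pixel is membrane signal.

Area scans average both channels column-wise over a user box and normalise
by the mean membrane-dye intensity over patch pixels.

## FRAP

Recovery of a uniformly bleached circular spot of radius w follows the
Soumpasis closed form f(t) = e^{−2τ/t}[I₀(2τ/t) + I₁(2τ/t)] with
τ_D = w²/4D, evaluated via exponentially scaled Bessel functions for
stability at small t. The measured observable adds an immobile fraction
and a bleach floor: I(t) = floor + (1−immobile)(1−floor)f(t). Fitting is
bounded nonlinear least squares from a fixed 3×3 multi-start grid
(τ_D ∈ {t_max/30, t_max/10, t_max/3}; immobile ∈ {0, 0.2, 0.5}); the best
residual wins with ties to the smallest τ_D, so the result is
deterministic. The circular-spot uniform-bleach model is a reconstruction:
the assay bleached circular spots but the exact bleach profile is not
modelled.

## Tension response

Pooled (σ, F_eff) pairs are summarised by a four-parameter Hill curve with
additive baseline, F(σ) = F_base + (F_max−F_base)·σⁿ/(σ_halfⁿ+σⁿ) — the
minimal sigmoid that accommodates the nonzero low-tension efficiency seen
in the assay. The fit is bounded least squares (n ∈ [0.5, 10], σ_half
within the data range) with the same deterministic multi-start policy;
flat data short-circuit to a degenerate fit with σ_half undefined.
Unweighted by default; inverse-variance weights are accepted. The Hill
form is descriptive ("guides the eye"), not a kinetic model. Binned
summaries use left-closed/right-open bins with the last bin closed.

## Synthetic data: what it emulates, and what it does not

The generator renders the three frames of a stretch-and-incubate
experiment (relaxed, stretched, post-incubation) with exact ground truth:

* **Strain field** — per-patch isotropic scaling about the centroid, with
  magnitude from a linear ramp in the column coordinate that vanishes at
  the sheet centre (the substrate dilates anisotropically, more towards the
  side walls, spanning roughly 0–5%). Explicit per-patch dilatations can
  be prescribed instead.
* **Patch behaviours** — *follows* (area scales with the substrate, dye
  intensity diluted by 1/(1+ΔA/A₀) at fixed fluorophore count), *slides*
  (adhesion loses the race: constant area, small translation), *ruptures*
  (the outline grows but 1–5 interior elliptical holes return exactly the
  gained area, so the net dilatation is zero and no dilution occurs).
  Default mix 60/20/20.
* **Exact rasterisation** — patches are the N nearest pixels to a centre,
  and the stored ground-truth ΔA/A₀ is the realised pixel-count ratio, so
  noiseless closed-loop recovery is exact by construction rather than
  approximate.
* **Lipid mixing** — the post-incubation LUV-dye level inside each patch is
  set from a Hill law of the patch's true tension (defaults: base 1.3%,
  plateau 4.2%, σ_half 3.4 mN/m, n = 4 — the supported-bilayer regime; the
  GUV generator defaults to a 16.5% plateau regime).
* **Vesicles** — docked/hemifused spots are truncated Gaussian peaks whose
  expected count is linear in tension with a nonzero floor (0.033 µm⁻² at
  4 mN/m; the tension dependence of docking is a modelling choice — the
  assay reports increased affinity but no functional form). Hemifused
  spots add 50% of the patch's membrane-dye mean; docked spots add none.
  Uniform reference discs on the bare substrate define I_max.
* **Noise** — Poisson shot noise on photon counts (0.5 grey/photon gain),
  Gaussian read noise (SD 2 grey), and 1% per-frame exponential bleaching
  of both channels.
* **GUV stacks** — thin spherical-cap shells plus adhesion disc on a voxel
  grid, docked spots only on the free membrane, settled reference vesicles
  on the substrate slice.

Not emulated: optical point-spread blur (edges are pixel-sharp), stage
drift, focus changes and FRET between dyes. Consequently the synthetic
area-change error under the default noise model is far below the ~0.5%
instrumental accuracy of the real assay — passing the area-accuracy test
bounds the algorithmic error only, not microscope physics. Conversely the
noiseless closed-loop identities (dilatation, F_eff, event counts recovered
exactly) are strong algorithm checks precisely because rendering is exact.

## Problem sizes and numerical choices

Simulation studies in the tests and the acceptance script use 512×512
fields at 0.132 µm/px (one 900 µm² patch for area accuracy, 100 fields),
GUV stacks at 0.25 µm voxels, 120-point FRAP records, and blind end-to-end
experiments of 30 patches (ten 3-patch fields) spanning 0–6 mN/m — sizes
chosen so each study runs in seconds to a minute while leaving sampling
error well below the tolerances asserted. All randomness derives from one
integer seed per run; identical seeds give bit-identical scenes and
byte-identical analysis tables. Root finding and curve fitting use
deterministic bracketing/multi-start, never random restarts.

Known limitations: the GUV tension from cap geometry depends on the
iso-volume assumption and on voxel-accurate radii (a 0.25 µm voxel error
on R̃_V and R_i propagates to ~10–15% in σ for weakly adhered caps);
sub-hemisphere caps are supported in the mechanics but the geometric stack
read-out assumes a dome (the equator must be visible); and the Hill
σ_half is poorly identified when the transition amplitude is comparable to
the per-point noise (see the test suite's simulation study, which uses the
large-amplitude vesicle regime for that reason).
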