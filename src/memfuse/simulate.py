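"""Synthetic two-channel microscopy scenes with exact ground truth.

Emulates the tension-fusion assay end to end so every analysis stage can be
tested against known truth:

* isolated bright membrane patches (membrane-dye channel) on a dark
  background, dilated by an anisotropic substrate strain field that is zero
  at the sheet centre and grows linearly towards the edges;
* three patch behaviours — *follows* (area scales with the substrate),
  *slides* (adhesion too weak, area constant, small translation),
  *ruptures* (boundary grows but interior holes relax the tension so the
  net area stays constant);
* docked / hemifused vesicles as sub-diffraction spots whose expected count
  grows linearly with tension, plus uniform reference discs (vesicles
  adhered to the bare substrate) that define the intensity maximum;
* tension-dependent lipid-mixing intensity in the vesicle-dye channel set
  from a Hill law of the true tension;
* per-frame exponential photobleaching, Poisson shot noise and Gaussian
  read noise;
* spherical-cap shells for adhered giant vesicles, and closed-form FRAP
  and tension-response datasets.

Patches are rasterised as the N nearest pixels to a centre, so pixel
counts — and therefore the stored ground-truth dilatation
dA/A0 = N_m/N_0 - 1 — are exact integers ratios: on noiseless scenes the
measured dilatation equals the truth identically, not approximately.
All randomness flows from one integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from memfuse.mechanics import MechanicalParameters, tension_hooke, tension_from_area
from memfuse.response import HillFit, hill_model
from memfuse.frap import FrapCurve, recovery_model

__all__ = [
    "SceneConfig",
    "PatchTruth",
    "GroundTruth",
    "Scene",
    "generate_patch_scene",
    "generate_guv_stack",
    "measure_guv_geometry",
    "generate_frap_curve",
    "generate_tension_response_dataset",
    "write_scene",
    "load_manifest",
]

# channel conventions: 0 = membrane (patch/GUV) dye, 1 = vesicle (LUV) dye
BLUE_BACKGROUND = 10.0
BLUE_PATCH_AMP = 1000.0
RED_BACKGROUND = 100.0
RED_IMAX = 1100.0
SPOT_SIGMA = 1.2  # px, Gaussian width of docked-vesicle peaks
SPOT_SUPPORT = 3  # px, truncation radius of spot rendering
REF_DISC_RADIUS = 3  # px, uniform reference discs (>= spot measure radius)
FRAME_LABELS = ("relaxed", "stretched", "post_incubation")


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions of one synthetic patch field.

    Defaults emulate the supported-bilayer assay: 0.132 um pixels, patches
    of 100-900 um^2, substrate dilation 0-~5% across the field, Hill truth
    with base 1.3%, plateau 4.2%, half-transition 3.4 mN/m, and docked-spot
    density calibrated to tens of vesicles on a tensed 900 um^2 patch.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.132  # um
    n_patches: int = 3
    patch_area_range: tuple[float, float] = (100.0, 400.0)  # um^2
    dilation_gradient: float = 0.0008  # fractional area change per um off-centre
    patch_behavior_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)
    hill_truth: tuple[float, float, float, float] = (1.3, 4.2, 3.4e-3, 4.0)
    docking_rate: float = 0.033  # spots per um^2 at 4 mN/m reference tension
    hemifused_fraction: float = 0.2
    bleach_rate: float = 0.01  # per-frame fractional decay
    noise: tuple[float, float] = (0.5, 2.0)  # (shot scale grey/photon, read sd)
    seed: int = 0
    tension_model: str = "hooke"
    target_dilations: tuple[float, ...] | None = None  # overrides the gradient
    n_reference_spots: int = 6
    max_dilation: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.patch_behavior_probs) - 1.0) > 1e-9:
            raise ValueError("behaviour probabilities must sum to 1")
        if min(self.patch_behavior_probs) < 0:
            raise ValueError("behaviour probabilities must be >= 0")
        if self.docking_rate < 0 or self.bleach_rate < 0:
            raise ValueError("rates must be >= 0")
        if min(self.noise) < 0:
            raise ValueError("noise levels must be >= 0")
        lo, hi = self.patch_area_range
        if not 0 < lo <= hi:
            raise ValueError("invalid patch_area_range")
        field_area = (
            self.image_shape[0] * self.image_shape[1] * self.pixel_size**2
        )
        if hi > field_area:
            raise ValueError("patch_area_range exceeds the image area")
        if self.tension_model not in ("hooke", "undulation"):
            raise ValueError("tension_model must be 'hooke' or 'undulation'")
        if self.target_dilations is not None and len(self.target_dilations) != self.n_patches:
            raise ValueError("target_dilations must list one value per patch")

    @property
    def hill(self) -> HillFit:
        fb, fm, sh, n = self.hill_truth
        return HillFit(F_base=fb, F_max=fm, sigma_half=sh, n_hill=n)


@dataclass
class PatchTruth:
    """Exact per-patch ground truth (post-rasterisation values)."""

    patch_id: int
    behavior: str
    centroid: tuple[float, float]  # (row, col) px, relaxed frame
    n_pixels_relaxed: int
    n_pixels_stretched: int  # net (holes excluded)
    rel_change: float
    sigma: float  # N/m (sigma - sigma0 under the hooke model)
    F_eff: float  # percent
    n_docked: int
    n_hemifused: int
    n_hole_pixels: int


@dataclass
class GroundTruth:
    """Full manifest of one generated scene."""

    patches: list[PatchTruth]
    I_back_red: float
    I_max_red: float
    blue_background: float
    tension_model: str
    pixel_size: float
    seed: int
    spot_positions: list[tuple[int, int, str]] = field(default_factory=list)
    reference_positions: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Scene:
    """Three two-channel frames plus the manifest."""

    relaxed: np.ndarray  # (2, rows, cols)
    stretched: np.ndarray
    post_incubation: np.ndarray
    truth: GroundTruth

    @property
    def frames(self):
        return {
            "relaxed": self.relaxed,
            "stretched": self.stretched,
            "post_incubation": self.post_incubation,
        }


# ---------------------------------------------------------------------------
# rasterisation helpers
# ---------------------------------------------------------------------------

def _nearest_pixels(
    center: tuple[float, float], n: int, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """The n pixels nearest to ``center`` (ties broken in raster order)."""
    r_c, c_c = center
    radius = math.sqrt(n / math.pi) + 3.0
    r0 = max(int(r_c - radius), 0)
    r1 = min(int(r_c + radius) + 2, shape[0])
    c0 = max(int(c_c - radius), 0)
    c1 = min(int(c_c + radius) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rr = rr.ravel()
    cc = cc.ravel()
    d2 = (rr - r_c) ** 2 + (cc - c_c) ** 2
    order = np.lexsort((cc, rr, d2))
    if order.size < n:
        raise ValueError("patch does not fit inside the image")
    sel = order[:n]
    return rr[sel], cc[sel]


def _ellipse_pixels(center, a, b, theta, allowed: np.ndarray):
    """Pixels of a rotated ellipse intersected with the ``allowed`` mask."""
    r_c, c_c = center
    extent = int(max(a, b)) + 2
    r0 = max(int(r_c) - extent, 0)
    r1 = min(int(r_c) + extent + 1, allowed.shape[0])
    c0 = max(int(c_c) - extent, 0)
    c1 = min(int(c_c) + extent + 1, allowed.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - r_c
    dc = cc - c_c
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros_like(allowed)
    mask[r0:r1, c0:c1] = inside
    return mask & allowed


def _carve_holes(
    patch_mask: np.ndarray,
    center: tuple[float, float],
    n_hole_pixels: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Carve 1-5 elliptical holes totalling exactly ``n_hole_pixels``.

    Holes are restricted to the deep interior (3 px inside the boundary) so
    they stay fully enclosed, and the last hole is trimmed or grown pixel
    by pixel to hit the requested total exactly.
    """
    from scipy import ndimage

    if n_hole_pixels <= 0:
        return np.zeros_like(patch_mask)
    interior = ndimage.binary_erosion(patch_mask, iterations=3)
    k = int(rng.integers(1, 6))
    per_hole = n_hole_pixels / k
    holes = np.zeros_like(patch_mask)
    centers = []
    rows, cols = np.nonzero(interior)
    for _ in range(k):
        if holes.sum() >= n_hole_pixels or rows.size == 0:
            break
        idx = int(rng.integers(rows.size))
        hc = (float(rows[idx]), float(cols[idx]))
        aspect = float(rng.uniform(0.5, 2.0))
        a = max(math.sqrt(per_hole * aspect / math.pi), 1.0)
        b = max(per_hole / (math.pi * a), 1.0)
        theta = float(rng.uniform(0, math.pi))
        holes |= _ellipse_pixels(hc, a, b, theta, interior)
        centers.append(hc)
    # exact adjustment around the first hole centre
    count = int(holes.sum())
    anchor = centers[0] if centers else center
    if count > n_hole_pixels:
        hr, hc_ = np.nonzero(holes)
        d2 = (hr - anchor[0]) ** 2 + (hc_ - anchor[1]) ** 2
        order = np.lexsort((hc_, hr, -d2))
        drop = order[: count - n_hole_pixels]
        holes[hr[drop], hc_[drop]] = False
    elif count < n_hole_pixels:
        grow_region = interior & ~holes
        gr, gc = np.nonzero(grow_region)
        d2 = (gr - anchor[0]) ** 2 + (gc - anchor[1]) ** 2
        order = np.lexsort((gc, gr, d2))
        need = n_hole_pixels - count
        if order.size < need:
            raise ValueError("patch interior too small for the requested holes")
        add = order[:need]
        holes[gr[add], gc[add]] = True
    return holes


def _render_spot(channel: np.ndarray, pos: tuple[int, int], amplitude: float) -> None:
    """Add a truncated Gaussian peak (zero beyond SPOT_SUPPORT px)."""
    r, c = pos
    r0, r1 = r - SPOT_SUPPORT, r + SPOT_SUPPORT + 1
    c0, c1 = c - SPOT_SUPPORT, c + SPOT_SUPPORT + 1
    rr, cc = np.mgrid[r0:r1, c0:c1]
    g = amplitude * np.exp(
        -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * SPOT_SIGMA**2)
    )
    g[(rr - r) ** 2 + (cc - c) ** 2 > SPOT_SUPPORT**2] = 0.0
    channel[r0:r1, c0:c1] += g


def _render_ref_disc(channel: np.ndarray, pos: tuple[int, int], value: float) -> None:
    r, c = pos
    rr, cc = np.mgrid[
        r - REF_DISC_RADIUS : r + REF_DISC_RADIUS + 1,
        c - REF_DISC_RADIUS : c + REF_DISC_RADIUS + 1,
    ]
    disc = (rr - r) ** 2 + (cc - c) ** 2 <= REF_DISC_RADIUS**2
    channel[rr[disc], cc[disc]] = value


def _apply_noise(
    frame: np.ndarray, noise: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise on photon counts plus Gaussian read noise."""
    shot, read = noise
    out = frame.astype(np.float64)
    if shot > 0:
        out = rng.poisson(out / shot).astype(np.float64) * shot
    if read > 0:
        out = out + rng.normal(0.0, read, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# patch scenes
# ---------------------------------------------------------------------------

def _docking_lambda(sigma: float, area_um2: float, rate: float) -> float:
    """Expected docked-spot count: linear in tension with a nonzero floor.

    Vesicles also dock to unstressed membrane (just fewer of them); the
    reference density ``rate`` applies at 4 mN/m.
    """
    return rate * area_um2 * (0.25 + 0.75 * max(sigma, 0.0) / 4e-3)


def generate_patch_scene(
    config: SceneConfig,
    params: MechanicalParameters | None = None,
    max_retries: int = 200,
) -> Scene:
    """Generate the three frames of a stretch-and-incubate experiment.

    Frame 0: relaxed patches.  Frame 1: substrate stretched — *follows*
    patches scale isotropically about their centroid by the local strain,
    *slides* patches translate without growing, *ruptures* patches grow
    their outline but lose exactly the gained area to interior holes.
    Frame 2: after vesicle incubation — the vesicle-dye channel carries the
    Hill-law lipid-mixing signal of each patch, docked/hemifused spots and
    the adhered-vesicle reference discs.

    Patch and spot placements that would overlap or touch the border are
    re-sampled; placement failure after ``max_retries`` raises.
    """
    params = params or MechanicalParameters()
    rng = np.random.default_rng(config.seed)
    shape = config.image_shape
    px = config.pixel_size
    hill = config.hill

    blue0 = np.full(shape, BLUE_BACKGROUND)
    blue1 = np.full(shape, BLUE_BACKGROUND)
    red_back = np.full(shape, RED_BACKGROUND)
    blue2 = np.full(shape, BLUE_BACKGROUND)
    red2 = np.full(shape, RED_BACKGROUND)

    occupied = np.zeros(shape, dtype=bool)
    labels_stretched = np.zeros(shape, dtype=np.int32)
    behaviors = ["follows", "slides", "ruptures"]
    truths: list[PatchTruth] = []
    spot_positions: list[tuple[int, int, str]] = []

    for pid in range(1, config.n_patches + 1):
        behavior = behaviors[
            int(rng.choice(3, p=np.asarray(config.patch_behavior_probs)))
        ]
        area = float(rng.uniform(*config.patch_area_range))
        n0 = max(int(round(area / px**2)), 16)
        r_relax = math.sqrt(n0 / math.pi)
        # stretched outline may grow by up to (1+max_dilation)
        r_margin = r_relax * math.sqrt(1.0 + config.max_dilation) + 8.0

        placed = False
        for _ in range(max_retries):
            r_c = float(rng.uniform(r_margin, shape[0] - r_margin))
            c_c = float(rng.uniform(r_margin, shape[1] - r_margin))
            rr, cc = np.mgrid[
                int(r_c - r_margin) : int(r_c + r_margin) + 1,
                int(c_c - r_margin) : int(c_c + r_margin) + 1,
            ]
            footprint = (rr - r_c) ** 2 + (cc - c_c) ** 2 <= r_margin**2
            if not occupied[rr[footprint], cc[footprint]].any():
                occupied[rr[footprint], cc[footprint]] = True
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place patch {pid} after {max_retries} retries"
            )

        # local substrate strain: linear ramp in the column coordinate,
        # zero at the sheet centre
        if config.target_dilations is not None:
            target = float(config.target_dilations[pid - 1])
        else:
            dist_um = abs(c_c - shape[1] / 2.0) * px
            target = min(config.dilation_gradient * dist_um, config.max_dilation)

        rows0, cols0 = _nearest_pixels((r_c, c_c), n0, shape)
        blue0[rows0, cols0] = BLUE_PATCH_AMP

        n_gross = int(round(n0 * (1.0 + target)))
        n_holes = 0
        if behavior == "follows":
            n_net = n_gross
            rows1, cols1 = _nearest_pixels((r_c, c_c), n_gross, shape)
            rel = n_net / n0 - 1.0
            amp1 = BLUE_PATCH_AMP * n0 / n_net  # dye dilution at fixed count
            patch_mask1 = np.zeros(shape, dtype=bool)
            patch_mask1[rows1, cols1] = True
        elif behavior == "slides":
            dr, dc = (int(rng.integers(-3, 4)), int(rng.integers(-3, 4)))
            rows1, cols1 = rows0 + dr, cols0 + dc
            n_net = n0
            rel = 0.0
            amp1 = BLUE_PATCH_AMP
            patch_mask1 = np.zeros(shape, dtype=bool)
            patch_mask1[rows1, cols1] = True
        else:  # ruptures: outline grows, holes give the area back
            rows_g, cols_g = _nearest_pixels((r_c, c_c), n_gross, shape)
            gross_mask = np.zeros(shape, dtype=bool)
            gross_mask[rows_g, cols_g] = True
            n_holes = n_gross - n0
            holes = _carve_holes(gross_mask, (r_c, c_c), n_holes, rng)
            patch_mask1 = gross_mask & ~holes
            n_net = int(patch_mask1.sum())
            rel = n_net / n0 - 1.0  # == 0 exactly by construction
            amp1 = BLUE_PATCH_AMP  # tension relaxed: no dilution

        blue1[patch_mask1] = amp1
        labels_stretched[patch_mask1] = pid

        if config.tension_model == "hooke":
            sigma = tension_hooke(rel, params).sigma
        else:
            sigma = tension_from_area(rel, params).sigma
        f_eff = float(hill_model(max(sigma, 0.0), hill))

        # post-incubation frame: same geometry as stretched
        blue2[patch_mask1] = amp1
        red2[patch_mask1] = RED_BACKGROUND + f_eff / 100.0 * (
            RED_IMAX - RED_BACKGROUND
        )

        # docked / hemifused spots on this patch
        lam = _docking_lambda(sigma, n_net * px**2, config.docking_rate)
        n_spots = int(rng.poisson(lam))
        from scipy import ndimage as _ndi

        spot_allowed = _ndi.binary_erosion(
            patch_mask1, iterations=SPOT_SUPPORT + 2
        )
        ar, ac = np.nonzero(spot_allowed)
        placed_spots: list[tuple[int, int]] = []
        n_docked = n_hemi = 0
        for _ in range(n_spots):
            for _try in range(max_retries):
                if ar.size == 0:
                    break
                j = int(rng.integers(ar.size))
                pos = (int(ar[j]), int(ac[j]))
                if all(
                    (pos[0] - q[0]) ** 2 + (pos[1] - q[1]) ** 2 >= 81
                    for q in placed_spots
                ):
                    break
            else:
                continue
            if ar.size == 0:
                break
            placed_spots.append(pos)
            amp = float(rng.uniform(0.6, 0.95)) * (RED_IMAX - RED_BACKGROUND)
            _render_spot(red2, pos, amp)
            if rng.uniform() < config.hemifused_fraction:
                _render_spot(blue2, pos, 0.5 * amp1)
                spot_positions.append((*pos, "hemifused"))
                n_hemi += 1
            else:
                spot_positions.append((*pos, "docked"))
                n_docked += 1

        truths.append(
            PatchTruth(
                patch_id=pid,
                behavior=behavior,
                centroid=(r_c, c_c),
                n_pixels_relaxed=n0,
                n_pixels_stretched=n_net,
                rel_change=rel,
                sigma=sigma,
                F_eff=f_eff,
                n_docked=n_docked,
                n_hemifused=n_hemi,
                n_hole_pixels=n_holes,
            )
        )

    # adhered-vesicle reference discs on the bare substrate
    ref_positions: list[tuple[int, int]] = []
    margin = REF_DISC_RADIUS + 2
    for _ in range(config.n_reference_spots):
        for _try in range(max_retries):
            r = int(rng.integers(margin, shape[0] - margin))
            c = int(rng.integers(margin, shape[1] - margin))
            rr, cc = np.mgrid[r - margin : r + margin + 1, c - margin : c + margin + 1]
            if not occupied[rr, cc].any() and all(
                (r - q[0]) ** 2 + (c - q[1]) ** 2 >= 144 for q in ref_positions
            ):
                break
        else:
            continue
        ref_positions.append((r, c))
        _render_ref_disc(red2, (r, c), RED_IMAX)

    # assemble frames with bleaching and noise
    decay = 1.0 - config.bleach_rate
    frames = []
    for k, (blue, red) in enumerate(
        ((blue0, red_back), (blue1, red_back.copy()), (blue2, red2))
    ):
        frame = np.stack([blue, red]) * decay**k
        frames.append(_apply_noise(frame, config.noise, rng))

    truth = GroundTruth(
        patches=truths,
        I_back_red=RED_BACKGROUND,
        I_max_red=RED_IMAX,
        blue_background=BLUE_BACKGROUND,
        tension_model=config.tension_model,
        pixel_size=px,
        seed=config.seed,
        spot_positions=spot_positions,
        reference_positions=ref_positions,
    )
    return Scene(frames[0], frames[1], frames[2], truth)


# ---------------------------------------------------------------------------
# GUV stacks
# ---------------------------------------------------------------------------

def generate_guv_stack(
    R_V: float,
    R_i: float,
    voxel_size: float = 0.25,
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    F_eff: float = 16.5,
    dome: bool = True,
    n_docked: int = 12,
    shell_thickness: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Render a sessile GUV as a thin spherical-cap shell in a z-stack.

    Returns a (2, z, rows, cols) stack — channel 0 the GUV membrane dye,
    channel 1 the LUV dye — plus a ground-truth dict.  The adhesion disc at
    the substrate slice carries LUV-dye intensity proportional to the true
    fusion efficiency; docked spots are placed only on the free membrane
    (docking is impossible in the contact zone).
    """
    if not 0 <= R_i <= R_V:
        raise ValueError("requires 0 <= R_i <= R_V")
    rng = np.random.default_rng(seed)
    s = 1.0 if dome else -1.0
    h = R_V + s * math.sqrt(R_V**2 - R_i**2)
    half_w = R_V + 3.0 * voxel_size
    n_xy = 2 * int(math.ceil(half_w / voxel_size)) + 1
    n_z = int(math.ceil((h + 2.0 * voxel_size) / voxel_size)) + 1
    if shell_thickness is None:
        shell_thickness = 1.2 * voxel_size

    zc = h - R_V  # sphere centre height above the substrate (z = 0)
    z = np.arange(n_z) * voxel_size
    y = (np.arange(n_xy) - n_xy // 2) * voxel_size
    x = y.copy()
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    r_sphere = np.sqrt(yy**2 + xx**2 + (zz - zc) ** 2)
    r_lat = np.sqrt(yy**2 + xx**2)

    # the shell is the part of the sphere surface above the substrate plane
    shell = (np.abs(r_sphere - R_V) <= shell_thickness / 2.0) & (zz >= 0)
    if not dome:
        # below-hemisphere cap: only the part above the contact plane belongs
        shell &= zz <= h + shell_thickness

    if R_i > 0:
        adhesion = (zz <= voxel_size / 2.0) & (r_lat <= R_i)
    else:
        adhesion = np.zeros_like(shell)  # free vesicle: no contact zone

    guv_dye = np.full(shell.shape, BLUE_BACKGROUND)
    guv_dye[shell] = BLUE_PATCH_AMP
    guv_dye[adhesion] = BLUE_PATCH_AMP

    luv_dye = np.full(shell.shape, RED_BACKGROUND)
    luv_dye[adhesion] = RED_BACKGROUND + F_eff / 100.0 * (RED_IMAX - RED_BACKGROUND)

    # settled reference vesicles on the substrate around the adhesion zone
    ref_ring = (zz <= voxel_size / 2.0) & (r_lat > R_i + 1.0) & (r_lat < half_w - 1.0)
    ring_z, ring_y, ring_x = np.nonzero(ref_ring)
    ref_positions = []
    for _ in range(4):
        if ring_y.size == 0:
            break
        j = int(rng.integers(ring_y.size))
        pos = (int(ring_y[j]), int(ring_x[j]))
        if all((pos[0] - q[0]) ** 2 + (pos[1] - q[1]) ** 2 >= 144 for q in ref_positions):
            if (
                REF_DISC_RADIUS <= pos[0] < luv_dye.shape[1] - REF_DISC_RADIUS
                and REF_DISC_RADIUS <= pos[1] < luv_dye.shape[2] - REF_DISC_RADIUS
            ):
                _render_ref_disc(luv_dye[int(ring_z[j])], pos, RED_IMAX)
                ref_positions.append(pos)

    # docked spots on the free membrane (strictly above the substrate)
    free = shell & (zz > 2.0 * voxel_size)
    fz, fy, fx = np.nonzero(free)
    docked = []
    for _ in range(n_docked):
        if fz.size == 0:
            break
        j = int(rng.integers(fz.size))
        amp = float(rng.uniform(0.6, 0.95)) * (RED_IMAX - RED_BACKGROUND)
        _render_spot(luv_dye[fz[j]], (int(fy[j]), int(fx[j])), amp)
        docked.append((int(fz[j]), int(fy[j]), int(fx[j])))

    stack = np.stack([guv_dye, luv_dye])
    if max(noise) > 0:
        stack = _apply_noise(stack, noise, rng)

    from memfuse.mechanics import GUVGeometry, guv_geometry_to_dilation

    rel = guv_geometry_to_dilation(GUVGeometry(R_V, R_i, dome))
    truth = {
        "R_V": R_V,
        "R_i": R_i,
        "dome": dome,
        "voxel_size": voxel_size,
        "rel_change": rel,
        "F_eff": F_eff,
        "n_docked": len(docked),
        "docked_positions": docked,
        "reference_positions": ref_positions,
        "I_back": RED_BACKGROUND,
        "I_max": RED_IMAX,
    }
    return stack, truth


def measure_guv_geometry(
    guv_channel: np.ndarray, voxel_size: float, threshold: float | None = None
) -> tuple[float, float]:
    """Geometric read-out of (R_V, R_i) from a noise-free membrane stack.

    R_i from the adhesion-disc area at the substrate slice (pi R_i^2);
    R_V from the largest lateral shell extent over all slices (the equator
    of a past-hemisphere cap).  Accurate to about one voxel; intended for
    render-then-measure round trips, not for noisy data.
    """
    if threshold is None:
        threshold = 0.5 * (BLUE_BACKGROUND + BLUE_PATCH_AMP)
    mask = np.asarray(guv_channel) >= threshold
    bottom = mask[0]
    n_disc = int(bottom.sum())
    r_i = math.sqrt(n_disc / math.pi) * voxel_size
    n_xy = mask.shape[1]
    y = (np.arange(n_xy) - n_xy // 2) * voxel_size
    yy, xx = np.meshgrid(y, y, indexing="ij")
    r_lat = np.sqrt(yy**2 + xx**2)
    r_v = 0.0
    for z in range(1, mask.shape[0]):
        if mask[z].any():
            r_v = max(r_v, float(r_lat[mask[z]].max()))
    return r_v, r_i


# ---------------------------------------------------------------------------
# FRAP curves and tension-response tables
# ---------------------------------------------------------------------------

def generate_frap_curve(
    D: float,
    immobile_fraction: float,
    spot_radius: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    floor: float = 0.0,
) -> FrapCurve:
    """Synthetic recovery curve from the circular-spot closed form."""
    if D <= 0:
        raise ValueError("D must be > 0")
    if not 0 <= immobile_fraction <= 1:
        raise ValueError("immobile_fraction must be in [0, 1]")
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and > 0")
    tau_d = spot_radius**2 / (4.0 * D)
    y = np.asarray(recovery_model(times, tau_d, immobile_fraction, floor), dtype=float)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return FrapCurve(times=times, intensities=y, spot_radius=spot_radius)


def generate_tension_response_dataset(
    hill_truth: tuple[float, float, float, float],
    n_points: int,
    tension_range: tuple[float, float] = (0.0, 6e-3),
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Table of (sigma, F_eff) pairs from a Hill law plus Gaussian noise."""
    import pandas as pd

    if n_points < 8:
        raise ValueError("need at least 8 points")
    lo, hi = tension_range
    if not (0 <= lo < hi <= 10e-3):
        raise ValueError("tension range must lie within [0, 10 mN/m]")
    fb, fm, sh, n = hill_truth
    hill = HillFit(F_base=fb, F_max=fm, sigma_half=sh, n_hill=n)
    sigma = np.linspace(lo, hi, n_points)
    F = np.asarray(hill_model(sigma, hill), dtype=float)
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, size=F.shape)
    return pd.DataFrame({"sigma_N_per_m": sigma, "F_eff_percent": F})


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_scene(directory, config: SceneConfig, scene: Scene) -> None:
    """Write the scene as 16-bit multi-page TIFFs + JSON manifest + YAML config.

    One TIFF per frame, one page per channel.
    """
    import pathlib

    import tifffile
    import yaml

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for label, frame in scene.frames.items():
        data = np.clip(np.round(frame), 0, 65535).astype(np.uint16)
        tifffile.imwrite(directory / f"{label}.tif", data)
    manifest = {
        "patches": [asdict(p) for p in scene.truth.patches],
        "I_back_red": scene.truth.I_back_red,
        "I_max_red": scene.truth.I_max_red,
        "blue_background": scene.truth.blue_background,
        "tension_model": scene.truth.tension_model,
        "pixel_size": scene.truth.pixel_size,
        "seed": scene.truth.seed,
        "spot_positions": [list(s) for s in scene.truth.spot_positions],
        "reference_positions": [list(s) for s in scene.truth.reference_positions],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    cfg = {
        k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()
    }
    (directory / "scene_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_manifest(directory) -> dict:
    import pathlib

    return json.loads((pathlib.Path(directory) / "manifest.json").read_text())
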