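"""End-to-end analysis: frames in, per-patch tension/fusion table out.

Ties the stages together exactly as they are applied to a real field:
threshold the membrane-dye channel of the relaxed frame (the same threshold
is reused on the later frames of the field to avoid bias), segment and
measure patches with holes subtracted, match patches between the relaxed
and stretched frames, convert the area dilatation to lateral tension,
quantify lipid mixing in the vesicle-dye channel of the post-incubation
frame with docked/hemifused vesicles excluded, and pool patches for the
Hill fit of fusion efficiency versus tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from memfuse import segmentation as seg
from memfuse import fusion as fq
from memfuse.mechanics import (
    MechanicalParameters,
    propagate_uncertainty,
    tension_from_area,
    tension_hooke,
)
from memfuse.response import HillFit, fit_hill

__all__ = [
    "AnalysisOptions",
    "analyze_scene",
    "analyze_experiment",
    "analyze_guv_stack",
    "synthetic_tension_experiment",
]


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunables of the standard analysis."""

    pixel_size: float = 0.132  # um
    min_segment_size: float = 20.0  # um^2, pre-filter for specks
    min_patch_area: float = 100.0  # um^2, analysis window (relaxed frame)
    max_patch_area: float = 7000.0
    area_err: float = 0.0  # um^2 per-frame area uncertainty, propagated if set
    tension_model: str = "hooke"
    spot_radius_range: tuple[float, float] = (1.0, 4.0)


def analyze_scene(
    relaxed: np.ndarray,
    stretched: np.ndarray,
    post_incubation: np.ndarray | None = None,
    options: AnalysisOptions | None = None,
    params: MechanicalParameters | None = None,
) -> pd.DataFrame:
    """Analyse one field: (2, rows, cols) frames -> per-patch table.

    Channel 0 is the membrane dye, channel 1 the vesicle dye.  Returns one
    row per matched, size-filtered patch with columns for areas (um^2),
    dilatation, tension (mN/m), fusion efficiency (percent) and event
    counts.  Without a post-incubation frame the fusion columns are NaN.
    """
    options = options or AnalysisOptions()
    params = params or MechanicalParameters()
    px = options.pixel_size

    for name, frame in (("relaxed", relaxed), ("stretched", stretched)):
        if frame.ndim != 3 or frame.shape[0] < 2:
            raise ValueError(f"{name} frame must have two channels (2, rows, cols)")

    threshold = seg.li_threshold(relaxed[0])
    labels_r, recs_r = seg.segment_patches(
        relaxed[0], threshold, px, options.min_segment_size, "relaxed"
    )
    labels_s, recs_s = seg.segment_patches(
        stretched[0], threshold, px, options.min_segment_size, "stretched"
    )
    pairs, _, _ = seg.match_patches(recs_r, recs_s)

    # hole-aware measurement and the analysis size window (relaxed areas)
    rows = []
    fusion_ready = post_incubation is not None
    if fusion_ready:
        if post_incubation.ndim != 3 or post_incubation.shape[0] < 2:
            raise ValueError("post-incubation frame must have two channels")
        spots = fq.detect_vesicle_spots(
            post_incubation[1], options.spot_radius_range
        )
        I_back = fq.estimate_background(post_incubation[1], labels_s, spots)
        try:
            I_max = fq.estimate_imax(post_incubation[1], spots)
        except ValueError:
            fusion_ready = False
            spots, I_back, I_max = [], 0.0, 1.0
        if fusion_ready:
            blue_back = float(np.median(post_incubation[0][labels_s == 0]))
            counts = _classify_and_count(
                spots, post_incubation[0], labels_s, blue_back
            )

    for rec_r, rec_s in pairs:
        full_r = seg.measure_patch_area(labels_r, rec_r.patch_id, px, "relaxed")
        full_s = seg.measure_patch_area(labels_s, rec_s.patch_id, px, "stretched")
        if not options.min_patch_area <= full_r.net_area <= options.max_patch_area:
            continue
        dil = seg.compute_area_dilation(
            full_r, full_s, options.area_err, options.area_err
        )
        if options.tension_model == "hooke":
            est = tension_hooke(dil.rel_change, params)
            err = propagate_uncertainty(dil.rel_change_err, params, "hooke")
        else:
            est = tension_from_area(
                dil.rel_change, params, rel_change_err=dil.rel_change_err
            )
            err = est.sigma_err

        row = {
            "patch_id": rec_s.patch_id,
            "A0_um2": dil.A0,
            "Am_um2": dil.Am,
            "rel_change": dil.rel_change,
            "rel_change_err": dil.rel_change_err,
            "sigma_N_per_m": est.sigma,
            "sigma_err_N_per_m": err,
            "sigma_mN_per_m": est.sigma * 1e3,
            "tension_model": est.model,
            "F_eff_percent": np.nan,
            "I_patch": np.nan,
            "I_back": np.nan,
            "I_max": np.nan,
            "n_docked": 0,
            "n_hemifused": 0,
        }
        if fusion_ready:
            m = fq.measure_patch_intensity(
                post_incubation[1], labels_s, rec_s.patch_id, spots, I_back, I_max
            )
            row["F_eff_percent"] = fq.fusion_efficiency(m)
            row["I_patch"] = m.I_patch
            row["I_back"] = I_back
            row["I_max"] = I_max
            ev = counts.get(rec_s.patch_id, {"docked": 0, "hemifused": 0})
            row["n_docked"] = ev["docked"]
            row["n_hemifused"] = ev["hemifused"]
        rows.append(row)

    return pd.DataFrame(rows)


def synthetic_tension_experiment(
    seed: int = 0,
    n_patches: int = 30,
    sigma_max: float = 6e-3,
    hill_truth: tuple[float, float, float, float] = (1.3, 4.2, 3.4e-3, 4.0),
    patches_per_scene: int = 3,
    params: MechanicalParameters | None = None,
) -> tuple[pd.DataFrame, HillFit]:
    """Blind closed-loop experiment: simulate fields, analyse them, fit Hill.

    Generates enough fields to pool ``n_patches`` membrane patches whose
    planted dilatations span tensions from 0 to ``sigma_max`` (Hookean
    model), runs the full analysis without looking at the ground truth, and
    fits the Hill curve to the pooled (tension, efficiency) pairs.  The
    recovered sigma_half is then comparable to ``hill_truth[2]``.
    """
    from memfuse.simulate import SceneConfig, generate_patch_scene

    params = params or MechanicalParameters()
    dilations = np.linspace(0.0, sigma_max / params.K_A, n_patches)
    scenes = []
    for i in range(0, n_patches, patches_per_scene):
        chunk = tuple(dilations[i : i + patches_per_scene])
        cfg = SceneConfig(
            n_patches=len(chunk),
            patch_area_range=(150.0, 400.0),
            patch_behavior_probs=(1.0, 0.0, 0.0),
            target_dilations=chunk,
            hill_truth=hill_truth,
            seed=(seed * 1009 + i) % 2**31,
        )
        scene = generate_patch_scene(cfg, params)
        scenes.append((scene.relaxed, scene.stretched, scene.post_incubation))
    return analyze_experiment(scenes, params=params)


def analyze_guv_stack(
    stack: np.ndarray,
    voxel_size: float,
    params: MechanicalParameters | None = None,
) -> dict:
    """Sessile-GUV route: z-stack in, tension and fusion efficiency out.

    ``stack`` is (2, z, rows, cols): channel 0 the GUV membrane dye,
    channel 1 the LUV dye.  The cap geometry (R_V, R_i) is read from the
    membrane shell, converted to an area dilatation by volume-conserving
    cap algebra and inverted through the undulation model; lipid mixing is
    the LUV-dye intensity of the contact zone (where docking is impossible)
    referenced to the brightest settled vesicle on the substrate slice.
    """
    from memfuse.mechanics import GUVGeometry, guv_geometry_to_dilation, guv_tension
    from memfuse.simulate import measure_guv_geometry

    params = params or MechanicalParameters()
    if stack.ndim != 4 or stack.shape[0] < 2:
        raise ValueError("GUV stack must have shape (2, z, rows, cols)")
    guv_dye, luv_dye = np.asarray(stack[0], float), np.asarray(stack[1], float)
    threshold = seg.li_threshold(guv_dye)
    r_v, r_i = measure_guv_geometry(guv_dye, voxel_size, threshold)
    geom = GUVGeometry(R_V=r_v, R_i=min(r_i, r_v), dome=True)
    est = guv_tension(geom, params)

    n_xy = luv_dye.shape[1]
    axis = (np.arange(n_xy) - n_xy // 2) * voxel_size
    yy, xx = np.meshgrid(axis, axis, indexing="ij")
    adhesion = np.sqrt(yy**2 + xx**2) <= max(r_i - voxel_size, 0.0)
    if not adhesion.any():
        raise ValueError("no adhesion zone detected (free vesicle?)")

    substrate = luv_dye[0]
    spots = fq.detect_vesicle_spots(substrate)
    smask = fq.spot_mask(substrate.shape, spots)
    back_pix = substrate[~adhesion & ~smask]
    I_back = float(np.median(back_pix))
    I_max = fq.estimate_imax(substrate, spots)
    m = fq.guv_adhesion_intensity(luv_dye, adhesion, I_back=I_back, I_max=I_max)
    return {
        "R_V_um": r_v,
        "R_i_um": r_i,
        "rel_change": guv_geometry_to_dilation(geom),
        "sigma_N_per_m": est.sigma,
        "sigma_mN_per_m": est.sigma * 1e3,
        "F_eff_percent": fq.fusion_efficiency(m),
        "I_adhesion": m.I_patch,
        "I_back": I_back,
        "I_max": I_max,
    }


def _classify_and_count(spots, blue_channel, labels, blue_back):
    """Classify every spot against its local membrane-dye baseline."""
    labels = np.asarray(labels)
    blue = np.asarray(blue_channel, dtype=np.float64)
    smask = fq.spot_mask(blue.shape, spots)
    for s in spots:
        pid = int(labels[s.position])
        if pid:
            pix = blue[(labels == pid) & ~smask]
        else:
            pix = blue[(labels == 0) & ~smask]
        med = float(np.median(pix))
        sd = float(np.median(np.abs(pix - med))) * fq.MAD_SCALE
        baseline = med if pid else blue_back
        fq.classify_spot(s, blue, baseline, max(sd, 1e-6))
    return fq.count_events(spots, labels)


def analyze_experiment(
    scenes: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    options: AnalysisOptions | None = None,
    params: MechanicalParameters | None = None,
) -> tuple[pd.DataFrame, HillFit]:
    """Pool per-patch results from several fields and fit the Hill curve.

    ``scenes`` is a list of (relaxed, stretched, post_incubation) frame
    triples.  Returns the pooled table and the Hill fit of fusion
    efficiency (percent) versus tension (N/m).
    """
    tables = [
        analyze_scene(r, s, p, options, params).assign(scene=i)
        for i, (r, s, p) in enumerate(scenes)
    ]
    pooled = pd.concat(tables, ignore_index=True)
    ok = pooled["F_eff_percent"].notna()
    fit = fit_hill(
        pooled.loc[ok, "sigma_N_per_m"].to_numpy(),
        pooled.loc[ok, "F_eff_percent"].to_numpy(),
    )
    return pooled, fit
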