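"""FRAP: fluorescence recovery after photobleaching for a circular spot.

Recovery of a uniformly bleached circular spot of radius w in a 2-D
membrane with lateral diffusion coefficient D follows the Soumpasis
closed form

    f(t) = exp(-2 tau_D / t) [ I0(2 tau_D / t) + I1(2 tau_D / t) ],
    tau_D = w^2 / (4 D),

where I0, I1 are modified Bessel functions of the first kind.  f rises
monotonically from 0 to 1.  A fraction of the dye may be immobile and a
bleach floor may remain, so the observed normalised intensity is

    I(t) = floor + (1 - immobile) (1 - floor) f(t).

Fitting is bounded nonlinear least squares over (tau_D, immobile, floor)
from a deterministic multi-start grid; D is recovered as w^2/(4 tau_D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import i0e, i1e

__all__ = ["FrapCurve", "FrapFit", "normalize_frap", "recovery_model", "fit_frap"]


@dataclass(frozen=True)
class FrapCurve:
    """A normalised post-bleach recovery curve.

    ``times`` are seconds after the end of the bleach (strictly increasing,
    > 0); ``intensities`` are normalised so the pre-bleach level is 1.
    """

    times: np.ndarray
    intensities: np.ndarray
    spot_radius: float  # um
    pre_bleach: float = 1.0
    post_bleach: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if not (np.all(t > 0) and np.all(np.diff(t) > 0)):
            raise ValueError("times must be strictly increasing and > 0")
        if not self.spot_radius > 0:
            raise ValueError("spot_radius must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(
            self, "intensities", np.asarray(self.intensities, dtype=float)
        )


@dataclass(frozen=True)
class FrapFit:
    """Fitted diffusion coefficient and immobile fraction."""

    D: float  # um^2/s
    immobile_fraction: float
    tau_D: float  # s
    floor: float
    rms_residual: float
    spot_radius: float
    warnings: tuple[str, ...] = ()


def normalize_frap(
    times: np.ndarray,
    intensities: np.ndarray,
    pre_bleach: float,
    background: float,
    spot_radius: float,
    bleach_end: float = 0.0,
) -> FrapCurve:
    """Map raw intensities to (I - background)/(pre_bleach - background).

    Times are re-zeroed at the end of the bleach.  The normalisation is
    affine-invariant: applying gain and offset to the raw data (and its
    pre-bleach/background references) leaves the curve unchanged.
    """
    if pre_bleach <= background:
        raise ValueError("pre-bleach level must exceed background")
    t = np.asarray(times, dtype=float) - bleach_end
    norm = (np.asarray(intensities, dtype=float) - background) / (
        pre_bleach - background
    )
    return FrapCurve(times=t, intensities=norm, spot_radius=spot_radius)


def recovery_model(
    t: np.ndarray | float,
    tau_D: float,
    immobile_fraction: float = 0.0,
    floor: float = 0.0,
) -> np.ndarray | float:
    """Normalised intensity of the circular-spot recovery at time(s) t.

    Uses exponentially scaled Bessel functions for numerical stability at
    small t (large argument): e^{-x}(I0(x)+I1(x)) = i0e(x) + i1e(x).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    x = 2.0 * tau_D / t
    mobile = i0e(x) + i1e(x)
    out = floor + (1.0 - immobile_fraction) * (1.0 - floor) * mobile
    return out if out.ndim else float(out)


#: multi-start grid: tau_D as fractions of the record length, immobile guesses
_TAU_STARTS = (1.0 / 30.0, 1.0 / 10.0, 1.0 / 3.0)
_IMMOBILE_STARTS = (0.0, 0.2, 0.5)


def fit_frap(curve: FrapCurve) -> FrapFit:
    """Fit (tau_D, immobile_fraction, floor) to a recovery curve.

    Bounded least squares (tau_D > 0, fractions in [0, 1]) started from a
    fixed 3x3 grid of initial values; the start with the smallest residual
    wins, ties going to the smallest tau_D, so the fit is deterministic.
    Emits warnings (on the result) if fewer than 8 points are available or
    the record is shorter than 3 tau_D.
    """
    t = curve.times
    y = curve.intensities
    warnings = []
    if t.size < 8:
        warnings.append(f"only {t.size} post-bleach points (< 8)")
    t_max = float(t[-1])

    def residuals(p):
        return recovery_model(t, p[0], p[1], p[2]) - y

    best = None
    for tau_frac in _TAU_STARTS:
        for imm0 in _IMMOBILE_STARTS:
            x0 = [tau_frac * t_max, imm0, max(min(float(y[0]), 0.9), 0.0)]
            try:
                sol = least_squares(
                    residuals,
                    x0,
                    bounds=([1e-12, 0.0, 0.0], [np.inf, 1.0, 1.0]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            cost = float(np.sqrt(2.0 * sol.cost / t.size))
            key = (round(cost, 12), sol.x[0])
            if best is None or key < best[0]:
                best = (key, sol, cost)
    if best is None:
        raise RuntimeError(
            "FRAP fit failed to converge from every start of the multi-start grid"
        )
    _, sol, rms = best
    tau_D, immobile, floor = sol.x
    if t_max < 3.0 * tau_D:
        warnings.append(
            f"record ({t_max:g} s) shorter than 3*tau_D ({3 * tau_D:g} s)"
        )
    return FrapFit(
        D=curve.spot_radius**2 / (4.0 * tau_D),
        immobile_fraction=float(immobile),
        tau_D=float(tau_D),
        floor=float(floor),
        rms_residual=rms,
        spot_radius=curve.spot_radius,
        warnings=tuple(warnings),
    )
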