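"""Fusion efficiency versus lateral tension: pooling, binning, Hill fit.

Pooled per-patch (or per-GUV) pairs (sigma, F_eff) show a sigmoidal rise of
fusion efficiency above a threshold tension.  The transition is summarised
by a four-parameter Hill curve with an additive baseline,

    F(sigma) = F_base + (F_max - F_base) sigma^n / (sigma_half^n + sigma^n),

which captures a nonzero low-tension efficiency (F_base), a saturating
high-tension plateau (F_max), the half-transition tension sigma_half and
the steepness n.  The fit is descriptive (it "guides the eye"), not a
mechanistic kinetic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HillFit",
    "hill_model",
    "fit_hill",
    "bin_by_tension",
    "plot_tension_response",
]


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters; tensions in N/m, efficiencies in percent."""

    F_base: float
    F_max: float
    sigma_half: float
    n_hill: float
    perr: tuple[float, float, float, float] | None = None
    rms_residual: float = float("nan")
    n_points: int = 0
    degenerate: bool = False

    def __call__(self, sigma):
        return hill_model(sigma, self)


def hill_model(sigma, fit: HillFit):
    """Evaluate the Hill curve at tension(s) sigma (N/m)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    with np.errstate(divide="ignore"):
        sn = np.where(sigma > 0, sigma**fit.n_hill, 0.0)
    out = fit.F_base + (fit.F_max - fit.F_base) * sn / (fit.sigma_half**fit.n_hill + sn)
    return out if out.ndim else float(out)


_N_STARTS = (1.0, 2.0, 4.0)
_HALF_FRACS = (0.25, 0.5, 0.75)


def fit_hill(
    sigma: np.ndarray,
    F: np.ndarray,
    weights: np.ndarray | None = None,
) -> HillFit:
    """Bounded least-squares Hill fit of F_eff (percent) vs tension (N/m).

    Requires >= 6 points with >= 3 distinct tensions.  Bounds: n in
    [0.5, 10], sigma_half within the positive data range.  A deterministic
    multi-start grid over (sigma_half, n) is used; best residual wins, ties
    to the smallest sigma_half.  Flat data (zero F variance) short-circuits
    to a degenerate fit with F_max = F_base and an undefined sigma_half.
    ``weights`` are optional inverse-variance weights per point.
    """
    sigma = np.asarray(sigma, dtype=float)
    F = np.asarray(F, dtype=float)
    if sigma.size != F.size:
        raise ValueError("sigma and F must have equal length")
    if sigma.size < 6:
        raise ValueError("need at least 6 points")
    if np.unique(sigma).size < 3:
        raise ValueError("need at least 3 distinct tension values")
    w = np.ones_like(F) if weights is None else np.sqrt(np.asarray(weights, float))

    if np.ptp(F) == 0.0:
        return HillFit(
            F_base=float(F[0]),
            F_max=float(F[0]),
            sigma_half=float("nan"),
            n_hill=1.0,
            n_points=sigma.size,
            rms_residual=0.0,
            degenerate=True,
        )

    pos = sigma[sigma > 0]
    s_lo = float(pos.min()) if pos.size else 1e-6
    s_hi = float(sigma.max())
    f_lo, f_hi = float(F.min()), float(F.max())
    span = f_hi - f_lo

    def residuals(p):
        fit = HillFit(F_base=p[0], F_max=p[1], sigma_half=p[2], n_hill=p[3])
        return w * (hill_model(sigma, fit) - F)

    lower = [f_lo - span, f_lo - span, s_lo, 0.5]
    upper = [f_hi + span, f_hi + span, s_hi, 10.0]
    best = None
    for frac in _HALF_FRACS:
        for n0 in _N_STARTS:
            x0 = [f_lo, f_hi, s_lo + frac * (s_hi - s_lo), n0]
            try:
                sol = least_squares(
                    residuals, x0, bounds=(lower, upper),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            rms = float(np.sqrt(2.0 * sol.cost / sigma.size))
            key = (round(rms, 12), sol.x[2])
            if best is None or key < best[0]:
                best = (key, sol, rms)
    if best is None:
        raise RuntimeError("Hill fit failed from every start")
    _, sol, rms = best

    # asymptotic parameter errors from the Jacobian (Gauss-Newton covariance)
    perr = None
    dof = sigma.size - 4
    if dof > 0:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (2.0 * sol.cost / dof)
            perr = tuple(float(x) for x in np.sqrt(np.diag(cov)))
        except np.linalg.LinAlgError:
            perr = None
    return HillFit(
        F_base=float(sol.x[0]),
        F_max=float(sol.x[1]),
        sigma_half=float(sol.x[2]),
        n_hill=float(sol.x[3]),
        perr=perr,
        rms_residual=rms,
        n_points=int(sigma.size),
    )


def plot_tension_response(sigma, F, fit: HillFit | None = None, ax=None):
    """Scatter of pooled (tension, efficiency) pairs with the Hill curve.

    Tensions are plotted in mN/m.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sigma = np.asarray(sigma, dtype=float)
    ax.plot(sigma * 1e3, F, "ko", ms=4, label="patches / GUVs")
    if fit is not None and not fit.degenerate:
        grid = np.linspace(0.0, sigma.max() * 1.05, 300)
        ax.plot(grid * 1e3, hill_model(grid, fit), "r-", label="Hill fit")
    ax.set_xlabel("lateral tension $\\sigma$ (mN/m)")
    ax.set_ylabel("fusion efficiency $F_\\mathrm{eff}$ (%)")
    ax.legend(frameon=False)
    return ax


def bin_by_tension(
    sigma: np.ndarray, F: np.ndarray, edges: np.ndarray
) -> list[dict]:
    """Bin (sigma, F) pairs into tension bins and report mean, sd, count.

    Bins are left-closed/right-open, except the last which is closed on
    both sides.  Empty bins are reported with count 0 and NaN statistics.
    """
    sigma = np.asarray(sigma, dtype=float)
    F = np.asarray(F, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    out = []
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        if i == edges.size - 2:
            sel = (sigma >= lo) & (sigma <= hi)
        else:
            sel = (sigma >= lo) & (sigma < hi)
        vals = F[sel]
        out.append(
            {
                "lo": float(lo),
                "hi": float(hi),
                "count": int(vals.size),
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            }
        )
    return out
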