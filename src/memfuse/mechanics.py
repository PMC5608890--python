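"""Tension <-> area-dilatation conversions for lipid bilayers.

Two constitutive models are implemented.  The Hookean law

    sigma = sigma0 + K_A * (dA/A0)

relates lateral tension directly to the relative area change through the
area compressibility modulus ``K_A``; it applies to strongly coupled,
supported bilayers where thermal undulations are suppressed.  For weakly
adhered vesicles the excess area stored in thermal undulations matters and
the dilatation picks up a logarithmic entropic term

    dA/A0 = (sigma - sigma0)/K_A + (k_B T / 8 pi kappa) * ln(sigma/sigma0)

with bending rigidity ``kappa`` and pre-stress ``sigma0``.  The forward map
is evaluated exactly; the inverse (tension from a measured dilatation) is a
bracketed root search on the strictly monotone forward function.

By convention the Hookean model reports the tension *difference*
``sigma - sigma0`` (the pre-stress of a freshly deposited patch is not
individually known), while the undulation model reports absolute tension.
The ``model`` tag on :class:`TensionEstimate` disambiguates.

Units are SI throughout (N/m, J, K); display conversion to mN/m is left to
the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.constants import k as BOLTZMANN  # J/K

__all__ = [
    "MechanicalParameters",
    "TensionEstimate",
    "GUVGeometry",
    "tension_hooke",
    "area_from_tension",
    "tension_from_area",
    "guv_geometry_to_dilation",
    "guv_tension",
    "propagate_uncertainty",
    "strain_from_markers",
]

# Default material constants for the DOPC/DOPE/DOPS/cholesterol composition:
# K_A = 0.28 N/m, kappa = 0.85e-19 J (~21 k_B T at 293 K), pre-stress
# sigma0 = 9.7e-5 N/m for vesicles prior to adhesion.
DEFAULT_KA = 0.28
DEFAULT_KAPPA = 0.85e-19
DEFAULT_SIGMA0 = 9.7e-5
DEFAULT_TEMPERATURE = 293.0


@dataclass(frozen=True)
class MechanicalParameters:
    """Material constants shared by all tension computations.

    Parameters
    ----------
    K_A : float
        Area compressibility modulus, N/m.
    kappa : float
        Bending rigidity, J.
    sigma0 : float
        Pre-stress tension, N/m.
    temperature : float
        Absolute temperature, K.
    """

    K_A: float = DEFAULT_KA
    kappa: float = DEFAULT_KAPPA
    sigma0: float = DEFAULT_SIGMA0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("K_A", "kappa", "sigma0", "temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        ratio = self.kappa_in_kT
        if not 1.0 <= ratio <= 1000.0:
            raise ValueError(
                f"kappa/(k_B T) = {ratio:.3g} outside the plausible bilayer "
                "range [1, 1000]"
            )

    @property
    def kT(self) -> float:
        """Thermal energy k_B * T in J."""
        return BOLTZMANN * self.temperature

    @property
    def kappa_in_kT(self) -> float:
        """Bending rigidity in units of k_B T."""
        return self.kappa / self.kT

    @property
    def undulation_prefactor(self) -> float:
        """k_B T / (8 pi kappa), the entropic-term prefactor."""
        return self.kT / (8.0 * math.pi * self.kappa)


@dataclass(frozen=True)
class TensionEstimate:
    """A lateral-tension value with uncertainty and model provenance.

    ``sigma`` is sigma - sigma0 for ``model='hooke'`` and absolute sigma for
    ``model='undulation'``.
    """

    sigma: float
    sigma_err: float = 0.0
    model: str = "hooke"

    def __post_init__(self) -> None:
        if self.sigma_err < 0:
            raise ValueError("sigma_err must be >= 0")
        if self.model not in ("hooke", "undulation"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "undulation" and not self.sigma > 0:
            raise ValueError("undulation-model tension must be > 0")

    @property
    def sigma_mN_per_m(self) -> float:
        return self.sigma * 1e3


@dataclass(frozen=True)
class GUVGeometry:
    """Spherical-cap geometry of a sessile vesicle.

    ``R_V`` is the spherical radius of the cap and ``R_i`` the contact
    (adhesion) radius, both in um.  ``dome`` is True when the cap exceeds a
    hemisphere (the usual strongly adhered case).
    """

    R_V: float
    R_i: float
    dome: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.R_i <= self.R_V:
            raise ValueError("geometry requires 0 <= R_i <= R_V")


def tension_hooke(
    rel_change: float, params: MechanicalParameters | None = None
) -> TensionEstimate:
    """Hookean tension difference sigma - sigma0 = K_A * dA/A0.

    Negative dilatation (compression) gives a negative tension difference.
    """
    params = params or MechanicalParameters()
    if rel_change < -1:
        raise ValueError("rel_change must be >= -1")
    return TensionEstimate(sigma=params.K_A * rel_change, model="hooke")


def area_from_tension(
    sigma: float, params: MechanicalParameters | None = None
) -> float:
    """Area dilatation dA/A0 at absolute tension ``sigma`` (undulation model).

    Evaluates the Hookean term plus the entropic undulation term
    (k_B T / 8 pi kappa) ln(sigma/sigma0).  Strictly increasing in sigma.
    """
    params = params or MechanicalParameters()
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return (sigma - params.sigma0) / params.K_A + (
        params.undulation_prefactor * math.log(sigma / params.sigma0)
    )


#: Bracket for the numerical inversion of the undulation model, N/m.
_SIGMA_BRACKET = (1e-9, 1.0)


def tension_from_area(
    rel_change: float,
    params: MechanicalParameters | None = None,
    rel_change_err: float = 0.0,
) -> TensionEstimate:
    """Invert the undulation model: absolute sigma with area_from_tension(sigma) = dA/A0.

    The forward map is strictly monotone so the root on the bracket
    [1e-9, 1] N/m is unique; it is found by Brent's method to 1e-10
    relative tolerance.  Dilatations below the value at the lower bracket
    edge are not resolvable and raise ``ValueError``.
    """
    params = params or MechanicalParameters()
    lo, hi = _SIGMA_BRACKET
    f_lo = area_from_tension(lo, params) - rel_change
    f_hi = area_from_tension(hi, params) - rel_change
    if f_lo > 0:
        raise ValueError(
            "tension below resolvable range: dA/A0 smaller than the value at "
            f"sigma = {lo:g} N/m"
        )
    if f_hi < 0:
        raise ValueError("dA/A0 exceeds the value at the upper bracket (1 N/m)")
    sigma = brentq(
        lambda s: area_from_tension(s, params) - rel_change,
        lo,
        hi,
        rtol=1e-12,
        xtol=1e-15,
        maxiter=200,
    )
    err = (
        propagate_uncertainty(rel_change_err, params, model="undulation", sigma=sigma)
        if rel_change_err
        else 0.0
    )
    return TensionEstimate(sigma=sigma, sigma_err=err, model="undulation")


def guv_geometry_to_dilation(geom: GUVGeometry) -> float:
    """Relative area dilatation of an adhered vesicle from its cap shape.

    The sessile vesicle is a spherical cap of radius ``R_V`` truncated at
    the substrate with contact radius ``R_i``.  Cap height
    h = R_V + s*sqrt(R_V^2 - R_i^2) (s = +1 past the hemisphere, -1 below),
    membrane area A_m = 2 pi R_V h + pi R_i^2 (free cap plus adhesion disc),
    enclosed volume V = (pi h^2 / 3)(3 R_V - h).  Assuming the volume is
    conserved from the free, spherical state of radius R_0 = (3V/4pi)^{1/3},
    the dilatation is A_m / (4 pi R_0^2) - 1.  It is >= 0, with equality
    only for the free sphere (R_i = 0, dome).
    """
    s = 1.0 if geom.dome else -1.0
    h = geom.R_V + s * math.sqrt(geom.R_V**2 - geom.R_i**2)
    if h <= 0:
        raise ValueError("degenerate cap (zero height)")
    area_m = 2.0 * math.pi * geom.R_V * h + math.pi * geom.R_i**2
    volume = (math.pi * h**2 / 3.0) * (3.0 * geom.R_V - h)
    r0 = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return area_m / (4.0 * math.pi * r0**2) - 1.0


def guv_tension(
    geom: GUVGeometry,
    params: MechanicalParameters | None = None,
    rel_change_err: float = 0.0,
) -> TensionEstimate:
    """Absolute membrane tension of a sessile vesicle from its cap geometry.

    Composition of :func:`guv_geometry_to_dilation` (volume-conserving cap
    algebra) and :func:`tension_from_area` (undulation-model inversion).
    """
    rel = guv_geometry_to_dilation(geom)
    return tension_from_area(rel, params, rel_change_err=rel_change_err)


def propagate_uncertainty(
    rel_change_err: float,
    params: MechanicalParameters | None = None,
    model: str = "hooke",
    sigma: float | None = None,
) -> float:
    """First-order propagation of a dA/A0 uncertainty into a tension uncertainty.

    Hooke: sigma_err = K_A * rel_change_err.  Undulation: delta method with
    d sigma / d(dA/A0) = 1 / (1/K_A + k_B T / (8 pi kappa sigma)) evaluated
    at the tension estimate ``sigma``.
    """
    params = params or MechanicalParameters()
    if rel_change_err < 0:
        raise ValueError("rel_change_err must be >= 0")
    if model == "hooke":
        return params.K_A * rel_change_err
    if model == "undulation":
        if sigma is None:
            raise ValueError("undulation-model propagation needs sigma")
        dsigma_dA = 1.0 / (1.0 / params.K_A + params.undulation_prefactor / sigma)
        return dsigma_dA * rel_change_err
    raise ValueError(f"unknown model {model!r}")


def strain_from_markers(
    d1: float, d1_after: float, d2: float, d2_after: float
) -> float:
    """Local area dilatation from two approximately orthogonal fiducial-marker pairs.

    With stretch ratios lambda_i = d_i'/d_i along the two directions the
    area of the deformed unit cell is lambda_1*lambda_2, so
    dA/A0 = lambda_1*lambda_2 - 1.  Used to calibrate substrate dilation
    from markers (e.g. quantum dots) embedded in the elastomer.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("baseline marker distances must be > 0")
    return (d1_after / d1) * (d2_after / d2) - 1.0
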