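"""Ball–Woodrow–Berry / Leuning / Yin stomatal conductance model.

Stomatal conductance to CO2 responds to the photosynthetic flux and to vapor
pressure deficit:

    gs = g0 + (A + Rd) / (Ci − Ci*) · fvpd,   fvpd = 1 / [1/(a1 − b1·VPD) − 1]

where g0 is the residual conductance as irradiance approaches zero, a1 is the
Ci/Ca ratio for vapor-saturated air, b1 the decline of that ratio per kPa of
VPD, and Ci* = Γ* − Rd/gm is the Ci-based CO2 compensation point in the
absence of day respiration.  Instruments report stomatal conductance on a
water-vapor basis; dividing by 1.6 (the ratio of the diffusivities of water
vapor and CO2 in air) converts it to the CO2 basis used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "StomatalParams",
    "FvpdDomainError",
    "fvpd",
    "ci_star",
    "gs_model",
    "gs_water_to_co2",
    "GS_WATER_TO_CO2_FACTOR",
]

#: Ratio of diffusivities of H2O and CO2 in air.
GS_WATER_TO_CO2_FACTOR = 1.6


class FvpdDomainError(ValueError):
    """a1 − b1·VPD fell outside (0, 1), where fvpd is undefined or negative."""


@dataclass
class StomatalParams:
    """Parameters of the BWB-Leuning-Yin model.

    g0 : residual stomatal conductance, mol m⁻² s⁻¹
    a1 : Ci/Ca ratio at vapor saturation (dimensionless, in (0, 1))
    b1 : decline of that ratio with VPD, kPa⁻¹
    """

    g0: float
    a1: float
    b1: float

    def __post_init__(self) -> None:
        if self.g0 < 0:
            raise ValueError("g0 must be >= 0")
        if not 0.0 < self.a1 < 1.0:
            raise ValueError("a1 must lie in (0, 1)")
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def fvpd(vpd, a1, b1, clamp: bool = False, clamp_lo: float = 1e-3,
         clamp_hi: float = 0.999):
    """VPD response factor fvpd = 1 / [1/(a1 − b1·VPD) − 1].

    Defined for a1 − b1·VPD in (0, 1): it decreases from large values near
    vapor saturation toward 0 as VPD approaches a1/b1.  Outside that domain
    the model has no meaning; in fitting mode (``clamp=False``) a
    :class:`FvpdDomainError` is raised, while in prediction mode
    (``clamp=True``) the argument is clamped into the domain with a warning.
    """
    vpd = np.asarray(vpd, dtype=float)
    u = a1 - b1 * vpd
    out_of_domain = (u <= 0.0) | (u >= 1.0)
    if np.any(out_of_domain):
        if not clamp:
            raise FvpdDomainError(
                f"a1 - b1*VPD outside (0, 1) for {int(np.sum(out_of_domain))} "
                f"observation(s); a1={a1}, b1={b1}")
        warnings.warn("fvpd domain violation clamped in prediction mode",
                      stacklevel=2)
        u = np.clip(u, clamp_lo, clamp_hi)
    result = 1.0 / (1.0 / u - 1.0)
    return float(result) if result.ndim == 0 else result


def ci_star(gamma_star, rd, gm):
    """Ci-based CO2 compensation point: Ci* = Γ* − Rd/gm (μbar)."""
    gm = np.asarray(gm, dtype=float)
    if np.any(gm <= 0):
        raise ValueError("gm must be > 0")
    result = np.asarray(gamma_star, dtype=float) - np.asarray(rd, dtype=float) / gm
    return float(result) if result.ndim == 0 else result


def gs_model(a, rd, ci, cistar, params: StomatalParams, vpd, clamp: bool = False):
    """Stomatal conductance to CO2 from the BWB-Leuning-Yin model.

    gs = g0 + (A + Rd)/(Ci − Ci*) · fvpd(VPD).  Requires Ci > Ci*, where the
    model is singular.
    """
    ci = np.asarray(ci, dtype=float)
    cistar = np.asarray(cistar, dtype=float)
    if np.any(ci <= cistar):
        raise ValueError("gs model requires Ci > Ci*")
    fv = fvpd(vpd, params.a1, params.b1, clamp=clamp)
    result = params.g0 + (np.asarray(a) + np.asarray(rd)) / (ci - cistar) * fv
    return float(result) if np.ndim(result) == 0 else result


def gs_water_to_co2(gsw):
    """Convert stomatal conductance from the water-vapor to the CO2 basis."""
    gsw = np.asarray(gsw, dtype=float)
    if np.any(gsw < 0):
        raise ValueError("gsw must be >= 0")
    result = gsw / GS_WATER_TO_CO2_FACTOR
    return float(result) if result.ndim == 0 else result
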