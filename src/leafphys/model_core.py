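"""Core biochemistry of C3 leaf photosynthesis.

Implements the Farquhar–von Caemmerer–Berry (FvCB) model: net assimilation is
the minimum of a Rubisco-limited rate (Ac) and an electron-transport-limited
rate (Aj), evaluated at the chloroplast CO2 partial pressure Cc.  Electron
transport J responds to incident irradiance through a non-rectangular
hyperbola, and all rate parameters follow (peaked) Arrhenius temperature
responses normalized to 25 °C.  A quadratic closed form expresses the
Ci-based model with a finite mesophyll conductance gm (the NRH-A form), and
linear relations tie photosynthetic capacity to leaf nitrogen content.

Units follow gas-exchange convention: rates in μmol m⁻² s⁻¹, CO2 partial
pressures in μbar (numerically equal to μmol mol⁻¹ at 1 bar), O2 in mbar,
conductances in mol m⁻² s⁻¹ (bar⁻¹ for gm), energies in J mol⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "R_GAS",
    "Environment",
    "KineticConstants",
    "BiochemParams",
    "NitrogenRelations",
    "LinearRelation",
    "RatesAtT",
    "arrhenius",
    "peaked_arrhenius",
    "gamma_star",
    "j_from_light",
    "an_cc",
    "nrh_a_ci",
    "rates_at_t",
    "params_from_nitrogen",
]

#: Universal gas constant, J K⁻¹ mol⁻¹.
R_GAS = 8.314

#: Reference chloroplast O2 partial pressure (21 % O2 at 1 bar), mbar.
O_REF = 210.0


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class Environment:
    """Driving variables for one gas-exchange observation.

    iinc : incident irradiance, μmol photon m⁻² s⁻¹
    ca   : ambient CO2 partial pressure, μbar
    t    : leaf temperature, °C
    vpd  : leaf-to-air vapor pressure deficit, kPa
    o    : chloroplast O2 partial pressure, mbar (210 = 21 % O2)
    """

    iinc: float
    ca: float
    t: float
    vpd: float
    o: float = O_REF

    def __post_init__(self) -> None:
        _check_finite(iinc=self.iinc, ca=self.ca, t=self.t, vpd=self.vpd, o=self.o)
        if self.iinc < 0:
            raise ValueError("iinc must be >= 0")
        if self.ca <= 0:
            raise ValueError("ca must be > 0")
        if self.o < 0:
            raise ValueError("o must be >= 0")
        if self.vpd < 0:
            raise ValueError("vpd must be >= 0")
        if not -5.0 <= self.t <= 50.0:
            raise ValueError("leaf temperature outside [-5, 50] °C")


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics and the CO2 compensation point, with activation energies.

    Defaults are the tobacco-based values commonly assumed conserved among C3
    species (Bernacchi et al.): KmC25 = 272.4 μbar, KmO25 = 165.8 mbar,
    EKmC = 80,990 and EKmO = 23,720 J mol⁻¹.  gamma_star25 is the chloroplast
    CO2 compensation point in the absence of day respiration at 25 °C and
    210 mbar O2; it scales proportionally with O.
    """

    kmc25: float = 272.4
    kmo25: float = 165.8
    e_kmc: float = 80990.0
    e_kmo: float = 23720.0
    gamma_star25: float = 37.43
    e_gamma_star: float = 24460.0
    o_ref: float = O_REF

    def __post_init__(self) -> None:
        for name in ("kmc25", "kmo25", "e_kmc", "e_kmo", "gamma_star25", "o_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_KINETICS = KineticConstants()


@dataclass
class BiochemParams:
    """FvCB parameter set referenced to 25 °C plus temperature-response constants.

    vcmax25, jmax25 : maximum carboxylation / electron transport, μmol m⁻² s⁻¹
    kappa2ll : conversion efficiency of incident light into J at limiting
        light, mol e⁻ (mol photon)⁻¹
    theta : convexity of the J–Iinc response (dimensionless, fixed 0.8)
    rd25  : day respiration at 25 °C, μmol CO2 m⁻² s⁻¹
    gm25  : mesophyll conductance at 25 °C, mol m⁻² s⁻¹ bar⁻¹

    Activation energies (E, J mol⁻¹), entropy terms (S, J K⁻¹ mol⁻¹) and
    deactivation energies (D, J mol⁻¹) parameterize the temperature responses.
    Defaults for the fixed constants: ERd = 46,390; SJmax = 650;
    DJmax = 200,000; Egm = 49,600; Sgm = 1,400; Dgm = 437,400.  EVcmax and
    EJmax default to literature values (65,330 and 43,540 J mol⁻¹) and may be
    re-estimated.
    """

    vcmax25: float
    jmax25: float
    kappa2ll: float
    rd25: float
    gm25: float
    theta: float = 0.8
    e_vcmax: float = 65330.0
    e_jmax: float = 43540.0
    e_rd: float = 46390.0
    e_gm: float = 49600.0
    s_jmax: float = 650.0
    d_jmax: float = 200000.0
    s_gm: float = 1400.0
    d_gm: float = 437400.0

    def __post_init__(self) -> None:
        for name in ("vcmax25", "jmax25", "kappa2ll", "rd25", "gm25"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if self.d_jmax <= 0 or self.d_gm <= 0:
            raise ValueError("deactivation energies must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiochemParams":
        return cls(**d)

    def replace(self, **kwargs) -> "BiochemParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LinearRelation:
    """y = slope * x + intercept."""

    slope: float
    intercept: float = 0.0

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class NitrogenRelations:
    """Linear dependence of photosynthetic parameters on leaf N per area (Na).

    Capacity parameters scale with nitrogen above a base content Nb:
    Vcmax25 = chi_v (Na − Nb), Jmax25 = chi_j (Na − Nb); chi_v and chi_j in
    μmol (g N)⁻¹ s⁻¹.  kappa2ll, rd25, gm25 and g0 follow fitted straight
    lines in Na (slope, intercept pairs).
    """

    # Defaults are the Lilium reference fits; reference.nitrogen_relations()
    # recomputes them from the reference estimate table.
    chi_v: float = 62.0
    chi_j: float = 93.0
    nb: float = 0.35
    kappa2ll: LinearRelation = field(default=LinearRelation(0.0959744, 0.0759152))
    rd25: LinearRelation = field(default=LinearRelation(0.5981026, -0.4401833))
    gm25: LinearRelation = field(default=LinearRelation(0.2130684, -0.2117948))
    g0: LinearRelation = field(default=LinearRelation(0.0139060, -0.0104142))

    def __post_init__(self) -> None:
        if self.chi_v <= 0 or self.chi_j <= 0:
            raise ValueError("chi_v and chi_j must be > 0")
        if self.nb < 0:
            raise ValueError("nb must be >= 0")


@dataclass(frozen=True)
class RatesAtT:
    """FvCB rates and kinetic constants evaluated at one leaf temperature."""

    vcmax: float
    jmax: float
    rd: float
    gm: float
    kmc: float
    kmo: float
    gamma_star: float


def arrhenius(x25, e, t):
    """Arrhenius temperature scaling normalized at 25 °C.

    X(T) = X25 · exp[(T − 25)·E / (298·R·(T + 273))].
    """
    x25 = np.asarray(x25, dtype=float)
    e = np.asarray(e, dtype=float)
    t = np.asarray(t, dtype=float)
    _check_finite(x25=x25, e=e, t=t)
    if np.any(t <= -273.0):
        raise ValueError("temperature below absolute zero")
    return x25 * np.exp((t - 25.0) * e / (298.0 * R_GAS * (t + 273.0)))


def peaked_arrhenius(x25, e, s, d, t):
    """Peaked Arrhenius response with entropy term S and deactivation energy D.

    The deactivation ratio is evaluated in log space so large S·T or D do not
    overflow the exponentials.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(d <= 0):
        raise ValueError("deactivation energy D must be > 0")
    base = arrhenius(x25, e, t)
    tk = t + 273.0
    a = (298.0 * s - d) / (298.0 * R_GAS)
    b = (tk * s - d) / (R_GAS * tk)
    # log[(1 + e^a)/(1 + e^b)] = log1p(e^a) − log1p(e^b), stable for any sign
    log_ratio = np.logaddexp(0.0, a) - np.logaddexp(0.0, b)
    return base * np.exp(log_ratio)


def gamma_star(t, o=O_REF, constants: KineticConstants = DEFAULT_KINETICS):
    """CO2 compensation point in the absence of day respiration, μbar.

    Proportional to the O2 partial pressure and Arrhenius in temperature:
    Γ*(T, O) = Γ*₂₅ · (O / O_ref) · f_Arrhenius(T).
    """
    o = np.asarray(o, dtype=float)
    if np.any(o < 0):
        raise ValueError("O must be >= 0")
    base = constants.gamma_star25 * o / constants.o_ref
    return arrhenius(base, constants.e_gamma_star, t)


def j_from_light(iinc, kappa2ll, jmax, theta=0.8):
    """Electron transport rate J from incident irradiance (NRH light response).

    Lower root of θJ² − (κ₂LL·Iinc + Jmax)·J + κ₂LL·Iinc·Jmax = 0, the
    non-rectangular hyperbola rising with initial slope κ₂LL and saturating
    at Jmax.  A slightly negative discriminant from rounding is clamped to 0.
    """
    iinc = np.asarray(iinc, dtype=float)
    if np.any(iinc < 0):
        raise ValueError("iinc must be >= 0")
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    if np.any(np.asarray(jmax) <= 0):
        raise ValueError("jmax must be > 0")
    b = kappa2ll * iinc + jmax
    disc = b * b - 4.0 * theta * jmax * kappa2ll * iinc
    disc = np.maximum(disc, 0.0)
    return (b - np.sqrt(disc)) / (2.0 * theta)


def an_cc(cc, rates: RatesAtT, j, o=O_REF):
    """Net assimilation at chloroplast CO2 Cc: (Ac, Aj, An, limitation).

    Ac = (Cc − Γ*)·Vcmax / (Cc + KmC(1 + O/KmO)) − Rd
    Aj = (Cc − Γ*)·J / (4Cc + 8Γ*) − Rd
    An = min(Ac, Aj); limitation is "Rubisco" where Ac < Aj else
    "electron-transport".
    """
    cc = np.asarray(cc, dtype=float)
    if np.any(cc < 0):
        raise ValueError("cc must be >= 0")
    ac = (cc - rates.gamma_star) * rates.vcmax / (
        cc + rates.kmc * (1.0 + o / rates.kmo)
    ) - rates.rd
    aj = (cc - rates.gamma_star) * np.asarray(j) / (4.0 * cc + 8.0 * rates.gamma_star) - rates.rd
    an = np.minimum(ac, aj)
    limitation = np.where(ac < aj, "Rubisco", "electron-transport")
    if an.ndim == 0:
        return float(ac), float(aj), float(an), str(limitation)
    return ac, aj, an, limitation


def nrh_a_ci(ci, x1, x2, rd, gm, gamma_star):
    """Ci-based net assimilation with finite mesophyll conductance (NRH-A form).

    Lower root of A² − A·[x1 − Rd + gm(Ci + x2)] + gm[(Ci − Γ*)x1 − Rd(Ci + x2)] = 0,
    i.e. the solution of A = (Cc − Γ*)·x1/(Cc + x2) − Rd with Cc = Ci − A/gm.
    The electron-transport branch uses x1 = J/4, x2 = 2Γ*; the Rubisco branch
    uses x1 = Vcmax, x2 = KmC(1 + O/KmO).
    """
    ci = np.asarray(ci, dtype=float)
    gm = np.asarray(gm, dtype=float)
    if np.any(gm <= 0):
        raise ValueError("gm must be > 0")
    b = np.asarray(x1) - np.asarray(rd) + gm * (ci + np.asarray(x2))
    c = gm * ((ci - np.asarray(gamma_star)) * np.asarray(x1) - np.asarray(rd) * (ci + np.asarray(x2)))
    disc = b * b - 4.0 * c
    if np.any(disc < -1e-6 * np.maximum(b * b, 1.0)):
        raise ArithmeticError("negative discriminant in the Ci-based quadratic")
    disc = np.maximum(disc, 0.0)
    a = 0.5 * (b - np.sqrt(disc))
    return float(a) if a.ndim == 0 else a


def rates_at_t(biochem: BiochemParams, t, constants: KineticConstants = DEFAULT_KINETICS,
               o=O_REF) -> RatesAtT:
    """Evaluate all temperature-dependent rates at leaf temperature ``t``.

    Vcmax, Rd, KmC, KmO and Γ* follow the plain Arrhenius response; Jmax and
    gm follow the peaked response.  kappa2ll and theta are treated as
    temperature-invariant.
    """
    return RatesAtT(
        vcmax=arrhenius(biochem.vcmax25, biochem.e_vcmax, t),
        jmax=peaked_arrhenius(biochem.jmax25, biochem.e_jmax, biochem.s_jmax,
                              biochem.d_jmax, t),
        rd=arrhenius(biochem.rd25, biochem.e_rd, t),
        gm=peaked_arrhenius(biochem.gm25, biochem.e_gm, biochem.s_gm,
                            biochem.d_gm, t),
        kmc=arrhenius(constants.kmc25, constants.e_kmc, t),
        kmo=arrhenius(constants.kmo25, constants.e_kmo, t),
        gamma_star=gamma_star(t, o=o, constants=constants),
    )


def params_from_nitrogen(na: float, rel: NitrogenRelations = NitrogenRelations(),
                         theta: float = 0.8) -> tuple[BiochemParams, float]:
    """Build a 25 °C parameter set (and g0) from leaf nitrogen content Na.

    Capacity parameters are chi·(Na − Nb), floored at zero with a warning when
    Na ≤ Nb; the remaining parameters come from their fitted linear relations
    (also floored at zero).
    """
    if na < 0:
        raise ValueError("na must be >= 0")
    excess = na - rel.nb
    if excess <= 0:
        warnings.warn(
            f"Na = {na} g m⁻² is at or below the base content Nb = {rel.nb}; "
            "photosynthetic capacity set to zero", stacklevel=2)
        excess = 0.0
    biochem = BiochemParams(
        vcmax25=rel.chi_v * excess,
        jmax25=rel.chi_j * excess,
        kappa2ll=max(float(rel.kappa2ll(na)), 0.0),
        rd25=max(float(rel.rd25(na)), 0.0),
        gm25=max(float(rel.gm25(na)), 1e-6),
        theta=theta,
    )
    g0 = max(float(rel.g0(na)), 0.0)
    return biochem, g0
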