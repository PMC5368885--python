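"""Parameter estimation for the FvCB and BWB-Leuning-Yin models.

The sequential chain mirrors the standard fluorescence-assisted gas-exchange
protocol:

1. day respiration Rd and the fluorescence calibration factor s from the
   non-photorespiratory (low O2, high CO2) measurements, where
   An = s·(Iinc·Φ2/4) − Rd is linear;
2. Jmax25 and κ2LL by fitting the non-rectangular light response of
   J = s·Iinc·Φ2, with Jmax temperature-corrected through the peaked
   Arrhenius function;
3. mesophyll conductance gm25 by the NRH-A method: nonlinear least squares of
   the Ci-based electron-transport-limited quadratic over the
   electron-transport-limited light window;
4. Vcmax25 over the whole response curve with An as the minimum of the two
   Ci-based branches;
5. the stomatal parameters (g0, a1, b1) from (gs, An, Ci, VPD) records.

Alternative day-respiration estimators (Kok: intercept of An vs Iinc; Yin:
intercept of An vs Iinc·Φ2/4) and their cross-calibration are provided as
well, since the Kok method is known to underestimate Rd.

Nonlinear fits use Levenberg–Marquardt (lmfit) with numeric Jacobians; linear
fits use ordinary least squares (statsmodels).  Standard errors come from the
Gauss–Newton Jacobian approximation at the optimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .model_core import (
    DEFAULT_KINETICS,
    KineticConstants,
    arrhenius,
    gamma_star,
    j_from_light,
    nrh_a_ci,
    peaked_arrhenius,
)
from .conductance import gs_water_to_co2

__all__ = [
    "FitResult",
    "RdCalibration",
    "CalibrationFactor",
    "UnidentifiableError",
    "fit_rd_kok",
    "fit_rd_yin",
    "calibrate_rd",
    "fit_s_calibration",
    "fit_jmax_k2ll",
    "fit_gm_nrh",
    "fit_gm_nrh_screened",
    "fit_gm_vcmax_joint",
    "fit_vcmax",
    "fit_stomatal",
    "fit_na_relation",
    "f_test_nested",
]

logger = logging.getLogger(__name__)

#: Default limiting-light window for the Kok/Yin regressions, μmol m⁻² s⁻¹.
KOK_WINDOW = (20.0, 200.0)
#: Default upper irradiance of the electron-transport-limited window.
AJ_LIGHT_MAX = 1000.0

_FTOL = 1e-12


class UnidentifiableError(RuntimeError):
    """A parameter is not identifiable from the supplied data."""


@dataclass
class FitResult:
    """Estimates, uncertainties and convergence metadata from one fit."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    rss: float
    df: int
    n_obs: int
    n_iter: int = 0
    converged: bool = True
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if self.df <= 0:
            raise ValueError("residual degrees of freedom must be > 0")

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


@dataclass
class RdCalibration:
    """Linear map from Kok-method Rd to Yin-method Rd."""

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")

    def __call__(self, rd_kok):
        return self.intercept + self.slope * np.asarray(rd_kok, dtype=float)


@dataclass
class CalibrationFactor:
    """Fluorescence-to-electron-transport calibration: J = s · Iinc · Φ2."""

    s: float
    rd25: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.s < 1.0:
            raise ValueError("calibration factor s must lie in (0, 1)")


def _ols(y: np.ndarray, design: np.ndarray) -> sm.regression.linear_model.RegressionResults:
    return sm.OLS(y, design).fit()


def _window_mask(iinc: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (iinc >= lo) & (iinc <= hi)


def _require_points(mask: np.ndarray, n: int, what: str) -> None:
    if int(np.sum(mask)) < n:
        raise ValueError(f"need at least {n} points for {what}, "
                         f"got {int(np.sum(mask))}")


def fit_rd_kok(curve: pd.DataFrame, window: tuple[float, float] = KOK_WINDOW) -> FitResult:
    """Day respiration by the Kok method: −intercept of OLS An on Iinc.

    Uses the initial, approximately linear part of the light response
    (default window 20–200 μmol m⁻² s⁻¹, Iinc > 0).
    """
    iinc = curve["Iinc"].to_numpy(dtype=float)
    an = curve["An"].to_numpy(dtype=float)
    mask = _window_mask(iinc, window) & (iinc > 0)
    _require_points(mask, 3, "the Kok regression")
    if np.ptp(iinc[mask]) == 0:
        raise ValueError("zero variance in Iinc within the Kok window")
    res = _ols(an[mask], sm.add_constant(iinc[mask]))
    return FitResult(
        estimates={"rd": -res.params[0], "slope": res.params[1]},
        standard_errors={"rd": res.bse[0], "slope": res.bse[1]},
        rss=float(res.ssr), df=int(res.df_resid), n_obs=int(mask.sum()),
    )


def fit_rd_yin(curve: pd.DataFrame, window: tuple[float, float] = KOK_WINDOW) -> FitResult:
    """Day respiration by the Yin method: −intercept of OLS An on Iinc·Φ2/4.

    The regressor is proportional to electron transport, so curvature of the
    An–Iinc response from the declining quantum yield is absorbed by the
    regressor instead of biasing the intercept.
    """
    iinc = curve["Iinc"].to_numpy(dtype=float)
    an = curve["An"].to_numpy(dtype=float)
    phi2 = curve["Phi2"].to_numpy(dtype=float)
    mask = _window_mask(iinc, window) & (iinc > 0) & np.isfinite(phi2)
    _require_points(mask, 3, "the Yin regression")
    x = iinc[mask] * phi2[mask] / 4.0
    if np.ptp(x) == 0:
        raise ValueError("zero variance in Iinc*Phi2/4 within the window")
    res = _ols(an[mask], sm.add_constant(x))
    return FitResult(
        estimates={"rd": -res.params[0], "slope": res.params[1]},
        standard_errors={"rd": res.bse[0], "slope": res.bse[1]},
        rss=float(res.ssr), df=int(res.df_resid), n_obs=int(mask.sum()),
    )


def calibrate_rd(paired: list[tuple[float, float]] | np.ndarray) -> RdCalibration:
    """Fit the linear map Rd_yin = intercept + slope · Rd_kok from paired estimates."""
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (rd_kok, rd_yin) pairs")
    kok, yin = arr[:, 0], arr[:, 1]
    if np.ptp(kok) == 0:
        raise ValueError("degenerate pairs: no spread in Kok estimates")
    if np.allclose(kok, yin):
        return RdCalibration(intercept=0.0, slope=1.0)
    res = _ols(yin, sm.add_constant(kok))
    return RdCalibration(intercept=float(res.params[0]), slope=float(res.params[1]))


def fit_s_calibration(nonphotoresp: pd.DataFrame, low_light_max: float = 200.0,
                      ca_step_iinc: float = 800.0, e_rd: float = 46390.0,
                      temperature_adjust: bool = True, screen: bool = True,
                      k_sigma: float = 3.0, abs_tol: float = 1e-6,
                      max_iter: int = 6) -> CalibrationFactor:
    """Fluorescence calibration factor s (and Rd25) from non-photorespiratory data.

    Under suppressed photorespiration the electron-transport-limited rate
    reduces to An = s·(Iinc·Φ2/4) − Rd, so the OLS slope of An on Iinc·Φ2/4 is
    the factor converting Iinc·Φ2 into J.  Points used: the limiting-light
    steps of the light response plus the high-CO2 steps measured at the
    standard irradiance (``ca_step_iinc``).  With ``temperature_adjust`` the
    intercept term is −Rd25 · f_Arrhenius(T; ERd), which accommodates
    leaf-temperature drift between steps and returns Rd directly at 25 °C.

    The regression is only valid on electron-transport-limited points; a
    high-CO2 step at the lower end of the CO2 series can slip into Rubisco
    limitation, which depresses An one-sidedly below the line.  With
    ``screen=True`` the fit anchors on the limiting-light steps (which cannot
    be Rubisco-limited) and admits each high-CO2 point only if its residual is
    not more than ``abs_tol + k_sigma·rms`` below the current line.
    """
    if "regime" in nonphotoresp.columns:
        regimes = set(nonphotoresp["regime"].unique())
        if regimes - {"nonphotoresp"}:
            raise ValueError(
                f"photorespiratory records mixed into the calibration fit: {regimes}")
    iinc = nonphotoresp["Iinc"].to_numpy(dtype=float)
    an = nonphotoresp["An"].to_numpy(dtype=float)
    phi2 = nonphotoresp["Phi2"].to_numpy(dtype=float)
    t = nonphotoresp["Tleaf"].to_numpy(dtype=float)
    finite = np.isfinite(phi2)
    core = (iinc > 0) & (iinc <= low_light_max) & finite
    candidates = (iinc == ca_step_iinc) & finite
    _require_points(core | candidates, 3, "the s-calibration regression")
    x = iinc * phi2 / 4.0
    if temperature_adjust:
        ft = arrhenius(np.ones_like(t), e_rd, t)
    else:
        ft = np.ones_like(x)
    design = np.column_stack([x, -ft])

    included = core | candidates if not screen else core.copy()
    res = None
    for _ in range(max_iter):
        res = _ols(an[included], design[included])
        if not screen:
            break
        resid = an - design @ res.params
        sigma = float(np.sqrt(np.mean(resid[included] ** 2)))
        new_included = core | (candidates & (resid >= -(abs_tol + k_sigma * sigma)))
        if np.array_equal(new_included, included):
            break
        included = new_included
    s, rd25 = float(res.params[0]), float(res.params[1])
    cal = CalibrationFactor(s=s, rd25=rd25)
    logger.info("s-calibration: s=%.4f, Rd25=%.4f (n=%d, %d high-CO2 point(s) "
                "screened out)", s, rd25, int(included.sum()),
                int(np.sum(candidates & ~included)))
    return cal


def fit_jmax_k2ll(points: pd.DataFrame, theta: float = 0.8,
                  e_jmax: float = 43540.0, s_jmax: float = 650.0,
                  d_jmax: float = 200000.0, vary_e_jmax: bool = False) -> FitResult:
    """Jmax25 and κ2LL from (Iinc, T, J) points.

    Nonlinear least squares of the non-rectangular light response with
    Jmax = peaked_arrhenius(Jmax25, EJmax, SJmax, DJmax, T).  ``points`` needs
    columns Iinc, Tleaf and J, spanning limiting and saturating light.
    """
    iinc = points["Iinc"].to_numpy(dtype=float)
    t = points["Tleaf"].to_numpy(dtype=float)
    j = points["J"].to_numpy(dtype=float)
    mask = (iinc > 0) & np.isfinite(j)
    _require_points(mask, 6, "the Jmax25/kappa2LL fit")
    iinc, t, j = iinc[mask], t[mask], j[mask]

    params = lmfit.Parameters()
    params.add("jmax25", value=max(1.2 * np.max(j), 50.0), min=10.0, max=600.0)
    params.add("kappa2ll", value=0.25, min=0.02, max=0.6)
    if vary_e_jmax:
        params.add("e_jmax", value=e_jmax, min=5000.0, max=150000.0)

    def residual(p):
        ej = p["e_jmax"].value if vary_e_jmax else e_jmax
        jmax_t = peaked_arrhenius(p["jmax25"].value, ej, s_jmax, d_jmax, t)
        return j - j_from_light(iinc, p["kappa2ll"].value, jmax_t, theta)

    out = lmfit.minimize(residual, params, method="leastsq",
                         ftol=_FTOL, xtol=_FTOL)
    return _from_lmfit(out)


def fit_gm_nrh(curve: pd.DataFrame, rd25: float, s: float | None = None,
               e_rd: float = 46390.0, e_gm: float = 49600.0,
               s_gm: float = 1400.0, d_gm: float = 437400.0,
               light_max: float = AJ_LIGHT_MAX,
               constants: KineticConstants = DEFAULT_KINETICS,
               o: float = 210.0) -> FitResult:
    """Mesophyll conductance by the NRH-A method on the Aj-limited window.

    Fits the Ci-based electron-transport-limited quadratic (x1 = J/4,
    x2 = 2Γ*) to points with 0 < Iinc ≤ ``light_max``, with
    gm = peaked_arrhenius(gm25, Egm, Sgm, Dgm, T) and a single gm25 across the
    curve.  J must be present per point as a column ``J`` (fluorescence
    derived, J = s·Iinc·Φ2) or is computed from Φ2 when ``s`` is given.
    """
    df = curve
    iinc = df["Iinc"].to_numpy(dtype=float)
    mask = (iinc > 0) & (iinc <= light_max)
    _require_points(mask, 3, "the NRH-A gm fit")
    df = df.loc[mask]
    an = df["An"].to_numpy(dtype=float)
    ci = df["Ci"].to_numpy(dtype=float)
    t = df["Tleaf"].to_numpy(dtype=float)
    if "J" in df.columns:
        j = df["J"].to_numpy(dtype=float)
    elif s is not None:
        j = s * df["Iinc"].to_numpy(dtype=float) * df["Phi2"].to_numpy(dtype=float)
    else:
        raise ValueError("supply a J column or the calibration factor s")
    rd = arrhenius(rd25, e_rd, t)
    gstar = gamma_star(t, o=o, constants=constants)

    params = lmfit.Parameters()
    params.add("gm25", value=0.2, min=1e-4, max=20.0)

    def residual(p):
        gm_t = peaked_arrhenius(p["gm25"].value, e_gm, s_gm, d_gm, t)
        return an - nrh_a_ci(ci, j / 4.0, 2.0 * gstar, rd, gm_t, gstar)

    out = lmfit.minimize(residual, params, method="leastsq", ftol=_FTOL, xtol=_FTOL)
    result = _from_lmfit(out)
    if result.estimates["gm25"] >= 0.99 * params["gm25"].max:
        result.extras["at_upper_bound"] = True
        warnings.warn("gm25 at its upper bound: mesophyll conductance is "
                      "effectively infinite for these data", stacklevel=2)
    return result


def fit_gm_nrh_screened(curve: pd.DataFrame, rd25: float, s: float | None = None,
                        start_light_max: float = 200.0,
                        light_max: float = AJ_LIGHT_MAX,
                        k_sigma: float = 3.0, abs_tol: float = 1e-6,
                        max_iter: int = 6, **kwargs) -> FitResult:
    """NRH-A mesophyll conductance fit with a data-driven limitation screen.

    The electron-transport-limited window of a light-response curve depends on
    the leaf's parameters and on the CO2 drawdown at each step, so a fixed
    irradiance cutoff can admit Rubisco-limited points, which depress An below
    the electron-transport prediction and bias gm.  This fit screens them out
    the way a practitioner screens for linearity of An against J: it starts
    from the low-light steps (``Iinc <= start_light_max``), which are
    electron-transport-limited across the model's whole parameter range, and
    iteratively admits higher-light points (up to ``light_max``) whose
    observed An is consistent with the current fit — i.e. not more than
    ``abs_tol + k_sigma * rms(residuals)`` *below* the prediction.  Rubisco
    contamination deviates one-sidedly downward, so the test is one-sided and
    converges in a few passes; on noise-free data it separates the branches
    exactly.
    """
    iinc = curve["Iinc"].to_numpy(dtype=float)
    candidates = (iinc > 0) & (iinc <= light_max)
    core = (iinc > 0) & (iinc <= start_light_max)
    _require_points(core, 3, "the screened NRH-A gm fit")
    included = core.copy()
    fit = None
    for _ in range(max_iter):
        fit = fit_gm_nrh(curve.loc[included], rd25=rd25, s=s,
                         light_max=light_max, **kwargs)
        resid_all = _gm_residuals(curve, fit.estimates["gm25"], rd25, s=s,
                                  **kwargs)
        sigma = float(np.sqrt(np.mean(resid_all[included] ** 2)))
        tol = abs_tol + k_sigma * sigma
        new_included = core | (candidates & (resid_all >= -tol))
        if np.array_equal(new_included, included):
            break
        included = new_included
    fit.extras["n_screened_out"] = int(np.sum(candidates & ~included))
    fit.extras["n_used"] = int(np.sum(included))
    return fit


def _gm_residuals(curve: pd.DataFrame, gm25: float, rd25: float,
                  s: float | None = None, e_rd: float = 46390.0,
                  e_gm: float = 49600.0, s_gm: float = 1400.0,
                  d_gm: float = 437400.0,
                  constants: KineticConstants = DEFAULT_KINETICS,
                  o: float = 210.0) -> np.ndarray:
    """An residuals of the electron-transport NRH-A prediction for all rows."""
    an = curve["An"].to_numpy(dtype=float)
    ci = curve["Ci"].to_numpy(dtype=float)
    t = curve["Tleaf"].to_numpy(dtype=float)
    if "J" in curve.columns:
        j = curve["J"].to_numpy(dtype=float)
    else:
        j = s * curve["Iinc"].to_numpy(dtype=float) * curve["Phi2"].to_numpy(dtype=float)
    rd = arrhenius(rd25, e_rd, t)
    gstar = gamma_star(t, o=o, constants=constants)
    gm_t = peaked_arrhenius(gm25, e_gm, s_gm, d_gm, t)
    return an - nrh_a_ci(ci, j / 4.0, 2.0 * gstar, rd, gm_t, gstar)


def fit_vcmax(curve: pd.DataFrame, jmax25: float, kappa2ll: float, rd25: float,
              gm25: float, theta: float = 0.8, e_vcmax: float = 65330.0,
              e_jmax: float = 43540.0, s_jmax: float = 650.0,
              d_jmax: float = 200000.0, e_rd: float = 46390.0,
              e_gm: float = 49600.0, s_gm: float = 1400.0,
              d_gm: float = 437400.0,
              constants: KineticConstants = DEFAULT_KINETICS,
              o: float = 210.0) -> FitResult:
    """Vcmax25 by fitting An = min(Ac, Aj) in Ci-based form to a whole curve.

    All other parameters (Jmax25, κ2LL, Rd25, gm25 and the temperature
    constants) are supplied as knowns.  Raises :class:`UnidentifiableError`
    when no point of the curve is Rubisco-limited at the optimum, in which
    case the data carry no information on Vcmax.
    """
    an = curve["An"].to_numpy(dtype=float)
    ci = curve["Ci"].to_numpy(dtype=float)
    t = curve["Tleaf"].to_numpy(dtype=float)
    iinc = curve["Iinc"].to_numpy(dtype=float)
    if len(an) < 3:
        raise ValueError("need at least 3 points for the Vcmax fit")
    rd = arrhenius(rd25, e_rd, t)
    gm_t = peaked_arrhenius(gm25, e_gm, s_gm, d_gm, t)
    gstar = gamma_star(t, o=o, constants=constants)
    jmax_t = peaked_arrhenius(jmax25, e_jmax, s_jmax, d_jmax, t)
    j = j_from_light(iinc, kappa2ll, jmax_t, theta)
    aj = nrh_a_ci(ci, j / 4.0, 2.0 * gstar, rd, gm_t, gstar)
    kmc = arrhenius(constants.kmc25, constants.e_kmc, t)
    kmo = arrhenius(constants.kmo25, constants.e_kmo, t)
    x2_c = kmc * (1.0 + o / kmo)

    def predict(vcmax25):
        vcmax_t = arrhenius(vcmax25, e_vcmax, t)
        ac = nrh_a_ci(ci, vcmax_t, x2_c, rd, gm_t, gstar)
        return np.minimum(ac, aj), ac

    def residual(p):
        pred, _ = predict(p["vcmax25"].value)
        return an - pred

    # Once every point's prediction is on the Aj branch the objective is flat
    # in Vcmax25, so a single start can stall; a small multi-start (low starts
    # keep the Ac branch active) makes the fit robust.
    out = None
    for start in (30.0, 80.0, 150.0):
        params = lmfit.Parameters()
        params.add("vcmax25", value=start, min=1.0, max=800.0)
        candidate = lmfit.minimize(residual, params, method="leastsq",
                                   ftol=_FTOL, xtol=_FTOL)
        rss = float(np.sum(np.asarray(candidate.residual) ** 2))
        if out is None or rss < best_rss - 1e-12:
            out, best_rss = candidate, rss
    result = _from_lmfit(out)
    _, ac = predict(result.estimates["vcmax25"])
    n_rubisco = int(np.sum(ac < aj - 1e-12))
    result.extras["n_rubisco_limited"] = n_rubisco
    if n_rubisco == 0:
        raise UnidentifiableError(
            "no Rubisco-limited points at the optimum: Vcmax25 is not "
            "identifiable from this curve")
    return result


def fit_gm_vcmax_joint(curve: pd.DataFrame, rd25: float, jmax25: float,
                       kappa2ll: float, gm25_start: float = 0.15,
                       vcmax25_start: float = 100.0, theta: float = 0.8,
                       e_vcmax: float = 65330.0, e_jmax: float = 43540.0,
                       s_jmax: float = 650.0, d_jmax: float = 200000.0,
                       e_rd: float = 46390.0, e_gm: float = 49600.0,
                       s_gm: float = 1400.0, d_gm: float = 437400.0,
                       constants: KineticConstants = DEFAULT_KINETICS,
                       o: float = 210.0) -> FitResult:
    """Joint fit of gm25 and Vcmax25 to a whole curve with An = min(Ac, Aj).

    Both Ci-based branches share the mesophyll drawdown, so Rubisco-limited
    points also inform gm; fitting the two parameters jointly avoids having to
    classify each point's limitation before fitting, which is fragile when the
    branches nearly co-limit.  Starting values should come from the screened
    NRH-A fit and an initial Vcmax fit.  Raises
    :class:`UnidentifiableError` when no point is Rubisco-limited at the
    optimum.
    """
    an = curve["An"].to_numpy(dtype=float)
    ci = curve["Ci"].to_numpy(dtype=float)
    t = curve["Tleaf"].to_numpy(dtype=float)
    iinc = curve["Iinc"].to_numpy(dtype=float)
    if len(an) < 4:
        raise ValueError("need at least 4 points for the joint gm/Vcmax fit")
    rd = arrhenius(rd25, e_rd, t)
    gstar = gamma_star(t, o=o, constants=constants)
    jmax_t = peaked_arrhenius(jmax25, e_jmax, s_jmax, d_jmax, t)
    j = j_from_light(iinc, kappa2ll, jmax_t, theta)
    kmc = arrhenius(constants.kmc25, constants.e_kmc, t)
    kmo = arrhenius(constants.kmo25, constants.e_kmo, t)
    x2_c = kmc * (1.0 + o / kmo)

    def branches(gm25, vcmax25):
        gm_t = peaked_arrhenius(gm25, e_gm, s_gm, d_gm, t)
        vcmax_t = arrhenius(vcmax25, e_vcmax, t)
        ac = nrh_a_ci(ci, vcmax_t, x2_c, rd, gm_t, gstar)
        aj = nrh_a_ci(ci, j / 4.0, 2.0 * gstar, rd, gm_t, gstar)
        return ac, aj

    def residual(p):
        ac, aj = branches(p["gm25"].value, p["vcmax25"].value)
        return an - np.minimum(ac, aj)

    # multi-start on Vcmax25: the objective is flat in Vcmax25 wherever every
    # prediction sits on the Aj branch, so starts keeping Ac active are needed
    out = best_rss = None
    for start in dict.fromkeys((vcmax25_start, 30.0, 150.0)):
        params = lmfit.Parameters()
        params.add("gm25", value=gm25_start, min=1e-4, max=20.0)
        params.add("vcmax25", value=start, min=1.0, max=800.0)
        candidate = lmfit.minimize(residual, params, method="leastsq",
                                   ftol=_FTOL, xtol=_FTOL)
        ac, aj = branches(candidate.params["gm25"].value,
                          candidate.params["vcmax25"].value)
        if not np.any(ac < aj - 1e-12):
            continue  # flat in Vcmax25: not a usable optimum
        rss = float(np.sum(np.asarray(candidate.residual) ** 2))
        if best_rss is None or rss < best_rss - 1e-12:
            out, best_rss = candidate, rss
    if out is None:
        raise UnidentifiableError(
            "no Rubisco-limited points at the joint optimum: Vcmax25 is not "
            "identifiable from this curve")
    result = _from_lmfit(out)
    ac, aj = branches(result["gm25"], result["vcmax25"])
    result.extras["n_rubisco_limited"] = int(np.sum(ac < aj - 1e-12))
    return result


def fit_stomatal(records: pd.DataFrame, fix_g0: np.ndarray | float | None = None,
                 a1_bounds: tuple[float, float] = (0.01, 0.99),
                 b1_max: float = 5.0, ci_margin: float = 1.0,
                 domain_floor: float = 1e-3) -> FitResult:
    """g0, a1 and b1 of the stomatal model from (gs, An, Ci, VPD) records.

    ``records`` needs columns An, Ci, VPD, Rd, CiStar and either gs (CO2
    basis) or gsw (water-vapor basis, converted internally by 1.6).  Points
    with Ci ≤ Ci* + ``ci_margin`` are excluded (the model is singular there)
    with a logged count.  Candidate (a1, b1) steps that push any observation
    outside the fvpd domain are penalized, which keeps the bounded
    least-squares search inside the model's domain.

    ``fix_g0`` fixes the residual conductance instead of fitting it — either a
    scalar or one value per record (e.g. from a nitrogen relation) for pooled
    fits across leaves of different nitrogen status.
    """
    df = records
    if "gs" in df.columns:
        gs = df["gs"].to_numpy(dtype=float)
    elif "gsw" in df.columns:
        gs = gs_water_to_co2(df["gsw"].to_numpy(dtype=float))
    else:
        raise ValueError("records need a gs or gsw column")
    an = df["An"].to_numpy(dtype=float)
    ci = df["Ci"].to_numpy(dtype=float)
    vpd = df["VPD"].to_numpy(dtype=float)
    rd = df["Rd"].to_numpy(dtype=float)
    cistar = df["CiStar"].to_numpy(dtype=float)

    keep = ci > cistar + ci_margin
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("stomatal fit: excluded %d point(s) with Ci <= Ci* + %g",
                    n_excluded, ci_margin)
    _require_points(keep, 6, "the stomatal fit")
    gs, an, ci, vpd, rd, cistar = (v[keep] for v in (gs, an, ci, vpd, rd, cistar))
    if np.ptp(vpd) < 0.05:
        warnings.warn("VPD range too narrow: b1 is weakly identifiable",
                      stacklevel=2)

    g0_arr = None
    vary_g0 = fix_g0 is None
    if not vary_g0:
        g0_arr = np.asarray(fix_g0, dtype=float)
        if g0_arr.ndim > 0:
            if g0_arr.shape[0] != keep.shape[0]:
                raise ValueError("fix_g0 array must match the number of records")
            g0_arr = g0_arr[keep]

    params = lmfit.Parameters()
    params.add("a1", value=0.6, min=a1_bounds[0], max=a1_bounds[1])
    params.add("b1", value=0.1, min=0.0, max=b1_max)
    if vary_g0:
        params.add("g0", value=0.02, min=0.0, max=1.0)

    def residual(p):
        u = p["a1"].value - p["b1"].value * vpd
        penalty = 1e2 * np.maximum(domain_floor - u, 0.0)
        u_safe = np.clip(u, domain_floor, 0.999)
        fv = 1.0 / (1.0 / u_safe - 1.0)
        g0 = p["g0"].value if vary_g0 else g0_arr
        pred = g0 + (an + rd) / (ci - cistar) * fv
        return gs - pred + penalty

    out = lmfit.minimize(residual, params, method="leastsq", ftol=_FTOL, xtol=_FTOL)
    result = _from_lmfit(out)
    result.extras["n_excluded_near_cistar"] = n_excluded
    return result


def fit_na_relation(na: np.ndarray, estimates: np.ndarray,
                    through_offset: float | None = None) -> FitResult:
    """Linear relation of a parameter estimate to leaf nitrogen content.

    With ``through_offset`` = Nb, fits y = slope·(Na − Nb) through the origin
    (the capacity-parameter form); otherwise fits slope and intercept freely.
    """
    na = np.asarray(na, dtype=float)
    y = np.asarray(estimates, dtype=float)
    if na.size < 3:
        raise ValueError("need at least 3 (Na, estimate) points")
    if np.ptp(na) == 0:
        raise ValueError("degenerate Na spread")
    if through_offset is not None:
        x = na - through_offset
        res = _ols(y, x[:, None])
        est = {"slope": float(res.params[0]), "intercept": 0.0}
        se = {"slope": float(res.bse[0]), "intercept": 0.0}
    else:
        res = _ols(y, sm.add_constant(na))
        est = {"slope": float(res.params[1]), "intercept": float(res.params[0])}
        se = {"slope": float(res.bse[1]), "intercept": float(res.bse[0])}
    return FitResult(estimates=est, standard_errors=se, rss=float(res.ssr),
                     df=int(res.df_resid), n_obs=int(na.size))


def f_test_nested(rss_full: float, df_full: int, rss_reduced: float,
                  df_reduced: int) -> tuple[float, float]:
    """F-test of a reduced (fewer-parameter) model against the full model.

    F = [(RSS_reduced − RSS_full)/(df_reduced − df_full)] / (RSS_full/df_full),
    with the p-value from the F(df_reduced − df_full, df_full) distribution.
    """
    if df_reduced <= df_full:
        raise ValueError("reduced model must have more residual df than full")
    if df_full <= 0:
        raise ValueError("df_full must be > 0")
    if rss_reduced < rss_full - 1e-12 * max(rss_full, 1.0):
        raise ValueError("rss_reduced must be >= rss_full for nested models")
    num_df = df_reduced - df_full
    f = ((rss_reduced - rss_full) / num_df) / (rss_full / df_full)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, num_df, df_full))
    return float(f), p


def _from_lmfit(out: lmfit.minimizer.MinimizerResult) -> FitResult:
    estimates = {name: float(p.value) for name, p in out.params.items()}
    ses = {name: (float(p.stderr) if p.stderr is not None else np.nan)
           for name, p in out.params.items()}
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        rss=float(np.sum(np.asarray(out.residual) ** 2)),
        df=int(out.nfree),
        n_obs=int(out.ndata),
        n_iter=int(out.nfev),
        converged=bool(out.success),
    )
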