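"""Orchestration of the three-step analysis over a curve dataset.

Step 1 fits every model parameter per treatment (the treatment-specific
parameterization); step 2 replaces treatment-specific values by shared ones —
linear nitrogen relations for the biochemical parameters and pooled stomatal
slopes a1/b1 (per water level or across all treatments); step 3 predicts An
and gs from each parameterization and compares predictions with observations
through a through-origin slope, the squared Pearson correlation and the
relative root-mean-square error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .model_core import (
    BiochemParams,
    DEFAULT_KINETICS,
    Environment,
    KineticConstants,
    arrhenius,
    gamma_star,
    j_from_light,
    nrh_a_ci,
    params_from_nitrogen,
    peaked_arrhenius,
    NitrogenRelations,
    LinearRelation,
)
from .conductance import StomatalParams, ci_star, gs_model, gs_water_to_co2
from .coupled_solver import solve_leaf
from .estimation import (
    FitResult,
    UnidentifiableError,
    calibrate_rd,
    fit_gm_nrh_screened,
    fit_gm_vcmax_joint,
    fit_jmax_k2ll,
    fit_na_relation,
    fit_rd_kok,
    fit_rd_yin,
    fit_s_calibration,
    fit_stomatal,
    fit_vcmax,
)

__all__ = [
    "PredictionComparison",
    "TreatmentFit",
    "run_treatment_fit",
    "run_shared_fit",
    "predict_an",
    "predict_gs",
    "evaluate",
]

logger = logging.getLogger(__name__)

_PARAM_COLUMNS = ["s", "rd25", "jmax25", "kappa2ll", "gm25", "vcmax25",
                  "g0", "a1", "b1"]


@dataclass
class PredictionComparison:
    """Agreement between predicted (y) and observed (x) values.

    slope_through_origin = Σxy/Σx² (the regression of y on x forced through
    the origin); r2 is the squared Pearson correlation; rRMSE is the RMSE
    divided by the mean observed value.
    """

    slope_through_origin: float
    r2: float
    rrmse: float
    n: int
    mode: str = ""
    basis: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TreatmentFit:
    """All fit results for one treatment, in estimation order."""

    water: str
    nitrogen: str
    na: float
    s: float
    rd25: float
    jmax_fit: FitResult
    gm_fit: FitResult
    vcmax_fit: FitResult
    stomatal_fit: FitResult
    rd_diagnostics: dict

    @property
    def biochem(self) -> BiochemParams:
        return BiochemParams(
            vcmax25=self.vcmax_fit["vcmax25"],
            jmax25=self.jmax_fit["jmax25"],
            kappa2ll=self.jmax_fit["kappa2ll"],
            rd25=self.rd25,
            gm25=self.gm_fit["gm25"],
        )

    @property
    def stomatal(self) -> StomatalParams:
        return StomatalParams(g0=self.stomatal_fit["g0"],
                              a1=self.stomatal_fit["a1"],
                              b1=self.stomatal_fit["b1"])

    def row(self) -> dict:
        row = {"water": self.water, "nitrogen": self.nitrogen, "Na": self.na,
               "s": self.s, "rd25": self.rd25}
        for name, fit in (("jmax25", self.jmax_fit), ("kappa2ll", self.jmax_fit),
                          ("gm25", self.gm_fit), ("vcmax25", self.vcmax_fit),
                          ("g0", self.stomatal_fit), ("a1", self.stomatal_fit),
                          ("b1", self.stomatal_fit)):
            row[name] = fit.estimates[name]
            row[f"{name}_se"] = fit.standard_errors[name]
        return row


def _attach_j(df: pd.DataFrame, s: float) -> pd.DataFrame:
    out = df.copy()
    out["J"] = s * out["Iinc"].to_numpy() * out["Phi2"].to_numpy()
    return out


def _stomatal_records(df: pd.DataFrame, rd25: float, gm25: float,
                      biochem_consts: dict,
                      constants: KineticConstants) -> pd.DataFrame:
    t = df["Tleaf"].to_numpy(dtype=float)
    rd = arrhenius(rd25, biochem_consts.get("e_rd", 46390.0), t)
    gm = peaked_arrhenius(gm25, biochem_consts.get("e_gm", 49600.0),
                          biochem_consts.get("s_gm", 1400.0),
                          biochem_consts.get("d_gm", 437400.0), t)
    gstar = gamma_star(t, o=210.0, constants=constants)
    out = df.copy()
    out["Rd"] = rd
    out["CiStar"] = ci_star(gstar, rd, gm)
    out["gs"] = gs_water_to_co2(out["gsw"].to_numpy(dtype=float))
    return out


def _rd_diagnostics(light: pd.DataFrame) -> dict:
    """Kok and Yin day-respiration estimates per curve, plus their calibration."""
    pairs, per_curve = [], {}
    for cid, curve in light.groupby("curve_id"):
        try:
            kok = fit_rd_kok(curve)
            yin = fit_rd_yin(curve)
        except ValueError:
            continue
        per_curve[cid] = {"rd_kok": kok["rd"], "rd_yin": yin["rd"]}
        pairs.append((kok["rd"], yin["rd"]))
    diag = {"per_curve": per_curve}
    if len(pairs) >= 3:
        try:
            diag["calibration"] = calibrate_rd(pairs)
        except ValueError:
            pass
    return diag


def _refine_gm_vcmax(light: pd.DataFrame, rd25: float, jmax_fit: FitResult,
                     gm_fit: FitResult, vcmax_fit: FitResult, theta: float,
                     e_vcmax: float, e_jmax: float, gm_light_max: float,
                     constants: KineticConstants) -> tuple[FitResult, FitResult]:
    """Polish gm25 and Vcmax25 with a joint fit of the min(Ac, Aj) model.

    The residual screen that seeds the gm fit is conservative near
    co-limitation, and Rubisco-limited points also carry information on gm
    through the mesophyll drawdown; a joint two-parameter fit over the whole
    curve uses both without having to classify each point first.  The screened
    gm and initial Vcmax estimates are the starting point.  On noise-free data
    they are already at the joint optimum and remain unchanged.  The two
    parameters are reported as separate results sharing the joint fit's RSS.
    """
    try:
        joint = fit_gm_vcmax_joint(
            light, rd25=rd25, jmax25=jmax_fit["jmax25"],
            kappa2ll=jmax_fit["kappa2ll"], gm25_start=gm_fit["gm25"],
            vcmax25_start=vcmax_fit["vcmax25"], theta=theta, e_vcmax=e_vcmax,
            e_jmax=e_jmax, constants=constants)
    except UnidentifiableError:
        # keep the sequential estimates when the joint surface is flat in
        # Vcmax25 (weak Rubisco representation); flag it for the caller
        logger.warning("joint gm/Vcmax polish unidentifiable; keeping the "
                       "sequential estimates")
        gm_fit.extras["joint_refine_failed"] = True
        vcmax_fit.extras["joint_refine_failed"] = True
        return gm_fit, vcmax_fit
    gm_out = FitResult(
        estimates={"gm25": joint["gm25"]},
        standard_errors={"gm25": joint.standard_errors["gm25"]},
        rss=joint.rss, df=joint.df, n_obs=joint.n_obs,
        n_iter=joint.n_iter, converged=joint.converged,
        extras=dict(gm_fit.extras))
    vcmax_out = FitResult(
        estimates={"vcmax25": joint["vcmax25"]},
        standard_errors={"vcmax25": joint.standard_errors["vcmax25"]},
        rss=joint.rss, df=joint.df, n_obs=joint.n_obs,
        n_iter=joint.n_iter, converged=joint.converged,
        extras=dict(joint.extras))
    return gm_out, vcmax_out


def run_treatment_fit(dataset: pd.DataFrame,
                      constants: KineticConstants = DEFAULT_KINETICS,
                      gm_light_max: float = 1000.0,
                      theta: float = 0.8,
                      e_vcmax: float = 65330.0, e_jmax: float = 43540.0,
                      include_ci_curves_in_stomatal: bool = True,
                      ) -> tuple[pd.DataFrame, dict[str, TreatmentFit]]:
    """Run the sequential estimation chain for every treatment in a dataset.

    Per treatment: (Rd25, s) from the non-photorespiratory calibration, then
    Jmax25/κ2LL from fluorescence-derived J, then gm25 (NRH-A, electron-
    transport-limited window), then Vcmax25 over the whole light curve, then
    (g0, a1, b1) from the conductance records.  Treatments missing a required
    regime are skipped with a log entry.  Returns a parameter table shaped one
    row per treatment (estimate and SE columns) plus the full fit objects.
    """
    if dataset.empty:
        raise ValueError("empty dataset")
    tables, details = [], {}
    for (water, nitrogen), group in dataset.groupby(["water", "nitrogen"], sort=False):
        label = f"{water}/{nitrogen}"
        nonphoto = group[group["regime"] == "nonphotoresp"]
        light = group[group["regime"] == "light_curve"]
        if nonphoto.empty or light.empty:
            logger.warning("treatment %s lacks a required regime; skipped", label)
            continue
        try:
            fit = _fit_one_treatment(
                group, nonphoto, light, water, nitrogen, constants,
                gm_light_max, theta, e_vcmax, e_jmax,
                include_ci_curves_in_stomatal)
        except UnidentifiableError as exc:
            logger.warning("treatment %s skipped: %s", label, exc)
            continue
        details[label] = fit
        tables.append(fit.row())
    return pd.DataFrame(tables), details


def _fit_one_treatment(group, nonphoto, light, water, nitrogen, constants,
                       gm_light_max, theta, e_vcmax, e_jmax,
                       include_ci_curves_in_stomatal) -> TreatmentFit:
    cal = fit_s_calibration(nonphoto)
    light_j = _attach_j(light, cal.s)
    jmax_fit = fit_jmax_k2ll(light_j, theta=theta, e_jmax=e_jmax)
    # downstream fits use the light-response-smoothed J at each step's
    # temperature rather than the raw per-point fluorescence J, so Φ2
    # measurement noise does not enter the gm/Vcmax stages as
    # errors-in-variables
    light_smooth = light.copy()
    jmax_t = peaked_arrhenius(jmax_fit["jmax25"], e_jmax, 650.0, 200000.0,
                              light["Tleaf"].to_numpy(dtype=float))
    light_smooth["J"] = j_from_light(light["Iinc"].to_numpy(dtype=float),
                                     jmax_fit["kappa2ll"], jmax_t, theta)
    gm_fit = fit_gm_nrh_screened(light_smooth, rd25=cal.rd25,
                                 light_max=gm_light_max, constants=constants)
    vcmax_fit = fit_vcmax(
        light_smooth, jmax25=jmax_fit["jmax25"], kappa2ll=jmax_fit["kappa2ll"],
        rd25=cal.rd25, gm25=gm_fit["gm25"], theta=theta,
        e_vcmax=e_vcmax, e_jmax=e_jmax, constants=constants)
    gm_fit, vcmax_fit = _refine_gm_vcmax(
        light_smooth, cal.rd25, jmax_fit, gm_fit, vcmax_fit, theta=theta,
        e_vcmax=e_vcmax, e_jmax=e_jmax, gm_light_max=gm_light_max,
        constants=constants)
    gs_source = light
    if include_ci_curves_in_stomatal:
        ci_rows = group[group["regime"] == "ci_curve"]
        if not ci_rows.empty:
            gs_source = pd.concat([light, ci_rows], ignore_index=True)
    gs_source = gs_source[gs_source["Iinc"] > 0]
    records = _stomatal_records(gs_source, cal.rd25, gm_fit["gm25"], {},
                                constants)
    stomatal_fit = fit_stomatal(records)
    return TreatmentFit(
        water=water, nitrogen=nitrogen, na=float(group["Na"].iloc[0]),
        s=cal.s, rd25=cal.rd25, jmax_fit=jmax_fit, gm_fit=gm_fit,
        vcmax_fit=vcmax_fit, stomatal_fit=stomatal_fit,
        rd_diagnostics=_rd_diagnostics(light))


def run_shared_fit(dataset: pd.DataFrame, param_table: pd.DataFrame,
                   sharing: str = "all", nb: float = 0.35,
                   constants: KineticConstants = DEFAULT_KINETICS) -> dict:
    """Fit the shared parameterization from per-treatment estimates and raw data.

    Fits the nitrogen relations across treatments (capacity parameters through
    the base content Nb, the rest with free intercepts) and pools the stomatal
    slopes a1/b1 — jointly over all treatments (``sharing='all'``) or per
    water level (``sharing='per_water'``) — with g0 fixed per record from its
    fitted nitrogen relation and Rd/Ci* from the per-treatment estimates.
    """
    if param_table.shape[0] < 3:
        raise ValueError("need at least 3 treatments for shared fitting")
    na = param_table["Na"].to_numpy(dtype=float)
    relations_fits = {
        "vcmax25": fit_na_relation(na, param_table["vcmax25"], through_offset=nb),
        "jmax25": fit_na_relation(na, param_table["jmax25"], through_offset=nb),
        "kappa2ll": fit_na_relation(na, param_table["kappa2ll"]),
        "rd25": fit_na_relation(na, param_table["rd25"]),
        "gm25": fit_na_relation(na, param_table["gm25"]),
        "g0": fit_na_relation(na, param_table["g0"]),
    }
    relations = NitrogenRelations(
        chi_v=relations_fits["vcmax25"]["slope"],
        chi_j=relations_fits["jmax25"]["slope"],
        nb=nb,
        **{name: LinearRelation(relations_fits[name]["slope"],
                                relations_fits[name]["intercept"])
           for name in ("kappa2ll", "rd25", "gm25", "g0")},
    )

    # pooled stomatal fits with g0 tied to Na
    lookup = param_table.set_index(["water", "nitrogen"])
    rows = dataset[(dataset["regime"].isin(["light_curve", "ci_curve"]))
                   & (dataset["Iinc"] > 0)]
    groups = {"all": [rows]} if sharing == "all" else {
        water: [sub] for water, sub in rows.groupby("water")}
    pooled = {}
    for name, subsets in groups.items():
        sub = subsets[0]
        parts = []
        for (water, nitrogen), g in sub.groupby(["water", "nitrogen"], sort=False):
            est = lookup.loc[(water, nitrogen)]
            parts.append(_stomatal_records(g, float(est["rd25"]),
                                           float(est["gm25"]), {}, constants))
        records = pd.concat(parts, ignore_index=True)
        g0_fixed = relations.g0(records["Na"].to_numpy(dtype=float))
        g0_fixed = np.maximum(g0_fixed, 0.0)
        pooled[name] = fit_stomatal(records, fix_g0=g0_fixed)
    return {"relations": relations, "relation_fits": relations_fits,
            "pooled_stomatal": pooled}


def _params_for_row(row, params_by_treatment) -> tuple[BiochemParams, StomatalParams]:
    key = (row.water, row.nitrogen)
    entry = params_by_treatment[key] if key in params_by_treatment else \
        params_by_treatment[f"{row.water}/{row.nitrogen}"]
    return entry


def predict_an(dataset: pd.DataFrame, params_by_treatment: dict,
               basis: str = "ci_based",
               constants: KineticConstants = DEFAULT_KINETICS) -> pd.DataFrame:
    """Predict An for every record of a dataset.

    ``params_by_treatment`` maps (water, nitrogen) (or "water/nitrogen") to a
    (BiochemParams, StomatalParams) pair.  ``basis='ci_based'`` evaluates the
    Ci-based FvCB model at the measured Ci; ``basis='coupled'`` solves the
    coupled model from Ca, Iinc, T and VPD only.  Returns the dataset with an
    ``An_pred`` column (and ``gs_pred``/``Ci_pred`` for the coupled basis).
    """
    if basis not in ("ci_based", "coupled"):
        raise ValueError("basis must be 'ci_based' or 'coupled'")
    needed = {"Iinc", "Tleaf", "VPD", "Ca" if basis == "coupled" else "Ci"}
    missing = needed - set(dataset.columns)
    if missing:
        raise ValueError(f"missing columns for basis {basis!r}: {sorted(missing)}")
    out = dataset.copy()
    an_pred = np.empty(len(out))
    gs_pred = np.full(len(out), np.nan)
    ci_pred = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        biochem, stomatal = _params_for_row(row, params_by_treatment)
        o = 210.0 if getattr(row, "O2_pct", 21.0) >= 20 else 0.0
        if basis == "ci_based":
            t = row.Tleaf
            rd = arrhenius(biochem.rd25, biochem.e_rd, t)
            gm = peaked_arrhenius(biochem.gm25, biochem.e_gm, biochem.s_gm,
                                  biochem.d_gm, t)
            gstar = gamma_star(t, o=o, constants=constants)
            jmax = peaked_arrhenius(biochem.jmax25, biochem.e_jmax,
                                    biochem.s_jmax, biochem.d_jmax, t)
            j = j_from_light(row.Iinc, biochem.kappa2ll, jmax, biochem.theta)
            vcmax = arrhenius(biochem.vcmax25, biochem.e_vcmax, t)
            kmc = arrhenius(constants.kmc25, constants.e_kmc, t)
            kmo = arrhenius(constants.kmo25, constants.e_kmo, t)
            aj = nrh_a_ci(row.Ci, j / 4.0, 2.0 * gstar, rd, gm, gstar)
            ac = nrh_a_ci(row.Ci, vcmax, kmc * (1 + o / kmo), rd, gm, gstar)
            an_pred[i] = min(ac, aj)
        else:
            env = Environment(iinc=row.Iinc, ca=row.Ca, t=row.Tleaf,
                              vpd=row.VPD, o=o)
            sol = solve_leaf(env, biochem, stomatal, constants)
            an_pred[i] = sol.an
            gs_pred[i] = sol.gs
            ci_pred[i] = sol.ci
    out["An_pred"] = an_pred
    if basis == "coupled":
        out["gs_pred"] = gs_pred
        out["Ci_pred"] = ci_pred
    return out


def predict_gs(dataset: pd.DataFrame, params_by_treatment: dict,
               constants: KineticConstants = DEFAULT_KINETICS) -> pd.DataFrame:
    """Predict gs from the stomatal model using measured An, Ci and VPD."""
    out = dataset.copy()
    gs_pred = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        biochem, stomatal = _params_for_row(row, params_by_treatment)
        t = row.Tleaf
        rd = arrhenius(biochem.rd25, biochem.e_rd, t)
        gm = peaked_arrhenius(biochem.gm25, biochem.e_gm, biochem.s_gm,
                              biochem.d_gm, t)
        gstar = gamma_star(t, o=210.0, constants=constants)
        cistar = ci_star(gstar, rd, gm)
        if row.Ci <= cistar + 1.0:
            gs_pred[i] = np.nan
            continue
        gs_pred[i] = gs_model(row.An, rd, row.Ci, cistar, stomatal, row.VPD,
                              clamp=True)
    out["gs_pred"] = gs_pred
    return out


def evaluate(predicted, observed, mode: str = "", basis: str = "") -> PredictionComparison:
    """Compare predictions with observations (slope through origin, r², rRMSE)."""
    y = np.asarray(predicted, dtype=float)
    x = np.asarray(observed, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need at least 2 paired finite values")
    xbar = float(np.mean(x))
    if xbar == 0:
        raise ValueError("rRMSE undefined: mean observation is zero")
    slope = float(np.sum(x * y) / np.sum(x * x))
    r = np.corrcoef(x, y)[0, 1]
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return PredictionComparison(
        slope_through_origin=slope, r2=float(r * r), rrmse=rmse / xbar,
        n=int(x.size), mode=mode, basis=basis)
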