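"""Synthetic gas-exchange and chlorophyll-fluorescence datasets.

Emulates the structure of a greenhouse water × nitrogen factorial on Lilium:
two water levels crossed with four nitrogen supplies, light-response curves
measured at ambient CO2, CO2-response curves at fixed irradiance, and a
combined gas-exchange/fluorescence calibration measurement under a
non-photorespiratory regime (low O2, high CO2).  Every record is
forward-simulated with the coupled FvCB + stomatal + mesophyll solver, so a
noise-free dataset is an exact realization of the model that the estimation
chain inverts.

Fluorescence is emitted through the lumped calibration factor
s = ρ2·β·(1 − f_pseudo/(1 − f_cyc)): the generator computes the true electron
transport J from the light response and reports Φ2 = J/(s·Iinc) (with
Fs/Fm′ = 1 − Φ2 recoverable).  Leaf temperature and VPD drift between steps,
mimicking measurement under inadequate greenhouse climate control.

The non-photorespiratory regime is simulated as fully suppressing
photorespiration (chloroplast O2 set to zero, hence Γ* = 0), which is the
condition the calibration regression An = s·(Iinc·Φ2/4) − Rd assumes; the
O2_pct column records the nominal 2 % protocol value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (
    BiochemParams,
    DEFAULT_KINETICS,
    Environment,
    KineticConstants,
    NitrogenRelations,
    j_from_light,
    params_from_nitrogen,
    rates_at_t,
)
from .conductance import StomatalParams, GS_WATER_TO_CO2_FACTOR
from .coupled_solver import solve_leaf
from . import reference

__all__ = [
    "LIGHT_STEPS",
    "CA_STEPS",
    "HIGH_CA_STEPS",
    "FluorescenceModel",
    "NoiseModel",
    "TreatmentSpec",
    "generate_environment",
    "generate_curve",
    "generate_experiment",
    "default_design",
    "design_from_nitrogen",
    "write_dataset",
    "CURVE_COLUMNS",
]

#: Irradiance steps of a light-response curve, μmol m⁻² s⁻¹ (measured downward).
LIGHT_STEPS = (1500.0, 1200.0, 1000.0, 600.0, 400.0, 200.0, 100.0, 50.0, 20.0, 0.0)
#: Ambient CO2 steps of a CO2-response curve, μmol mol⁻¹ (at Iinc = 800).
CA_STEPS = (50.0, 100.0, 150.0, 200.0, 250.0, 380.0, 650.0, 1000.0, 1500.0)
#: High-CO2 steps of the calibration measurement, μmol mol⁻¹ (at Iinc = 800).
HIGH_CA_STEPS = (650.0, 1000.0, 1500.0)

#: Ambient CO2 during light curves, μmol mol⁻¹.
CA_AMBIENT = 370.0
#: Chamber CO2 during the non-photorespiratory light curve, μmol mol⁻¹.
CA_NONPHOTO = 1000.0
#: Irradiance during CO2-response and high-CO2 calibration steps.
IINC_CA_CURVE = 800.0

CURVE_COLUMNS = [
    "curve_id", "treatment", "water", "nitrogen", "Na", "Iinc", "Ca", "An",
    "Ci", "gsw", "Tleaf", "VPD", "Phi2", "O2_pct", "regime",
]


@dataclass(frozen=True)
class FluorescenceModel:
    """Physiology behind the fluorescence calibration factor.

    rho2     : proportion of absorbed light partitioned to photosystem II
    beta     : leaf absorptance by photosynthetic pigments
    fcyc     : fraction of PSI electrons in cyclic flow
    fpseudo  : fraction of PSI electrons in pseudocyclic flow

    The implied calibration factor is s = ρ2·β·(1 − f_pseudo/(1 − f_cyc)).
    """

    rho2: float = 0.5
    beta: float = 0.85
    fcyc: float = 0.1
    fpseudo: float = 0.1

    def __post_init__(self) -> None:
        for name in ("rho2", "beta", "fcyc", "fpseudo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.s < 1.0:
            raise ValueError("implied calibration factor s outside (0, 1)")

    @property
    def s(self) -> float:
        return self.rho2 * self.beta * (1.0 - self.fpseudo / (1.0 - self.fcyc))


#: Water-deficit leaves divert more electrons to pseudocyclic flow, lowering s.
FLUOR_WELL_WATERED = FluorescenceModel()
FLUOR_WATER_DEFICIT = FluorescenceModel(fpseudo=0.2)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: additive on An and Φ2, multiplicative on gsw."""

    sd_an: float = 0.3
    cv_gsw: float = 0.05
    sd_phi2: float = 0.01

    def __post_init__(self) -> None:
        if min(self.sd_an, self.cv_gsw, self.sd_phi2) < 0:
            raise ValueError("noise parameters must be nonnegative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(sd_an=0.0, cv_gsw=0.0, sd_phi2=0.0)


@dataclass
class TreatmentSpec:
    """Ground truth for one water × nitrogen treatment."""

    water: str
    nitrogen: str
    na: float
    biochem: BiochemParams
    stomatal: StomatalParams
    fluorescence: FluorescenceModel = field(default=FLUOR_WELL_WATERED)
    n_replicates: int = 6

    def __post_init__(self) -> None:
        if self.na < 0:
            raise ValueError("na must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.water}/{self.nitrogen}"

    def truth_dict(self) -> dict:
        d = {"water": self.water, "nitrogen": self.nitrogen, "Na": self.na,
             "n_replicates": self.n_replicates,
             "s": self.fluorescence.s,
             "fluorescence": asdict(self.fluorescence)}
        d.update(self.biochem.to_dict())
        d.update(self.stomatal.to_dict())
        return d


def generate_environment(n_points: int, rng: np.random.Generator | int,
                         t_range: tuple[float, float] = (15.0, 30.0),
                         vpd_range: tuple[float, float] = (0.5, 2.5),
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform leaf-temperature and VPD draws for ``n_points`` steps."""
    if n_points <= 0:
        raise ValueError("n_points must be > 0")
    rng = np.random.default_rng(rng)
    t = rng.uniform(t_range[0], t_range[1], size=n_points)
    vpd = rng.uniform(vpd_range[0], vpd_range[1], size=n_points)
    return t, vpd


def _draw_vpd(rng: np.random.Generator, vpd_range: tuple[float, float],
              a1: float, b1: float, floor: float = 0.05,
              max_tries: int = 1000) -> float:
    """Draw a VPD inside the fvpd domain (a1 − b1·VPD > floor), redrawing."""
    for _ in range(max_tries):
        vpd = rng.uniform(*vpd_range)
        if a1 - b1 * vpd > floor:
            return float(vpd)
    # domain is (almost) empty over the configured range: fall back to the
    # largest admissible VPD
    return float(max(vpd_range[0], (a1 - 2 * floor) / b1 if b1 > 0 else vpd_range[0]))


def _phi2_from_j(j: float, iinc: float, s: float, kappa2ll: float) -> float:
    """Apparent PSII operating efficiency Φ2 = J/(s·Iinc); κ2LL/s at Iinc → 0."""
    if iinc <= 0:
        return kappa2ll / s
    return j / (s * iinc)


def generate_curve(spec: TreatmentSpec, regime: str, noise: NoiseModel,
                   seed: np.random.Generator | int, curve_id: str = "curve-1",
                   t_range: tuple[float, float] = (18.0, 22.0),
                   vpd_range: tuple[float, float] = (0.5, 2.5),
                   constants: KineticConstants = DEFAULT_KINETICS) -> pd.DataFrame:
    """Forward-simulate one response curve for a treatment.

    regime: ``light_curve`` (irradiance steps at ambient CO2, 21 % O2),
    ``ci_curve`` (CO2 steps at fixed irradiance, 21 % O2) or ``nonphotoresp``
    (irradiance steps at high CO2 plus three high-CO2 steps, photorespiration
    suppressed).  Leaf temperature and VPD are drawn per step from the given
    ranges (the light-curve default 18–22 °C reflects measurement at
    20 ± 2 °C); VPD draws outside the fvpd domain are rejected and redrawn.
    With all noise terms zero the records lie exactly on the coupled model.
    """
    rng = np.random.default_rng(seed)
    if regime == "light_curve":
        steps = [(i, CA_AMBIENT, 210.0) for i in LIGHT_STEPS]
        o2_pct = 21.0
    elif regime == "ci_curve":
        steps = [(IINC_CA_CURVE, ca, 210.0) for ca in CA_STEPS]
        o2_pct = 21.0
    elif regime == "nonphotoresp":
        steps = [(i, CA_NONPHOTO, 0.0) for i in LIGHT_STEPS if i > 0]
        steps += [(IINC_CA_CURVE, ca, 0.0) for ca in HIGH_CA_STEPS]
        o2_pct = 2.0
    else:
        raise ValueError(f"unknown regime {regime!r}")

    s = spec.fluorescence.s
    rows = []
    for iinc, ca, o in steps:
        t = rng.uniform(*t_range)
        vpd = _draw_vpd(rng, vpd_range, spec.stomatal.a1, spec.stomatal.b1)
        env = Environment(iinc=iinc, ca=ca, t=t, vpd=vpd, o=o)
        sol = solve_leaf(env, spec.biochem, spec.stomatal, constants)
        phi2 = _phi2_from_j(sol.j, iinc, s, spec.biochem.kappa2ll)
        an = sol.an + noise.sd_an * rng.standard_normal()
        gsw = sol.gs * GS_WATER_TO_CO2_FACTOR * (
            1.0 + noise.cv_gsw * rng.standard_normal())
        phi2_obs = phi2 + noise.sd_phi2 * rng.standard_normal()
        rows.append({
            "curve_id": curve_id,
            "treatment": spec.label,
            "water": spec.water,
            "nitrogen": spec.nitrogen,
            "Na": spec.na,
            "Iinc": iinc,
            "Ca": ca,
            "An": an,
            "Ci": sol.ci,
            "gsw": gsw,
            "Tleaf": t,
            "VPD": vpd,
            "Phi2": phi2_obs,
            "O2_pct": o2_pct,
            "regime": regime,
        })
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def generate_experiment(design: list[TreatmentSpec],
                        noise: NoiseModel = NoiseModel(),
                        seed: int = 0,
                        n_nonphotoresp: int | None = None,
                        n_ci_curves: int = 0,
                        light_t_range: tuple[float, float] = (18.0, 22.0),
                        vpd_range: tuple[float, float] = (0.5, 2.5),
                        constants: KineticConstants = DEFAULT_KINETICS,
                        ) -> tuple[pd.DataFrame, dict]:
    """Simulate a full factorial experiment.

    Per treatment: ``n_replicates`` light-response curves, ``n_nonphotoresp``
    calibration curves (default: the same replication as the light curves,
    one per measured plant) and optionally ``n_ci_curves`` CO2-response
    curves.  Returns the dataset in the curve-CSV schema plus a truth sidecar
    (a dict keyed by treatment label, recording the seed and every true
    parameter).
    """
    if not design:
        raise ValueError("design must contain at least one treatment")
    ss = np.random.SeedSequence(seed)
    frames = []
    truth = {"seed": seed, "noise": asdict(noise), "treatments": {}}
    for spec, child in zip(design, ss.spawn(len(design))):
        truth["treatments"][spec.label] = spec.truth_dict()
        n_npr = spec.n_replicates if n_nonphotoresp is None else n_nonphotoresp
        kinds = (["light_curve"] * spec.n_replicates
                 + ["nonphotoresp"] * n_npr
                 + ["ci_curve"] * n_ci_curves)
        for k, (kind, curve_seed) in enumerate(zip(kinds, child.spawn(len(kinds)))):
            cid = f"{spec.water[:2]}-{spec.nitrogen}-{kind}-{k}"
            frames.append(generate_curve(
                spec, kind, noise, curve_seed, curve_id=cid,
                t_range=light_t_range, vpd_range=vpd_range, constants=constants))
    return pd.concat(frames, ignore_index=True), truth


def default_design(n_replicates: int = 6) -> list[TreatmentSpec]:
    """The 2 water × 4 nitrogen factorial with the Lilium reference truths."""
    design = []
    for water in reference.WATERS:
        fluor = FLUOR_WELL_WATERED if water == "well-watered" else FLUOR_WATER_DEFICIT
        for nitrogen in reference.NITROGENS:
            design.append(TreatmentSpec(
                water=water, nitrogen=nitrogen,
                na=reference.reference_na(water, nitrogen),
                biochem=reference.reference_biochem(water, nitrogen),
                stomatal=reference.reference_stomatal(water, nitrogen),
                fluorescence=fluor, n_replicates=n_replicates))
    return design


def design_from_nitrogen(na_values: dict[str, float], water: str,
                         relations: NitrogenRelations | None = None,
                         stomatal_a1b1: tuple[float, float] | None = None,
                         fluorescence: FluorescenceModel | None = None,
                         n_replicates: int = 6) -> list[TreatmentSpec]:
    """Build treatments whose parameters sit exactly on the nitrogen relations.

    ``na_values`` maps nitrogen labels to Na (g N m⁻²).  Biochemical
    parameters and g0 come from ``relations`` (default: the reference fits);
    a1/b1 are shared across treatments (default: the pooled per-water
    reference values).
    """
    relations = relations or reference.nitrogen_relations()
    if stomatal_a1b1 is None:
        a1 = reference.OVERALL_STOMATAL[water]["a1"][0]
        b1 = reference.OVERALL_STOMATAL[water]["b1"][0]
    else:
        a1, b1 = stomatal_a1b1
    if fluorescence is None:
        fluorescence = (FLUOR_WELL_WATERED if water == "well-watered"
                        else FLUOR_WATER_DEFICIT)
    design = []
    for nitrogen, na in na_values.items():
        biochem, g0 = params_from_nitrogen(na, relations)
        design.append(TreatmentSpec(
            water=water, nitrogen=nitrogen, na=na, biochem=biochem,
            stomatal=StomatalParams(g0=g0, a1=a1, b1=b1),
            fluorescence=fluorescence, n_replicates=n_replicates))
    return design


def generate_shared_stomatal_dataset(water: str = "well-watered",
                                     noise: NoiseModel = NoiseModel(),
                                     seed: int = 0, n_replicates: int = 6,
                                     relations: NitrogenRelations | None = None,
                                     vpd_range: tuple[float, float] = (0.5, 2.5),
                                     ) -> tuple[pd.DataFrame, dict]:
    """Conductance records from four N levels sharing one (a1, b1) truth.

    Generates ``n_replicates`` light curves per nitrogen level with the pooled
    per-water a1/b1 as the shared stomatal truth and g0 tied to Na through its
    nitrogen relation, then attaches the per-record quantities a pooled
    stomatal fit needs: Rd and Ci* evaluated from the generating biochemistry
    at each record's leaf temperature, and the true g0 (column ``g0_true``).
    Only records with Iinc > 0 are returned.  The truth dict carries the
    shared a1/b1 and the per-treatment parameters.
    """
    from .model_core import arrhenius, gamma_star
    from .conductance import ci_star

    na_values = {n: reference.reference_na(water, n) for n in reference.NITROGENS}
    design = design_from_nitrogen(na_values, water, relations=relations,
                                  n_replicates=n_replicates)
    ss = np.random.SeedSequence(seed)
    frames = []
    specs: dict[str, TreatmentSpec] = {}
    for spec, child in zip(design, ss.spawn(len(design))):
        specs[spec.nitrogen] = spec
        for k, curve_seed in enumerate(child.spawn(spec.n_replicates)):
            frames.append(generate_curve(
                spec, "light_curve", noise, curve_seed,
                curve_id=f"{spec.nitrogen}-{k}", vpd_range=vpd_range))
    df = pd.concat(frames, ignore_index=True)
    df = df[df["Iinc"] > 0].reset_index(drop=True)
    rd_col = np.empty(len(df))
    cistar_col = np.empty(len(df))
    g0_col = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        b = specs[row.nitrogen].biochem
        rd = float(arrhenius(b.rd25, b.e_rd, row.Tleaf))
        gm = peaked_arrhenius_gm(b, row.Tleaf)
        gstar = float(gamma_star(row.Tleaf))
        rd_col[i] = rd
        cistar_col[i] = ci_star(gstar, rd, gm)
        g0_col[i] = specs[row.nitrogen].stomatal.g0
    df["Rd"] = rd_col
    df["CiStar"] = cistar_col
    df["g0_true"] = g0_col
    a1 = design[0].stomatal.a1
    b1 = design[0].stomatal.b1
    truth = {"seed": seed, "a1": a1, "b1": b1,
             "treatments": {s.nitrogen: s.truth_dict() for s in design}}
    return df, truth


def peaked_arrhenius_gm(biochem: BiochemParams, t: float) -> float:
    """Mesophyll conductance at leaf temperature ``t`` for one parameter set."""
    from .model_core import peaked_arrhenius
    return float(peaked_arrhenius(biochem.gm25, biochem.e_gm, biochem.s_gm,
                                  biochem.d_gm, t))


def write_dataset(df: pd.DataFrame, truth: dict, path: str | Path) -> None:
    """Write the curve CSV plus a JSON truth sidecar (``<path>.truth.json``)."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=1, sort_keys=True))
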