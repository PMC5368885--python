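"""Published parameter estimates for greenhouse Lilium under water × nitrogen regimes.

These are the per-treatment FvCB and BWB-Leuning-Yin parameter estimates (with
standard errors) for *Lilium* 'Sorbonne' grown under two water levels
(well-watered / water-deficit) crossed with four nitrogen supplies
(N25–N85 mg available N per kg substrate).  They serve as ground-truth
parameter sets for the synthetic data generator and as fixtures for
consistency checks.

Leaf nitrogen content per treatment was only reported graphically; the default
``reference_na`` values are back-computed from Vcmax25 through the published
nitrogen relation Vcmax25 = χV(Na − Nb) with χV = 62 μmol (g N)⁻¹ s⁻¹ and
Nb = 0.35 g N m⁻², which keeps the reference set exactly consistent with that
relation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_core import BiochemParams, LinearRelation, NitrogenRelations
from .conductance import StomatalParams

__all__ = [
    "WATERS",
    "NITROGENS",
    "FVCB_ESTIMATES",
    "STOMATAL_ESTIMATES",
    "OVERALL_STOMATAL",
    "CHI_V",
    "CHI_J",
    "N_BASE",
    "reference_biochem",
    "reference_stomatal",
    "reference_na",
    "reference_table",
    "nitrogen_relations",
]

WATERS = ("well-watered", "water-deficit")
NITROGENS = ("N85", "N65", "N45", "N25")

#: Published slopes of the capacity–nitrogen relations, μmol (g N)⁻¹ s⁻¹.
CHI_V = 62.0
CHI_J = 93.0
#: Base leaf nitrogen content at which capacity is zero, g N m⁻².
N_BASE = 0.35

# (estimate, standard error) per (water, nitrogen).
FVCB_ESTIMATES: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("well-watered", "N85"): {"kappa2ll": (0.242, 0.017), "jmax25": (150, 6),
                              "vcmax25": (109, 8), "rd25": (0.867, 0.18)},
    ("well-watered", "N65"): {"kappa2ll": (0.309, 0.020), "jmax25": (141, 4),
                              "vcmax25": (96, 5), "rd25": (0.696, 0.15)},
    ("well-watered", "N45"): {"kappa2ll": (0.238, 0.013), "jmax25": (130, 5),
                              "vcmax25": (90, 5), "rd25": (0.740, 0.12)},
    ("well-watered", "N25"): {"kappa2ll": (0.251, 0.026), "jmax25": (118, 6),
                              "vcmax25": (77, 5), "rd25": (0.492, 0.10)},
    ("water-deficit", "N85"): {"kappa2ll": (0.218, 0.016), "jmax25": (137, 8),
                               "vcmax25": (88, 6), "rd25": (0.514, 0.17)},
    ("water-deficit", "N65"): {"kappa2ll": (0.265, 0.017), "jmax25": (126, 3),
                               "vcmax25": (80, 5), "rd25": (0.448, 0.10)},
    ("water-deficit", "N45"): {"kappa2ll": (0.212, 0.029), "jmax25": (103, 7),
                               "vcmax25": (68, 4), "rd25": (0.412, 0.16)},
    ("water-deficit", "N25"): {"kappa2ll": (0.172, 0.019), "jmax25": (96, 7),
                               "vcmax25": (58, 4), "rd25": (0.409, 0.14)},
}

STOMATAL_ESTIMATES: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("well-watered", "N85"): {"g0": (0.021, 0.002), "a1": (0.575, 0.029),
                              "b1": (0.203, 0.027), "gm25": (0.236, 0.017)},
    ("well-watered", "N65"): {"g0": (0.019, 0.002), "a1": (0.671, 0.026),
                              "b1": (0.275, 0.021), "gm25": (0.197, 0.023)},
    ("well-watered", "N45"): {"g0": (0.014, 0.002), "a1": (0.690, 0.033),
                              "b1": (0.321, 0.030), "gm25": (0.172, 0.032)},
    ("well-watered", "N25"): {"g0": (0.011, 0.001), "a1": (0.688, 0.021),
                              "b1": (0.291, 0.021), "gm25": (0.161, 0.035)},
    ("water-deficit", "N85"): {"g0": (0.011, 0.001), "a1": (0.300, 0.041),
                               "b1": (0.013, 0.025), "gm25": (0.126, 0.014)},
    ("water-deficit", "N65"): {"g0": (0.009, 0.001), "a1": (0.284, 0.039),
                               "b1": (0.007, 0.022), "gm25": (0.155, 0.025)},
    ("water-deficit", "N45"): {"g0": (0.008, 0.001), "a1": (0.308, 0.037),
                               "b1": (0.023, 0.024), "gm25": (0.103, 0.023)},
    ("water-deficit", "N25"): {"g0": (0.012, 0.001), "a1": (0.317, 0.034),
                               "b1": (0.086, 0.023), "gm25": (0.041, 0.013)},
}

#: Pooled a1/b1 estimates: per water level and across all treatments.
OVERALL_STOMATAL: dict[str, dict[str, tuple[float, float]]] = {
    "well-watered": {"a1": (0.661, 0.013), "b1": (0.270, 0.012)},
    "water-deficit": {"a1": (0.262, 0.019), "b1": (0.013, 0.012)},
    "all": {"a1": (0.558, 0.012), "b1": (0.197, 0.010)},
}


def reference_na(water: str, nitrogen: str) -> float:
    """Leaf nitrogen content implied by Vcmax25 = χV(Na − Nb), g N m⁻²."""
    vcmax25 = FVCB_ESTIMATES[(water, nitrogen)]["vcmax25"][0]
    return vcmax25 / CHI_V + N_BASE


def reference_biochem(water: str, nitrogen: str, **overrides) -> BiochemParams:
    """FvCB parameter set (25 °C) for one treatment, with mesophyll conductance."""
    fv = FVCB_ESTIMATES[(water, nitrogen)]
    st = STOMATAL_ESTIMATES[(water, nitrogen)]
    kwargs = dict(
        vcmax25=fv["vcmax25"][0],
        jmax25=fv["jmax25"][0],
        kappa2ll=fv["kappa2ll"][0],
        rd25=fv["rd25"][0],
        gm25=st["gm25"][0],
    )
    kwargs.update(overrides)
    return BiochemParams(**kwargs)


def reference_stomatal(water: str, nitrogen: str | None = None,
                       pooled: bool = False) -> StomatalParams:
    """Stomatal parameters for one treatment or the pooled per-water set.

    With ``pooled=True`` (or ``nitrogen=None``), a1 and b1 come from the pooled
    per-water estimates and g0 from the treatment (or the N85 treatment if
    nitrogen is not given).
    """
    if pooled or nitrogen is None:
        a1, b1 = OVERALL_STOMATAL[water]["a1"][0], OVERALL_STOMATAL[water]["b1"][0]
        g0 = STOMATAL_ESTIMATES[(water, nitrogen or "N85")]["g0"][0]
        return StomatalParams(g0=g0, a1=a1, b1=b1)
    st = STOMATAL_ESTIMATES[(water, nitrogen)]
    return StomatalParams(g0=st["g0"][0], a1=st["a1"][0], b1=st["b1"][0])


def reference_table() -> pd.DataFrame:
    """All reference estimates as a tidy table (one row per treatment)."""
    rows = []
    for water in WATERS:
        for nitrogen in NITROGENS:
            row = {"water": water, "nitrogen": nitrogen,
                   "Na": reference_na(water, nitrogen)}
            for name, (est, se) in FVCB_ESTIMATES[(water, nitrogen)].items():
                row[name] = est
                row[f"{name}_se"] = se
            for name, (est, se) in STOMATAL_ESTIMATES[(water, nitrogen)].items():
                row[name] = est
                row[f"{name}_se"] = se
            rows.append(row)
    return pd.DataFrame(rows)


def nitrogen_relations() -> NitrogenRelations:
    """Nitrogen relations fitted to the reference estimates.

    Capacity slopes are the published χV and χJ; the straight lines for
    kappa2ll, rd25, gm25 and g0 are ordinary least-squares fits of the eight
    reference treatment estimates against the reference Na values.
    """
    table = reference_table()
    na = table["Na"].to_numpy()

    def _line(column: str) -> LinearRelation:
        slope, intercept = np.polyfit(na, table[column].to_numpy(), 1)
        return LinearRelation(slope=float(slope), intercept=float(intercept))

    return NitrogenRelations(
        chi_v=CHI_V, chi_j=CHI_J, nb=N_BASE,
        kappa2ll=_line("kappa2ll"), rd25=_line("rd25"),
        gm25=_line("gm25"), g0=_line("g0"),
    )
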