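"""Estimation operations: regressions, nonlinear fits, F-test."""

import numpy as np
import pandas as pd
import pytest

from leafphys.estimation import (
    UnidentifiableError,
    calibrate_rd,
    f_test_nested,
    fit_gm_nrh,
    fit_jmax_k2ll,
    fit_na_relation,
    fit_rd_kok,
    fit_rd_yin,
    fit_s_calibration,
    fit_stomatal,
    fit_vcmax,
)
from leafphys.model_core import (
    arrhenius,
    gamma_star,
    j_from_light,
    nrh_a_ci,
    peaked_arrhenius,
)
from leafphys.conductance import fvpd


def _curve(iinc, an, phi2=None, t=25.0):
    df = pd.DataFrame({"Iinc": iinc, "An": an})
    df["Tleaf"] = t
    if phi2 is not None:
        df["Phi2"] = phi2
    return df


class TestRdRegressions:
    def test_kok_exact_line(self):
        fit = fit_rd_kok(_curve([20.0, 50.0, 100.0], [0.5, 2.0, 4.5]))
        assert fit["rd"] == pytest.approx(0.5, abs=1e-10)
        assert fit["slope"] == pytest.approx(0.05, abs=1e-10)

    def test_kok_recovers_linear_forward_model_exactly(self):
        iinc = np.array([20.0, 50.0, 100.0, 150.0, 200.0])
        fit = fit_rd_kok(_curve(iinc, 0.04 * iinc - 0.9))
        assert fit["rd"] == pytest.approx(0.9, abs=1e-12)

    def test_kok_noisy_monte_carlo_mean(self):
        """Mean recovered Rd over 200 noisy replicates within 5% of truth."""
        rng = np.random.default_rng(7)
        iinc = np.linspace(20, 200, 5)
        rds = []
        for _ in range(200):
            an = 0.05 * iinc - 0.8 + rng.normal(0, 0.2, iinc.size)
            rds.append(fit_rd_kok(_curve(iinc, an))["rd"])
        assert np.mean(rds) == pytest.approx(0.8, rel=0.05)

    def test_kok_se_coverage(self):
        """±1 SE covers the true Rd in roughly 68% of replicates."""
        rng = np.random.default_rng(11)
        iinc = np.linspace(20, 200, 8)
        hits = 0
        n = 300
        for _ in range(n):
            an = 0.05 * iinc - 0.8 + rng.normal(0, 0.2, iinc.size)
            fit = fit_rd_kok(_curve(iinc, an))
            hits += abs(fit["rd"] - 0.8) <= fit.standard_errors["rd"]
        assert 0.55 <= hits / n <= 0.80

    def test_kok_rejects_insufficient_points(self):
        with pytest.raises(ValueError):
            fit_rd_kok(_curve([50.0, 100.0], [1.0, 2.0]))

    def test_yin_exact_line(self):
        iinc = np.array([20.0, 50.0, 100.0, 200.0])
        phi2 = np.full(4, 0.7)
        an = 0.4 * (iinc * phi2 / 4) - 0.6
        fit = fit_rd_yin(_curve(iinc, an, phi2))
        assert fit["rd"] == pytest.approx(0.6, abs=1e-10)

    def test_constant_phi2_matches_kok_up_to_rescaling(self):
        iinc = np.array([20.0, 50.0, 100.0, 200.0])
        phi2 = np.full(4, 0.65)
        an = 0.03 * iinc - 0.5
        kok = fit_rd_kok(_curve(iinc, an))
        yin = fit_rd_yin(_curve(iinc, an, phi2))
        assert yin["rd"] == pytest.approx(kok["rd"], abs=1e-10)
        assert yin["slope"] == pytest.approx(kok["slope"] * 4 / 0.65, rel=1e-9)

    def test_yin_less_biased_under_sublinear_light_response(self):
        """With Φ2 tracking the declining quantum yield, the Yin intercept
        stays unbiased while Kok underestimates Rd."""
        iinc = np.linspace(20, 200, 8)
        s, rd = 0.4, 0.8
        phi2 = 0.75 / (1 + iinc / 500)  # sub-linear An-Iinc response
        an = s * (iinc * phi2 / 4) - rd
        kok = fit_rd_kok(_curve(iinc, an))
        yin = fit_rd_yin(_curve(iinc, an, phi2))
        assert kok["rd"] < rd  # the known underestimation
        assert abs(yin["rd"] - rd) < abs(kok["rd"] - rd)


class TestRdCalibration:
    def test_identity_for_identical_pairs(self):
        cal = calibrate_rd([(0.5, 0.5), (0.8, 0.8), (1.1, 1.1)])
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0)

    def test_exact_linear_map(self):
        kok = np.array([0.3, 0.6, 0.9, 1.2])
        cal = calibrate_rd(np.column_stack([kok, 1.2 * kok + 0.1]))
        assert cal.slope == pytest.approx(1.2, abs=1e-10)
        assert cal.intercept == pytest.approx(0.1, abs=1e-10)
        assert cal(1.0) == pytest.approx(1.3)

    def test_correction_reduces_rmse_for_biased_estimates(self):
        rng = np.random.default_rng(3)
        truth = rng.uniform(0.4, 1.2, 40)
        kok = 0.7 * truth - 0.05 + rng.normal(0, 0.02, truth.size)
        yin = truth + rng.normal(0, 0.02, truth.size)
        cal = calibrate_rd(np.column_stack([kok, yin]))
        corrected = cal(kok)
        rmse_raw = np.sqrt(np.mean((kok - truth) ** 2))
        rmse_cor = np.sqrt(np.mean((corrected - truth) ** 2))
        assert rmse_cor < rmse_raw

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rd([(0.5, 0.5), (0.5, 0.6), (0.5, 0.7)])


def _nonphoto_frame(s=0.42, rd25=0.7, t=25.0):
    iinc = np.array([20.0, 50.0, 100.0, 200.0, 800.0, 800.0, 800.0])
    j = np.array([6.0, 15.0, 28.0, 50.0, 90.0, 95.0, 100.0])
    phi2 = j / (s * iinc)
    an = s * (iinc * phi2 / 4) - rd25 * float(arrhenius(1.0, 46390.0, t))
    return pd.DataFrame({"Iinc": iinc, "An": an, "Phi2": phi2, "Tleaf": t,
                         "regime": "nonphotoresp"})


class TestSCalibration:
    def test_exact_recovery(self):
        cal = fit_s_calibration(_nonphoto_frame(s=0.42, rd25=0.7))
        assert cal.s == pytest.approx(0.42, abs=1e-12)
        assert cal.rd25 == pytest.approx(0.7, abs=1e-10)

    def test_temperature_adjustment_inverts_arrhenius(self):
        cal = fit_s_calibration(_nonphoto_frame(s=0.42, rd25=0.7, t=18.0))
        assert cal.rd25 == pytest.approx(0.7, abs=1e-10)

    def test_photorespiratory_rows_rejected(self):
        df = _nonphoto_frame()
        df.loc[0, "regime"] = "light_curve"
        with pytest.raises(ValueError):
            fit_s_calibration(df)

    def test_s_decreases_with_lower_absorptance(self):
        from leafphys.synthetic_data import (
            FluorescenceModel, NoiseModel, TreatmentSpec, generate_curve)
        from leafphys import reference

        def s_for(beta):
            spec = TreatmentSpec(
                water="well-watered", nitrogen="N85", na=2.1,
                biochem=reference.reference_biochem("well-watered", "N85"),
                stomatal=reference.reference_stomatal("well-watered", "N85"),
                fluorescence=FluorescenceModel(beta=beta))
            curve = generate_curve(spec, "nonphotoresp", NoiseModel.zero(), 5)
            return fit_s_calibration(curve).s

        assert s_for(0.70) < s_for(0.85)

    def test_pooled_slope_equals_subset_slopes_when_linear(self):
        df = _nonphoto_frame(s=0.42, rd25=0.7)
        low = fit_s_calibration(df[df.Iinc <= 200])
        assert low.s == pytest.approx(0.42, abs=1e-12)


class TestJmaxKappa2LL:
    def _points(self, jmax25=141.0, k2ll=0.309, t=None):
        iinc = np.array([20, 50, 100, 200, 400, 600, 1000, 1200, 1500] * 2,
                        dtype=float)
        t = np.full(iinc.size, 25.0) if t is None else t
        jmax_t = peaked_arrhenius(jmax25, 43540.0, 650.0, 200000.0, t)
        j = j_from_light(iinc, k2ll, jmax_t, 0.8)
        return pd.DataFrame({"Iinc": iinc, "Tleaf": t, "J": j})

    def test_exact_recovery_at_constant_temperature(self):
        fit = fit_jmax_k2ll(self._points())
        assert fit["jmax25"] == pytest.approx(141.0, rel=1e-8)
        assert fit["kappa2ll"] == pytest.approx(0.309, rel=1e-8)

    def test_exact_recovery_under_fluctuating_temperature(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(15, 30, 18)
        fit = fit_jmax_k2ll(self._points(t=t))
        assert fit["jmax25"] == pytest.approx(141.0, rel=1e-8)
        assert fit["kappa2ll"] == pytest.approx(0.309, rel=1e-8)

    def test_noisy_recovery_within_published_uncertainty(self):
        rng = np.random.default_rng(9)
        frames = [self._points(t=rng.uniform(18, 22, 18)) for _ in range(3)]
        df = pd.concat(frames, ignore_index=True)
        df["J"] = df["J"] + rng.normal(0, 2.0, len(df))
        fit = fit_jmax_k2ll(df)
        # published well-watered N65 estimates: 141 (SE 4), 0.309 (SE 0.020)
        assert abs(fit["jmax25"] - 141.0) < 8.0
        assert abs(fit["kappa2ll"] - 0.309) < 0.040


class TestGmAndVcmax:
    def _forward_curve(self, gm25=0.236, vcmax25=109.0, jmax25=150.0,
                       k2ll=0.242, rd25=0.867, n=20, seed=2):
        """Noise-free (An, Ci) data from the Ci-based min(Ac, Aj) model."""
        rng = np.random.default_rng(seed)
        iinc = np.concatenate([np.linspace(50, 1000, n - 6),
                               np.linspace(1100, 1500, 6)])
        t = rng.uniform(18, 22, iinc.size)
        # low-Ci points at high light are Rubisco-limited for the default truth
        ci = np.where(iinc > 1000, rng.uniform(80, 150, iinc.size),
                      rng.uniform(150, 320, iinc.size))
        jmax_t = peaked_arrhenius(jmax25, 43540.0, 650.0, 200000.0, t)
        j = j_from_light(iinc, k2ll, jmax_t, 0.8)
        rd = arrhenius(rd25, 46390.0, t)
        gm_t = peaked_arrhenius(gm25, 49600.0, 1400.0, 437400.0, t)
        gstar = gamma_star(t)
        kmc = arrhenius(272.4, 80990.0, t)
        kmo = arrhenius(165.8, 23720.0, t)
        aj = nrh_a_ci(ci, j / 4, 2 * gstar, rd, gm_t, gstar)
        ac = nrh_a_ci(ci, arrhenius(vcmax25, 65330.0, t),
                      kmc * (1 + 210 / kmo), rd, gm_t, gstar)
        return pd.DataFrame({"Iinc": iinc, "Tleaf": t, "Ci": ci, "J": j,
                             "An": np.minimum(ac, aj),
                             "aj_only": aj, "is_aj": aj <= ac})

    def test_gm_exact_on_aj_limited_forward_data(self):
        df = self._forward_curve()
        df = df[df.is_aj]
        fit = fit_gm_nrh(df, rd25=0.867)
        assert fit["gm25"] == pytest.approx(0.236, rel=1e-7)

    def test_gm_upper_bound_flags_effectively_infinite(self):
        df = self._forward_curve(gm25=1e9)
        df["An"] = df["aj_only"]
        df = df[df.Iinc <= 1000]
        with pytest.warns(UserWarning, match="effectively infinite"):
            fit = fit_gm_nrh(df, rd25=0.867)
        assert fit.extras.get("at_upper_bound")

    def test_vcmax_exact_recovery(self):
        df = self._forward_curve()
        fit = fit_vcmax(df, jmax25=150.0, kappa2ll=0.242, rd25=0.867,
                        gm25=0.236)
        assert fit["vcmax25"] == pytest.approx(109.0, rel=1e-7)
        assert fit.extras["n_rubisco_limited"] > 0

    def test_vcmax_unidentifiable_on_purely_aj_limited_curve(self):
        df = self._forward_curve(vcmax25=400.0)  # Rubisco never limits
        assert not (~df.is_aj).any()
        with pytest.raises(UnidentifiableError):
            fit_vcmax(df, jmax25=150.0, kappa2ll=0.242, rd25=0.867, gm25=0.236)

    def test_light_and_co2_curves_give_same_vcmax(self):
        """Estimates from a light curve and a CO2 curve generated from one
        truth agree (the two curve types are interchangeable for Vcmax)."""
        from leafphys import reference
        from leafphys.estimation import fit_vcmax as fv
        from leafphys.synthetic_data import (
            NoiseModel, TreatmentSpec, generate_curve, FLUOR_WELL_WATERED)

        spec = TreatmentSpec(
            water="well-watered", nitrogen="N85",
            na=reference.reference_na("well-watered", "N85"),
            biochem=reference.reference_biochem("well-watered", "N85"),
            stomatal=reference.reference_stomatal("well-watered", "N85"),
            fluorescence=FLUOR_WELL_WATERED)
        b = spec.biochem
        results = {}
        for regime in ("light_curve", "ci_curve"):
            curve = generate_curve(spec, regime, NoiseModel.zero(), 17)
            t = curve["Tleaf"].to_numpy()
            jmax_t = peaked_arrhenius(b.jmax25, b.e_jmax, b.s_jmax, b.d_jmax, t)
            curve["J"] = j_from_light(curve["Iinc"].to_numpy(), b.kappa2ll,
                                      jmax_t, b.theta)
            fit = fv(curve, jmax25=b.jmax25, kappa2ll=b.kappa2ll,
                     rd25=b.rd25, gm25=b.gm25)
            results[regime] = fit["vcmax25"]
        assert results["light_curve"] == pytest.approx(results["ci_curve"],
                                                       rel=1e-6)


class TestStomatalFit:
    def _records(self, g0=0.021, a1=0.575, b1=0.203, n=40, seed=4, noise=0.0):
        rng = np.random.default_rng(seed)
        an = rng.uniform(2, 20, n)
        ci = rng.uniform(120, 320, n)
        rd = np.full(n, 0.8)
        cistar = np.full(n, 33.8)
        vpd = rng.uniform(0.5, (a1 - 0.06) / b1 if b1 > 0 else 2.5, n)
        fv = fvpd(vpd, a1, b1)
        gs = g0 + (an + rd) / (ci - cistar) * fv
        gs = gs * (1 + noise * rng.standard_normal(n))
        return pd.DataFrame({"An": an, "Ci": ci, "VPD": vpd, "Rd": rd,
                             "CiStar": cistar, "gs": gs})

    def test_exact_recovery(self):
        fit = fit_stomatal(self._records())
        assert fit["g0"] == pytest.approx(0.021, abs=1e-8)
        assert fit["a1"] == pytest.approx(0.575, abs=1e-7)
        assert fit["b1"] == pytest.approx(0.203, abs=1e-7)

    def test_zero_b1_truth_recovered_and_vpd_insensitive(self):
        fit = fit_stomatal(self._records(b1=0.0))
        assert fit["b1"] == pytest.approx(0.0, abs=1e-5)

    def test_noisy_recovery_within_published_uncertainty(self):
        fit = fit_stomatal(self._records(n=60, noise=0.05))
        # published well-watered N85: g0 0.021 (0.002), a1 0.575 (0.029),
        # b1 0.203 (0.027)
        assert abs(fit["g0"] - 0.021) < 0.004
        assert abs(fit["a1"] - 0.575) < 0.058
        assert abs(fit["b1"] - 0.203) < 0.054

    def test_points_near_cistar_excluded(self):
        df = self._records()
        df.loc[0, "Ci"] = df.loc[0, "CiStar"] + 0.5
        fit = fit_stomatal(df)
        assert fit.extras["n_excluded_near_cistar"] == 1

    def test_fixed_g0_per_record(self):
        df = self._records()
        fit = fit_stomatal(df, fix_g0=np.full(len(df), 0.021))
        assert "g0" not in fit.estimates
        assert fit["a1"] == pytest.approx(0.575, abs=1e-7)

    def test_narrow_vpd_range_warns(self):
        df = self._records()
        df["VPD"] = 1.0
        with pytest.warns(UserWarning, match="VPD range"):
            fit_stomatal(df)


class TestNaRelation:
    def test_exact_line(self):
        na = np.array([0.9, 1.3, 1.7, 2.1])
        fit = fit_na_relation(na, 0.1 * na + 0.02)
        assert fit["slope"] == pytest.approx(0.1, abs=1e-12)
        assert fit["intercept"] == pytest.approx(0.02, abs=1e-12)

    @pytest.mark.parametrize("chi", [62.0, 93.0])
    def test_published_capacity_slopes_through_base_content(self, chi):
        rng = np.random.default_rng(1)
        na = np.concatenate([rng.uniform(1.2, 2.2, 4), rng.uniform(1.2, 2.2, 4)])
        fit = fit_na_relation(na, chi * (na - 0.35), through_offset=0.35)
        assert fit["slope"] == pytest.approx(chi, rel=1e-10)
        assert fit["intercept"] == 0.0

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            fit_na_relation([1.0, 1.0, 1.0], [1, 2, 3])


class TestFTest:
    def test_equal_rss_gives_f_zero_p_one(self):
        f, p = f_test_nested(5.0, 18, 5.0, 20)
        assert f == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        f, p = f_test_nested(8.0, 18, 10.0, 20)
        assert f == pytest.approx(((10 - 8) / 2) / (8 / 18))
        assert 0 < p < 1

    def test_invalid_df_ordering(self):
        with pytest.raises(ValueError):
            f_test_nested(8.0, 20, 10.0, 18)
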