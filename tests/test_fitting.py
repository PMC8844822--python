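"""Model fitting, censoring, selection, inhibition and competition analyses."""

import math

import numpy as np
import pandas as pd
import pytest

import nadasekin as nk
from nadasekin.fitting import _aicc
from nadasekin.models import evaluate_rate

from conftest import FL_NAD, FL_NADP, SAMTIR_NADP, CD38_NAD, noiseless_dataset


class TestRateModelFits:
    def test_noiseless_hyperbola_exact_recovery(self):
        ds = noiseless_dataset("eq1", CD38_NAD)
        fit = nk.fit_rate_model(ds, "eq1")
        assert fit.params["Km"] == pytest.approx(10.4, rel=1e-6)
        assert fit.params["Vmax"] == pytest.approx(6649.0, rel=1e-6)
        assert fit.rss < 1e-10

    def test_noiseless_catalytic_inhibition_recovery(self, samtir_nadp_dataset):
        fit = nk.fit_rate_model(samtir_nadp_dataset, "eq2")
        assert fit.params["Km"] == pytest.approx(83.5, rel=1e-4)
        assert fit.params["Vmax"] == pytest.approx(582.0, rel=1e-4)
        assert fit.params["Kis"] == pytest.approx(151.0, rel=1e-4)
        assert not fit.censored["Kis"]

    def test_noiseless_dual_inhibition_recovery_with_censored_kis(self, fl_nad_dataset):
        fit = nk.fit_rate_model(fl_nad_dataset, "eq3")
        assert fit.params["Km"] == pytest.approx(30.3, rel=1e-3)
        assert fit.params["Kia"] == pytest.approx(324.0, rel=1e-3)
        assert fit.censored["Kis"] and not fit.censored["Kia"]
        p = fit.to_parameters()
        assert p.kis_unbounded

    def test_catalytic_site_fit_not_reattributed(self):
        # Kis well below Km: no allosteric twin exists, site stays catalytic
        ds = noiseless_dataset("eq3", FL_NADP)
        fit = nk.fit_rate_model(ds, "eq3")
        assert fit.params["Kis"] == pytest.approx(132.0, rel=1e-3)
        assert fit.censored["Kia"] and not fit.censored["Kis"]

    def test_censored_constant_reported_as_bound(self, fl_nad_dataset):
        fit = nk.fit_rate_model(fl_nad_dataset, "eq3")
        assert fit.to_record()["Kis"] == "> 8000"

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({"S_uM": [10.0, 100.0, 1000.0], "rate_mU_mg": [1.0, 5.0, 8.0]})
        with pytest.raises(ValueError):
            nk.fit_rate_model(nk.RateDataset(data=df), "eq3")

    def test_brute_force_rss_oracle_two_parameter_model(self):
        # independent dense-grid least squares for the hyperbola
        cfg = nk.SimulationConfig(model="eq1", params=CD38_NAD, cv=0.05, seed=42)
        ds = nk.generate_initial_rates(cfg)
        fit = nk.fit_rate_model(ds, "eq1")
        kms = np.geomspace(1.0, 100.0, 300)
        vmaxs = np.geomspace(2000.0, 20000.0, 300)
        S, r = ds.S, ds.rate
        pred = vmaxs[None, :, None] * S[None, None, :] / (kms[:, None, None] + S[None, None, :])
        rss_grid = float(np.min(np.sum((pred - r[None, None, :]) ** 2, axis=2)))
        assert fit.rss <= rss_grid * 1.01


class TestModelSelection:
    @pytest.mark.parametrize("model,params", [
        ("eq1", CD38_NAD),
        ("eq2", SAMTIR_NADP),
    ])
    def test_noiseless_selection_picks_generating_model(self, model, params):
        chosen, _ = nk.select_substrate_model(noiseless_dataset(model, params))
        assert chosen == model

    def test_both_sites_finite_selects_dual_model(self):
        params = {"Km": 30.3, "Vmax": 22.4, "Kis": 1500.0, "Kia": 324.0}
        chosen, fit = nk.select_substrate_model(noiseless_dataset("eq3", params))
        assert chosen == "eq3"

    def test_narrow_substrate_range_rejected(self):
        df = pd.DataFrame({"S_uM": np.linspace(100, 400, 10),
                           "rate_mU_mg": np.linspace(1, 4, 10)})
        with pytest.raises(ValueError, match="30-fold"):
            nk.select_substrate_model(nk.RateDataset(data=df))

    def test_selection_consistency_under_noise(self):
        # the generating model must win in the vast majority of noisy replicates
        for model, params in (("eq1", CD38_NAD), ("eq2", SAMTIR_NADP)):
            hits = 0
            n_rep = 50
            for k in range(n_rep):
                cfg = nk.SimulationConfig(model=model, params=params, cv=0.05, seed=1000 + k)
                chosen, _ = nk.select_substrate_model(nk.generate_initial_rates(cfg))
                hits += chosen == model
            assert hits / n_rep >= 0.9, (model, hits)

    def test_aicc_penalizes_extra_parameters(self):
        assert _aicc(1.0, 12, 3) > _aicc(1.0, 12, 2)


class TestDoubleReciprocal:
    def test_hyperbola_gives_exact_line(self):
        ds = noiseless_dataset("eq1", CD38_NAD)
        lb = nk.double_reciprocal(ds)
        assert len(lb) == 1
        row = lb.iloc[0]
        assert row["intercept"] == pytest.approx(1.0 / 6649.0, rel=1e-6)
        assert row["slope"] == pytest.approx(10.4 / 6649.0, rel=1e-6)
        assert not row["nonlinear"]

    def test_noncompetitive_intercepts_scale_with_inhibitor(self):
        Ki = 40.0
        cfg = nk.SimulationConfig(
            model="eq5", params={"Km": 69.5, "Vmax": 723.0, "Ki": Ki, "a": 1.0, "n": 1.0},
            s_points=8, s_min=15.0, s_max=600.0, i_levels=(0.0, 25.0, 50.0, 80.0),
            cv=0.0, seed=0,
        )
        lb = nk.double_reciprocal(nk.generate_initial_rates(cfg))
        base = lb.loc[lb["I_uM"] == 0.0, "intercept"].iloc[0]
        for _, row in lb.iterrows():
            expected = base * (1.0 + row["I_uM"] / Ki)
            assert row["intercept"] == pytest.approx(expected, rel=1e-6)

    def test_substrate_inhibited_data_flag_curvature(self, samtir_nadp_dataset):
        lb = nk.double_reciprocal(samtir_nadp_dataset)
        assert bool(lb.iloc[0]["nonlinear"])

    def test_zero_rates_rejected(self):
        df = pd.DataFrame({"S_uM": [1.0, 2.0, 3.0], "rate_mU_mg": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            nk.double_reciprocal(nk.RateDataset(data=df))


class TestIc50Fitting:
    def test_exact_series_zero_residual(self):
        df = nk.generate_ic50_series(87.0, cv=0.0, seed=0)
        fit = nk.fit_ic50(df["I_uM"], df["activity"])
        assert fit.params["ic50"] == pytest.approx(87.0, rel=1e-6)
        assert fit.rss < 1e-12

    def test_flat_series_flagged_divergent(self):
        I = [0.0, 10.0, 50.0, 100.0, 300.0]
        fit = nk.fit_ic50(I, [1.0, 1.0, 1.0, 1.0, 1.0])
        assert fit.censored["ic50"] or any("divergent" in w for w in fit.warnings)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            nk.fit_ic50([10.0, 50.0, 100.0, 300.0], [0.9, 0.6, 0.5, 0.2])


class TestMixedInhibition:
    def test_noiseless_recovery_and_mixed_classification(self):
        cfg = nk.SimulationConfig(
            model="eq5", params={"Km": 69.5, "Vmax": 723.0, "Ki": 15.0, "a": 0.5, "n": 2.0},
            s_points=8, s_min=15.0, s_max=600.0,
            i_levels=(0.0, 25.0, 50.0, 80.0, 120.0), cv=0.0, seed=0,
        )
        res = nk.fit_mixed_inhibition(nk.generate_inhibition_grid(cfg))
        assert res.fit.params["Ki"] == pytest.approx(15.0, rel=1e-4)
        assert res.fit.params["a"] == pytest.approx(0.5, rel=1e-4)
        assert res.fit.params["n"] == pytest.approx(2.0, rel=1e-4)
        assert res.classification == "mixed"
        assert res.slopes_nonlinear  # multi-site binding bends the replots

    def test_pure_noncompetitive_classification_with_linear_replots(self):
        cfg = nk.SimulationConfig(
            model="eq5", params={"Km": 69.5, "Vmax": 723.0, "Ki": 40.0, "a": 1.0, "n": 1.0},
            s_points=8, s_min=15.0, s_max=600.0,
            i_levels=(0.0, 25.0, 50.0, 80.0, 120.0), cv=0.0, seed=0,
        )
        res = nk.fit_mixed_inhibition(nk.generate_inhibition_grid(cfg))
        assert res.classification == "noncompetitive"
        assert not res.slopes_nonlinear and not res.intercepts_nonlinear

    def test_missing_control_level_rejected(self):
        df = pd.DataFrame({
            "S_uM": np.tile(np.geomspace(15, 600, 6), 3),
            "I_uM": np.repeat([25.0, 50.0, 120.0], 6),
            "rate_mU_mg": np.ones(18),
        })
        with pytest.raises(ValueError, match="I=0"):
            nk.fit_mixed_inhibition(nk.RateDataset(data=df))


@pytest.fixture(scope="module")
def nad_titration():
    return {
        lvl: noiseless_dataset("eq3", {k: v for k, v in truth.items() if k != "model"})
        for lvl, truth in nk.NMN_TITRATION_TRUTHS["NAD"].items()
    }


class TestCompetitionAnalysis:
    def test_nad_titration_is_competitive_allosteric(self, nad_titration):
        analysis = nk.nmn_titration_analysis(nad_titration)
        assert analysis.verdict == "competitive-allosteric"
        assert analysis.kia_trend.significant_positive
        vopts = [v for _, v in analysis.maxima]
        assert all(b > a for a, b in zip(vopts, vopts[1:]))

    def test_nadp_titration_is_non_allosteric(self):
        datasets = {
            lvl: noiseless_dataset("eq3", {k: v for k, v in truth.items() if k != "model"})
            for lvl, truth in nk.NMN_TITRATION_TRUTHS["NADP"].items()
        }
        analysis = nk.nmn_titration_analysis(datasets)
        assert analysis.verdict == "non-allosteric"
        assert analysis.kia_trend is None  # allosteric constant censored throughout
        assert analysis.kis_trend is not None
        assert not analysis.kis_trend.significant_positive

    def test_generative_apparent_kia_model_detected(self):
        # apparent Kia(E) = Kia0 * (1 + E/Ka): textbook competitive shift
        Kia0, Ka = 324.0, 15.0
        datasets = {}
        for lvl in (5.0, 10.0, 20.0, 50.0):
            params = {"Km": 30.3, "Vmax": 22.4 * (1 + lvl / 10.0),
                      "Kia": Kia0 * (1 + lvl / Ka)}
            datasets[lvl] = noiseless_dataset("eq3", params)
        analysis = nk.nmn_titration_analysis(datasets)
        assert analysis.verdict == "competitive-allosteric"

    def test_fewer_than_three_levels_rejected(self, nad_titration):
        subset = dict(list(nad_titration.items())[:2])
        with pytest.raises(ValueError):
            nk.nmn_titration_analysis(subset)


class TestTrendRegression:
    def test_reference_kia_column_regression(self):
        tr = nk.trend_regression([5, 10, 20, 50], [385.1, 414.9, 787.0, 1201.7])
        assert tr.slope == pytest.approx(18.58, abs=0.05)
        assert tr.intercept == pytest.approx(302.4, abs=0.5)
        assert tr.significant_positive

    def test_reference_kis_column_has_no_trend(self):
        tr = nk.trend_regression([5, 10, 20, 50], [52.7, 57.4, 60.0, 48.0])
        assert not tr.significant_positive


class TestRecoveryUnderNoise:
    """Median parameter recovery from noisy replicates, per generating law."""

    N_SEEDS = 40  # recovery invariants use medians; 40 replicates bound the runtime

    def median_estimate(self, model, params, target, **kw):
        from nadasekin.cli import recovery_experiment

        r = recovery_experiment(model, params, target, n_datasets=self.N_SEEDS,
                                cv=0.05, seed=2024, **kw)
        return r["median"], r["truth"]

    def test_dual_inhibition_km_and_kia(self):
        med, truth = self.median_estimate("eq3", FL_NAD, "Kia")
        assert abs(med / truth - 1) < 0.10
        med, truth = self.median_estimate("eq3", FL_NAD, "Km")
        assert abs(med / truth - 1) < 0.10

    def test_catalytic_inhibition_kis(self):
        med, truth = self.median_estimate("eq2", SAMTIR_NADP, "Kis")
        assert abs(med / truth - 1) < 0.10

    def test_mixed_inhibition_ki(self):
        med, truth = self.median_estimate(
            "eq5", {"Km": 69.5, "Vmax": 723.0, "Ki": 15.0, "a": 0.5, "n": 2.0}, "Ki",
            s_points=8, s_min=15.0, s_max=600.0, i_levels=(0.0, 25.0, 50.0, 80.0, 120.0),
        )
        assert abs(med / truth - 1) < 0.10

    def test_ic50_recovery(self):
        from nadasekin.cli import ic50_recovery

        r = ic50_recovery(87.0, n_datasets=self.N_SEEDS, cv=0.03, seed=2024)
        assert abs(r["median"] / 87.0 - 1) < 0.10
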