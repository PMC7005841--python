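"""Diversity mixed model: recovery, inference and prediction behaviour."""

import numpy as np
import pandas as pd
import pytest

from gqay.diversity import (
    DiversityModel,
    SingularDesignError,
    legume_robustness,
    select_diversity_form,
)
from gqay.experiment import SimulationParams


class TestFit:
    def test_noise_free_fit_recovers_generating_slopes(self, noise_free_annual):
        res = DiversityModel(noise_free_annual, "biomass_yield").fit()
        truth = SimulationParams().sqrt_slope
        for m, est in res.diversity_slopes.items():
            assert est == pytest.approx(truth[m], rel=1e-6)
        assert res.sigma2_block == res.sigma2_plot == res.sigma2_resid == 0.0

    def test_noise_free_predictions_equal_generating_means(self, noise_free_annual):
        res = DiversityModel(noise_free_annual, "biomass_yield").fit()
        merged = noise_free_annual.copy()
        # predictions at each sward's own covariates reproduce the data
        import patsy
        (X,) = patsy.build_design_matrices([res.design_info], res.model.data)
        pred = np.asarray(X) @ res.fe_params.to_numpy()
        assert pred == pytest.approx(merged["biomass_yield"].to_numpy(), rel=1e-8)

    def test_variance_components_are_nonnegative(self, annual_table):
        res = DiversityModel(annual_table, "qa_me").fit()
        assert res.sigma2_block >= 0 and res.sigma2_plot >= 0 and res.sigma2_resid > 0
        assert (res.bse_robust > 0).all()
        # robust covariance is symmetric PSD
        C = res.cov_robust.to_numpy()
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-8

    def test_missing_management_level_is_informative_error(self, annual_table):
        sub = annual_table[annual_table.management != "extensive"]
        with pytest.raises(SingularDesignError, match="extensive"):
            DiversityModel(sub, "qa_me")

    def test_missing_column_rejected(self, annual_table):
        with pytest.raises(ValueError, match="lacks"):
            DiversityModel(annual_table.drop(columns=["richness"]), "qa_me")

    @pytest.mark.parametrize("bad", ["cubic", "exp"])
    def test_unknown_form_rejected(self, annual_table, bad):
        with pytest.raises(ValueError):
            DiversityModel(annual_table, "qa_me", diversity_form=bad)


class TestInference:
    def test_bonferroni_thresholds_divide_levels(self, annual_table):
        res = DiversityModel(annual_table, "qa_me").fit()
        table = res.effect_table(n_tests=6)
        for _, row in table.iterrows():
            expected = "".join(
                "*" for level in (0.05, 0.01, 0.001) if row.p_raw < level / 6
            )
            assert row.significance == expected
        with pytest.raises(ValueError):
            res.effect_table(n_tests=0)

    def test_pairwise_wald_covers_all_pairs_and_is_symmetric(self, annual_table):
        res = DiversityModel(annual_table, "qa_me").fit()
        pw = res.pairwise_wald()
        assert len(pw) == 10
        # swapping the pair flips the sign of the difference, not the statistic
        names = res._slope_names()
        cov = res.cov_robust
        for _, row in pw.iterrows():
            n1, n2 = names[row.management_1], names[row.management_2]
            d_rev = res.fe_params[n2] - res.fe_params[n1]
            var = cov.loc[n1, n1] + cov.loc[n2, n2] - 2 * cov.loc[n1, n2]
            assert d_rev**2 / var == pytest.approx(row.wald_stat, rel=1e-12)


class TestPrediction:
    def test_sqrt_prediction_gap_is_three_slopes(self, annual_table):
        res = DiversityModel(annual_table, "qa_me").fit()
        grid = res.predict_grid([1, 16]).pivot(
            index="management", columns="richness", values="predicted")
        gaps = (grid[16.0] - grid[1.0]) / (np.sqrt(16) - 1)
        for m, slope in res.diversity_slopes.items():
            assert gaps[m] == pytest.approx(slope, rel=1e-9)

    def test_extrapolation_warns(self, annual_table):
        res = DiversityModel(annual_table, "qa_me").fit()
        with pytest.warns(UserWarning, match="extrapolat"):
            res.predict_grid([80])


class TestFormSelection:
    def test_identical_candidates_tie(self, annual_table):
        race = select_diversity_form(annual_table, "qa_me", forms=["sqrt", "sqrt"])
        assert race.aic.iloc[0] == pytest.approx(race.aic.iloc[1])

    def test_race_uses_identical_observation_sets(self, annual_table):
        race = select_diversity_form(annual_table, "qa_me")
        assert race.n_obs.nunique() == 1
        assert (race.error == "").all()
        assert set(race.form) == {"sqrt", "linear", "linear_squared", "log", "inverse"}


class TestLegumeRobustness:
    def test_no_legumes_collapses_both_variants(self, annual_table):
        df = annual_table.copy()
        df["legume_present"] = 0
        df["legume_share"] = 0.0
        out = legume_robustness(df, "qa_me")
        assert out.slope_legume_presence.to_numpy() == pytest.approx(
            out.slope_legume_sqrt_share.to_numpy(), rel=1e-9)

    def test_variants_agree_on_presence_generated_data(self, annual_table):
        out = legume_robustness(annual_table, "biomass_yield")
        # data were generated with a presence-only legume effect: both
        # parameterizations must land near the same diversity slopes
        rel = np.abs(
            out.slope_legume_presence - out.slope_legume_sqrt_share
        ) / out.slope_legume_presence.abs()
        assert (rel < 0.15).all()
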