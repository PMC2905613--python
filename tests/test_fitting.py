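"""Expected-likelihood logistic fits, pseudo-r^2, fit ratios and risk estimates."""

import numpy as np
import pytest

import markerfit as mf
from markerfit.fitting import GenotypeCoding, fit_weighted_logistic


def sm_logit_oracle(dist, coding, case_fraction=0.5):
    """Independent IRLS fit: statsmodels GLM on the six (genotype, status) cells."""
    import statsmodels.api as sm

    X = np.vstack([coding.design, coding.design])
    y = np.r_[np.ones(3), np.zeros(3)]
    w = np.r_[case_fraction * dist.case_probs, (1 - case_fraction) * dist.control_probs]
    keep = w > 0
    model = sm.GLM(y[keep], X[keep], family=sm.families.Binomial(), freq_weights=w[keep])
    return model.fit(tol=1e-12).params


def dist_for(moi="dominant", grr=1.3, p=0.3, r2=1.0, baseline=0.05):
    return mf.expected_marker_distribution(
        mf.TwoLocusScenario(p, p, r2), mf.PenetranceModel(moi, grr, baseline)
    )


class TestFitExpected:
    @pytest.mark.parametrize("coding", ["multiplicative_trend", "dominant", "recessive", "general"])
    def test_null_scenario_has_no_association(self, coding):
        dist = mf.expected_marker_distribution(
            mf.TwoLocusScenario(0.3, 0.3, 1.0), mf.PenetranceModel("dominant", 1.0)
        )
        fit = mf.fit_expected(dist, mf.CODINGS[coding])
        assert fit.pseudo_r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.or_het == pytest.approx(1.0, abs=1e-9)
        assert fit.or_hom == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_dominant_or_at_complete_ld_is_the_penetrance_odds_ratio(self, p):
        # (0.065/0.935) / (0.05/0.95) ~ 1.3209: an odds ratio, above the GRR of 1.3
        fit = mf.fit_expected(dist_for(p=p), mf.CODINGS["dominant"])
        expected = (0.065 / 0.935) / (0.05 / 0.95)
        assert fit.or_het == pytest.approx(expected, rel=1e-10)
        assert fit.or_hom == pytest.approx(expected, rel=1e-10)

    def test_matches_independent_irls_oracle(self, random_scenarios):
        for scen, pen in random_scenarios:
            dist = mf.expected_marker_distribution(scen, pen)
            for name in ("multiplicative_trend", "dominant", "recessive", "general"):
                coding = mf.CODINGS[name]
                ours = mf.fit_expected(dist, coding).coefficients
                oracle = sm_logit_oracle(dist, coding)
                np.testing.assert_allclose(ours, oracle, rtol=1e-8, atol=1e-12)

    def test_general_coding_is_saturated(self, random_scenarios):
        for scen, pen in random_scenarios[:30]:
            dist = mf.expected_marker_distribution(scen, pen)
            fit = mf.fit_expected(dist, mf.CODINGS["general"])
            observed = 0.5 * dist.case_probs / (0.5 * dist.case_probs + 0.5 * dist.control_probs)
            np.testing.assert_allclose(fit.fitted_case_probs(), observed, rtol=1e-10)
            for other in ("multiplicative_trend", "dominant", "recessive"):
                assert fit.pseudo_r2 >= mf.fit_expected(dist, mf.CODINGS[other]).pseudo_r2 - 1e-12

    def test_loglik_bracketed_by_null_and_saturated(self, random_scenarios):
        for scen, pen in random_scenarios[:30]:
            dist = mf.expected_marker_distribution(scen, pen)
            lls = {
                name: mf.fit_expected(dist, mf.CODINGS[name]).expected_loglik
                for name in ("null", "multiplicative_trend", "general")
            }
            assert lls["null"] == pytest.approx(-np.log(2), abs=1e-12)
            assert lls["null"] - 1e-12 <= lls["multiplicative_trend"] <= lls["general"] + 1e-12

    def test_affine_reparameterization_leaves_fit_invariant(self):
        dist = dist_for()
        base = mf.fit_expected(dist, mf.CODINGS["multiplicative_trend"])
        shifted = GenotypeCoding("shifted_trend", np.array([[1.0, 1.0], [1.0, 3.0], [1.0, 5.0]]))
        alt = mf.fit_expected(dist, shifted)
        assert alt.expected_loglik == pytest.approx(base.expected_loglik, abs=1e-12)
        assert alt.or_het == pytest.approx(base.or_het, rel=1e-10)
        assert alt.or_hom == pytest.approx(base.or_hom, rel=1e-10)

    def test_separation_raises(self):
        dist = mf.MarkerCaseControlDistribution(
            np.array([0.2, 0.3, 0.5]), np.array([0.5, 0.5, 0.0]), prevalence=0.05
        )
        with pytest.raises(mf.ConvergenceError, match="separation"):
            mf.fit_expected(dist, mf.CODINGS["recessive"])

    def test_zero_mass_class_dropped_from_design(self):
        dist = mf.MarkerCaseControlDistribution(
            np.array([0.6, 0.4, 0.0]), np.array([0.7, 0.3, 0.0]), prevalence=0.05
        )
        fit = mf.fit_expected(dist, mf.CODINGS["multiplicative_trend"])
        assert np.isfinite(fit.expected_loglik)
        with pytest.raises(mf.ConvergenceError, match="fewer populated classes"):
            mf.fit_expected(dist, mf.CODINGS["general"])

    def test_genotype_relabelling_symmetry_is_exact(self, random_scenarios):
        # reversing genotype indices and swapping dominant <-> recessive codings
        # leaves pseudo-r^2 (hence fit ratios) unchanged
        for scen, pen in random_scenarios[:30]:
            dist = mf.expected_marker_distribution(scen, pen)
            rev = mf.MarkerCaseControlDistribution(
                dist.case_probs[::-1].copy(), dist.control_probs[::-1].copy(), dist.prevalence
            )
            pairs = [("dominant", "recessive"), ("multiplicative_trend", "multiplicative_trend")]
            for fwd, bwd in pairs:
                a = mf.fit_expected(dist, mf.CODINGS[fwd]).pseudo_r2
                b = mf.fit_expected(rev, mf.CODINGS[bwd]).pseudo_r2
                assert b == pytest.approx(a, rel=1e-9, abs=1e-12)


class TestPseudoR2:
    def test_intercept_only_vs_itself_is_zero(self):
        assert mf.pseudo_r2(-np.log(2), -np.log(2)) == 0.0
        assert mf.pseudo_r2(-np.log(2), -np.log(2), "coxsnell") == 0.0

    def test_mcfadden_and_coxsnell_ratios_agree_at_small_effects(self):
        # the two definitions give near-identical *ratios* between codings
        for grr in (1.1, 1.3):
            for p in np.arange(0.05, 1.0, 0.05):
                for r2 in (1.0, 0.8, 0.5):
                    dist = dist_for(grr=grr, p=round(p, 2), r2=r2)
                    pen = mf.PenetranceModel("dominant", grr)
                    mcf = mf.fit_ratio(dist, pen, "mcfadden").ratio
                    cs = mf.fit_ratio(dist, pen, "coxsnell").ratio
                    assert cs == pytest.approx(mcf, rel=0.01)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            mf.pseudo_r2(-0.5, -np.log(2), "nagelkerke")


class TestFitRatio:
    def test_rare_dominant_allele_ratio_near_one(self):
        # the true and multiplicative fits become indistinguishable as the
        # risk allele gets rare (the high-risk homozygote vanishes)
        pen = mf.PenetranceModel("dominant", 2.0)
        excess = [
            mf.fit_ratio(dist_for(grr=2.0, p=p), pen).ratio - 1.0 for p in (0.05, 0.01, 0.001)
        ]
        assert excess[0] > excess[1] > excess[2] > 0
        assert excess[1] < 5e-3
        assert excess[2] < 5e-4

    def test_multiplicative_truth_gives_ratio_one(self):
        pen = mf.PenetranceModel("multiplicative", 1.3)
        dist = mf.expected_marker_distribution(mf.TwoLocusScenario(0.3, 0.3, 0.8), pen)
        assert mf.fit_ratio(dist, pen).ratio == pytest.approx(1.0, abs=1e-12)

    def test_ratio_approximately_invariant_to_grr(self):
        ratios = [
            mf.fit_ratio(dist_for(grr=g), mf.PenetranceModel("dominant", g)).ratio
            for g in (1.1, 1.3, 2.0)
        ]
        assert (max(ratios) - min(ratios)) / min(ratios) < 0.05

    def test_null_ratio_is_flagged_undefined(self):
        pen_null = mf.PenetranceModel("dominant", 1.0)
        dist = mf.expected_marker_distribution(mf.TwoLocusScenario(0.3, 0.3, 1.0), pen_null)
        cmp_ = mf.fit_ratio(dist, pen_null)
        assert not cmp_.defined
        assert np.isnan(cmp_.ratio)

    def test_ratio_at_least_one_and_decaying_in_ld(self, dominant13):
        prev = np.inf
        for r2 in (1.0, 0.8, 0.5):
            cmp_ = mf.fit_ratio(dist_for(r2=r2), dominant13)
            assert cmp_.ratio >= 1.0 - 1e-9
            assert cmp_.ratio <= prev + 1e-12
            prev = cmp_.ratio


class TestEstimateRisks:
    def test_one_result_per_coding_and_recessive_het_or_is_one(self):
        dist = dist_for(moi="recessive", grr=2.0, p=0.3)
        fits = mf.estimate_risks(dist, [mf.CODINGS["recessive"], mf.CODINGS["multiplicative_trend"]])
        assert [f.coding.name for f in fits] == ["recessive", "multiplicative_trend"]
        assert fits[0].or_het == pytest.approx(1.0, abs=1e-12)

    def test_rare_recessive_allele_both_models_near_null_het_or(self):
        # heterozygotes carry no risk and high-risk homozygotes vanish, so both
        # codings' heterozygote OR approaches 1 as the allele gets rare
        ors = {
            p: [
                f.or_het
                for f in mf.estimate_risks(
                    dist_for(moi="recessive", grr=2.0, p=p),
                    [mf.CODINGS["recessive"], mf.CODINGS["multiplicative_trend"]],
                )
            ]
            for p in (0.05, 0.02, 0.005)
        }
        for p, (or_rec, or_mult) in ors.items():
            assert or_rec == pytest.approx(1.0, abs=1e-12)  # exact: design rows equal
        assert ors[0.005][1] < ors[0.02][1] < ors[0.05][1]
        assert ors[0.005][1] == pytest.approx(1.0, abs=6e-3)


class TestWeightedLogistic:
    def test_trend_slope_zero_on_balanced_weights(self):
        w = np.array([0.2, 0.5, 0.3])
        beta, _ = fit_weighted_logistic(0.5 * w, 0.5 * w, mf.CODINGS["multiplicative_trend"].design)
        assert beta[1] == pytest.approx(0.0, abs=1e-12)
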