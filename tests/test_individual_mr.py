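"""Unit and property tests for the GRS two-stage MR machinery."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from vitdmr import (
    GRSWeights,
    IndividualDataset,
    compute_grs,
    confounder_scan,
    meta_analyze,
    scenario,
    simulate_cohort,
    stage1_exposure_regression,
    stage2_outcome_regression,
    stratified_analysis,
    two_stage_analysis,
    wald_two_stage,
)
from vitdmr.individual_mr import TwoStageResult


EXPOSURE_BETAS = (0.0312, 0.0167, 0.0361, 0.0262, 0.0893, 0.0164)
VIDS = tuple(f"rs{i}" for i in range(6))


def make_dataset(dosages, **pheno_cols):
    n = len(dosages)
    dose = pd.DataFrame(np.asarray(dosages, dtype=float), columns=list(VIDS))
    pheno = pd.DataFrame({k: v for k, v in pheno_cols.items()}, index=dose.index)
    return IndividualDataset(dosages=dose, phenotypes=pheno, cohort_id="test")


def make_ts(beta, se, cohort="c"):
    return wald_two_stage((1.0, 0.0), (beta, se), cohort_id=cohort)


# ---------------------------------------------------------------------------
# GRS construction
# ---------------------------------------------------------------------------

class TestComputeGRS:
    def test_weighted_score_arithmetic(self):
        weights = GRSWeights(VIDS, EXPOSURE_BETAS)
        data = make_dataset(np.full((3, 6), 2.0), outcome=[0, 0, 1])
        grs = compute_grs(data, weights, "weighted")
        assert np.allclose(grs, 2 * sum(EXPOSURE_BETAS))  # 0.4318
        assert grs.iloc[0] == pytest.approx(0.4318)

    def test_unweighted_score_is_allele_count(self):
        weights = GRSWeights(VIDS, EXPOSURE_BETAS)
        data = make_dataset(np.full((2, 6), 2.0), outcome=[0, 1])
        assert np.allclose(compute_grs(data, weights, "unweighted"), 12.0)

    def test_unit_weights_equal_unweighted(self):
        rng = np.random.default_rng(1)
        dose = rng.binomial(2, 0.4, (50, 6))
        data = make_dataset(dose, outcome=np.zeros(50))
        unit = GRSWeights(VIDS, (1.0,) * 6)
        some = GRSWeights(VIDS, EXPOSURE_BETAS)
        np.testing.assert_array_equal(
            compute_grs(data, unit, "weighted").to_numpy(),
            compute_grs(data, some, "unweighted").to_numpy(),
        )

    def test_missing_dosages_mean_imputed(self):
        dose = np.array([[2.0] * 6, [0.0] * 6, [np.nan] + [1.0] * 5])
        data = make_dataset(dose, outcome=[0, 0, 0])
        weights = GRSWeights(VIDS, (1.0,) * 6)
        grs = compute_grs(data, weights, "weighted")
        # imputed value is the column mean of the observed dosages (1.0)
        assert grs.iloc[2] == pytest.approx(6.0)

    def test_column_mismatch_is_error(self):
        data = make_dataset(np.zeros((2, 6)), outcome=[0, 1])
        weights = GRSWeights(("rsX",), (0.1,))
        with pytest.raises(ValueError, match="missing"):
            compute_grs(data, weights)


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

class TestStage1:
    def test_f_statistic_matches_analytic_form(self):
        """Univariable F equals (n-2) R^2 / (1 - R^2) for the fitted R^2."""
        rng = np.random.default_rng(2)
        n = 2821
        dose = rng.binomial(2, 0.4, (n, 6)).astype(float)
        grs = dose @ np.array(EXPOSURE_BETAS) * 4.0
        exposure = 3.6 + grs + rng.normal(0, 0.49, n)
        data = make_dataset(dose, exposure=exposure)
        res = stage1_exposure_regression(data, pd.Series(grs, index=data.phenotypes.index))
        assert res.f_statistic == pytest.approx(
            (res.n - 2) * res.r2 / (1 - res.r2), rel=1e-10
        )
        assert not res.weak_instrument

    def test_null_instrument_f_distribution_and_weak_flag(self):
        """With GRS unrelated to exposure, F ~ F(1, n-2): the weak-instrument
        flag appears at about the F(1, n-2) CDF at 10."""
        rng = np.random.default_rng(3)
        n, reps = 150, 400
        flags, fs = 0, []
        for _ in range(reps):
            dose = rng.binomial(2, 0.3, (n, 6)).astype(float)
            exposure = rng.normal(3.6, 0.5, n)
            data = make_dataset(dose, exposure=exposure)
            grs = pd.Series(dose @ np.ones(6), index=data.phenotypes.index)
            res = stage1_exposure_regression(data, grs)
            flags += res.weak_instrument
            fs.append(res.f_statistic)
        expected = stats.f.cdf(10, 1, n - 2)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(flags / reps - expected) < 4 * se + 1e-9
        # the F sample should look like F(1, n-2)
        assert stats.kstest(fs, stats.f(1, n - 2).cdf).pvalue > 0.001

    def test_exact_linear_exposure_is_degenerate(self):
        rng = np.random.default_rng(4)
        dose = rng.binomial(2, 0.4, (100, 6)).astype(float)
        grs = pd.Series(dose @ np.ones(6))
        data = make_dataset(dose, exposure=1.0 + 2.0 * grs.to_numpy())
        with pytest.raises(ValueError, match="R\\^2 = 1"):
            stage1_exposure_regression(data, grs)

    def test_all_missing_exposure_is_error(self):
        data = make_dataset(np.zeros((40, 6)), exposure=np.full(40, np.nan))
        grs = pd.Series(np.zeros(40), index=data.phenotypes.index)
        with pytest.raises(ValueError, match="missing"):
            stage1_exposure_regression(data, grs)


# ---------------------------------------------------------------------------
# Confounder scan
# ---------------------------------------------------------------------------

class TestConfounderScan:
    def test_type_i_error_near_nominal_for_independent_confounder(self):
        rng = np.random.default_rng(5)
        n, reps, flagged = 400, 300, 0
        for _ in range(reps):
            dose = rng.binomial(2, 0.4, (n, 6)).astype(float)
            data = make_dataset(
                dose,
                outcome=np.zeros(n),
                bmi=rng.normal(27, 4, n),
            )
            grs = pd.Series(dose @ np.ones(6), index=data.phenotypes.index)
            tab = confounder_scan(data, grs, ["bmi"])
            flagged += int(tab["flagged"].iloc[0])
        rate = flagged / reps
        assert 0.05 - 4 * np.sqrt(0.05 * 0.95 / reps) < rate < 0.05 + 4 * np.sqrt(
            0.05 * 0.95 / reps
        )

    def test_deterministic_function_of_grs_is_flagged(self):
        rng = np.random.default_rng(6)
        dose = rng.binomial(2, 0.4, (500, 6)).astype(float)
        grs_vals = dose @ np.ones(6)
        data = make_dataset(dose, outcome=np.zeros(500), age=2.0 * grs_vals + 30)
        grs = pd.Series(grs_vals, index=data.phenotypes.index)
        tab = confounder_scan(data, grs, ["age"])
        assert tab["flagged"].iloc[0]
        assert tab["p_value"].iloc[0] < 1e-10

    def test_binary_and_categorical_kinds_dispatch(self):
        rng = np.random.default_rng(7)
        n = 600
        dose = rng.binomial(2, 0.4, (n, 6)).astype(float)
        data = make_dataset(
            dose,
            outcome=np.zeros(n),
            sex=rng.integers(0, 2, n).astype(float),
            centre=rng.choice(["a", "b", "c"], n),
        )
        grs = pd.Series(dose @ np.ones(6), index=data.phenotypes.index)
        tab = confounder_scan(data, grs, ["sex", "centre"])
        assert list(tab["kind"]) == ["binary", "categorical"]
        assert (tab["p_value"] > 0).all()

    def test_empty_set_gives_empty_table(self):
        data = make_dataset(np.zeros((10, 6)), outcome=np.zeros(10))
        tab = confounder_scan(data, pd.Series(np.zeros(10)), [])
        assert len(tab) == 0

    def test_unknown_confounder_is_error(self):
        data = make_dataset(np.zeros((10, 6)), outcome=np.zeros(10))
        with pytest.raises(ValueError, match="unknown confounder"):
            confounder_scan(data, pd.Series(np.zeros(10)), ["smoking"])


# ---------------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------------

class TestStage2:
    def test_null_grs_z_statistic_calibrated(self):
        rng = np.random.default_rng(8)
        n, reps, rej = 600, 300, 0
        for _ in range(reps):
            dose = rng.binomial(2, 0.4, (n, 6)).astype(float)
            data = make_dataset(dose, outcome=rng.integers(0, 2, n).astype(float))
            grs = pd.Series(dose @ np.ones(6), index=data.phenotypes.index)
            res = stage2_outcome_regression(data, grs)
            rej += abs(res.beta2 / res.se2) > 1.96
        rate = rej / reps
        assert rate < 0.05 + 4 * np.sqrt(0.05 * 0.95 / reps)

    def test_recovers_planted_log_odds_slope(self):
        rng = np.random.default_rng(9)
        n = 20_000
        dose = rng.binomial(2, 0.4, (n, 6)).astype(float)
        grs_vals = dose @ np.ones(6) - 6 * 0.8
        prob = 1 / (1 + np.exp(-(-0.2 + 0.5 * grs_vals)))
        data = make_dataset(dose, outcome=(rng.random(n) < prob).astype(float))
        grs = pd.Series(grs_vals, index=data.phenotypes.index)
        res = stage2_outcome_regression(data, grs)
        assert abs(res.beta2 - 0.5) < 3 * res.se2

    def test_grs_rescaling_halves_coefficient(self):
        rng = np.random.default_rng(10)
        n = 2_000
        dose = rng.binomial(2, 0.4, (n, 6)).astype(float)
        grs_vals = dose @ np.ones(6)
        prob = 1 / (1 + np.exp(-(-2.0 + 0.2 * grs_vals)))
        data = make_dataset(dose, outcome=(rng.random(n) < prob).astype(float))
        idx = data.phenotypes.index
        res1 = stage2_outcome_regression(data, pd.Series(grs_vals, index=idx))
        res2 = stage2_outcome_regression(data, pd.Series(2 * grs_vals, index=idx))
        assert res2.beta2 == pytest.approx(res1.beta2 / 2, rel=1e-6)

    def test_single_class_outcome_is_error(self):
        data = make_dataset(np.zeros((50, 6)), outcome=np.zeros(50))
        with pytest.raises(ValueError, match="cases and controls"):
            stage2_outcome_regression(data, pd.Series(np.zeros(50)))


# ---------------------------------------------------------------------------
# Wald ratio with Taylor SE
# ---------------------------------------------------------------------------

class TestWaldTwoStage:
    def test_zero_numerator_gives_null_or(self):
        res = wald_two_stage((0.055, 0.008), (0.0, 0.02))
        assert res.causal_beta == 0.0
        assert res.or_ == 1.0

    def test_zero_stage1_se_reduces_to_scaled_stage2_se(self):
        res = wald_two_stage((0.5, 0.0), (0.3, 0.04))
        assert res.causal_se == pytest.approx(0.04 / 0.5, abs=1e-15)

    def test_zero_stage1_beta_is_error(self):
        with pytest.raises(ValueError, match="Wald ratio undefined"):
            wald_two_stage((0.0, 0.01), (0.3, 0.04))

    def test_taylor_se_matches_parametric_bootstrap_oracle(self):
        b1, s1, b2, s2 = 0.5, 0.02, 0.3, 0.05
        res = wald_two_stage((b1, s1), (b2, s2))
        rng = np.random.default_rng(11)
        draws = rng.normal(b2, s2, 100_000) / rng.normal(b1, s1, 100_000)
        assert res.causal_se == pytest.approx(draws.std(ddof=1), rel=0.05)


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

class TestMetaAnalyze:
    def test_identical_estimates_pool_to_themselves(self):
        results = [make_ts(0.12, 0.05, f"c{i}") for i in range(5)]
        meta = meta_analyze(results)
        assert meta.pooled_beta == pytest.approx(0.12)
        assert meta.q_stat == pytest.approx(0.0, abs=1e-20)
        assert meta.tau2 == 0.0

    def test_matches_statsmodels_combine_effects_oracle(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(12)
        for _ in range(10):
            m = int(rng.integers(3, 9))
            b = rng.normal(0.1, 0.3, m)
            se = rng.uniform(0.05, 0.4, m)
            meta = meta_analyze(
                [make_ts(b[i], se[i], f"c{i}") for i in range(m)]
            )
            ref = combine_effects(b, se**2, method_re="chi2")
            # statsmodels reports the untruncated moment estimator
            assert meta.tau2 == pytest.approx(max(0.0, float(ref.tau2)), abs=1e-10)
            if float(ref.tau2) > 0:
                assert meta.pooled_beta == pytest.approx(
                    float(ref.mean_effect_re), abs=1e-10
                )
                assert meta.pooled_se == pytest.approx(
                    float(ref.sd_eff_w_re), abs=1e-10
                )

    def test_dl_tau2_recovery_on_synthetic_cohorts(self):
        """Method-of-moments tau^2 is unbiased over replicates when cohort
        estimates are drawn with known between-cohort variance."""
        rng = np.random.default_rng(13)
        tau2_true = 0.04
        se = np.array([0.10, 0.15, 0.12, 0.2, 0.08])
        est = []
        for _ in range(2000):
            b = rng.normal(0.0, np.sqrt(tau2_true + se**2))
            est.append(meta_analyze(
                [make_ts(b[i], se[i], f"c{i}") for i in range(5)]
            ).tau2)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - tau2_true) < 4 * mc_se

    def test_single_result_returned_with_zero_tau2(self):
        meta = meta_analyze([make_ts(0.2, 0.1)])
        assert meta.tau2 == 0.0
        assert meta.pooled_beta == pytest.approx(0.2)
        assert len(meta.cohort_estimates) == 1


# ---------------------------------------------------------------------------
# End-to-end invariances and stratification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def simulated_pair():
    from vitdmr import simulate_two_sample

    cfg = replace(scenario("observational_effect"), n_individuals=8_000, seed=77)
    return simulate_two_sample(cfg, case_fraction=0.4)


class TestTwoStageAnalysis:
    def test_causal_estimate_invariant_to_grs_rescaling(self, simulated_pair, grs_weights):
        expo, outc = simulated_pair
        meta1 = two_stage_analysis(expo, [outc], grs_weights)
        scaled = GRSWeights(
            grs_weights.variant_ids, tuple(3.0 * w for w in grs_weights.weights)
        )
        meta3 = two_stage_analysis(expo, [outc], scaled)
        assert meta3.pooled_beta == pytest.approx(meta1.pooled_beta, rel=1e-9)
        assert meta3.pooled_se == pytest.approx(meta1.pooled_se, rel=1e-6)

    def test_pooled_estimate_recovers_generating_effect(self):
        """Mean pooled estimate across replicate two-cohort studies stays
        within Monte-Carlo error of the generating causal log-OR."""
        from vitdmr import simulate_two_sample
        from vitdmr.synthetic_data import calibrate_genetic_effects

        cfg = scenario("observational_effect")
        betas, _ = calibrate_genetic_effects(cfg)
        w = GRSWeights(tuple(cfg.variant_ids), tuple(betas))
        est, ses = [], []
        for s in range(40):
            c = replace(cfg, n_individuals=12_000, seed=3_000 + s)
            expo, outc = simulate_two_sample(c, case_fraction=0.35)
            meta = two_stage_analysis(expo, [outc], w)
            est.append(meta.pooled_beta)
            ses.append(meta.pooled_se)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - cfg.causal_beta) < 3 * mc_se


class TestStratified:
    @pytest.fixture(scope="class")
    def site_pair(self):
        from vitdmr import SimConfig, simulate_two_sample

        cfg = SimConfig(
            n_individuals=12_000,
            site_causal_beta={"distal": -1.2},
            seed=123,
        )
        return simulate_two_sample(cfg, case_fraction=0.4)

    def test_detects_planted_site_specific_effect(self, site_pair, grs_weights):
        expo, outc = site_pair
        distal = stratified_analysis(expo, [outc], grs_weights, site="distal")
        proximal = stratified_analysis(expo, [outc], grs_weights, site="proximal")
        assert distal.p_value < 0.05
        assert distal.pooled_beta < 0
        assert proximal.p_value > 0.05

    def test_all_cases_one_site_equals_unstratified(self, grs_weights):
        rng = np.random.default_rng(14)
        n = 3_000
        dose = rng.binomial(2, 0.4, (n, 6)).astype(float)
        outcome = rng.integers(0, 2, n).astype(float)
        site = np.where(outcome == 1, "rectum", None)
        pheno = pd.DataFrame(
            {"exposure": np.nan, "outcome": outcome, "site": site}
        )
        outc = IndividualDataset(
            dosages=pd.DataFrame(dose, columns=list(grs_weights.variant_ids)),
            phenotypes=pheno,
            cohort_id="one_site",
        )
        cfg = replace(scenario("null"), n_individuals=3_000, seed=15)
        expo = simulate_cohort(cfg, "expo")
        strat = stratified_analysis(expo, [outc], grs_weights, site="rectum")
        full = two_stage_analysis(expo, [outc], grs_weights)
        assert strat.pooled_beta == pytest.approx(full.pooled_beta, abs=1e-12)

    def test_unknown_site_is_error(self, simulated_pair, grs_weights):
        expo, outc = simulated_pair
        with pytest.raises(ValueError, match="unknown tumour site"):
            stratified_analysis(expo, [outc], grs_weights, site="sigmoid")
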