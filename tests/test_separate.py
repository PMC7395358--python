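"""Per-outcome model: likelihood oracle checks, fitting, ICC, Wald table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

import jointlogit as jl
from jointlogit.errors import ParameterizationError, SeparationError
from jointlogit.joint import JointCovariance, mc_loglik_oracle
from jointlogit.separate import SeparateFit

from conftest import make_config, plain_logistic_loglik


def _full_cov(v):
    M = np.eye(3) * 0.5
    M[0, 0] = v
    return M


class TestLoglikSeparate:
    def test_zero_variances_equal_plain_logistic(self, small_dataset):
        beta = np.array([0.4, -0.3])
        ll = jl.loglik_separate(beta, 0.0, 0.0, small_dataset, 1, quad_nodes=7)
        cc = small_dataset.complete_cases()
        eta = cc.design_matrix() @ beta
        assert ll == pytest.approx(
            plain_logistic_loglik(cc.outcomes[:, 0], eta), abs=1e-8
        )

    def test_zero_model_gives_minus_n_log2(self, small_dataset):
        ll = jl.loglik_separate([0.0, 0.0], 0.0, 0.0, small_dataset, 1)
        assert ll == pytest.approx(-small_dataset.n_complete * np.log(2), abs=1e-8)

    def test_matches_monte_carlo_oracle(self, tiny_dataset):
        beta = np.array([[0.5, ]])
        var_c, var_h = 0.4, 0.4
        ll = jl.loglik_separate(beta[0], var_c, var_h, tiny_dataset, 1, quad_nodes=7)
        est, se = mc_loglik_oracle(
            beta, JointCovariance(_full_cov(var_c), _full_cov(var_h)),
            tiny_dataset, n_draws=400_000, seed=17, outcomes=(1,),
        )
        assert abs(ll - est) < 3 * se

    def test_quadrature_node_sequence_converges(self, tiny_dataset):
        lls = [
            jl.loglik_separate([0.3], 0.6, 0.5, tiny_dataset, 2, quad_nodes=k)
            for k in (3, 5, 9)
        ]
        d1, d2 = abs(lls[1] - lls[0]), abs(lls[2] - lls[1])
        assert d2 <= d1

    def test_invariant_to_relabeling(self, small_dataset):
        beta = [0.2, 0.1]
        ll = jl.loglik_separate(beta, 0.3, 0.2, small_dataset, 1)
        shuffled = small_dataset.df.sample(frac=1.0, random_state=1)
        shuffled = shuffled.assign(
            cluster_id="X" + shuffled["cluster_id"],
            household_id="X" + shuffled["household_id"],
        )
        ds2 = jl.SurveyDataset(shuffled, small_dataset.covariate_names)
        assert jl.loglik_separate(beta, 0.3, 0.2, ds2, 1) == pytest.approx(
            ll, abs=1e-9
        )

    def test_negative_variance_rejected(self, small_dataset):
        with pytest.raises(ParameterizationError):
            jl.loglik_separate([0.0, 0.0], -0.1, 0.0, small_dataset, 1)


class TestFitSeparate:
    def test_recovers_intercept_with_no_clustering(self):
        cfg = make_config(
            n_clusters=50, households_per_cluster=10,
            individuals_per_household=10,
            beta=((-1.0,), (0.0,), (0.0,)),
            sigma_c=np.zeros((3, 3)).tolist(),
            sigma_h=np.zeros((3, 3)).tolist(),
            seed=31,
        )
        dataset, _ = jl.simulate_survey(cfg)
        fit = jl.fit_separate(dataset, 1, quad_nodes=5)
        assert fit.converged
        assert abs(fit.beta[0] + 1.0) < 3 * fit.se_beta[0]
        assert fit.var_cluster < 0.05
        assert fit.var_household < 0.05

    def test_recovers_survey_magnitude_variances(self):
        # variance components at the blood-test magnitudes (0.394 / 0.385)
        cfg = make_config(
            n_clusters=300, households_per_cluster=10,
            individuals_per_household=3,
            beta=((-0.5,), (0.0,), (0.0,)),
            sigma_c=np.diag([0.394, 0.1, 0.1]).tolist(),
            sigma_h=np.diag([0.385, 0.1, 0.1]).tolist(),
            seed=37,
        )
        dataset, _ = jl.simulate_survey(cfg)
        fit = jl.fit_separate(dataset, 1, quad_nodes=5)
        assert fit.converged
        assert abs(fit.var_cluster - 0.394) < 3 * fit.se_var_cluster
        assert abs(fit.var_household - 0.385) < 3 * fit.se_var_household

    def test_loglik_at_optimum_beats_truth(self, small_dataset):
        fit = jl.fit_separate(small_dataset, 1, quad_nodes=5, compute_se=False)
        ll_true = jl.loglik_separate(
            [-0.5, 0.4], 0.4, 0.4, small_dataset, 1, quad_nodes=5
        )
        assert fit.loglik >= ll_true - 1e-6

    def test_constant_outcome_raises_separation(self, small_dataset):
        df = small_dataset.df.copy()
        df["y1"] = 1.0
        ds = jl.SurveyDataset(df, small_dataset.covariate_names)
        with pytest.raises(SeparationError):
            jl.fit_separate(ds, 1)


class TestComputeIcc:
    @pytest.mark.parametrize(
        "var_c,var_h,expected_cluster,expected_cum",
        [
            (0.0, 0.0, 0.0, 0.0),
            (0.394, 0.385, 0.0968, 0.1914),   # blood-test magnitudes
            (0.696, 0.039, 0.1729, 0.1826),   # awareness magnitudes
            (3.29, 0.0, 0.5, 0.5),
        ],
    )
    def test_known_values(self, var_c, var_h, expected_cluster, expected_cum):
        res = jl.compute_icc(var_c, var_h)
        assert round(res.icc_cluster, 4) == pytest.approx(expected_cluster)
        assert round(res.icc_household_cumulative, 4) == pytest.approx(expected_cum)

    def test_level1_constant_is_rounded_pi2_over_3(self):
        assert jl.LEVEL1_VARIANCE == 3.29
        assert abs(jl.LEVEL1_VARIANCE - jl.LEVEL1_VARIANCE_EXACT) < 0.005

    def test_exact_level1_option(self):
        res = jl.compute_icc(0.394, 0.385, level1=jl.LEVEL1_VARIANCE_EXACT)
        assert res.icc_cluster == pytest.approx(0.394 / (0.779 + np.pi**2 / 3))

    def test_invalid_level1(self):
        with pytest.raises(ParameterizationError):
            jl.compute_icc(0.1, 0.1, level1=0.0)

    @given(
        var_c=st.floats(0.0, 5.0),
        var_h=st.floats(0.0, 5.0),
        bump=st.floats(0.01, 2.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True, database=None)
    def test_monotone_in_cluster_variance_and_ordered(self, var_c, var_h, bump):
        lo = jl.compute_icc(var_c, var_h)
        hi = jl.compute_icc(var_c + bump, var_h)
        assert hi.icc_cluster > lo.icc_cluster
        assert 0.0 <= lo.icc_cluster <= lo.icc_household_cumulative < 1.0


class TestWaldTable:
    def _fake_fit(self, beta, se):
        return SeparateFit(
            outcome=1, term_names=[f"t{i}" for i in range(len(beta))],
            beta=np.asarray(beta, dtype=float),
            se_beta=np.asarray(se, dtype=float),
            var_cluster=0.4, var_household=0.2,
            se_var_cluster=0.1, se_var_household=0.1,
            loglik=-10.0, converged=True, n_used=100, quad_nodes=7,
        )

    def test_zero_estimate_gives_p_one(self):
        tab = jl.wald_table(self._fake_fit([0.0], [1.0]))
        assert tab.loc[0, "p"] == pytest.approx(1.0)

    def test_z_of_196_gives_p_near_005(self):
        tab = jl.wald_table(self._fake_fit([1.96], [1.0]))
        assert tab.loc[0, "p"] == pytest.approx(0.05, abs=1e-3)

    def test_variance_rows_one_sided(self):
        tab = jl.wald_table(self._fake_fit([0.0], [1.0]))
        var_rows = tab[tab["type"] == "variance"]
        assert len(var_rows) == 2
        # one-sided: var 0.4, se 0.1 -> z = 4 -> tiny p
        assert var_rows.iloc[0]["p"] < 1e-4

    def test_missing_se_marks_p_missing(self):
        fit = self._fake_fit([1.0], [1.0])
        fit.se_beta = None
        tab = jl.wald_table(fit)
        assert np.isnan(tab.loc[0, "p"])

    def test_true_zero_coefficient_p_uniform_across_replicates(self):
        # type-I calibration of the fixed-effect Wald p at small scale
        pvals = []
        for seed in range(100):
            cfg = make_config(
                n_clusters=60, households_per_cluster=4,
                individuals_per_household=3,
                beta=((-0.3, 0.0), (0.0, 0.0), (0.0, 0.0)),
                sigma_c=np.diag([0.3, 0.1, 0.1]).tolist(),
                sigma_h=np.diag([0.2, 0.1, 0.1]).tolist(),
                covariates=[
                    jl.CovariateSpec("x", "binary", "household", prevalence=0.5)
                ],
                seed=500 + seed,
            )
            dataset, _ = jl.simulate_survey(cfg)
            fit = jl.fit_separate(dataset, 1, quad_nodes=3)
            tab = jl.wald_table(fit)
            pvals.append(tab.loc[1, "p"])
        stat = kstest(pvals, "uniform")
        assert stat.pvalue > 0.01
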