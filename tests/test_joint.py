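"""Joint model: factorization, oracle agreement, fitting, LRT mechanics."""

import dataclasses

import numpy as np
import pytest

import jointlogit as jl
from jointlogit._engine import ParamLayout, aghq_loglik
from jointlogit.errors import ComparabilityError, ParameterizationError
from jointlogit.joint import JointCovariance, _prepare_joint

from conftest import exchangeable_cov, make_config, plain_logistic_loglik


@pytest.fixture
def tiny_beta():
    return np.array([[0.5], [0.0], [-0.5]])


class TestJointCovariance:
    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ParameterizationError):
            JointCovariance(sigma_c=bad, sigma_h=np.eye(3))

    def test_cross_covariances_naming(self):
        cov = JointCovariance(
            sigma_c=np.array(exchangeable_cov([1, 1, 1], 0.5)),
            sigma_h=np.eye(3),
        )
        cross = cov.cross_covariances()
        assert set(cross) == {
            "d1^12", "d1^13", "d1^23", "d2^12", "d2^13", "d2^23"
        }
        assert cross["d1^12"] == pytest.approx(0.5)
        assert cross["d2^12"] == 0.0


class TestLoglikJoint:
    def test_diagonal_covariance_factorizes_by_outcome(self, small_dataset, tiny_beta):
        beta = np.hstack([tiny_beta, np.array([[0.4], [-0.2], [0.5]])])
        cov = JointCovariance(np.diag([0.3, 0.5, 0.7]), np.diag([0.2, 0.4, 0.1]))
        ll_joint = jl.loglik_joint(beta, cov, small_dataset, quad_nodes=5)
        ll_sum = sum(
            jl.loglik_separate(
                beta[q], cov.sigma_c[q, q], cov.sigma_h[q, q],
                small_dataset, q + 1, quad_nodes=5,
            )
            for q in range(3)
        )
        assert abs(ll_joint - ll_sum) < 1e-8

    def test_zero_variances_sum_of_plain_logistic(self, small_dataset, tiny_beta):
        beta = np.hstack([tiny_beta, np.zeros((3, 1))])
        cov = JointCovariance(np.zeros((3, 3)), np.zeros((3, 3)))
        ll = jl.loglik_joint(beta, cov, small_dataset, quad_nodes=3)
        cc = small_dataset.complete_cases()
        X = cc.design_matrix()
        expected = sum(
            plain_logistic_loglik(cc.outcomes[:, q], X @ beta[q])
            for q in range(3)
        )
        assert ll == pytest.approx(expected, abs=1e-7)

    def test_matches_monte_carlo_oracle(self, tiny_dataset, tiny_beta):
        cov = JointCovariance(
            np.array(exchangeable_cov([0.4, 0.4, 0.4], 0.5)),
            np.array(exchangeable_cov([0.4, 0.4, 0.4], 0.5)),
        )
        ll = jl.loglik_joint(tiny_beta, cov, tiny_dataset, quad_nodes=5)
        est, se = jl.mc_loglik_oracle(
            tiny_beta, cov, tiny_dataset, n_draws=300_000, seed=5
        )
        assert abs(ll - est) < 3 * se

    def test_cluster_permutation_invariance(self, small_dataset, tiny_beta):
        cov = JointCovariance(
            np.array(exchangeable_cov([0.5, 0.4, 0.3], 0.4)), np.eye(3) * 0.2
        )
        beta = np.hstack([tiny_beta, np.zeros((3, 1))])
        ll = jl.loglik_joint(beta, cov, small_dataset, quad_nodes=3)
        relabel = {
            c: f"z{99 - i}" for i, c in
            enumerate(sorted(small_dataset.df["cluster_id"].unique()))
        }
        df = small_dataset.df.copy()
        df["cluster_id"] = df["cluster_id"].map(relabel)
        ds2 = jl.SurveyDataset(df, small_dataset.covariate_names)
        assert jl.loglik_joint(beta, cov, ds2, quad_nodes=3) == pytest.approx(
            ll, abs=1e-9
        )

    def test_quadrature_node_sequence_converges(self, tiny_dataset, tiny_beta):
        cov = JointCovariance(
            np.array(exchangeable_cov([0.5, 0.5, 0.5], 0.5)),
            np.array(exchangeable_cov([0.4, 0.4, 0.4], 0.3)),
        )
        lls = [
            jl.loglik_joint(tiny_beta, cov, tiny_dataset, quad_nodes=k)
            for k in (3, 5, 7)
        ]
        assert abs(lls[2] - lls[1]) <= abs(lls[1] - lls[0])

    def test_analytic_score_close_to_finite_differences(self, tiny_dataset):
        pdat = _prepare_joint(tiny_dataset)
        lay = ParamLayout(3, pdat.n_terms, restrict=False)
        theta = lay.pack(
            np.array([[0.5], [0.0], [-0.5]]),
            np.array(exchangeable_cov([0.4, 0.5, 0.6], 0.4)),
            np.array(exchangeable_cov([0.3, 0.3, 0.3], 0.2)),
        )
        beta, Sc, Sh, Tc, Th = lay.unpack(theta)
        _, grads = aghq_loglik(beta, Sc, Sh, pdat, 5, want_grad=True)
        ga = lay.pack_grad(grads, Tc, Th)

        def f(th):
            b, sc, sh, _, _ = lay.unpack(th)
            return aghq_loglik(b, sc, sh, pdat, 5)

        gfd = np.empty_like(theta)
        for i in range(len(theta)):
            h = 1e-5
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            gfd[i] = (f(tp) - f(tm)) / (2 * h)
        # adaptation is held fixed in the analytic score; tolerance reflects
        # the quadrature-level error of that approximation
        assert np.max(np.abs(ga - gfd)) < 5e-3


class TestMcOracle:
    def test_zero_variances_exact(self, small_dataset, tiny_beta):
        beta = np.hstack([tiny_beta, np.zeros((3, 1))])
        cov = JointCovariance(np.zeros((3, 3)), np.zeros((3, 3)))
        est, se = jl.mc_loglik_oracle(beta, cov, small_dataset, n_draws=1000, seed=0)
        cc = small_dataset.complete_cases()
        X = cc.design_matrix()
        expected = sum(
            plain_logistic_loglik(cc.outcomes[:, q], X @ beta[q])
            for q in range(3)
        )
        assert est == pytest.approx(expected, abs=1e-4)
        assert se < 1e-4

    def test_se_shrinks_with_sqrt_draws(self, tiny_dataset, tiny_beta):
        cov = JointCovariance(
            np.array(exchangeable_cov([0.4, 0.4, 0.4], 0.5)), np.eye(3) * 0.4
        )
        _, se1 = jl.mc_loglik_oracle(tiny_beta, cov, tiny_dataset,
                                     n_draws=50_000, seed=3)
        _, se2 = jl.mc_loglik_oracle(tiny_beta, cov, tiny_dataset,
                                     n_draws=100_000, seed=4)
        assert se2 / se1 == pytest.approx(1 / np.sqrt(2), rel=0.2)


class TestFitJoint:
    def test_recovers_cross_covariance(self):
        # cluster-level correlation 0.6 between outcomes 2 and 3 at
        # survey-like variances 0.7 / 0.85
        sigma_c = np.diag([0.5, 0.7, 0.85])
        d23 = 0.6 * np.sqrt(0.7 * 0.85)
        sigma_c[1, 2] = sigma_c[2, 1] = d23
        cfg = make_config(
            n_clusters=200, households_per_cluster=4,
            individuals_per_household=2,
            beta=((-0.8,), (0.4,), (0.0,)),
            sigma_c=sigma_c.tolist(),
            sigma_h=np.diag([0.3, 0.25, 0.2]).tolist(),
            seed=101,
        )
        dataset, _ = jl.simulate_survey(cfg)
        fit = jl.fit_joint(dataset, quad_nodes=3)
        est = fit.covariance.sigma_c[1, 2]
        se = fit.se_sigma_c[1, 2]
        assert se > 0
        assert abs(est - d23) < 3 * se

    def test_null_cross_covariance_matches_separate_fits(self):
        cfg = make_config(
            n_clusters=120, households_per_cluster=4,
            individuals_per_household=2,
            beta=((-0.8,), (0.4,), (0.0,)),
            sigma_c=np.diag([0.5, 0.7, 0.85]).tolist(),
            sigma_h=np.diag([0.3, 0.25, 0.2]).tolist(),
            seed=103,
        )
        dataset, _ = jl.simulate_survey(cfg)
        full = jl.fit_joint(dataset, quad_nodes=3)
        sep = [
            jl.fit_separate(dataset, q, quad_nodes=3, compute_se=True)
            for q in (1, 2, 3)
        ]
        for q in range(3):
            for d_est, d_se in zip(
                (full.covariance.sigma_c, full.covariance.sigma_h),
                (full.se_sigma_c, full.se_sigma_h),
            ):
                for p in range(q + 1, 3):
                    assert abs(d_est[q, p]) < 3 * max(d_se[q, p], 1e-3)
            assert abs(full.beta[q, 0] - sep[q].beta[0]) < 3 * sep[q].se_beta[0]

    def test_restricted_never_beats_full(self, small_dataset):
        full, restricted = jl.fit_joint_pair(
            small_dataset, quad_nodes=3, compute_se=False
        )
        assert full.loglik >= restricted.loglik - 1e-9
        assert restricted.covariance.is_diagonal


class TestLRT:
    def test_identical_fits_give_zero_statistic(self, small_dataset):
        _, restricted = jl.fit_joint_pair(
            small_dataset, quad_nodes=3, compute_se=False
        )
        pseudo_full = dataclasses.replace(restricted, restrict_cross=False)
        res = jl.lrt_cross_covariances(pseudo_full, restricted)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 6

    def test_requires_comparable_fits(self, small_dataset):
        full, restricted = jl.fit_joint_pair(
            small_dataset, quad_nodes=3, compute_se=False
        )
        with pytest.raises(ComparabilityError):
            jl.lrt_cross_covariances(restricted, restricted)
        other = dataclasses.replace(restricted, quad_nodes=5)
        with pytest.raises(ComparabilityError):
            jl.lrt_cross_covariances(full, other)
        alien = dataclasses.replace(restricted, data_hash="deadbeef")
        with pytest.raises(ComparabilityError):
            jl.lrt_cross_covariances(full, alien)

    def test_strong_cross_correlation_rejected(self):
        cfg = make_config(
            n_clusters=80, households_per_cluster=4,
            individuals_per_household=2,
            beta=((-0.8,), (0.4,), (0.0,)),
            sigma_c=exchangeable_cov([0.7, 0.85, 0.75], 0.8),
            sigma_h=np.diag([0.3, 0.25, 0.2]).tolist(),
            seed=107,
        )
        dataset, _ = jl.simulate_survey(cfg)
        full, restricted = jl.fit_joint_pair(
            dataset, quad_nodes=3, compute_se=False
        )
        res = jl.lrt_cross_covariances(full, restricted)
        assert res.p_value < 0.05
        assert "joint model preferred" in res.decision_note
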