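import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from jointlogit.config import CovariateSpec, SimulationConfig
from jointlogit.data import SurveyDataset
from jointlogit.simulate import simulate_survey


def exchangeable_cov(variances, rho):
    sd = np.sqrt(np.asarray(variances, dtype=float))
    R = np.full((3, 3), rho)
    np.fill_diagonal(R, 1.0)
    return (np.outer(sd, sd) * R).tolist()


def make_config(
    n_clusters=2,
    households_per_cluster=2,
    individuals_per_household=2,
    beta=((0.5,), (0.0,), (-0.5,)),
    sigma_c=None,
    sigma_h=None,
    covariates=(),
    missing_rate=0.0,
    seed=0,
):
    if sigma_c is None:
        sigma_c = exchangeable_cov([0.4, 0.4, 0.4], 0.5)
    if sigma_h is None:
        sigma_h = exchangeable_cov([0.4, 0.4, 0.4], 0.5)
    return SimulationConfig(
        n_clusters=n_clusters,
        households_per_cluster=households_per_cluster,
        individuals_per_household=individuals_per_household,
        beta=[list(b) for b in beta],
        sigma_c=sigma_c,
        sigma_h=sigma_h,
        covariates=list(covariates),
        missing_rate=missing_rate,
        seed=seed,
    )


@pytest.fixture
def tiny_dataset():
    """2 clusters x 2 households x 2 persons, dense cross-outcome covariance."""
    dataset, _ = simulate_survey(make_config(seed=3))
    return dataset


@pytest.fixture
def small_dataset():
    """20 clusters x 4 households x 2 persons with a household covariate."""
    cfg = make_config(
        n_clusters=20,
        households_per_cluster=4,
        beta=((-0.5, 0.4), (0.3, -0.2), (0.0, 0.5)),
        covariates=[CovariateSpec("elec", "binary", "household", prevalence=0.3)],
        seed=11,
    )
    dataset, _ = simulate_survey(cfg)
    return dataset


def manual_dataset(rows, covariate_names=None):
    """Build a SurveyDataset from (cluster, household, person, y1, y2, y3, *x)."""
    cov_names = covariate_names or []
    cols = ["cluster_id", "household_id", "person_id", "y1", "y2", "y3"] + cov_names
    df = pd.DataFrame(rows, columns=cols)
    return SurveyDataset(df, covariate_names=cov_names)


def plain_logistic_loglik(y, eta):
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
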