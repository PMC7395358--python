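"""Synthetic three-level survey generator.

Draws datasets from exactly the generative model the joint analysis assumes:
individuals in households in clusters, three Bernoulli outcomes with
outcome-specific fixed effects, and trivariate normal random intercepts at
cluster and household level with within-level cross-outcome covariance and
zero cross-level covariance.

Reproducibility contract: a single seeded ``numpy.random.Generator`` is used
and the draw order is fixed as

    1. cluster random effects, then cluster-level covariates;
    2. household counts (if sampled), household random effects, then
       household-level covariates;
    3. individual counts (if sampled), then individual-level covariates;
    4. the three outcomes (one uniform triple per individual);
    5. the joint-missingness mask.

The same config and seed therefore always produce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import CovariateSpec, SimulationConfig
from .data import SurveyDataset
from .separate import ICCResult, compute_icc
from ._engine import _chol_psd

# Logistic-normal attenuation constant (16*sqrt(3) / (15*pi))^2.
_ATTEN = (16.0 * np.sqrt(3.0) / (15.0 * np.pi)) ** 2


@dataclass
class RandomEffectsDraw:
    """True random-intercept draws returned alongside a simulated dataset."""

    u_c: dict     # cluster_id -> 3-vector (log-odds units)
    u_hc: dict    # (cluster_id, household_id) -> 3-vector

    def cluster_matrix(self) -> np.ndarray:
        return np.array([self.u_c[k] for k in sorted(self.u_c)])

    def household_matrix(self) -> np.ndarray:
        return np.array([self.u_hc[k] for k in sorted(self.u_hc)])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": "cluster", "cluster_id": c, "household_id": "",
             "u1": v[0], "u2": v[1], "u3": v[2]}
            for c, v in self.u_c.items()
        ] + [
            {"level": "household", "cluster_id": c, "household_id": h,
             "u1": v[0], "u2": v[1], "u3": v[2]}
            for (c, h), v in self.u_hc.items()
        ]
        return pd.DataFrame(rows)


def _draw_covariate(spec: CovariateSpec, size: int, rng: np.random.Generator):
    if spec.kind == "continuous":
        return rng.normal(spec.mean, spec.sd, size)
    if spec.kind == "binary":
        return (rng.random(size) < spec.prevalence).astype(float)
    return rng.choice(spec.levels, size=size, p=spec.probs)


def _encode(spec: CovariateSpec, values: np.ndarray) -> dict:
    """Map raw covariate draws to encoded column(s)."""
    if spec.kind != "categorical":
        return {spec.name: np.asarray(values, dtype=float)}
    cols = {}
    for lv in spec.levels:
        if lv == spec.reference:
            continue
        cols[f"{spec.name}[{lv}]"] = (np.asarray(values) == lv).astype(float)
    return cols


def simulate_survey(config: SimulationConfig):
    """Draw one survey. Returns ``(SurveyDataset, RandomEffectsDraw)``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    C = int(config.n_clusters)
    Lc = _chol_psd(config.sigma_c_array)
    Lh = _chol_psd(config.sigma_h_array)
    beta = config.beta_array

    cluster_ids = [f"c{i + 1:04d}" for i in range(C)]

    # 1. cluster random effects + cluster-level covariates
    u_c = rng.standard_normal((C, 3)) @ Lc.T
    cluster_cov = {
        s.name: _draw_covariate(s, C, rng)
        for s in config.covariates if s.level == "cluster"
    }

    # 2. households
    hpc = config.households_per_cluster
    if isinstance(hpc, (list, tuple, np.ndarray)):
        n_hh = np.asarray(hpc, dtype=int)
    else:
        n_hh = np.full(C, int(hpc), dtype=int)
    H = int(n_hh.sum())
    cl_of_h = np.repeat(np.arange(C), n_hh)
    household_ids = []
    for c in range(C):
        household_ids.extend(
            f"{cluster_ids[c]}-h{j + 1:03d}" for j in range(n_hh[c])
        )
    u_h = rng.standard_normal((H, 3)) @ Lh.T
    household_cov = {
        s.name: _draw_covariate(s, H, rng)
        for s in config.covariates if s.level == "household"
    }

    # 3. individuals
    iph = config.individuals_per_household
    if isinstance(iph, dict):
        n_ind = rng.poisson(float(iph["mean"]), H) + 1
    else:
        n_ind = np.full(H, int(iph), dtype=int)
    N = int(n_ind.sum())
    h_of_i = np.repeat(np.arange(H), n_ind)
    person_seq = np.concatenate([np.arange(k) for k in n_ind]) + 1
    individual_cov = {
        s.name: _draw_covariate(s, N, rng)
        for s in config.covariates if s.level == "individual"
    }

    # assemble encoded design in config covariate order
    columns = {}
    for spec in config.covariates:
        if spec.level == "cluster":
            raw = np.asarray(cluster_cov[spec.name])[cl_of_h][h_of_i]
        elif spec.level == "household":
            raw = np.asarray(household_cov[spec.name])[h_of_i]
        else:
            raw = np.asarray(individual_cov[spec.name])
        columns.update(_encode(spec, raw))
    names = config.column_names
    X = np.column_stack([np.ones(N)] + [columns[c] for c in names])

    # 4. outcomes
    eta = X @ beta.T + u_c[cl_of_h][h_of_i] + u_h[h_of_i]
    Y = (rng.random((N, 3)) < expit(eta)).astype(float)

    # 5. joint missingness: the whole outcome triple is dropped
    if config.missing_rate > 0:
        miss = rng.random(N) < config.missing_rate
        Y[miss] = np.nan

    df = pd.DataFrame(
        {
            "cluster_id": np.asarray(cluster_ids, dtype=object)[cl_of_h][h_of_i],
            "household_id": np.asarray(household_ids, dtype=object)[h_of_i],
            "person_id": [
                f"{household_ids[h]}-p{k:02d}"
                for h, k in zip(h_of_i, person_seq)
            ],
            "y1": Y[:, 0],
            "y2": Y[:, 1],
            "y3": Y[:, 2],
        }
    )
    for c in names:
        df[c] = columns[c]

    encoding_map = {
        s.name: {"reference": s.reference, "columns": s.column_names}
        for s in config.covariates if s.kind == "categorical"
    }
    dataset = SurveyDataset(df, covariate_names=names, encoding_map=encoding_map)
    draws = RandomEffectsDraw(
        u_c={cid: u_c[i].copy() for i, cid in enumerate(cluster_ids)},
        u_hc={
            (cluster_ids[cl_of_h[h]], household_ids[h]): u_h[h].copy()
            for h in range(H)
        },
    )
    return dataset, draws


def latent_icc_of_config(config: SimulationConfig, outcome: int) -> ICCResult:
    """Theoretical latent-scale ICC implied by a config's variance components."""
    if outcome not in (1, 2, 3):
        raise ValueError("outcome must be 1, 2, or 3")
    q = outcome - 1
    return compute_icc(
        float(config.sigma_c_array[q, q]), float(config.sigma_h_array[q, q])
    )


def _solve_intercepts(target_prev, slopes, cov_means, sigma_c, sigma_h):
    """Intercepts giving approximate marginal prevalences under the
    logistic-normal attenuation approximation (covariate variance ignored)."""
    out = []
    for q in range(3):
        tot_var = sigma_c[q][q] + sigma_h[q][q]
        shift = float(np.dot(slopes[q], cov_means))
        out.append(float(logit(target_prev[q]) * np.sqrt(1.0 + _ATTEN * tot_var) - shift))
    return out


def default_config(seed: int = 0, missing_rate: float = 0.0) -> SimulationConfig:
    """Desk-scale emulation of the Mozambique-style survey.

    50 clusters x 6 households x 3 individuals (~900 records), covariates at
    the levels they vary at in such surveys, cluster/household variance
    components at survey-like magnitudes, and intercepts placed so marginal
    prevalences are near (0.134, 0.772, 0.549).
    """
    return _emulation_config(
        n_clusters=50, households_per_cluster=6, individuals_per_household=3,
        seed=seed, missing_rate=missing_rate,
    )


def paper_scale_config(seed: int = 0, missing_rate: float = 0.0) -> SimulationConfig:
    """Survey-scale preset: 270 clusters, ~23 households each, household
    sizes 1 + Poisson(0.5) (mean 1.5 sampled adults)."""
    return _emulation_config(
        n_clusters=270, households_per_cluster=23,
        individuals_per_household={"sampler": "poisson_plus_one", "mean": 0.5},
        seed=seed, missing_rate=missing_rate,
    )


def _emulation_config(n_clusters, households_per_cluster, individuals_per_household,
                      seed, missing_rate):
    covariates = [
        CovariateSpec("age", "continuous", "individual", mean=31.0, sd=12.5),
        CovariateSpec("education", "continuous", "individual", mean=3.0, sd=3.69),
        CovariateSpec("male", "binary", "individual", prevalence=0.42),
        CovariateSpec(
            "wealth", "categorical", "household",
            levels=["poorest", "poorer", "middle", "richer", "richest"],
            probs=[0.122, 0.164, 0.189, 0.219, 0.306], reference="poorest",
        ),
        CovariateSpec("electricity", "binary", "household", prevalence=0.253),
    ]
    # generic log-odds effects at survey-plausible magnitudes
    slopes = [
        [-0.003, 0.02, -0.13, 0.25, 0.33, 0.89, 1.22, -0.30],
        [-0.005, 0.15, 0.68, 0.02, 0.25, 0.44, 0.62, 0.88],
        [-0.005, 0.15, -0.05, -0.03, 0.04, 0.18, 0.45, 0.47],
    ]
    cov_means = [31.0, 3.0, 0.42, 0.164, 0.189, 0.219, 0.306, 0.253]
    sd_c = np.sqrt([0.394, 0.696, 0.851])
    sd_h = np.sqrt([0.385, 0.039, 0.067])
    corr_c = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.4], [0.4, 0.4, 1.0]])
    corr_h = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.3], [0.3, 0.3, 1.0]])
    sigma_c = (np.outer(sd_c, sd_c) * corr_c).tolist()
    sigma_h = (np.outer(sd_h, sd_h) * corr_h).tolist()
    intercepts = _solve_intercepts(
        (0.134, 0.772, 0.549), slopes, cov_means, sigma_c, sigma_h
    )
    beta = [[intercepts[q]] + slopes[q] for q in range(3)]
    return SimulationConfig(
        n_clusters=n_clusters,
        households_per_cluster=households_per_cluster,
        individuals_per_household=individuals_per_household,
        beta=beta, sigma_c=sigma_c, sigma_h=sigma_h,
        covariates=covariates, missing_rate=missing_rate, seed=seed,
    )
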