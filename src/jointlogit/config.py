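"""Generative configuration for synthetic hierarchical surveys.

A :class:`SimulationConfig` fully specifies the three-level generative model:
hierarchy sizes, per-outcome fixed-effect vectors on the log-odds scale,
trivariate normal cluster- and household-level random-intercept covariance
blocks (zero covariance across levels), covariate generators, and joint
outcome missingness.  Configs round-trip through YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import yaml

from .errors import ConfigError, DimensionError, ParameterizationError
from ._engine import check_psd

LEVELS = ("individual", "household", "cluster")


@dataclass
class CovariateSpec:
    """One covariate generator.

    kind 'continuous' uses (mean, sd); 'binary' uses prevalence; 'categorical'
    uses (levels, probs, reference) and is dummy-encoded against the
    reference level.  `level` is the hierarchy level the value varies at.
    """

    name: str
    kind: str
    level: str = "individual"
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5
    levels: list = field(default_factory=list)
    probs: list = field(default_factory=list)
    reference: str | None = None

    def validate(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ConfigError(f"unknown covariate kind '{self.kind}'")
        if self.level not in LEVELS:
            raise ConfigError(f"unknown covariate level '{self.level}'")
        if self.kind == "continuous" and self.sd < 0:
            raise ConfigError(f"covariate '{self.name}': sd must be >= 0")
        if self.kind == "binary" and not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"covariate '{self.name}': prevalence not in [0,1]")
        if self.kind == "categorical":
            if len(self.levels) < 2 or len(self.levels) != len(self.probs):
                raise ConfigError(f"covariate '{self.name}': levels/probs mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-12:
                raise ConfigError(f"covariate '{self.name}': probs must sum to 1")
            if any(p < 0 for p in self.probs):
                raise ConfigError(f"covariate '{self.name}': negative probability")
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise ConfigError(f"covariate '{self.name}': reference not a level")
            self.reference = ref

    @property
    def column_names(self) -> list:
        if self.kind == "categorical":
            return [f"{self.name}[{lv}]" for lv in self.levels if lv != self.reference]
        return [self.name]


@dataclass
class SimulationConfig:
    """Full generative specification for a synthetic three-outcome survey."""

    n_clusters: int
    households_per_cluster: int | list
    individuals_per_household: int | dict
    beta: list                                # 3 x (1+p), first entry intercept
    sigma_c: list                             # 3x3 cluster-level covariance
    sigma_h: list                             # 3x3 household-level covariance
    covariates: list = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.covariates = [
            c if isinstance(c, CovariateSpec) else CovariateSpec(**c)
            for c in self.covariates
        ]
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if int(self.n_clusters) < 1:
            raise DimensionError("n_clusters must be >= 1")
        hpc = self.households_per_cluster
        if isinstance(hpc, (list, tuple, np.ndarray)):
            if len(hpc) != self.n_clusters or any(int(h) < 1 for h in hpc):
                raise DimensionError("per-cluster household list invalid")
        elif int(hpc) < 1:
            raise DimensionError("households_per_cluster must be >= 1")
        iph = self.individuals_per_household
        if isinstance(iph, dict):
            if iph.get("sampler") != "poisson_plus_one" or iph.get("mean", -1) < 0:
                raise ConfigError(
                    "individuals_per_household sampler spec must be "
                    "{'sampler': 'poisson_plus_one', 'mean': m >= 0}"
                )
        elif int(iph) < 1:
            raise DimensionError("individuals_per_household must be >= 1")
        for spec in self.covariates:
            spec.validate()
        try:
            beta = np.asarray(self.beta, dtype=float)
        except ValueError as exc:
            raise ParameterizationError(f"beta is not rectangular: {exc}") from exc
        n_cols = 1 + sum(len(s.column_names) for s in self.covariates)
        if beta.shape != (3, n_cols):
            raise ParameterizationError(
                f"beta must be 3 x {n_cols} (intercept + encoded covariates); "
                f"got {beta.shape}"
            )
        check_psd(np.asarray(self.sigma_c, float), "sigma_c")
        check_psd(np.asarray(self.sigma_h, float), "sigma_h")
        if not 0.0 <= float(self.missing_rate) < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")

    # -- convenience ---------------------------------------------------
    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)

    @property
    def sigma_c_array(self) -> np.ndarray:
        return np.asarray(self.sigma_c, dtype=float)

    @property
    def sigma_h_array(self) -> np.ndarray:
        return np.asarray(self.sigma_h, dtype=float)

    @property
    def column_names(self) -> list:
        out = []
        for s in self.covariates:
            out.extend(s.column_names)
        return out

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)
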