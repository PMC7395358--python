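"""Nested survey dataset container and CSV ingestion.

A :class:`SurveyDataset` wraps a validated pandas DataFrame with columns
``cluster_id, household_id, person_id, y1, y2, y3`` followed by the encoded
covariate columns.  IDs are opaque string tokens; each household id belongs
to exactly one cluster; outcomes are 0, 1 or missing (NaN).  Records with
any missing outcome are kept in the container and excluded (listwise) at
tabulation and fit time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, NestingError, SchemaError, DimensionError

ID_COLUMNS = ["cluster_id", "household_id", "person_id"]
OUTCOME_COLUMNS = ["y1", "y2", "y3"]


class SurveyDataset:
    """Individual-level records nested in households nested in clusters."""

    def __init__(self, df: pd.DataFrame, covariate_names=None, encoding_map=None):
        df = df.copy()
        for col in ID_COLUMNS + OUTCOME_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"dataset is missing required column '{col}'")
        for col in ID_COLUMNS:
            df[col] = df[col].astype(str)
        if covariate_names is None:
            covariate_names = [
                c for c in df.columns if c not in ID_COLUMNS + OUTCOME_COLUMNS
            ]
        for col in covariate_names:
            if col not in df.columns:
                raise SchemaError(f"declared covariate '{col}' not in data")
            df[col] = pd.to_numeric(df[col], errors="raise")
        if len(df) == 0:
            raise DimensionError("dataset has no records")

        y = df[OUTCOME_COLUMNS].to_numpy(dtype=float)
        valid = np.isnan(y) | (y == 0.0) | (y == 1.0)
        if not valid.all():
            bad = df.loc[~valid.all(axis=1), OUTCOME_COLUMNS].iloc[0].to_dict()
            raise DomainError(f"outcome values outside {{0, 1, missing}}: {bad}")

        nest = df.groupby("household_id")["cluster_id"].nunique()
        offenders = nest[nest > 1]
        if len(offenders) > 0:
            raise NestingError(
                "household id(s) appear under more than one cluster: "
                + ", ".join(offenders.index[:5])
            )

        self.df = df[ID_COLUMNS + OUTCOME_COLUMNS + list(covariate_names)]
        self.covariate_names = list(covariate_names)
        self.encoding_map = dict(encoding_map or {})

    # -- basic properties ----------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_clusters(self) -> int:
        return self.df["cluster_id"].nunique()

    @property
    def n_households(self) -> int:
        return self.df["household_id"].nunique()

    @property
    def outcomes(self) -> np.ndarray:
        return self.df[OUTCOME_COLUMNS].to_numpy(dtype=float)

    def complete_mask(self) -> np.ndarray:
        return ~np.isnan(self.outcomes).any(axis=1)

    @property
    def n_complete(self) -> int:
        return int(self.complete_mask().sum())

    def complete_cases(self) -> "SurveyDataset":
        """Listwise deletion: drop records with any missing outcome."""
        kept = self.df[self.complete_mask()]
        if len(kept) == 0:
            raise DimensionError("no complete-outcome records remain")
        return SurveyDataset(kept, self.covariate_names, self.encoding_map)

    def design_matrix(self) -> np.ndarray:
        """Intercept-first design matrix over all records."""
        return np.column_stack(
            [np.ones(self.n_records)]
            + [self.df[c].to_numpy(dtype=float) for c in self.covariate_names]
        )

    @property
    def term_names(self) -> list:
        return ["Intercept"] + self.covariate_names

    # -- IO --------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SurveyDataset)
            and self.covariate_names == other.covariate_names
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def _load_schema(schema) -> dict:
    if isinstance(schema, dict):
        return schema
    with open(schema, encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise SchemaError(f"schema file {schema} did not parse to a mapping")
    return loaded


def read_survey_csv(path, schema) -> SurveyDataset:
    """Read a delimited survey file against a column-role schema.

    Schema keys: ``cluster``, ``household``, ``person`` (optional),
    ``outcomes`` (list of 3 column names), ``covariates`` (list of
    ``{name, kind, reference?}`` mappings; categorical entries must declare a
    reference level), and optional ``missing_values`` (tokens mapped to
    missing outcomes, e.g. "don't know").
    """
    schema = _load_schema(schema)
    for key in ("cluster", "household", "outcomes"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key '{key}'")
    if len(schema["outcomes"]) != 3:
        raise SchemaError("schema must name exactly 3 outcome columns")

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    cov_specs = schema.get("covariates", [])
    wanted = (
        [schema["cluster"], schema["household"]]
        + ([schema["person"]] if schema.get("person") else [])
        + list(schema["outcomes"])
        + [c["name"] for c in cov_specs]
    )
    missing_cols = [c for c in wanted if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"columns not found in {path}: {missing_cols}")

    missing_tokens = {str(t).strip().lower() for t in schema.get("missing_values", [])}
    missing_tokens |= {"", "na", "nan"}

    out = pd.DataFrame()
    out["cluster_id"] = raw[schema["cluster"]]
    out["household_id"] = raw[schema["household"]]
    if schema.get("person"):
        out["person_id"] = raw[schema["person"]]
    else:
        out["person_id"] = [f"r{i + 1}" for i in range(len(raw))]

    for i, col in enumerate(schema["outcomes"], start=1):
        vals = raw[col].astype(str).str.strip()
        is_missing = vals.str.lower().isin(missing_tokens)
        parsed = pd.to_numeric(vals.where(~is_missing), errors="coerce")
        bad = (~is_missing) & (parsed.isna() | ~parsed.isin([0.0, 1.0]))
        if bad.any():
            raise DomainError(
                f"outcome column '{col}' contains value "
                f"'{vals[bad].iloc[0]}' outside {{0, 1, missing}}"
            )
        out[f"y{i}"] = parsed

    covariate_names: list = []
    encoding_map: dict = {}
    for spec in cov_specs:
        name, kind = spec["name"], spec.get("kind", "continuous")
        vals = raw[name].astype(str).str.strip()
        if kind in ("continuous", "binary"):
            parsed = pd.to_numeric(vals, errors="coerce")
            if parsed.isna().any():
                raise DomainError(f"covariate '{name}' has non-numeric values")
            if kind == "binary" and not parsed.isin([0.0, 1.0]).all():
                raise DomainError(f"binary covariate '{name}' must be 0/1")
            out[name] = parsed
            covariate_names.append(name)
        elif kind == "categorical":
            if "reference" not in spec:
                raise SchemaError(
                    f"categorical covariate '{name}' must declare a reference level"
                )
            ref = str(spec["reference"])
            levels = sorted(vals.unique())
            if ref not in levels:
                raise SchemaError(
                    f"reference level '{ref}' of '{name}' not present in data"
                )
            cols = []
            for lv in levels:
                if lv == ref:
                    continue
                col = f"{name}[{lv}]"
                out[col] = (vals == lv).astype(float)
                covariate_names.append(col)
                cols.append(col)
            encoding_map[name] = {"reference": ref, "columns": cols}
        else:
            raise SchemaError(f"unknown covariate kind '{kind}' for '{name}'")

    return SurveyDataset(out, covariate_names, encoding_map)
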