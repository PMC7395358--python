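"""End-to-end orchestration: data -> tables -> fits -> LRT -> comparison.

A pipeline config (YAML/JSON mapping) names either a simulation spec or an
input CSV + schema, an output directory, and analysis settings:

    output_dir: out/
    quad_nodes: 3
    alpha: 0.05
    seed: 7                  # optional; overrides simulate.seed
    simulate: { ... SimulationConfig fields ... }
    # or
    input: {csv: data.csv, schema: schema.yaml}

Every artifact is serialized as it is produced, so a failing stage leaves
the earlier outputs on disk; the failure is re-raised as a
:class:`PipelineError` carrying the stage name.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import yaml

from . import __version__
from .compare import compare_fits
from .config import SimulationConfig
from .data import read_survey_csv
from .errors import ConfigError, JointlogitError, PipelineError
from .joint import fit_joint_pair, lrt_cross_covariances
from .separate import fit_separate, wald_table
from .simulate import simulate_survey
from .tabulate import tabulate_patterns


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config, encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigError(f"pipeline config {config} did not parse to a mapping")
    return loaded


def _validate_config(cfg: dict) -> dict:
    if "output_dir" not in cfg:
        raise ConfigError("pipeline config must name an output_dir")
    has_sim = "simulate" in cfg
    has_input = "input" in cfg
    if has_sim == has_input:
        raise ConfigError("config must name exactly one of 'simulate' or 'input'")
    if has_input:
        inp = cfg["input"]
        for key in ("csv", "schema"):
            if key not in inp:
                raise ConfigError(f"input section must name '{key}'")
            if not Path(inp[key]).exists():
                raise ConfigError(f"input {key} path does not exist: {inp[key]}")
    else:
        sim = dict(cfg["simulate"])
        if "seed" in cfg:
            sim["seed"] = int(cfg["seed"])
        cfg["simulate"] = SimulationConfig.from_dict(sim)  # validates
    cfg.setdefault("quad_nodes", 3)
    cfg.setdefault("alpha", 0.05)
    return cfg


def run_pipeline(config) -> dict:
    """Execute the full analysis; returns artifact paths and fitted objects."""
    cfg = _validate_config(_load_config(config))
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = int(cfg["quad_nodes"])
    alpha = float(cfg["alpha"])
    log_lines = [
        f"jointlogit {__version__}",
        f"quad_nodes={nodes} alpha={alpha}",
    ]
    artifacts: dict = {}
    t0 = time.time()

    def _log_flush():
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n", "utf-8")

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except JointlogitError:
                log_lines.append(f"FAILED at stage: {name}")
                _log_flush()
                raise
            except Exception as exc:  # noqa: BLE001
                log_lines.append(f"FAILED at stage: {name} ({exc})")
                _log_flush()
                raise PipelineError(name, str(exc)) from exc
        return wrap

    # 1. data
    def _data():
        if "simulate" in cfg:
            sim_cfg = cfg["simulate"]
            dataset, draws = simulate_survey(sim_cfg)
            dataset.to_csv(outdir / "dataset.csv")
            draws.to_frame().to_csv(outdir / "random_effects.csv", index=False)
            artifacts["dataset"] = str(outdir / "dataset.csv")
            artifacts["random_effects"] = str(outdir / "random_effects.csv")
            log_lines.append(f"simulated dataset: seed={sim_cfg.seed}")
            return dataset
        ds = read_survey_csv(cfg["input"]["csv"], cfg["input"]["schema"])
        log_lines.append(f"read dataset: {cfg['input']['csv']}")
        return ds

    dataset = stage("data")(_data)
    n_excl = dataset.n_records - dataset.n_complete
    log_lines.append(
        f"records={dataset.n_records} clusters={dataset.n_clusters} "
        f"households={dataset.n_households} "
        f"excluded_incomplete={n_excl} analysed={dataset.n_complete}"
    )

    # 2. pattern table
    def _patterns():
        table = tabulate_patterns(dataset)
        table.to_csv(outdir / "pattern_table.csv")
        artifacts["pattern_table"] = str(outdir / "pattern_table.csv")
        return table

    pattern_table = stage("pattern_table")(_patterns)

    # 3. separate fits + ICCs
    def _separate():
        fits = []
        payload = []
        for q in (1, 2, 3):
            fit = fit_separate(dataset, q, quad_nodes=nodes)
            icc = fit.icc()
            d = fit.to_dict()
            d["icc_cluster"] = icc.icc_cluster
            d["icc_household_cumulative"] = icc.icc_household_cumulative
            d["wald_table"] = wald_table(fit).to_dict(orient="records")
            payload.append(d)
            fits.append(fit)
            log_lines.append(
                f"separate outcome {q}: loglik={fit.loglik:.6f} "
                f"var_c={fit.var_cluster:.4f} var_h={fit.var_household:.4f} "
                f"converged={fit.converged}"
            )
        with open(outdir / "separate_fits.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        artifacts["separate_fits"] = str(outdir / "separate_fits.json")
        return fits

    separate_fits = stage("separate_fits")(_separate)

    # 4. joint fits (restricted first; full warm-started) + LRT
    def _joint():
        full, restricted = fit_joint_pair(dataset, quad_nodes=nodes)
        full.to_json(outdir / "joint_full.json")
        restricted.to_json(outdir / "joint_restricted.json")
        full.covariance.to_csv(outdir / "joint_covariance.csv")
        artifacts["joint_full"] = str(outdir / "joint_full.json")
        artifacts["joint_restricted"] = str(outdir / "joint_restricted.json")
        artifacts["joint_covariance"] = str(outdir / "joint_covariance.csv")
        log_lines.append(
            f"joint restricted: loglik={restricted.loglik:.6f} "
            f"converged={restricted.converged}"
        )
        log_lines.append(
            f"joint full: loglik={full.loglik:.6f} converged={full.converged}"
        )
        return full, restricted

    joint_full, joint_restricted = stage("joint_fits")(_joint)

    def _lrt():
        res = lrt_cross_covariances(joint_full, joint_restricted, alpha=alpha)
        res.to_json(outdir / "lrt.json")
        artifacts["lrt"] = str(outdir / "lrt.json")
        log_lines.append(
            f"LRT: stat={res.statistic:.4f} df={res.df} p={res.p_value:.4g} "
            f"-> {res.decision_note}"
        )
        return res

    lrt = stage("lrt")(_lrt)

    # 5. comparison table
    def _compare():
        table = compare_fits(separate_fits, joint_full, alpha=alpha)
        table.to_csv(outdir / "comparison.csv")
        artifacts["comparison"] = str(outdir / "comparison.csv")
        log_lines.append(f"comparison: {len(table.flagged)} discordant term(s)")
        return table

    comparison = stage("comparison")(_compare)

    log_lines.append(f"elapsed_seconds={time.time() - t0:.2f}")
    _log_flush()
    artifacts["run_log"] = str(outdir / "run_log.txt")

    return {
        "artifacts": artifacts,
        "dataset": dataset,
        "pattern_table": pattern_table,
        "separate_fits": separate_fits,
        "joint_full": joint_full,
        "joint_restricted": joint_restricted,
        "lrt": lrt,
        "comparison": comparison,
    }
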