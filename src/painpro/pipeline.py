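"""End-to-end orchestration: simulate -> filter -> score -> fit -> report.

One YAML config drives every stage; all randomness derives from a single
top-level seed.  Each run writes its artifacts plus a manifest recording
the config hash, seeds, file list, package/table versions and the
conservation-of-records exclusion counts.  Stage logs go to a JSON-lines
file so record counts can be audited mechanically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, beta_model, describe, logit_model, morphine, registry, scores, simulate
from .errors import ConfigError
from .model_base import ModelSpec

_KNOWN_KEYS = {"seed", "simulate", "input", "conversion_table", "item_schema",
               "fit_pcs", "fit_opioid_use", "report", "n"}


def validate_config(config: dict) -> None:
    """Collect every config problem at once and raise a single error."""
    problems = []
    for key in config:
        if key not in _KNOWN_KEYS:
            problems.append(f"unknown config key {key!r}")
    if "seed" in config and not isinstance(config["seed"], int):
        problems.append("seed must be an integer")
    has_sim = isinstance(config.get("simulate"), dict)
    has_input = isinstance(config.get("input"), dict)
    if not has_sim and not has_input:
        problems.append("config needs a 'simulate' or an 'input' section")
    if has_input:
        for k in ("registry",):
            if k not in config["input"]:
                problems.append(f"input section missing {k!r}")
    ct = config.get("conversion_table")
    if ct is not None and not Path(ct).exists():
        problems.append(f"conversion table not found: {ct}")
    if problems:
        raise ConfigError(problems)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.events = []

    def log(self, stage: str, **counts):
        evt = {"stage": stage, **counts}
        self.events.append(evt)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(evt) + "\n")


def run_pipeline(config: dict, outdir) -> dict:
    """Run all stages and return the manifest (also written to disk).

    Any stage failure propagates with the stage name prefixed, after
    partial outputs already written are listed in the log.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stage_log = _StageLog(outdir / "run.log.jsonl")
    outputs: list[str] = []
    manifest: dict = {
        "painpro_version": __version__,
        "config_hash": _hash(config),
        "seed": seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def _save(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False, na_rep="")
        outputs.append(name)
        return path

    stage = "simulate"
    try:
        if "simulate" in config:
            sim_cfg = dict(config["simulate"])
            n = int(sim_cfg.pop("n", 4328))
            cfg = simulate.default_paperlike_config(n=n, seed=seed)
            for k, v in sim_cfg.items():
                if not hasattr(cfg, k):
                    raise ConfigError([f"unknown simulate override {k!r}"])
                setattr(cfg, k, v)
            records, admin, truth = simulate.generate(cfg)
            _save(records, "registry.csv")
            _save(admin, "administrations.csv")
            truth.to_json(outdir / "truth.json")
            outputs.append("truth.json")
            stage_log.log(stage, n_records=len(records), n_administrations=len(admin))
        else:
            paths = config["input"]
            records, admin, report = registry.read_registry(
                paths["registry"], paths.get("administrations"))
            stage = "read"
            stage_log.log(stage, **{k: v for k, v in report.items()
                                    if not isinstance(v, dict)})

        stage = "filter"
        records, admin, excl = registry.plausibility_filter(records, admin)
        records["subgroup"] = registry.allocate_subgroup(records)
        is_excluded = records["subgroup"].isin(registry.EXCLUSION_TOKENS)
        subgroup_excl = records.loc[is_excluded, "subgroup"].value_counts().to_dict()
        records = records[~is_excluded].copy()
        excl["excluded"].update({k: int(v) for k, v in subgroup_excl.items()})
        excl["records_kept"] = len(records)
        with open(outdir / "exclusions.json", "w") as fh:
            json.dump(excl, fh, indent=2)
        outputs.append("exclusions.json")
        _save(records, "filtered.csv")
        stage_log.log(stage, **{"kept": len(records), **excl["excluded"]})
        manifest["exclusions"] = excl

        stage = "score"
        records = scores.score_registry(records)
        table = morphine.DEFAULT_TABLE if not config.get("conversion_table") \
            else morphine.ConversionTable.from_yaml(config["conversion_table"])
        records["opioid_use"] = morphine.opioid_use_flag(records, admin).to_numpy()
        records["me_24h"] = morphine.me_24h(
            admin, records["patient_id"], table).to_numpy()
        _save(records, "scored.csv")
        stage_log.log(stage, n_records=len(records), n_scored=int(records["pcs"].notna().sum()))
        manifest["conversion_table_version"] = table.version

        stage = "fit_pcs"
        pcs_cfg = config.get("fit_pcs", {}) or {}
        fit = beta_model.fit_beta(records, ModelSpec(),
                                  income_mode=pcs_cfg.get("income_mode", "fixed"))
        mm = beta_model.emmeans(fit)
        contrasts = beta_model.pairwise_contrasts(mm, adjust=pcs_cfg.get("adjust", "tukey"))
        _save(mm.table, "pcs_emm.csv")
        _save(contrasts, "pcs_contrasts.csv")
        coef = {"coefficients": fit.params.to_dict(), "phi": fit.phi,
                "n_used": fit.n_used, "method": fit.method}
        with open(outdir / "pcs_model.json", "w") as fh:
            json.dump(coef, fh, indent=2)
        outputs.append("pcs_model.json")
        if pcs_cfg.get("oands_split", True):
            fit_int = beta_model.fit_beta(
                records, ModelSpec().with_interaction("subgroup", "oands_flag"))
            mm12, con12 = beta_model.emmeans_by_oands(fit_int)
            _save(mm12.table, "pcs_emm_by_oands.csv")
            _save(con12, "pcs_contrasts_by_oands.csv")
        stage_log.log(stage, n_used=fit.n_used, n_emm=len(mm.table),
                      n_contrasts=len(contrasts))

        stage = "fit_opioid_use"
        ou_cfg = config.get("fit_opioid_use", {}) or {}
        lfit = logit_model.fit_logistic(records,
                                        reference=ou_cfg.get("reference", "GA-o"))
        ors = logit_model.odds_ratios(lfit)
        rd = logit_model.risk_difference_contrasts(
            lfit, B=int(ou_cfg.get("bootstrap_B", 1000)), seed=seed,
            ci=ou_cfg.get("ci", "bootstrap"))
        _save(ors, "opioid_use_or.csv")
        _save(rd, "opioid_use_contrasts.csv")
        stage_log.log(stage, n_used=lfit.n_used, method=lfit.method)

        stage = "report"
        desc_vars = {"age": "continuous", "weight": "continuous", "sex": "categorical",
                     "oands_flag": "categorical", "pcs": "continuous",
                     "pits": "continuous", "eis": "continuous", "aes": "continuous",
                     "pro_score": "continuous", "opioid_use": "categorical"}
        desc_vars = {k: v for k, v in desc_vars.items() if k in records.columns}
        summary = describe.summarize(records, desc_vars, "subgroup")
        _save(summary, "summary.csv")
        (outdir / "summary.md").write_text(
            describe.summary_markdown(summary, "Cohort summary by anesthesia subgroup"))
        outputs.append("summary.md")
        stage_log.log(stage, n_rows=len(summary))
    except ConfigError:
        raise
    except Exception as err:
        raise type(err)(f"[stage {stage}] {err}") from err

    manifest["outputs"] = outputs
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    stable = {k: manifest[k] for k in
              ("painpro_version", "config_hash", "seed", "outputs",
               "conversion_table_version", "exclusions") if k in manifest}
    manifest["manifest_hash"] = _hash(stable)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(["config must be a YAML mapping"])
    return cfg
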