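"""End-to-end runner: simulate → classify → aggregate → environment → match → estimate.

Every inter-stage artifact is a headered CSV (results and balance
reports are JSON); a run manifest records the configuration snapshot,
per-stage input/output digests and record counts, so a run can be
audited and reproduced. Zip codes are 5-character strings throughout
(leading zeros preserved); fractions live on [0, 1] in files and only
become percents at presentation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import RuleSet, classify_entries
from .cohort import (
    attach_participants,
    filter_participants,
    participant_rates,
    zip_outcomes,
)
from .config import PipelineConfig
from .environment import build_zip_covariates
from .inference import ExperimentSpec, null_experiment, run_experiment
from .synthetic import SimConfig, gen_food_logs, gen_geography, gen_null_covariate, gen_zip_table

__all__ = ["RunManifest", "StageRecord", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class StageRecord:
    name: str
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)
    records_in: int | None = None
    records_out: int | None = None
    seconds: float = 0.0
    status: str = "ok"


@dataclass
class RunManifest:
    config: dict
    version: str
    started: str
    stages: list[StageRecord] = field(default_factory=list)
    finished: str | None = None

    def write(self, path: Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_csv(path: Path, stage: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing input file {path}")
    df = pd.read_csv(path)
    if "zip" in df.columns:
        df["zip"] = df["zip"].astype(str).str.zfill(5)
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_all(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the full pipeline, fail-fast, and write a manifest.

    With a ``simulate`` block in the configuration all inputs are
    generated first; otherwise ``config.inputs`` must point at existing
    files. Writes, per stage, the CSV/JSON artifacts into *outdir* and
    finally ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def stage(name):
        rec = StageRecord(name=name)
        manifest.stages.append(rec)
        return rec

    paths: dict[str, Path] = {k: Path(v) for k, v in config.inputs.items()}
    truth = None

    def need(key: str, stage_name: str) -> Path:
        if key not in paths:
            raise FileNotFoundError(
                f"stage {stage_name!r}: no input path configured for {key!r} "
                "(provide config.inputs or a simulate block)"
            )
        return paths[key]

    try:
        # ------------------------------------------------------ simulate
        if config.simulate is not None:
            rec = stage("simulate")
            t0 = time.time()
            sim = SimConfig(**{**config.simulate, "seed": config.seed})
            covariates, sim_outcomes, truth = gen_zip_table(sim)
            entries, participants = gen_food_logs(sim_outcomes, sim)
            tracts, xwalk, businesses, centroids = gen_geography(covariates, sim)
            demo_cols = [
                "zip", "income", "college_frac", "frac_white", "frac_black",
                "frac_hispanic", "ruca", "population",
            ]
            written = {
                "logs": entries,
                "participants": participants,
                "tracts": tracts,
                "crosswalk": xwalk,
                "businesses": businesses,
                "centroids": centroids,
                "demographics": covariates[demo_cols],
            }
            for key, df in written.items():
                paths[key] = outdir / f"{key}.csv"
                _write_csv(df, paths[key])
                rec.outputs[str(paths[key])] = _digest(paths[key])
            (outdir / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "effects": truth.effects,
                        "subgroup_effects": {
                            f"{g}:{f}": v for (g, f), v in truth.subgroup_effects.items()
                        },
                    },
                    indent=2,
                )
            )
            rec.records_out = len(entries)
            rec.seconds = time.time() - t0

        # ------------------------------------------------------ classify
        rec = stage("classify")
        t0 = time.time()
        rules = (
            RuleSet.from_dir(config.rules_dir) if config.rules_dir else RuleSet.default()
        )
        logs = _read_csv(need("logs", "classify"), "classify")
        rec.inputs[str(paths["logs"])] = _digest(paths["logs"])
        labels = classify_entries(logs, rules)
        labels_path = outdir / "labels.csv"
        _write_csv(labels, labels_path)
        rec.outputs[str(labels_path)] = _digest(labels_path)
        rec.records_in = len(logs)
        rec.records_out = len(labels)
        rec.seconds = time.time() - t0

        # ------------------------------------------------------ aggregate
        rec = stage("aggregate")
        t0 = time.time()
        participants = _read_csv(need("participants", "aggregate"), "aggregate")
        summaries = attach_participants(participant_rates(labels), participants)
        summaries = filter_participants(summaries, config.min_days)
        outcomes = zip_outcomes(summaries, config.min_participants)
        out_path = outdir / "zip_outcomes.csv"
        _write_csv(outcomes, out_path)
        rec.outputs[str(out_path)] = _digest(out_path)
        rec.records_in = len(labels)
        rec.records_out = len(outcomes)
        rec.seconds = time.time() - t0

        # ------------------------------------------------------ environment
        rec = stage("environment")
        t0 = time.time()
        tracts = _read_csv(need("tracts", "environment"), "environment")
        xwalk = _read_csv(need("crosswalk", "environment"), "environment")
        businesses = _read_csv(need("businesses", "environment"), "environment")
        centroids = _read_csv(need("centroids", "environment"), "environment")
        demographics = _read_csv(need("demographics", "environment"), "environment")
        for key in ("tracts", "crosswalk", "businesses", "centroids", "demographics"):
            rec.inputs[str(paths[key])] = _digest(paths[key])
        businesses["is_restaurant"] = businesses["is_restaurant"].astype(str).isin(["True", "1", "true"])
        businesses["is_fastfood_chain"] = businesses["is_fastfood_chain"].astype(str).isin(["True", "1", "true"])
        for col in ("population", "beyond_half_mile_frac", "food_desert"):
            tracts[col] = pd.to_numeric(tracts[col])
        for df, cols in (
            (businesses, ("latitude", "longitude")),
            (centroids, ("latitude", "longitude")),
        ):
            for col in cols:
                df[col] = pd.to_numeric(df[col])
        for col in demographics.columns:
            if col != "zip":
                demographics[col] = pd.to_numeric(demographics[col])
        covariates = build_zip_covariates(tracts, xwalk, businesses, centroids, demographics)
        cov_path = outdir / "zip_covariates.csv"
        _write_csv(covariates, cov_path)
        rec.outputs[str(cov_path)] = _digest(cov_path)
        rec.records_out = len(covariates)
        rec.seconds = time.time() - t0

        # ------------------------------------------------------ estimate
        rec = stage("estimate")
        t0 = time.time()
        cov_idx = covariates.set_index("zip")
        out_idx = outcomes.set_index("zip")
        all_results = []
        for subgroup in config.subgroups:
            for factor in config.factors:
                spec = ExperimentSpec(
                    factor=factor,
                    subgroup=subgroup,
                    split=config.split,
                    bootstrap_reps=config.bootstrap_reps,
                    balance_threshold=config.balance_threshold,
                    seed=config.seed,
                )
                res = run_experiment(spec, cov_idx, out_idx)
                for r in res.results:
                    all_results.append(
                        {
                            "factor": factor,
                            "subgroup": subgroup,
                            "outcome": r.outcome,
                            "relative_diff_pct": r.relative_diff_pct,
                            "ci_low_pct": r.ci_low_pct,
                            "ci_high_pct": r.ci_high_pct,
                            "p_value": r.p_value,
                            "t_test_p": r.t_test_p,
                            "n_pairs": r.n_pairs,
                            "dropped_treated": len(res.pairs.dropped_treated),
                            "max_abs_smd": res.balance.max_abs_smd,
                            "mean_smd": res.balance.mean_smd,
                            "caliper_used": res.pairs.caliper_used,
                        }
                    )
        results_path = outdir / "results.json"
        results_path.write_text(json.dumps(all_results, indent=2))
        rec.outputs[str(results_path)] = _digest(results_path)
        rec.records_out = len(all_results)
        rec.seconds = time.time() - t0

        # ------------------------------------------------------ null check
        if config.run_null_check:
            rec = stage("null_check")
            t0 = time.time()
            null_vals = gen_null_covariate(covariates, seed=config.seed)
            spec = ExperimentSpec(
                factor="null_service_frac",
                bootstrap_reps=config.bootstrap_reps,
                balance_threshold=config.balance_threshold,
                seed=config.seed,
            )
            res, corrs = null_experiment(null_vals, spec, cov_idx, out_idx)
            payload = {
                "correlations_with_factors": corrs,
                "results": [
                    {
                        "outcome": r.outcome,
                        "relative_diff_pct": r.relative_diff_pct,
                        "ci_low_pct": r.ci_low_pct,
                        "ci_high_pct": r.ci_high_pct,
                        "p_value": r.p_value,
                        "covers_zero": r.ci_low_pct <= 0.0 <= r.ci_high_pct,
                    }
                    for r in res.results
                ],
            }
            null_path = outdir / "null_results.json"
            null_path.write_text(json.dumps(payload, indent=2))
            rec.outputs[str(null_path)] = _digest(null_path)
            rec.seconds = time.time() - t0
    except Exception:
        manifest.stages[-1].status = "failed"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(outdir / "manifest.json")
        raise

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
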