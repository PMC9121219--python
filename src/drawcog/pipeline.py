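"""End-to-end orchestration of the cross-cohort drawing analysis.

One config object drives the whole workflow: simulate two cohorts,
extract the six drawing features, run the covariate-adjusted correlation
tables (combined and per cohort, BH-corrected), train the tuned forest
on cohort A, test on cohort B, run the permutation test and Shapley
importance.  Every number in the resulting report is recomputable from
the config and its seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .features import FEATURE_NAMES, extract_features
from .model import (AttributionMatrix, DrawingForestRegressor, EvaluationResult,
                    HyperparameterGrid, PermutationTestResult, evaluate,
                    permutation_test, shapley_importance)
from .simulate import CohortConfig, EffectConfig, iter_cohort
from .stream import DeviceProfile
from .stats import cohort_compare, feature_moca_table

log = logging.getLogger("drawcog")


def _default_seeds() -> dict[str, int]:
    return {"generation_a": 101, "generation_b": 202,
            "folds": 303, "permutation": 404, "shap": 505}


@dataclass
class RunConfig:
    """Single source of truth for a full analysis run."""

    device: DeviceProfile = field(default_factory=DeviceProfile)
    cohort_a: CohortConfig = field(default_factory=CohortConfig.us_like)
    cohort_b: CohortConfig = field(default_factory=CohortConfig.japan_like)
    effect: EffectConfig = field(default_factory=EffectConfig)
    grid: HyperparameterGrid = field(default_factory=HyperparameterGrid)
    cv_folds: int = 10
    n_permutations: int = 1000
    shap_background: int = 50
    seeds: dict[str, int] = field(default_factory=_default_seeds)

    def __post_init__(self) -> None:
        missing = set(_default_seeds()) - set(self.seeds)
        if missing:
            raise ValueError(f"missing seeds: {sorted(missing)}")
        if self.cohort_a.name == self.cohort_b.name:
            raise ValueError("cohorts must have distinct names")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["cohort_a"]["moca_range"] = list(self.cohort_a.moca_range)
        out["cohort_b"]["moca_range"] = list(self.cohort_b.moca_range)
        for key in ("max_depth", "max_features", "max_samples", "min_samples_leaf"):
            out["grid"][key] = list(out["grid"][key])
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw: dict = {}
        if "device" in raw:
            kw["device"] = DeviceProfile(**raw["device"])
        for key in ("cohort_a", "cohort_b"):
            if key in raw:
                spec = dict(raw[key])
                if "moca_range" in spec:
                    spec["moca_range"] = tuple(spec["moca_range"])
                kw[key] = CohortConfig(**spec)
        if "effect" in raw:
            kw["effect"] = EffectConfig(**raw["effect"])
        if "grid" in raw:
            spec = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                    for k, v in raw["grid"].items()}
            kw["grid"] = HyperparameterGrid(**spec)
        for key in ("cv_folds", "n_permutations", "shap_background", "seeds"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class CrossCohortResult:
    """Tuned model, held-out metrics, permutation p and feature importances."""

    best_params: dict
    metrics: EvaluationResult
    permutation: PermutationTestResult
    importances: pd.DataFrame
    attributions: AttributionMatrix
    model: DrawingForestRegressor


@dataclass
class RunReport:
    records: pd.DataFrame
    demographics: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    cross_cohort: CrossCohortResult
    provenance: dict

    def summary_dict(self) -> dict:
        cc = self.cross_cohort
        return {
            "provenance": self.provenance,
            "demographics": self.demographics.to_dict(orient="records"),
            "correlations": {k: v.to_dict(orient="records")
                             for k, v in self.correlations.items()},
            "cross_cohort": {
                "best_params": cc.best_params,
                **cc.metrics.as_dict(),
                "permutation_p": cc.permutation.p_value,
                "n_permutations": cc.permutation.n_permutations,
                "importances": cc.importances.to_dict(orient="records"),
            },
        }


def simulate_records(config: RunConfig) -> pd.DataFrame:
    """Simulate both cohorts and extract features (streaming, one row each)."""
    rows = []
    for cohort, seed_key in ((config.cohort_a, "generation_a"),
                             (config.cohort_b, "generation_b")):
        t0 = time.perf_counter()
        for stream, meta in iter_cohort(cohort, config.effect, config.device,
                                        config.seeds[seed_key]):
            meta.update(extract_features(stream).as_dict())
            rows.append(meta)
        log.info("simulated cohort %s (n=%d) in %.1fs", cohort.name,
                 cohort.n_participants, time.perf_counter() - t0)
    return pd.DataFrame(rows)


def run_full(config: RunConfig) -> RunReport:
    """Run the complete workflow; deterministic given the config."""
    stage = "simulate/extract"
    try:
        records = simulate_records(config)

        stage = "demographics"
        demographics = cohort_compare(records)

        stage = "correlate"
        correlations = {"all": feature_moca_table(records, "all")}
        for cohort in (config.cohort_a, config.cohort_b):
            correlations[cohort.name] = feature_moca_table(records, cohort.name)

        stage = "train/test"
        a = records[records["cohort"] == config.cohort_a.name]
        b = records[records["cohort"] == config.cohort_b.name]
        X_train = a[list(FEATURE_NAMES)].to_numpy(float)
        y_train = a["moca"].to_numpy(float)
        X_test = b[list(FEATURE_NAMES)].to_numpy(float)
        y_test = b["moca"].to_numpy(float)
        t0 = time.perf_counter()
        model = DrawingForestRegressor(grid=config.grid, cv=config.cv_folds,
                                       random_state=config.seeds["folds"])
        model.fit(X_train, y_train)
        log.info("tuned %d candidates in %.1fs; best=%s",
                 len(model.cv_results_), time.perf_counter() - t0,
                 model.best_params_)
        metrics = evaluate(model, X_test, y_test)
        log.info("held-out metrics: %s", metrics)

        stage = "permutation"
        t0 = time.perf_counter()
        perm = permutation_test(model, X_train, y_train, X_test, y_test,
                                n_permutations=config.n_permutations,
                                seed=config.seeds["permutation"])
        log.info("permutation test (B=%d) in %.1fs: p=%.4g",
                 config.n_permutations, time.perf_counter() - t0, perm.p_value)

        stage = "importance"
        attr, importances = shapley_importance(
            model, X_test, feature_names=FEATURE_NAMES,
            max_background=config.shap_background, seed=config.seeds["shap"])
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    provenance = {"config_hash": config.config_hash(),
                  "seeds": dict(config.seeds),
                  "software_version": __version__}
    cross = CrossCohortResult(best_params=model.best_params_, metrics=metrics,
                              permutation=perm, importances=importances,
                              attributions=attr, model=model)
    return RunReport(records=records, demographics=demographics,
                     correlations=correlations, cross_cohort=cross,
                     provenance=provenance)


def save_report(report: RunReport, outdir: str | Path) -> None:
    """Write the report JSON and the CSV side tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2)
    meta_cols = ["participant_id", "cohort", "age", "sex", "education_years", "moca"]
    report.records[meta_cols].to_csv(out / "metadata.csv", index=False)
    report.records[["participant_id", *FEATURE_NAMES]].to_csv(
        out / "features.csv", index=False)
    for name, table in report.correlations.items():
        table.to_csv(out / f"correlations_{name}.csv", index=False)
    cc = report.cross_cohort
    cc.importances.to_csv(out / "importances.csv", index=False)
    pd.DataFrame({"null_statistic": cc.permutation.null_statistics}).to_csv(
        out / "permutation_trace.csv", index=False)
    pd.DataFrame(cc.attributions.values,
                 columns=list(cc.attributions.feature_names)).to_csv(
        out / "attributions.csv", index=False)
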