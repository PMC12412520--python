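"""End-to-end orchestration: simulate -> segment -> features -> viability ->
rank -> classify -> IC50.

`run_pipeline` executes the enabled stages in order on a synthetic assay (or
one loaded from disk), keeps every intermediate artifact in the returned
result object, and — when an output directory is given — writes the
artifacts with a manifest recording seeds and content hashes so a re-run
with unchanged inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ClassifierReport,
    ClassifierSpec,
    SpheroidClassifier,
    cross_validate_by_experiment,
)
from .doseresponse import DoseResponseFit, fit_binary_bayes, fit_continuous
from .errors import PipelineError
from .features import FeatureTable, assemble_feature_frame, build_feature_table
from .select import RankedFeatures, rank_and_select
from .simgen import SimConfig, simulate_assay, write_assay
from .viability import label_readouts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "timeshift_predict"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    scheme: str = "two_class"
    k_features: int = 15
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    n_walkers: int = 32
    n_steps: int = 500
    n_burn: int = 500
    do_classify: bool = True
    do_ic50: bool = True
    out_dir: str | None = None
    seed: int = 0


def _stage_seeds(seed: int) -> dict[str, int]:
    """Fan a single global seed out to independent per-stage seeds."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("sim", "mi", "classifier", "mcmc")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    config: RunConfig
    seeds: dict[str, int]
    truth: pd.DataFrame
    readouts: pd.DataFrame
    features: pd.DataFrame
    labels: pd.DataFrame
    table: FeatureTable | None = None
    ranking: RankedFeatures | None = None
    report: ClassifierReport | None = None
    predictions: pd.DataFrame | None = None
    fits: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    manifest: dict | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the enabled pipeline stages and return all artifacts.

    Stage failures raise :class:`PipelineError` naming the failing stage;
    artifacts produced before the failure stay on disk when writing.
    """
    seeds = _stage_seeds(config.seed)
    sim = dataclasses.replace(config.sim, seed=seeds["sim"])

    def _run(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    observations, readouts, truth = _run("simulate", lambda: simulate_assay(sim))
    features = _run("features", lambda: assemble_feature_frame(observations))
    labels = _run("viability", lambda: label_readouts(readouts, scheme=config.scheme))
    label_col = "class2" if config.scheme == "two_class" else "class3"

    result = PipelineResult(
        config=config,
        seeds=seeds,
        truth=truth,
        readouts=readouts,
        features=features,
        labels=labels,
    )
    result.counts = {
        "n_spheroids_simulated": int(truth.shape[0]),
        "n_spheroids_with_features": int(features.shape[0]),
        "n_unusable": int(truth.shape[0] - features.shape[0]),
    }

    table = _run(
        "feature_table",
        lambda: build_feature_table(features, labels, label_column=label_col),
    )
    result.counts["n_rows_after_exclusion"] = int(table.data.shape[0])

    ranking = _run(
        "select",
        lambda: rank_and_select(
            table.data, table.y, k=config.k_features,
            feature_columns=table.feature_columns, rng=seeds["mi"],
        ),
    )
    result.ranking = ranking
    selected_table = FeatureTable(table.data, ranking.selected)
    result.table = selected_table

    if config.do_classify:
        spec = dataclasses.replace(config.classifier, seed=seeds["classifier"])
        report = _run(
            "classify", lambda: cross_validate_by_experiment(selected_table, spec)
        )
        result.report = report
        preds = report.predictions_frame().merge(
            table.data[["spheroid_id", "experiment_id", "concentration_um"]],
            on="spheroid_id",
        )
        result.predictions = preds

        if config.do_ic50:
            fits: dict = {"binary_by_experiment": {}, "continuous_by_experiment": {}}
            fits["binary_pooled"] = _run(
                "ic50",
                lambda: fit_binary_bayes(
                    preds["y_pred"].to_numpy(),
                    preds["concentration_um"].to_numpy(),
                    n_walkers=config.n_walkers,
                    n_steps=config.n_steps,
                    n_burn=config.n_burn,
                    seed=seeds["mcmc"],
                ),
            )
            act = labels.merge(
                table.data[["spheroid_id", "concentration_um"]], on="spheroid_id"
            )
            fits["continuous_pooled"] = _run(
                "ic50",
                lambda: fit_continuous(
                    act["metabolic_activity_pct"].to_numpy(),
                    act["concentration_um"].to_numpy(),
                ),
            )
            for i, (exp, grp) in enumerate(preds.groupby("experiment_id", sort=True)):
                if grp["y_pred"].nunique() < 2:
                    logger.warning("experiment %s: single predicted class; no fit", exp)
                    continue
                fits["binary_by_experiment"][exp] = fit_binary_bayes(
                    grp["y_pred"].to_numpy(),
                    grp["concentration_um"].to_numpy(),
                    n_walkers=config.n_walkers,
                    n_steps=config.n_steps,
                    n_burn=config.n_burn,
                    seed=(seeds["mcmc"] + i + 1) % (2**31),
                )
            for exp, grp in act.groupby("experiment_id", sort=True):
                try:
                    fits["continuous_by_experiment"][exp] = fit_continuous(
                        grp["metabolic_activity_pct"].to_numpy(),
                        grp["concentration_um"].to_numpy(),
                    )
                except ValueError:
                    continue
            result.fits = fits

    if config.out_dir is not None:
        result.manifest = _write_outputs(result, observations, Path(config.out_dir))
    return result


def _fit_to_json(fit: DoseResponseFit) -> dict:
    return fit.summary()


def _write_outputs(result: PipelineResult, observations, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    write_assay(observations, result.readouts, result.truth, out / "assay",
                config=result.config.sim)
    result.features.to_csv(out / "features.csv", index=False)
    result.labels.to_csv(out / "viability.csv", index=False)
    if result.ranking is not None:
        result.ranking.to_frame().to_csv(out / "ranking.csv", index=False)
    if result.predictions is not None:
        result.predictions.to_csv(out / "predictions.csv", index=False)
    report_json: dict = {"counts": result.counts, "seeds": result.seeds}
    if result.report is not None:
        report_json["cv_aggregate"] = result.report.aggregate
        report_json["cv_folds"] = [
            {"test_group": f.test_group, "metrics": f.metrics} for f in result.report.folds
        ]
    if result.fits:
        report_json["fits"] = {
            "binary_pooled": _fit_to_json(result.fits["binary_pooled"]),
            "continuous_pooled": _fit_to_json(result.fits["continuous_pooled"]),
            "binary_by_experiment": {
                k: _fit_to_json(v) for k, v in result.fits["binary_by_experiment"].items()
            },
            "continuous_by_experiment": {
                k: _fit_to_json(v)
                for k, v in result.fits["continuous_by_experiment"].items()
            },
        }
    (out / "report.json").write_text(json.dumps(report_json, indent=2, sort_keys=True))

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "seed": result.config.seed,
        "stage_seeds": result.seeds,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def timeshift_predict(
    table: FeatureTable,
    spec: ClassifierSpec,
    sampler_seed: int = 0,
    n_walkers: int = 32,
    n_steps: int = 500,
    n_burn: int = 500,
) -> dict:
    """Train on 48 h features, predict viability from the 24 h features.

    Each 48 h descriptor column is mapped onto its 24 h counterpart by name
    (same descriptor, earlier timepoint); missing 24 h columns raise an
    error naming them.  Returns the predictions, the binary-Bayes fit of the
    24 h predictions, and a note flagging that no ground truth exists at
    this timepoint.
    """
    cols48 = [c for c in table.feature_columns if c.endswith("_48h")]
    if not cols48:
        raise ValueError("table has no 48 h feature columns")
    mapped = {c: c.replace("_48h", "_24h") for c in cols48}
    missing = [m for m in mapped.values() if m not in table.data.columns]
    if missing:
        raise ValueError(f"24 h features missing: {missing}")

    clf = SpheroidClassifier(spec, cols48)
    clf.fit(table.data[cols48].to_numpy(dtype=float), table.y)
    X24 = table.data[[mapped[c] for c in cols48]].to_numpy(dtype=float)
    preds = clf.predict(X24)
    conc = table.data["concentration_um"].to_numpy(dtype=float)
    fit = None
    if np.unique(preds).size == 2:
        fit = fit_binary_bayes(
            preds, conc, n_walkers=n_walkers, n_steps=n_steps, n_burn=n_burn,
            seed=sampler_seed,
        )
    return {
        "predictions": pd.DataFrame(
            {
                "spheroid_id": table.data["spheroid_id"],
                "concentration_um": conc,
                "y_pred_24h": preds,
            }
        ),
        "fit": fit,
        "note": "no ground truth at this timepoint",
        "classifier": clf,
    }
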