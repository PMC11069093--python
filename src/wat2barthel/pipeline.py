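"""Configured end-to-end pipeline: simulate -> preprocess -> featurize ->
split -> tune/train -> evaluate, with CSV/JSON artifacts and a manifest.

File conventions (enforced by the readers/writers here): comma-separated
UTF-8 CSV, ISO-8601 timestamps, empty field = missing. Every run writes a
manifest recording the config hash, the per-stage seeds and the row counts
at every stage (including the number of patients excluded by the 14-day
sufficiency rule), so runs are auditable and reruns with identical config
and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, model, preprocessing, simulate

log = logging.getLogger("wat2barthel")

WAT_CSV_COLUMNS = ["patient_id", "timestamp", "steps", "heart_rate"]
METADATA_CSV_COLUMNS = ["patient_id", "true_bi", "aid_group", "encounter_date"]


# --------------------------------------------------------------------------
# Config
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; defaults follow the pipeline's canonical
    parameterisation (30-day window, 14-day sufficiency, width-3 smoothing,
    70/30 group-stratified split, 7-fold CV over the dense grid)."""

    output_dir: str = "results"
    wat_csv: str | None = None        # None -> simulate a cohort
    metadata_csv: str | None = None
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    window_days: int = 30
    min_days: int = 14
    train_fraction: float = 0.7
    cv_folds: int = 7
    scoring: str = "neg_mean_squared_error"
    reducer: str = "max"
    seed: int = 0
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["start_date"] = self.sim.start_date.isoformat()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            sim_d = dict(d["sim"])
            if "start_date" in sim_d and isinstance(sim_d["start_date"], str):
                sim_d["start_date"] = dt.date.fromisoformat(sim_d["start_date"])
            for key in ("meal_anchor_hours",):
                if key in sim_d:
                    sim_d[key] = tuple(sim_d[key])
            d["sim"] = simulate.SimConfig(**sim_d)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def derive_stage_seeds(global_seed: int) -> dict[str, int]:
    """Expand one global seed into independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(global_seed)
    names = ["simulate", "missingness", "split", "cv", "importance"]
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def write_wat_csv(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.loc[:, WAT_CSV_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_wat_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _check_schema(df, WAT_CSV_COLUMNS, path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    bad = df.index[df["steps"].notna() & (df["steps"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: negative step count at row {int(bad[0]) + 2}")
    return df


def write_metadata_csv(truths: list[simulate.PatientTruth], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "true_bi": t.true_bi,
                "aid_group": t.aid_group,
                "encounter_date": t.encounter_date.isoformat(),
            }
            for t in truths
        ],
        columns=METADATA_CSV_COLUMNS,
    ).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> list[simulate.PatientTruth]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _check_schema(df, METADATA_CSV_COLUMNS, path)
    truths = []
    for i, row in df.iterrows():
        try:
            truths.append(
                simulate.PatientTruth(
                    patient_id=str(row["patient_id"]),
                    true_bi=int(row["true_bi"]),
                    aid_group=str(row["aid_group"]),
                    encounter_date=dt.date.fromisoformat(str(row["encounter_date"])),
                    bi_class=evaluation.bi_to_class(float(row["true_bi"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return truths


def _check_schema(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write artifacts under ``config.output_dir``.

    Returns the manifest (also written as ``manifest.json``): config hash,
    stage seeds, row counts per stage, selected hyperparameters, and the
    evaluation summaries.
    """
    t0 = time.monotonic()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "counts": {},
    }

    # -- acquire data ------------------------------------------------------
    if config.wat_csv is not None:
        samples = read_wat_csv(config.wat_csv)
        truths = read_metadata_csv(config.metadata_csv)
        log.info("loaded %d samples for %d patients", len(samples), len(truths))
    else:
        sim_cfg = config.sim.with_(seed=seeds["simulate"])
        truths, samples = simulate.generate_cohort(sim_cfg)
        samples = simulate.inject_missingness(samples, sim_cfg, seed=seeds["missingness"])
        write_wat_csv(samples, outdir / "wat_samples.csv")
        write_metadata_csv(truths, outdir / "patient_metadata.csv")
        log.info("simulated %d patients (%d samples)", len(truths), len(samples))
    manifest["counts"]["patients"] = len(truths)
    manifest["counts"]["samples"] = int(len(samples))

    # -- preprocess --------------------------------------------------------
    hourly = preprocessing.aggregate_hourly(samples)
    window_ends = {t.patient_id: t.encounter_date for t in truths}
    profiles, excluded = preprocessing.build_profiles(
        hourly, window_ends, config.window_days, config.min_days
    )
    prof_frame = preprocessing.profiles_to_frame(profiles)
    prof_frame.to_csv(outdir / "profiles.csv", index=False)
    manifest["counts"]["profiles"] = len(profiles)
    manifest["counts"]["excluded_lt_min_days"] = len(excluded)
    manifest["excluded_patients"] = excluded
    log.info("profiles: %d kept, %d excluded by %d-day rule",
             len(profiles), len(excluded), config.min_days)

    # -- featurize ---------------------------------------------------------
    table = features.build_feature_table(profiles, truths, reducer=config.reducer)
    table.to_csv(outdir / "feature_table.csv", index=False)
    manifest["counts"]["feature_rows"] = len(table)

    # -- split -------------------------------------------------------------
    spec = model.SplitSpec(train_fraction=config.train_fraction, seed=seeds["split"])
    train, valid = model.stratified_split(table, spec)
    manifest["counts"]["train_rows"] = len(train)
    manifest["counts"]["validation_rows"] = len(valid)
    log.info("split: %d train / %d validation", len(train), len(valid))

    # -- tune + fit --------------------------------------------------------
    reducer_cols = [f"{s}_{config.reducer}" for s in features.SEGMENT_NAMES] + list(
        features.AID_COLUMNS
    )
    best, scores = model.cross_validate(
        train,
        k=config.cv_folds,
        scoring=config.scoring,
        seed=seeds["cv"],
        feature_columns=reducer_cols,
    )
    scores.to_csv(outdir / "cv_scores.csv", index=False)
    fitted = model.fit_tree(train, best, feature_columns=reducer_cols)
    (outdir / "model.json").write_text(fitted.to_json(), encoding="utf-8")
    (outdir / "model.txt").write_text(fitted.to_text() + "\n", encoding="utf-8")
    manifest["selected_hyperparams"] = {
        "min_impurity_decrease": best.min_impurity_decrease,
        "min_samples_leaf": best.min_samples_leaf,
        "min_samples_split": best.min_samples_split,
    }
    manifest["tree_depth"] = fitted.depth
    log.info("selected hyperparameters: %s; tree depth %d",
             manifest["selected_hyperparams"], fitted.depth)

    # -- evaluate ----------------------------------------------------------
    reports = {}
    predictions = {}
    for role, part in (("train", train), ("validation", valid)):
        y_true = part[features.TARGET_COLUMN].to_numpy(dtype=float)
        y_pred = fitted.predict(part.loc[:, reducer_cols])
        reports[role] = evaluation.evaluate_predictions(y_true, y_pred, role=role)
        predictions[role] = (y_true, y_pred)
    (outdir / "evaluation.json").write_text(
        json.dumps({r: rep.to_dict() for r, rep in reports.items()}, indent=2, sort_keys=True),
        encoding="utf-8",
    )
    (outdir / "evaluation.txt").write_text(
        "\n\n".join(rep.to_text() for rep in reports.values()) + "\n", encoding="utf-8"
    )
    manifest["evaluation"] = {
        role: {k: rep.to_dict()[k] for k in ("n", "mae", "mad", "rmse", "r2", "accuracy")}
        for role, rep in reports.items()
    }

    # -- permutation importance -------------------------------------------
    importance = model.permutation_importance(
        fitted, valid, n_repeats=50, seed=seeds["importance"], feature_columns=reducer_cols
    )
    importance.to_csv(outdir / "permutation_importance.csv", index=False)

    if config.make_figures:
        _write_figures(outdir, fitted, predictions, importance, reports)

    manifest["runtime_seconds"] = round(time.monotonic() - t0, 2)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest


def _write_figures(outdir: Path, fitted, predictions, importance, reports) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # real vs predicted, ordered by increasing true BI
    fig, axes = plt.subplots(1, len(predictions), figsize=(5 * len(predictions), 4))
    axes = np.atleast_1d(axes)
    for ax, (role, (y_true, y_pred)) in zip(axes, predictions.items()):
        order = np.argsort(y_true, kind="mergesort")
        ax.plot(y_true[order], "o-", label="real", ms=4)
        ax.plot(y_pred[order], "s--", label="predicted", ms=4)
        ax.set_title(role)
        ax.set_xlabel("subjects (by increasing BI)")
        ax.set_ylabel("Barthel Index")
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "predictions.png", dpi=120)
    plt.close(fig)

    # permutation importance distributions
    fig, ax = plt.subplots(figsize=(7, 4))
    order = (
        importance.groupby("feature")["mean_importance"].first().sort_values().index.tolist()
    )
    data = [importance.loc[importance["feature"] == f, "importance"] for f in order]
    ax.violinplot(data, vert=False, showmeans=True)
    ax.set_yticks(range(1, len(order) + 1), order)
    ax.set_xlabel("decrease in $R^2$ after shuffling")
    fig.tight_layout()
    fig.savefig(outdir / "importance.png", dpi=120)
    plt.close(fig)

    # confusion matrices
    fig, axes = plt.subplots(1, len(reports), figsize=(4 * len(reports), 3.5))
    axes = np.atleast_1d(axes)
    labels = list(evaluation.CLASS_LABELS)
    for ax, (role, rep) in zip(axes, reports.items()):
        cm = np.asarray(rep.confusion)
        ax.imshow(cm, cmap="Blues")
        for r in range(3):
            for c in range(3):
                ax.text(c, r, str(cm[r, c]), ha="center", va="center")
        ax.set_xticks(range(3), labels)
        ax.set_yticks(range(3), labels)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(role)
    fig.tight_layout()
    fig.savefig(outdir / "confusion.png", dpi=120)
    plt.close(fig)
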