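"""End-to-end orchestration: denoise -> rebalance -> split -> train -> classify.

A :class:`PipelineConfig` fully determines a run: the data source (a beat
file or a synthetic recipe), the denoiser settings, the rebalancing
targets, the network and training hyperparameters, the SVM settings, the
two ablation toggles, and a global seed from which every stochastic stage
derives its own seed.  ``run_pipeline`` executes the stages, evaluates on
the held-out partition, and writes a manifest from which the identical
run can be reproduced.

Rebalancing is applied to the training partition only, so upsampled
duplicates can never leak into the test set.  When denoising is disabled
(ablation arm), contact-loss sentinels are zero-filled so the network
still receives finite input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ecg_io, rebalance, synthetic_ecg
from .classify import fit_ova_svm, predict_labels
from .denoise import DenoiseConfig, denoise_beats
from .metrics import MetricsReport, multiclass_report
from .rdcnn import (
    RDCNNConfig,
    TrainConfig,
    build_model,
    count_parameters,
    extract_features,
    save_model,
    train_model,
)

logger = logging.getLogger("rdcnn_ecg")

MANIFEST_VERSION = "rdcnn-ecg-run-1"


@dataclass(frozen=True)
class SyntheticRecipe:
    """Synthetic data source: per-class counts plus a noise spec."""

    class_counts: dict[int, int] = field(
        default_factory=lambda: {0: 200, 1: 200, 2: 200, 3: 200, 4: 200}
    )
    beat_length: int = 187
    sampling_rate: float = 125.0
    noise: synthetic_ecg.NoiseSpec = field(default_factory=synthetic_ecg.NoiseSpec)


@dataclass(frozen=True)
class RebalanceSettings:
    """Training-partition rebalancing: optional majority subsample, then
    per-class resampling to a common target (None = balance to the largest
    class)."""

    target_per_class: int | None = None
    majority_class: int = 0
    majority_subsample: int | None = None


@dataclass(frozen=True)
class SVMSettings:
    kernel: str = "linear"
    C: float = 1.0
    gamma: float = 1e-4


@dataclass(frozen=True)
class PipelineConfig:
    data_path: str | None = None  # beat-CSV; overrides the synthetic recipe
    synthetic: SyntheticRecipe = field(default_factory=SyntheticRecipe)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    rebalance: RebalanceSettings = field(default_factory=RebalanceSettings)
    model: RDCNNConfig = field(default_factory=RDCNNConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    svm: SVMSettings = field(default_factory=SVMSettings)
    train_fraction: float = 0.8
    enable_denoise: bool = True
    enable_rebalance: bool = True
    output_dir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["class_counts"] = {
            str(k): v for k, v in self.synthetic.class_counts.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            if "class_counts" in syn:
                syn["class_counts"] = {
                    int(k): int(v) for k, v in syn["class_counts"].items()
                }
            if "noise" in syn and isinstance(syn["noise"], dict):
                syn["noise"] = synthetic_ecg.NoiseSpec(**syn["noise"])
            d["synthetic"] = SyntheticRecipe(**syn)
        for key, typ in (
            ("denoise", DenoiseConfig),
            ("rebalance", RebalanceSettings),
            ("model", RDCNNConfig),
            ("train", TrainConfig),
            ("svm", SVMSettings),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from a JSON or YAML file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig.from_dict(data)


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _derive_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage seeds derived from the global seed."""
    names = ["data", "split", "subsample", "resample", "model", "train", "svm"]
    state = np.random.SeedSequence(seed).generate_state(len(names), dtype=np.uint32)
    return {name: int(s) % (2**31 - 1) for name, s in zip(names, state)}


def _load_data(config: PipelineConfig, seed: int):
    if config.data_path is not None:
        beats, labels = ecg_io.read_beats(config.data_path)
        masks = ~np.isfinite(beats)
        fs = config.synthetic.sampling_rate
        return beats, labels, masks, fs
    recipe = config.synthetic
    beats, labels, masks = synthetic_ecg.generate_dataset(
        recipe.class_counts,
        recipe.beat_length,
        recipe.noise,
        seed=seed,
        sampling_rate=recipe.sampling_rate,
    )
    return beats, labels, masks, recipe.sampling_rate


def run_pipeline(
    config: PipelineConfig,
) -> tuple[MetricsReport, dict]:
    """Execute the full pipeline; returns (report, artifacts).

    Artifacts include the trained model, the SVM, the manifest dict, and
    per-stage information; when ``config.output_dir`` is set they are also
    written to disk (model archive, metrics JSON, confusion matrix CSV,
    training history CSV, run manifest).
    """
    seeds = _derive_seeds(config.seed)
    t0 = time.time()
    logger.info("stage seeds: %s", seeds)

    stage = "load"
    try:
        beats, labels, masks, fs = _load_data(config, seeds["data"])
        input_checksum = _checksum(np.nan_to_num(beats), labels)
        logger.info(
            "loaded %d beats of length %d (checksum %s)",
            beats.shape[0], beats.shape[1], input_checksum[:12],
        )

        stage = "denoise"
        if config.enable_denoise:
            beats = denoise_beats(beats, masks, config.denoise, fs)
        else:
            beats = np.nan_to_num(beats, nan=0.0)

        stage = "split"
        split = rebalance.SplitSpec(
            train_fraction=config.train_fraction,
            stratified=True,
            seed=seeds["split"],
        )
        (x_tr, y_tr), (x_te, y_te) = rebalance.split_train_test(beats, labels, split)

        stage = "rebalance"
        if config.enable_rebalance:
            rb = config.rebalance
            if rb.majority_subsample is not None:
                x_tr, y_tr = rebalance.subsample_majority(
                    x_tr, y_tr, rb.majority_class, rb.majority_subsample,
                    seeds["subsample"],
                )
            target = rb.target_per_class
            if target is None:
                target = int(np.bincount(y_tr).max())
            x_tr, y_tr = rebalance.resample_to_balance(
                x_tr, y_tr, target, seeds["resample"]
            )
        logger.info("training on %d rows, testing on %d", y_tr.size, y_te.size)

        stage = "train"
        model = build_model(config.model, beats.shape[1], seeds["model"])
        train_cfg = dataclasses.replace(config.train, seed=seeds["train"])
        train_model(model, x_tr, y_tr, train_cfg)
        n_params, _ = count_parameters(model)
        logger.info(
            "trained %d-parameter network for %d epochs",
            n_params, len(model.history["train_loss"]),
        )

        stage = "features"
        f_tr = extract_features(model, x_tr)
        f_te = extract_features(model, x_te)

        stage = "classify"
        svm = fit_ova_svm(
            f_tr, y_tr,
            C=config.svm.C, kernel=config.svm.kernel, gamma=config.svm.gamma,
            seed=seeds["svm"],
        )
        y_pred, scores = predict_labels(svm, f_te)

        stage = "evaluate"
        report = multiclass_report(
            y_te, y_pred, scores, n_classes=config.model.n_classes
        )
    except Exception:
        logger.exception(
            "pipeline failed in stage %r; resolved config: %s",
            stage, json.dumps(config.to_dict()),
        )
        raise

    manifest = {
        "version": MANIFEST_VERSION,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "input_checksum": input_checksum,
        "n_parameters": n_params,
        "epochs_run": len(model.history["train_loss"]),
        "runtime_seconds": time.time() - t0,
    }
    artifacts = {
        "model": model,
        "svm": svm,
        "manifest": manifest,
        "input_checksum": input_checksum,
        "n_parameters": n_params,
        "test_labels": y_te,
        "test_predictions": y_pred,
        "test_scores": scores,
    }
    if config.output_dir is not None:
        _write_artifacts(config.output_dir, report, artifacts)
    logger.info(
        "accuracy %.4f, macro F1 %.4f, kappa %.4f",
        report.accuracy, report.macro_f1, report.kappa.kappa,
    )
    return report, artifacts


def _write_artifacts(output_dir, report: MetricsReport, artifacts: dict) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_model(artifacts["model"], out / "model.npz")
    (out / "metrics.json").write_text(report.to_json() + "\n")
    np.savetxt(out / "confusion.csv", report.confusion, fmt="%d", delimiter=",")
    history = artifacts["model"].history
    rows = np.column_stack([history[k] for k in
                            ("train_loss", "train_acc", "val_loss", "val_acc")])
    np.savetxt(
        out / "history.csv", rows, delimiter=",",
        header="train_loss,train_acc,val_loss,val_acc", comments="",
    )
    (out / "manifest.json").write_text(
        json.dumps(artifacts["manifest"], indent=2) + "\n"
    )


def run_from_manifest(path) -> tuple[MetricsReport, dict]:
    """Re-execute a run from its manifest; reproduces the report."""
    manifest = json.loads(Path(path).read_text())
    if manifest.get("version") != MANIFEST_VERSION:
        raise ValueError(f"unsupported manifest version {manifest.get('version')}")
    config = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(config)


def run_ablation(
    config: PipelineConfig,
    flag_grid: list[tuple[bool, bool]] | None = None,
) -> list[dict]:
    """One pipeline run per (denoise, rebalance) flag combination.

    All runs share the same seed, hence identical input data (verified by
    checksum).  Returns a list of rows with the flags, the report, and the
    input checksum; failures are recorded per row without aborting the
    remaining runs.
    """
    if flag_grid is None:
        flag_grid = [(True, True), (True, False), (False, True), (False, False)]
    if not flag_grid:
        raise ValueError("flag grid must be non-empty")
    rows = []
    for denoise_on, rebalance_on in flag_grid:
        variant = dataclasses.replace(
            config,
            enable_denoise=denoise_on,
            enable_rebalance=rebalance_on,
            output_dir=None,
        )
        row = {"enable_denoise": denoise_on, "enable_rebalance": rebalance_on}
        try:
            report, artifacts = run_pipeline(variant)
            row["report"] = report
            row["input_checksum"] = artifacts["input_checksum"]
        except Exception as exc:  # keep partial results
            logger.exception("ablation run %s failed", row)
            row["error"] = str(exc)
        rows.append(row)
    return rows
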