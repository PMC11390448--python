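"""End-to-end orchestration: simulate -> preprocess -> crop -> pseudo-label
-> train instance classifier -> aggregate -> evaluate, seeded throughout.

Splits are patient-level and stratified by label; normalization statistics
and all model-selection choices are frozen on the training/validation
splits before the test split is touched. Rerunning with the same config
produces a byte-identical report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import aggregate as agg_mod
from . import mil, preprocess, roi
from .errors import ConfigurationError, PipelineStageError
from .mil import HeadConfig, PercentileContrastExtractor
from .nn import TrainConfig
from .phantom import PhantomConfig, PhantomVolume, generate_cohort
from . import metrics as metrics_mod


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(n_cases=20, n_controls=20))
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    margin_mm: float = 5.0
    instance_size: tuple[int, int] = (64, 64)
    head: HeadConfig = field(default_factory=HeadConfig)
    aggregator: agg_mod.AggregatorConfig = field(default_factory=agg_mod.AggregatorConfig)
    threshold: float = 0.5
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)  # train/val/test
    pooled_clustering: bool = False
    classifier_train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=60, batch_size=32, learning_rate=1e-3))

    def validate(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"split_fractions: must sum to 1, got {self.split_fractions}"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(f"threshold: must be in [0, 1], got {self.threshold}")
        self.phantom.validate()


def stratified_split(
    labels: Mapping[str, int], fractions: Sequence[float], seed: int
) -> dict[str, list[str]]:
    """Patient-level stratified train/val/test split; no patient straddles
    splits, and every split receives both classes (validated downstream
    where required)."""
    rng = np.random.default_rng(seed)
    splits = {"train": [], "val": [], "test": []}
    for cls in (1, 0):
        ids = sorted(pid for pid, y in labels.items() if y == cls)
        if not ids:
            raise ConfigurationError(f"split: cohort has no patients with label {cls}")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n = len(ids)
        n_train = max(1, int(round(fractions[0] * n)))
        n_val = int(round(fractions[1] * n))
        # test needs >= 2 per class for the DeLong variance; shave val, then
        # train, to get there whenever the class is large enough
        while n_train + n_val > n - 2 and n_val > 0:
            n_val -= 1
        while n_train + n_val > n - 2 and n_train > 1:
            n_train -= 1
        splits["train"] += ids[:n_train]
        splits["val"] += ids[n_train : n_train + n_val]
        splits["test"] += ids[n_train + n_val :]
    for name in splits:
        splits[name].sort()
    return splits


def _preprocess_cohort(cohort: Sequence[PhantomVolume], config: RunConfig, train_ids: set[str]):
    resampled = {}
    for vol in cohort:
        image, geo = preprocess.resample_image(vol.image, vol.geometry, config.target_spacing)
        organ, _ = preprocess.resample_mask(
            vol.organ_mask.astype(np.uint8), vol.geometry, config.target_spacing
        )
        tumor, _ = preprocess.resample_mask(
            vol.tumor_mask.astype(np.uint8), vol.geometry, config.target_spacing
        )
        resampled[vol.patient_id] = (image, organ.astype(bool), tumor.astype(bool), geo)
    stats = preprocess.compute_normalization_stats(
        [resampled[pid][0] for pid in sorted(train_ids)],
        [resampled[pid][1] for pid in sorted(train_ids)],
    )
    for pid, (image, organ, tumor, geo) in resampled.items():
        resampled[pid] = (preprocess.normalize_global(image, stats), organ, tumor, geo)
    return resampled, stats


def run_end_to_end(config: RunConfig) -> dict:
    """Execute all stages and return the metrics report (JSON-serializable)."""
    config.validate()

    try:
        cohort = generate_cohort(config.phantom)
        labels = {vol.patient_id: vol.label for vol in cohort}
    except Exception as exc:
        raise PipelineStageError("simulate", str(exc)) from exc

    try:
        splits = stratified_split(labels, config.split_fractions, config.seed)
    except Exception as exc:
        raise PipelineStageError("split", str(exc)) from exc

    try:
        resampled, stats = _preprocess_cohort(cohort, config, set(splits["train"]))
    except Exception as exc:
        raise PipelineStageError("preprocess", str(exc)) from exc

    try:
        stacks = {}
        for pid, (image, organ, _tumor, geo) in resampled.items():
            stacks[pid] = roi.build_instances(
                image, organ, geo, margin_mm=config.margin_mm,
                target_size=config.instance_size, patient_id=pid,
            )
    except Exception as exc:
        raise PipelineStageError("crop", str(exc)) from exc

    try:
        bags = {pid: b for pid, b in zip(
            sorted(stacks), mil.make_bags([stacks[p] for p in sorted(stacks)], labels)
        )}
        train_bags = [bags[p] for p in splits["train"]]
        extractor = PercentileContrastExtractor()
        pseudo = mil.label_cohort(
            train_bags, extractor, seed=config.seed, pooled=config.pooled_clustering
        )
        X_train = np.concatenate([bags[p].instances.instances for p in splits["train"]])
        y_train = np.concatenate([pseudo[p] for p in splits["train"]])
        tc = TrainConfig(
            epochs=config.classifier_train.epochs,
            batch_size=config.classifier_train.batch_size,
            learning_rate=config.classifier_train.learning_rate,
            seed=config.seed,
        )
        classifier = mil.train_instance_classifier(X_train, y_train, config.head, tc)
    except Exception as exc:
        raise PipelineStageError("train-mil", str(exc)) from exc

    try:
        summaries = {
            pid: agg_mod.summarize_probs(
                mil.predict_instance_probs(classifier, bags[pid]),
                bins=config.aggregator.summary_bins,
                scheme=config.aggregator.summary,
                top_k=config.aggregator.top_k,
            )
            for pid in bags
        }
        aggregator = agg_mod.train_aggregator(
            np.stack([summaries[p] for p in splits["train"]]),
            np.array([labels[p] for p in splits["train"]]),
            config.aggregator,
            seed=config.seed,
            val_summaries=np.stack([summaries[p] for p in splits["val"]]) if splits["val"] else None,
            val_labels=np.array([labels[p] for p in splits["val"]]) if splits["val"] else None,
        )
        test_probs = np.array(
            [float(aggregator.net.predict_proba(summaries[p][None])[0, 0]) for p in splits["test"]]
        )
        test_labels = np.array([labels[p] for p in splits["test"]])
    except Exception as exc:
        raise PipelineStageError("predict", str(exc)) from exc

    try:
        confusion = metrics_mod.confusion_at_threshold(test_probs, test_labels, config.threshold)
        summary = metrics_mod.summary_metrics(confusion)
        auc_est = metrics_mod.delong_ci(test_probs, test_labels)
    except Exception as exc:
        raise PipelineStageError("evaluate", str(exc)) from exc

    return {
        "seed": config.seed,
        "counts": {
            "patients": len(cohort),
            "cases": int(sum(labels.values())),
            "controls": int(len(labels) - sum(labels.values())),
            "train": len(splits["train"]),
            "val": len(splits["val"]),
            "test": len(splits["test"]),
            "train_instances": int(X_train.shape[0]),
        },
        "normalization": {"mean": stats.mean, "sd": stats.sd},
        "splits": splits,
        "test": {
            "patient_ids": splits["test"],
            "probabilities": [round(float(p), 12) for p in test_probs],
            "labels": [int(y) for y in test_labels],
            "threshold": config.threshold,
            "confusion": {"tp": confusion.tp, "fp": confusion.fp, "tn": confusion.tn, "fn": confusion.fn},
            "sensitivity": round(summary["sensitivity"], 12),
            "specificity": round(summary["specificity"], 12),
            "accuracy": round(summary["accuracy"], 12),
            "auc": round(auc_est.auc, 12),
            "auc_variance": round(auc_est.variance, 12),
            "auc_ci95": [round(auc_est.ci_low, 12), round(auc_est.ci_high, 12)],
        },
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2)
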