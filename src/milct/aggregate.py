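"""Patient-level aggregation: a bag's variable-length list of instance
probabilities is summarized into a fixed-length vector (a normalized
histogram by default) and mapped to a single cancer probability by a
one-hidden-layer network (18 units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .nn import DenseNet, TrainConfig


@dataclass(frozen=True)
class AggregatorConfig:
    summary_bins: int = 10
    hidden_units: int = 18
    summary: str = "histogram"  # or "mean_max", "topk"
    top_k: int = 3

    def __post_init__(self):
        if self.summary_bins < 2:
            raise ConfigurationError(f"summary_bins: must be >= 2, got {self.summary_bins}")
        if self.hidden_units < 1:
            raise ConfigurationError(f"hidden_units: must be >= 1, got {self.hidden_units}")
        if self.summary not in ("histogram", "mean_max", "topk"):
            raise ConfigurationError(f"summary: unknown scheme {self.summary!r}")


@dataclass
class PatientPrediction:
    patient_id: str
    probability: float
    threshold: float
    decision: int

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError(f"probability: {self.probability} outside [0, 1]")
        assert self.decision == int(self.probability >= self.threshold)


def summarize_probs(probs, bins: int = 10, scheme: str = "histogram", top_k: int = 3) -> np.ndarray:
    """Fixed-length, permutation- and duplication-invariant summary.

    Default: normalized histogram over ``bins`` equal bins on [0, 1] (the
    last bin is right-closed); components sum to 1.
    """
    probs = np.asarray(probs, dtype=np.float64).ravel()
    if probs.size == 0:
        raise ConfigurationError("probs: empty instance-probability list")
    if np.any((probs < 0) | (probs > 1)):
        raise ConfigurationError("probs: values must lie in [0, 1]")
    if scheme == "histogram":
        counts, _ = np.histogram(probs, bins=bins, range=(0.0, 1.0))
        return counts / probs.size
    if scheme == "mean_max":
        return np.array([probs.mean(), probs.max()])
    if scheme == "topk":
        top = np.sort(probs)[::-1]
        padded = np.pad(top, (0, max(0, top_k - top.size)), constant_values=0.0)[:top_k]
        return padded
    raise ConfigurationError(f"scheme: unknown {scheme!r}")


class Aggregator:
    """summary vector -> dense(hidden_units, ReLU) -> dense(1, logistic)."""

    def __init__(self, config: AggregatorConfig = AggregatorConfig(), seed: int = 0):
        self.config = config
        n_in = {"histogram": config.summary_bins, "mean_max": 2, "topk": config.top_k}[config.summary]
        self.net = DenseNet(
            n_in=n_in, n_hidden=config.hidden_units, n_out=1, output="sigmoid", seed=seed
        )

    def summarize(self, probs) -> np.ndarray:
        return summarize_probs(
            probs, bins=self.config.summary_bins, scheme=self.config.summary, top_k=self.config.top_k
        )

    def predict(self, probs) -> float:
        return float(self.net.predict_proba(self.summarize(probs)[None])[0, 0])


def train_aggregator(
    summaries: np.ndarray,
    labels: np.ndarray,
    config: AggregatorConfig = AggregatorConfig(),
    seed: int = 0,
    train_config: TrainConfig | None = None,
    val_summaries: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> Aggregator:
    """Train the aggregation network; when a validation split is supplied,
    the best-validation-loss weights are kept (model selection frozen on
    validation, not test)."""
    summaries = np.asarray(summaries, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("aggregator training requires both patient classes")
    agg = Aggregator(config, seed=seed)
    tc = train_config or TrainConfig(epochs=400, batch_size=16, learning_rate=5e-3, seed=seed)
    agg.net.fit(summaries, labels, tc, X_val=val_summaries, y_val=val_labels)
    return agg


def predict_patient(
    aggregator: Aggregator, probs, patient_id: str = "P0", threshold: float = 0.5
) -> PatientPrediction:
    p = aggregator.predict(probs)
    return PatientPrediction(
        patient_id=patient_id, probability=p, threshold=threshold, decision=int(p >= threshold)
    )
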