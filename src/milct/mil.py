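"""Multi-instance learning core: bags, feature extraction, K-means
pseudo-labeling inside positive bags, and the instance classifier.

Negative bags bypass clustering entirely: every instance is labeled 0.
Inside a positive bag, instance features are clustered into two groups and
the cluster whose centroid lies farther (Euclidean) from the centroid of
all negative-bag training instances is labeled 1. The instance classifier
is a pooling head (average pool -> dense 256, ReLU -> dropout 0.3 ->
dense 2, softmax) trained on the pseudo-labeled instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .errors import ConfigurationError
from .nn import DenseNet, TrainConfig
from .roi import InstanceStack


@dataclass
class Bag:
    """One patient's instances plus the observed bag (patient) label."""

    patient_id: str
    instances: InstanceStack
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ConfigurationError(f"label: must be 0 or 1 for {self.patient_id!r}")
        if len(self.instances) < 1:
            raise ConfigurationError(f"instances: bag {self.patient_id!r} is empty")

    def __len__(self) -> int:
        return len(self.instances)


@dataclass
class InstanceRecord:
    patient_id: str
    slice_index: int
    feature: np.ndarray
    pseudo_label: int
    predicted_prob: float = float("nan")


@dataclass(frozen=True)
class HeadConfig:
    pool_size: tuple[int, int] = (4, 4)
    dense_units: int = 256
    dropout_rate: float = 0.3
    # output layer fixed: dense(2) + softmax

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(f"dropout_rate: must be in [0, 1), got {self.dropout_rate}")
        if self.dense_units < 1:
            raise ConfigurationError(f"dense_units: must be >= 1, got {self.dense_units}")


def make_bags(
    stacks: Sequence[InstanceStack], labels: Mapping[str, int]
) -> list[Bag]:
    """One bag per patient; bag label = patient label."""
    bags = []
    for stack in stacks:
        if stack.patient_id not in labels:
            raise ConfigurationError(f"missing label for patient {stack.patient_id!r}")
        bags.append(Bag(stack.patient_id, stack, int(labels[stack.patient_id])))
    return bags


# --------------------------------------------------------------------------
# feature extractors
# --------------------------------------------------------------------------


class FeatureExtractor(Protocol):
    def extract(self, instances: np.ndarray) -> np.ndarray:  # (n,H,W) -> (n,d)
        ...


def _adaptive_avg_pool(instances: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Average-pool each 2D instance onto a grid of fixed output size."""
    n = instances.shape[0]
    rows = np.array_split(instances, grid[0], axis=1)
    pooled = np.empty((n, grid[0], grid[1]))
    for i, r in enumerate(rows):
        cols = np.array_split(r, grid[1], axis=2)
        for j, c in enumerate(cols):
            pooled[:, i, j] = c.mean(axis=(1, 2))
    return pooled


def window_avg_pool(instances: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Non-overlapping window average pooling (stride = window, remainder dropped)."""
    n, h, w = instances.shape
    ph, pw = window
    oh, ow = h // ph, w // pw
    if oh < 1 or ow < 1:
        raise ConfigurationError(f"pool_size: window {window} larger than instance {h}x{w}")
    trimmed = instances[:, : oh * ph, : ow * pw]
    return trimmed.reshape(n, oh, ph, ow, pw).mean(axis=(2, 4))


class AveragePoolExtractor:
    """Deterministic baseline: flatten an adaptive average pooling of the
    instance. A constant image c yields a feature of all c's."""

    def __init__(self, grid: tuple[int, int] = (8, 8)):
        self.grid = grid

    def extract(self, instances: np.ndarray) -> np.ndarray:
        instances = np.asarray(instances, dtype=np.float64)
        return _adaptive_avg_pool(instances, self.grid).reshape(instances.shape[0], -1)


class PercentileContrastExtractor:
    """Upper-percentile intensity features of each instance.

    A focal bright lesion lifts the top order statistics of a slice far more
    than it shifts area-driven averages, so these features cluster
    tumor-bearing vs tumor-free slices even when the organ cross-section
    varies strongly across the bag. Monotone-affine intensity normalization
    preserves the separation.
    """

    def __init__(self, percentiles: tuple[float, ...] = (97.0, 99.0, 99.9)):
        self.percentiles = percentiles

    def extract(self, instances: np.ndarray) -> np.ndarray:
        instances = np.asarray(instances, dtype=np.float64)
        flat = instances.reshape(instances.shape[0], -1)
        return np.percentile(flat, self.percentiles, axis=1).T


class RandomConvExtractor:
    """Frozen seeded random-convolution features: three conv(3x3)+ReLU+
    avgpool(2x2) blocks, then global average pooling per channel.

    A desk-scale stand-in for a pretrained backbone; deterministic for a
    fixed seed and never trained.
    """

    def __init__(self, channels: tuple[int, int, int] = (4, 8, 8), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.kernels = []
        c_in = 1
        for c_out in channels:
            self.kernels.append(rng.normal(0.0, np.sqrt(2.0 / (9 * c_in)), size=(c_out, c_in, 3, 3)))
            c_in = c_out

    def extract(self, instances: np.ndarray) -> np.ndarray:
        instances = np.asarray(instances, dtype=np.float64)
        feats = []
        for inst in instances:
            maps = inst[None]  # (C, H, W)
            for K in self.kernels:
                out = np.stack(
                    [
                        sum(ndimage.correlate(maps[c], K[o, c], mode="nearest") for c in range(maps.shape[0]))
                        for o in range(K.shape[0])
                    ]
                )
                out = np.maximum(out, 0.0)
                h, w = out.shape[1] // 2 * 2, out.shape[2] // 2 * 2
                out = out[:, :h, :w].reshape(out.shape[0], h // 2, 2, w // 2, 2).mean(axis=(2, 4))
                maps = out
            feats.append(maps.mean(axis=(1, 2)))
        return np.stack(feats)


def extract_features(instances: np.ndarray, extractor: FeatureExtractor) -> np.ndarray:
    instances = np.asarray(instances, dtype=np.float64)
    if instances.ndim != 3:
        raise ConfigurationError("instances: expected a (n, H, W) array")
    features = extractor.extract(instances)
    if features.shape[0] != instances.shape[0]:
        raise ConfigurationError("extractor returned wrong number of feature vectors")
    return features


# --------------------------------------------------------------------------
# pseudo-labeling
# --------------------------------------------------------------------------


_EXACT_KMEANS_MAX_N = 16


def _exact_two_partition(features: np.ndarray) -> np.ndarray:
    """Globally WCSS-optimal 2-partition by vectorized enumeration.

    Point 0 is fixed to cluster 0 (halves the search space); the optimum is
    itself a Lloyd fixed point, so this is the exact k=2 K-means solution.
    """
    n, _ = features.shape
    masks = np.arange(2 ** (n - 1), dtype=np.uint32)
    member = (masks[:, None] >> np.arange(n)) & 1  # (P, n) cluster-1 indicators
    c1 = member.sum(axis=1)
    valid = (c1 > 0) & (c1 < n)
    member = member[valid]
    c1 = c1[valid]
    s_total = features.sum(axis=0)
    s1 = member @ features
    s0 = s_total - s1
    # WCSS = sum ||x||^2 - sum_c |c| ||mean_c||^2
    between = (s1 * s1).sum(axis=1) / c1 + (s0 * s0).sum(axis=1) / (n - c1)
    best = int(np.argmax(between))
    return member[best].astype(int)


def kmeans_partition(features: np.ndarray, k: int = 2, seed: int = 0) -> np.ndarray:
    """K-means partition, deterministic for a fixed seed.

    k = 2 with n <= 16 is solved exactly by partition enumeration (Lloyd
    restarts are not guaranteed to reach the global optimum on tiny sets);
    everything else uses Lloyd with k-means++ init, 10 restarts, tol 1e-4.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 1:
        features = features[:, None]
    n = features.shape[0]
    if n < k:
        raise ConfigurationError(f"kmeans: need >= {k} instances, got {n}")
    if k == 2 and n <= _EXACT_KMEANS_MAX_N:
        return _exact_two_partition(features)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-4, random_state=seed)
    return km.fit_predict(features)


def assign_pseudo_labels(
    bag: Bag,
    assignments: np.ndarray,
    negative_centroid: np.ndarray,
    features: np.ndarray,
) -> np.ndarray:
    """Label 1 the cluster whose centroid is farther from the negative-bag
    instance centroid; ties break to the lower cluster index with a warning."""
    if bag.label != 1:
        raise ConfigurationError(f"assign_pseudo_labels: bag {bag.patient_id!r} is not positive")
    assignments = np.asarray(assignments)
    features = np.asarray(features, dtype=np.float64)
    clusters = np.unique(assignments)
    dists = {
        int(c): float(np.linalg.norm(features[assignments == c].mean(axis=0) - negative_centroid))
        for c in clusters
    }
    far = max(sorted(dists), key=lambda c: dists[c])
    ordered = sorted(dists.values())
    if len(ordered) > 1 and ordered[-1] == ordered[-2]:
        warnings.warn(
            f"centroid-distance tie in bag {bag.patient_id!r}; labeling lower cluster index positive"
        )
        far = min(c for c in dists if dists[c] == ordered[-1])
    return (assignments == far).astype(int)


def negative_instance_centroid(bags: Sequence[Bag], extractor: FeatureExtractor) -> np.ndarray:
    """Mean feature over all instances of the negative training bags."""
    feats = [
        extract_features(bag.instances.instances, extractor) for bag in bags if bag.label == 0
    ]
    if not feats:
        raise ConfigurationError("no negative bags available to anchor the positive cluster")
    return np.concatenate(feats).mean(axis=0)


def label_cohort(
    bags: Sequence[Bag],
    extractor: FeatureExtractor,
    seed: int = 0,
    pooled: bool = False,
) -> dict[str, np.ndarray]:
    """Pseudo-label every bag.

    Negative bags: all instances 0, no clustering. Positive bags: per-bag
    K-means by default (``pooled=True`` clusters all positive-bag instances
    together). Single-instance positive bags skip clustering and label the
    instance 1.
    """
    negative_centroid = negative_instance_centroid(bags, extractor)
    labels: dict[str, np.ndarray] = {}
    positives = [b for b in bags if b.label == 1]
    for bag in bags:
        if bag.label == 0:
            labels[bag.patient_id] = np.zeros(len(bag), dtype=int)

    if pooled and positives:
        feats = [extract_features(b.instances.instances, extractor) for b in positives]
        all_feats = np.concatenate(feats)
        if all_feats.shape[0] == 1:
            labels[positives[0].patient_id] = np.ones(1, dtype=int)
            return labels
        assignments = kmeans_partition(all_feats, k=2, seed=seed)
        # pick the positive cluster once, globally
        pooled_bag = positives[0]
        pooled_labels = assign_pseudo_labels(pooled_bag, assignments, negative_centroid, all_feats)
        start = 0
        for bag, f in zip(positives, feats):
            labels[bag.patient_id] = pooled_labels[start : start + len(f)]
            start += len(f)
        return labels

    for bag in positives:
        feats = extract_features(bag.instances.instances, extractor)
        if len(bag) == 1:
            labels[bag.patient_id] = np.ones(1, dtype=int)
            continue
        assignments = kmeans_partition(feats, k=2, seed=seed)
        labels[bag.patient_id] = assign_pseudo_labels(bag, assignments, negative_centroid, feats)
    return labels


# --------------------------------------------------------------------------
# instance classifier
# --------------------------------------------------------------------------


class InstanceClassifier:
    """Average pool (window = head.pool_size) -> dense(dense_units, ReLU) ->
    dropout -> dense(2, softmax), trained on pseudo-labeled instances."""

    def __init__(self, head: HeadConfig, instance_shape: tuple[int, int], seed: int = 0):
        self.head = head
        self.instance_shape = tuple(instance_shape)
        oh = instance_shape[0] // head.pool_size[0]
        ow = instance_shape[1] // head.pool_size[1]
        self.net = DenseNet(
            n_in=oh * ow,
            n_hidden=head.dense_units,
            n_out=2,
            output="softmax",
            dropout_rate=head.dropout_rate,
            seed=seed,
        )

    def _pool(self, instances: np.ndarray) -> np.ndarray:
        instances = np.asarray(instances, dtype=np.float64)
        if instances.shape[1:] != self.instance_shape:
            raise ConfigurationError(
                f"instance shape {instances.shape[1:]} != expected {self.instance_shape}"
            )
        pooled = window_avg_pool(instances, self.head.pool_size)
        return pooled.reshape(instances.shape[0], -1)

    def fit(self, instances: np.ndarray, labels: np.ndarray, config: TrainConfig) -> "InstanceClassifier":
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) < 2:
            raise ConfigurationError("training set contains a single pseudo-label class")
        self.net.fit(self._pool(instances), labels, config)
        return self

    def predict_proba(self, instances: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._pool(instances))


def train_instance_classifier(
    instances: np.ndarray,
    labels: np.ndarray,
    head: HeadConfig = HeadConfig(),
    train_config: TrainConfig = TrainConfig(),
) -> InstanceClassifier:
    instances = np.asarray(instances, dtype=np.float64)
    clf = InstanceClassifier(head, instances.shape[1:], seed=train_config.seed)
    return clf.fit(instances, labels, train_config)


def predict_instance_probs(classifier: InstanceClassifier, bag: Bag) -> np.ndarray:
    """Per-instance probability of class 1, order-preserving."""
    return classifier.predict_proba(bag.instances.instances)[:, 1]
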