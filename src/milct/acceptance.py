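"""Property-based acceptance measurements.

Each function recomputes one acceptance quantity from scratch by running the
package against an independent oracle (exhaustive enumeration, brute-force
pair counting, Monte-Carlo simulation, or a bootstrap). The oracles never
call the implementation path they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from . import mil
from .aggregate import AggregatorConfig
from .geometry import Geometry
from .metrics import delong_ci, roc_auc
from .phantom import PhantomConfig, generate_cohort
from .pipeline import RunConfig, report_to_json, run_end_to_end
from .preprocess import (
    EXCLUSION_REASONS,
    SeriesRecord,
    failing_reasons,
    resample_image,
    resample_mask,
    screen_series,
)
from .roi import build_instances, slices_with_organ

# ---------------------------------------------------------------- oracles


def _wcss(features: np.ndarray, assignments: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(assignments):
        pts = features[assignments == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def exhaustive_min_wcss(features: np.ndarray) -> float:
    """Global minimum within-cluster SS over all 2-partitions (point 0 fixed
    to cluster 0; empty clusters excluded)."""
    n = len(features)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        assign = np.array([(bits >> i) & 1 for i in range(n)])
        best = min(best, _wcss(features, assign))
    return best


def brute_force_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs Mann-Whitney statistic; ties count 1/2."""
    cases = probs[labels == 1]
    controls = probs[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))


# ------------------------------------------------------------ measurements


def kmeans_oracle_agreement(seed: int, n_trials: int = 100) -> dict:
    """Fraction of random feature sets (n <= 8, d <= 3, k = 2) where the
    K-means within-cluster SS equals the exhaustive-partition minimum."""
    rng = np.random.default_rng(seed)
    hits = 0
    for trial in range(n_trials):
        n = int(rng.integers(2, 9))
        d = int(rng.integers(1, 4))
        features = rng.normal(size=(n, d))
        assign = mil.kmeans_partition(features, k=2, seed=seed + trial)
        if _wcss(features, assign) <= exhaustive_min_wcss(features) * (1 + 1e-9) + 1e-12:
            hits += 1
    return {"value": hits / n_trials, "n": n_trials}


def auc_oracle_agreement(seed: int, n_trials: int = 200) -> dict:
    """Fraction of random score sets (n <= 20, tie-rich) where roc_auc equals
    brute-force pair counting exactly (float equality)."""
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_trials:
        n = int(rng.integers(4, 21))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        probs = np.round(rng.random(n), 1)  # coarse grid forces ties
        if roc_auc(probs, labels) == brute_force_auc(probs, labels):
            hits += 1
        done += 1
    return {"value": hits / n_trials, "n": n_trials}


def delong_coverage(seed: int, n_reps: int = 2000, n_each: int = 50, effect: float = 1.0) -> dict:
    """Empirical 95% CI coverage of the true AUC under a Gaussian score model
    (controls N(0,1), cases N(effect,1))."""
    true_auc = float(sstats.norm.cdf(effect / np.sqrt(2.0)))
    rng = np.random.default_rng(seed)
    labels = np.array([1] * n_each + [0] * n_each)
    covered = 0
    for _ in range(n_reps):
        scores = np.concatenate([rng.normal(effect, 1, n_each), rng.normal(0, 1, n_each)])
        est = delong_ci(scores, labels)
        covered += int(est.ci_low <= true_auc <= est.ci_high)
    return {"value": covered / n_reps, "n": n_reps, "true_auc": true_auc}


def delong_vs_bootstrap_variance(seed: int, n_each: int = 50, n_boot: int = 2000) -> dict:
    """Relative error of the DeLong variance against a stratified bootstrap
    variance oracle on one fixed seeded score set."""
    rng = np.random.default_rng(seed)
    cases = rng.normal(1.0, 1.0, n_each)
    controls = rng.normal(0.0, 1.0, n_each)
    labels = np.array([1] * n_each + [0] * n_each)
    analytic = delong_ci(np.concatenate([cases, controls]), labels).variance
    boot = np.empty(n_boot)
    for b in range(n_boot):
        rc = cases[rng.integers(0, n_each, n_each)]
        rn = controls[rng.integers(0, n_each, n_each)]
        boot[b] = roc_auc(np.concatenate([rc, rn]), labels)
    boot_var = float(np.var(boot, ddof=1))
    return {
        "value": abs(analytic - boot_var) / boot_var,
        "n": n_boot,
        "delong_variance": analytic,
        "bootstrap_variance": boot_var,
    }


def _phantom_bags_with_truth(config: PhantomConfig):
    cohort = generate_cohort(config)
    stacks, truth, labels = [], {}, {}
    for vol in cohort:
        stack = build_instances(vol.image, vol.organ_mask, vol.geometry, patient_id=vol.patient_id)
        stacks.append(stack)
        tumor_slices = set(slices_with_organ(vol.tumor_mask))
        truth[vol.patient_id] = np.array([int(k in tumor_slices) for k in stack.slice_indices])
        labels[vol.patient_id] = vol.label
    return mil.make_bags(stacks, labels), truth, labels


def bag_label_consistency(seed: int) -> dict:
    """Number of negative-bag instances carrying pseudo-label 1 across a
    seeded noisy phantom run (must be zero)."""
    config = PhantomConfig(n_cases=10, n_controls=10, noise_sd=15.0, seed=seed)
    bags, _, labels = _phantom_bags_with_truth(config)
    pseudo = mil.label_cohort(bags, mil.PercentileContrastExtractor(), seed=seed)
    violations = 0
    n_negative_instances = 0
    for bag in bags:
        if bag.label == 0:
            violations += int(pseudo[bag.patient_id].sum())
            n_negative_instances += len(bag)
    return {"value": violations, "n": n_negative_instances}


def pseudo_label_recovery(seed: int, n_cases: int = 20) -> dict:
    """Fraction of positive-bag instances whose pseudo-label matches the
    ground-truth tumor-slice indicator on a noiseless high-contrast cohort."""
    config = PhantomConfig(n_cases=n_cases, n_controls=10, noise_sd=0.0, seed=seed)
    bags, truth, labels = _phantom_bags_with_truth(config)
    pseudo = mil.label_cohort(bags, mil.PercentileContrastExtractor(), seed=seed)
    matched = total = 0
    for bag in bags:
        if bag.label == 1:
            matched += int((pseudo[bag.patient_id] == truth[bag.patient_id]).sum())
            total += len(bag)
    return {"value": matched / total, "n": total}


def end_to_end_recovery(seed: int) -> dict:
    """Test AUC on a moderate-noise 30/30 phantom cohort, test accuracy on the
    noiseless variant, and byte-identity of a rerun."""
    noisy_cfg = RunConfig(
        phantom=PhantomConfig(n_cases=30, n_controls=30, noise_sd=15.0, seed=seed), seed=seed
    )
    noisy = run_end_to_end(noisy_cfg)
    rerun_identical = report_to_json(run_end_to_end(noisy_cfg)) == report_to_json(noisy)
    noiseless = run_end_to_end(
        RunConfig(phantom=PhantomConfig(n_cases=30, n_controls=30, noise_sd=0.0, seed=seed), seed=seed)
    )
    return {
        "auc_noisy": noisy["test"]["auc"],
        "accuracy_noiseless": noiseless["test"]["accuracy"],
        "rerun_identical": rerun_identical,
        "n": noisy["counts"]["patients"],
    }


def preprocessing_contracts(seed: int) -> dict:
    """Three preprocessing contracts checked on seeded inputs: spline
    resampling reproduces constants, mask resampling introduces no new label
    values, and screening reasons are stable under check-order permutation."""
    import itertools

    rng = np.random.default_rng(seed)
    geo = Geometry(spacing=(1.0, 1.0, 2.5))

    const_ok = True
    for _ in range(5):
        value = float(rng.normal())
        out, _ = resample_image(np.full((12, 12, 8), value), geo, tuple(rng.uniform(0.5, 2.0, 3)))
        const_ok &= bool(np.allclose(out, value, atol=1e-9))

    labels_ok = True
    for _ in range(5):
        mask = rng.integers(0, 4, size=(10, 10, 10)).astype(np.int16)
        out, _ = resample_mask(mask, geo, tuple(rng.uniform(0.5, 2.0, 3)))
        labels_ok &= set(np.unique(out)) <= set(np.unique(mask))

    record = SeriesRecord(
        patient_id="P",
        slice_indices=[1, 3, 4],
        pixel_spacings=[(0.7, 0.7), (0.9, 0.9), (0.7, 0.7)],
        orientations=["A", "B", "A"],
        qa_flag="poor",
    )
    reported = screen_series([record]).excluded[0][1]
    reasons = failing_reasons(record)
    order_ok = all(
        next(r for r in EXCLUSION_REASONS if r in set(perm)) == reported
        for perm in itertools.permutations(reasons)
    )

    passed = int(const_ok) + int(labels_ok) + int(order_ok)
    return {
        "value": passed / 3.0,
        "n": 3,
        "constants_exact": bool(const_ok),
        "no_new_labels": bool(labels_ok),
        "screening_order_stable": bool(order_ok),
    }


def run_all(seed: int) -> dict:
    e2e = end_to_end_recovery(seed)
    return {
        "kmeans_oracle_agreement": kmeans_oracle_agreement(seed),
        "auc_oracle_agreement": auc_oracle_agreement(seed),
        "delong_coverage": delong_coverage(seed),
        "delong_bootstrap_relative_error": delong_vs_bootstrap_variance(seed),
        "bag_label_violations": bag_label_consistency(seed),
        "pseudo_label_recovery": pseudo_label_recovery(seed),
        "end_to_end_test_auc": {"value": e2e["auc_noisy"], "n": e2e["n"]},
        "end_to_end_noiseless_accuracy": {"value": e2e["accuracy_noiseless"], "n": e2e["n"]},
        "end_to_end_rerun_identical": {"value": int(e2e["rerun_identical"]), "n": e2e["n"]},
        "preprocessing_contracts": preprocessing_contracts(seed),
    }
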