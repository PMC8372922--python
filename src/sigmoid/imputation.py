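"""Predicting masked binary variables from feature-space clusters.

The application is gap-filling of draft genome-scale metabolic
reconstructions: reactions with similar inferred feature vectors co-occur
across genomes, so clustering reactions in feature space and asserting
"if one cluster member is present, all are" recovers reactions hidden by
incomplete sequencing.  Sweeping the dendrogram cut level from all-singletons
to one-big-cluster traces an ROC curve; the Jaccard overlap against the true
set peaks near the true network size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cooccurrence import cut_tree
from .datatypes import BinaryDataset, ClusterModel, ShapeError, ValidationError

__all__ = ["mask_fraction", "predict_from_clusters", "roc_sweep", "jaccard_curve"]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def mask_fraction(
    sample_vector: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Hide a fraction of the positive entries of one sample.

    round(fraction * positives) positives (half-away-from-zero, at least one
    when fraction > 0 and there are >= 2 positives, never more than all of
    them) are flipped to 0, chosen uniformly without replacement.  Zeros are
    never touched.  Returns (masked vector, indices of hidden positives).
    """
    v = np.asarray(sample_vector)
    if v.ndim != 1:
        raise ShapeError("sample_vector must be 1-D")
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must lie strictly between 0 and 1")
    positives = np.flatnonzero(v)
    if positives.size == 0:
        raise ValidationError("sample has no positive entries to mask")
    n_hide = _round_half_away(fraction * positives.size)
    if positives.size >= 2:
        n_hide = max(1, n_hide)
    n_hide = min(n_hide, positives.size)
    rng = np.random.default_rng(seed)
    hidden = np.sort(rng.choice(positives, size=n_hide, replace=False))
    masked = v.copy()
    masked[hidden] = 0
    return masked, hidden


def predict_from_clusters(
    masked_vector: np.ndarray, cluster_labels: np.ndarray
) -> np.ndarray:
    """Cluster-presence rule: predict 1 for every member of any cluster that
    contains at least one retained positive."""
    masked_vector = np.asarray(masked_vector)
    cluster_labels = np.asarray(cluster_labels)
    if masked_vector.shape != cluster_labels.shape:
        raise ShapeError("cluster labels must match the vector length")
    occupied = np.unique(cluster_labels[masked_vector == 1])
    return np.isin(cluster_labels, occupied).astype(np.int8)


def _per_sample_masks(
    test_data: BinaryDataset, fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray] | None]:
    """One mask per test sample, fixed across levels so the sweep is paired."""
    child = np.random.SeedSequence(seed).generate_state(test_data.n_samples)
    masks = []
    n_skipped = 0
    for s in range(test_data.n_samples):
        v = test_data.values[s]
        if v.sum() == 0:
            masks.append(None)
            n_skipped += 1
            continue
        masked, hidden = mask_fraction(v, fraction, int(child[s]))
        if hidden.size == 0:
            masks.append(None)
            n_skipped += 1
        else:
            masks.append((masked, hidden))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} sample(s) with no hidden positives excluded from averages",
            stacklevel=3,
        )
    return masks


def _labels_at_level(
    linkage_tree: ClusterModel, level: int, permute_rng: np.random.Generator | None
) -> np.ndarray:
    labels = cut_tree(linkage_tree, level)
    if permute_rng is not None:
        labels = permute_rng.permutation(labels)
    return labels


def roc_sweep(
    test_data: BinaryDataset,
    linkage_tree: ClusterModel,
    fraction: float,
    levels: list[int],
    seed: int,
    permute_labels: bool = False,
) -> tuple[pd.DataFrame, float]:
    """ROC across dendrogram cut levels, averaged over test samples.

    Per sample: TPR = fraction of hidden positives predicted present, FPR =
    fraction of true zeros predicted present.  Each level contributes one
    (FPR, TPR) point (sample-averaged); anchors (0,0) and (1,1) are appended
    and the AUC computed by the trapezoid rule after sorting by FPR.
    ``permute_labels`` shuffles each level's cluster labels — the null curve.
    """
    N = test_data.n_variables
    if any(not (1 <= lv <= N) for lv in levels):
        raise ValidationError(f"levels must lie in 1..{N}")
    masks = _per_sample_masks(test_data, fraction, seed)
    perm_rng = np.random.default_rng(seed + 1) if permute_labels else None
    rows = []
    for level in levels:
        labels = _labels_at_level(linkage_tree, level, perm_rng)
        tprs, fprs = [], []
        for s, mask in enumerate(masks):
            if mask is None:
                continue
            masked, hidden = mask
            pred = predict_from_clusters(masked, labels)
            truth = test_data.values[s]
            zeros = truth == 0
            tprs.append(pred[hidden].mean())
            fprs.append(pred[zeros].mean() if zeros.any() else 0.0)
        rows.append({"level": level, "fpr": np.mean(fprs), "tpr": np.mean(tprs)})
    table = pd.DataFrame(rows)
    pts = np.vstack(
        [[0.0, 0.0], table[["fpr", "tpr"]].to_numpy(), [1.0, 1.0]]
    )
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return table, auc


def jaccard_curve(
    test_data: BinaryDataset,
    linkage_tree: ClusterModel,
    fraction: float,
    levels: list[int],
    seed: int,
) -> pd.DataFrame:
    """Mean Jaccard(predicted, true positives) and mean relative predicted
    network size, per cut level."""
    N = test_data.n_variables
    if any(not (1 <= lv <= N) for lv in levels):
        raise ValidationError(f"levels must lie in 1..{N}")
    masks = _per_sample_masks(test_data, fraction, seed)
    rows = []
    for level in levels:
        labels = cut_tree(linkage_tree, level)
        jaccards, rel_sizes = [], []
        for s, mask in enumerate(masks):
            if mask is None:
                continue
            masked, _ = mask
            pred = predict_from_clusters(masked, labels)
            truth = test_data.values[s]
            inter = int(np.sum((pred == 1) & (truth == 1)))
            union = int(np.sum((pred == 1) | (truth == 1)))
            jaccards.append(inter / union if union else 1.0)
            rel_sizes.append(pred.sum() / truth.sum())
        rows.append(
            {
                "level": level,
                "relative_size": np.mean(rel_sizes),
                "mean_jaccard": np.mean(jaccards),
            }
        )
    return pd.DataFrame(rows)
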