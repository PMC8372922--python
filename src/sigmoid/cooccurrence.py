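"""Co-occurrence analyses: richness distributions with nulls, feature-space
clustering of variables, latent-space clustering of samples, and the exact
enrichment / association / differential-occurrence tests.

The motivating use case is micron-scale microbiome data: particles (samples)
by OTUs (variables), where the number of taxa co-occurring in one particle —
the richness — and the clusters of taxa with similar inferred features carry
the ecological signal.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact, hypergeom
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import (
    BinaryDataset,
    ClusterModel,
    DistanceMatrix,
    FeatureMatrix,
    LatentMatrix,
    ShapeError,
    ValidationError,
)
from .model import sample_data

__all__ = [
    "empirical_richness",
    "model_richness",
    "independent_null_richness",
    "feature_distance_matrix",
    "cluster_features",
    "cluster_samples",
    "silhouette_sweep",
    "pca_project",
    "enrichment_test",
    "pairwise_cooccurrence",
    "pairwise_association",
    "differential_occurrence",
]


def empirical_richness(data: BinaryDataset) -> np.ndarray:
    """P(n variables active in a sample), n = 0..N, from row-sum counts."""
    counts = np.bincount(
        data.values.sum(axis=1).astype(int), minlength=data.n_variables + 1
    )
    return counts / data.n_samples


def model_richness(
    latents: LatentMatrix,
    features: FeatureMatrix,
    n_replicates: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of the richness distribution over generative replicates.

    Each replicate redraws a full S x N dataset from the fitted probabilities,
    so the spread reflects generative sampling noise at the observed S.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    curves = np.stack(
        [
            empirical_richness(sample_data(latents, features, int(s)))
            for s in child_seeds
        ]
    )
    return curves.mean(axis=0), curves.std(axis=0)


def independent_null_richness(occurrence_freqs: np.ndarray) -> np.ndarray:
    """Poisson-binomial richness under independence, by iterative convolution.

    Given per-variable occurrence frequencies f_i, the distribution of
    sum_i Bernoulli(f_i) is built by convolving one variable at a time
    (dynamic programming, O(N^2)); this is the null that keeps the margins
    but erases all correlation between variables.
    """
    f = np.asarray(occurrence_freqs, dtype=float)
    if f.ndim != 1:
        raise ValidationError("occurrence frequencies must be a 1-D vector")
    if (f < 0).any() or (f > 1).any():
        raise ValidationError("occurrence frequencies must lie in [0, 1]")
    p = np.array([1.0])
    for fi in f:
        nxt = np.zeros(len(p) + 1)
        nxt[: len(p)] += p * (1.0 - fi)
        nxt[1:] += p * fi
        p = nxt
    return p


def feature_distance_matrix(features: FeatureMatrix) -> DistanceMatrix:
    """Euclidean distance between feature columns: d_ij = ||E_.i - E_.j||_2."""
    d = squareform(pdist(features.values.T, metric="euclidean"))
    return DistanceMatrix(d, features.variable_ids)


def cluster_features(
    dist: DistanceMatrix, linkage_method: str = "average", level: int = 1
) -> ClusterModel:
    """Agglomerative clustering of variables, cut into ``level`` flat clusters.

    ``level`` runs from 1 (everything in one cluster) to N (all singletons);
    the full merge tree is retained so callers can sweep levels cheaply.
    """
    n = dist.values.shape[0]
    if not (1 <= level <= n):
        raise ValidationError(f"level must lie in 1..{n}, got {level}")
    tree = linkage(squareform(dist.values, checks=False), method=linkage_method)
    labels = fcluster(tree, t=level, criterion="maxclust")
    return ClusterModel(
        kind="hierarchical", labels=labels, linkage_tree=tree, item_ids=dist.variable_ids
    )


def cut_tree(model: ClusterModel, level: int) -> np.ndarray:
    """Flat labels from an existing hierarchical model at a new level."""
    if model.linkage_tree is None:
        raise ValidationError("cluster model has no linkage tree")
    n = len(model.labels)
    if not (1 <= level <= n):
        raise ValidationError(f"level must lie in 1..{n}, got {level}")
    return fcluster(model.linkage_tree, t=level, criterion="maxclust")


def cluster_samples(
    latents: LatentMatrix, k: int, seed: int, n_init: int = 10
) -> tuple[ClusterModel, float]:
    """K-means on the latent rows; returns labels and the mean silhouette."""
    S = latents.n_samples
    if not (2 <= k < S):
        raise ValidationError(f"k must lie in 2..{S - 1}, got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(latents.values)
    score = float(silhouette_score(latents.values, labels))
    return (
        ClusterModel(kind="kmeans", labels=labels, seed=seed, item_ids=latents.sample_ids),
        score,
    )


def silhouette_sweep(
    latents: LatentMatrix, k_values: list[int], seed: int
) -> tuple[int, dict[int, float]]:
    """Silhouette score per k; returns (argmax k, {k: score})."""
    scores = {k: cluster_samples(latents, k, seed)[1] for k in k_values}
    best = max(scores, key=lambda k: scores[k])
    return best, scores


def pca_project(latents: LatentMatrix, n_components: int) -> np.ndarray:
    """Centered principal-component scores of the latent rows."""
    if n_components > latents.k:
        raise ValidationError(
            f"n_components={n_components} exceeds latent dimension K={latents.k}"
        )
    return PCA(n_components=n_components).fit_transform(latents.values)


def enrichment_test(
    cluster_members: set, annotated: set, universe_size: int
) -> float:
    """Single-tailed hypergeometric enrichment p-value, P(overlap >= observed).

    Tests whether an annotation category (e.g. a taxonomic family) is
    over-represented in a cluster relative to drawing the cluster uniformly
    from the universe.
    """
    cluster_members, annotated = set(cluster_members), set(annotated)
    if len(cluster_members) > universe_size or len(annotated) > universe_size:
        raise ValidationError("set sizes exceed the universe")
    overlap = len(cluster_members & annotated)
    return float(
        hypergeom.sf(
            overlap - 1, universe_size, len(annotated), len(cluster_members)
        )
    )


def _variable_index(data: BinaryDataset, subset) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(data.variable_ids)}
    missing = [v for v in subset if v not in lookup]
    if missing:
        raise ValidationError(f"unknown variable ids: {missing}")
    return np.array([lookup[v] for v in subset])


def pairwise_cooccurrence(data: BinaryDataset, subset=None) -> np.ndarray:
    """Co-occurrence frequency matrix: entry (i, j) is the fraction of samples
    where both variables are present; the diagonal is the occurrence frequency."""
    if subset is None:
        cols = data.values.astype(float)
    else:
        if len(subset) == 0:
            raise ValidationError("subset must be non-empty")
        cols = data.values[:, _variable_index(data, subset)].astype(float)
    return (cols.T @ cols) / data.n_samples


def pairwise_association(data: BinaryDataset) -> dict[tuple[int, int], tuple[int, float]]:
    """Per-pair association: phi-coefficient sign and one-sided Fisher p-value.

    The p-value tests for *positive* association (upper tail of the
    hypergeometric distribution of the co-presence count given the margins);
    the sign is that of the 2x2 determinant n11*n00 - n10*n01.  Exact tests
    are used because presence counts can be small.
    """
    if data.n_variables < 2:
        raise ValidationError("need at least two variables")
    sigma = data.values.astype(np.int64)
    S = data.n_samples
    co = sigma.T @ sigma
    occ = np.diag(co)
    out: dict[tuple[int, int], tuple[int, float]] = {}
    for i in range(data.n_variables):
        for j in range(i + 1, data.n_variables):
            n11 = int(co[i, j])
            n10 = int(occ[i] - n11)
            n01 = int(occ[j] - n11)
            n00 = S - n11 - n10 - n01
            sign = int(np.sign(n11 * n00 - n10 * n01))
            p = float(
                fisher_exact([[n11, n10], [n01, n00]], alternative="greater")[1]
            )
            out[(i, j)] = (sign, p)
    return out


def differential_occurrence(
    data: BinaryDataset, sample_labels: np.ndarray, target_cluster
) -> np.ndarray:
    """Hypergeometric upper-tail p-value per variable for over-occurrence in
    one sample cluster.

    For variable i with m_i total occurrences, the count inside a cluster of
    size c is hypergeometric(S, m_i, c) under the null that occurrences are
    exchangeable across samples; small p flags variables concentrated in the
    target cluster.
    """
    sample_labels = np.asarray(sample_labels)
    if sample_labels.shape[0] != data.n_samples:
        raise ShapeError("sample_labels length must equal the number of samples")
    in_cluster = sample_labels == target_cluster
    c = int(in_cluster.sum())
    if c == 0:
        raise ValidationError(f"target cluster {target_cluster!r} is empty")
    S = data.n_samples
    totals = data.values.sum(axis=0).astype(int)
    inside = data.values[in_cluster].sum(axis=0).astype(int)
    return hypergeom.sf(inside - 1, S, totals, c)
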