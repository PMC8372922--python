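"""Synthetic-data generators with planted ground truth.

Two families of fixtures: (a) datasets drawn from a planted low-rank logistic
model — used for parameter-recovery, model-selection and richness tests —
and (b) block-structured presence/absence matrices with known variable blocks
and sample clusters — used for clustering and imputation tests.  Every
generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BinaryDataset, FeatureMatrix, LatentMatrix, ValidationError
from .model import sample_data

__all__ = [
    "generate_parameters",
    "generate_dataset",
    "planted_block_dataset",
    "PlantedModel",
]


@dataclass(frozen=True)
class PlantedModel:
    """A fixture bundle: data plus the parameters that generated it."""

    data: BinaryDataset
    latents: LatentMatrix
    features: FeatureMatrix


def generate_parameters(
    S: int,
    N: int,
    K: int,
    latent_scale: float = 1.0,
    feature_scale: float = 1.0,
    seed: int = 0,
) -> tuple[LatentMatrix, FeatureMatrix]:
    """Planted parameters: beta ~ N(0, latent_scale^2), E ~ N(0, feature_scale^2).

    Unit scales give activation probabilities spanning roughly (0.05, 0.95)
    at K = 3, wide enough that recovery is informative but not saturated.
    """
    if S <= 0 or N <= 0 or K <= 0:
        raise ValidationError("S, N, K must be positive")
    rng = np.random.default_rng(seed)
    beta = rng.normal(0.0, latent_scale, size=(S, K))
    energies = rng.normal(0.0, feature_scale, size=(K, N))
    return LatentMatrix(beta), FeatureMatrix(energies)


def generate_dataset(
    latents: LatentMatrix, features: FeatureMatrix, seed: int
) -> PlantedModel:
    """Bernoulli draw from planted parameters, bundled with its ground truth."""
    data = sample_data(latents, features, seed)
    return PlantedModel(data=data, latents=latents, features=features)


def planted_block_dataset(
    S: int,
    N: int,
    n_variable_blocks: int,
    n_sample_clusters: int,
    within_p: float,
    between_p: float,
    seed: int = 0,
) -> tuple[BinaryDataset, np.ndarray, np.ndarray]:
    """Block-structured binary matrix with known partitions.

    Sample cluster c activates the variables of block (c mod n_variable_blocks)
    with probability ``within_p`` and all other variables with ``between_p``.
    Returns (data, variable block labels, sample cluster labels).
    """
    for p in (within_p, between_p):
        if not (0.0 <= p <= 1.0):
            raise ValidationError("probabilities must lie in [0, 1]")
    if within_p <= between_p:
        raise ValidationError("within_p must exceed between_p")
    if n_variable_blocks > N or n_sample_clusters > S:
        raise ValidationError("more blocks/clusters than variables/samples")
    rng = np.random.default_rng(seed)
    variable_blocks = np.sort(np.arange(N) % n_variable_blocks)
    sample_clusters = np.sort(np.arange(S) % n_sample_clusters)
    probs = np.full((S, N), between_p)
    for c in range(n_sample_clusters):
        block = c % n_variable_blocks
        rows = sample_clusters == c
        cols = variable_blocks == block
        probs[np.ix_(rows, cols)] = within_p
    values = (rng.random((S, N)) < probs).astype(np.int8)
    return BinaryDataset(values), variable_blocks, sample_clusters
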