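"""Core containers for binary datasets and model parameters.

The central objects are a binary sample-by-variable matrix (``BinaryDataset``),
the sample-specific intensive variables or *latents* (``LatentMatrix``, S x K),
and the variable-specific *energies* or features (``FeatureMatrix``, K x N).
A latent/feature pair defines, through a logistic (Gibbs-Boltzmann) link, the
probability that each binary variable is active in each sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ShapeError(ValueError):
    """Dimension mismatch between paired objects."""


class ValidationError(ValueError):
    """Input violates a documented invariant."""


def _as_ids(ids: Sequence[str] | None, n: int, prefix: str) -> tuple[str, ...]:
    if ids is None:
        return tuple(f"{prefix}{i}" for i in range(n))
    ids = tuple(str(x) for x in ids)
    if len(ids) != n:
        raise ShapeError(f"expected {n} {prefix!r} identifiers, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{prefix!r} identifiers are not unique")
    return ids


@dataclass(frozen=True)
class BinaryDataset:
    """S x N matrix of 0/1 observations with sample and variable identifiers."""

    values: np.ndarray
    sample_ids: tuple[str, ...] = None  # type: ignore[assignment]
    variable_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ShapeError(f"data must be 2-D, got shape {values.shape}")
        if values.size and not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValidationError(
                f"non-binary entry {values[tuple(bad)]!r} at row {bad[0]}, column {bad[1]}"
            )
        object.__setattr__(self, "values", values.astype(np.int8, copy=False))
        object.__setattr__(self, "sample_ids", _as_ids(self.sample_ids, values.shape[0], "s"))
        object.__setattr__(self, "variable_ids", _as_ids(self.variable_ids, values.shape[1], "v"))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, index: np.ndarray) -> "BinaryDataset":
        index = np.asarray(index)
        return BinaryDataset(
            self.values[index],
            tuple(np.asarray(self.sample_ids, dtype=object)[index]),
            self.variable_ids,
        )


def _check_finite(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ShapeError(f"{name} must be 2-D, got shape {values.shape}")
    if not np.isfinite(values).all():
        raise ValidationError(f"{name} contains non-finite entries")
    return values


@dataclass(frozen=True)
class LatentMatrix:
    """S x K matrix of sample-specific intensive variables (unitless)."""

    values: np.ndarray
    sample_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = _check_finite(self.values, "latents")
        if values.shape[1] < 1 and values.shape[0] > 0:
            raise ValidationError("latent dimension K must be >= 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", _as_ids(self.sample_ids, values.shape[0], "s"))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureMatrix:
    """K x N matrix of variable-specific energies (unitless)."""

    values: np.ndarray
    variable_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = _check_finite(self.values, "features")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variable_ids", _as_ids(self.variable_ids, values.shape[1], "v"))

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FitConfig:
    """Hyper-parameters of the maximum-likelihood fit.

    ``K`` is the only scientifically meaningful knob: the number of energy
    types (constraints) the model may learn.  The remainder control the
    gradient-ascent loop.
    """

    K: int = 2
    max_iters: int = 5000
    step_size: float = 0.5
    tol: float = 1e-8
    init_scale: float = 0.1
    seed: int = 0
    clamp_eps: float = 1e-12
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValidationError("K must be a positive integer")
        if self.max_iters <= 0:
            raise ValidationError("max_iters must be positive")
        if self.step_size <= 0:
            raise ValidationError("step_size must be positive")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if not (0.0 < self.clamp_eps < 0.5):
            raise ValidationError("clamp_eps must lie in (0, 0.5)")
        if self.init_scale < 0:
            raise ValidationError("init_scale must be non-negative")

    def replace(self, **kwargs) -> "FitConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    latents: LatentMatrix
    features: FeatureMatrix
    log_likelihood: float
    trajectory: np.ndarray
    converged: bool
    n_iters: int
    config: FitConfig | None = None

    def __post_init__(self) -> None:
        traj = np.asarray(self.trajectory, dtype=float)
        if traj.size and not np.isfinite(traj).all():
            raise ValidationError("likelihood trajectory contains non-finite values")
        object.__setattr__(self, "trajectory", traj)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix over variables."""

    values: np.ndarray
    variable_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = _check_finite(self.values, "distances")
        if values.shape[0] != values.shape[1]:
            raise ShapeError("distance matrix must be square")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValidationError("distance matrix must be symmetric")
        if (values < -1e-12).any() or np.abs(np.diag(values)).max(initial=0.0) > 1e-9:
            raise ValidationError("distances must be non-negative with zero diagonal")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variable_ids", _as_ids(self.variable_ids, values.shape[0], "v"))


@dataclass(frozen=True)
class ClusterModel:
    """Flat cluster labels, optionally backed by a full agglomerative tree."""

    kind: str  # "hierarchical" | "kmeans"
    labels: np.ndarray
    linkage_tree: np.ndarray | None = None
    seed: int | None = None
    item_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "item_ids", _as_ids(self.item_ids, labels.shape[0], "x"))

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def warn_if(condition: bool, message: str) -> None:
    if condition:
        warnings.warn(message, stacklevel=3)
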