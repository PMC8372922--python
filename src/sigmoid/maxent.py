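"""Exact pairwise maximum-entropy (Ising-type) comparator for small N.

For N binary variables the pairwise max-ent model is

    p(sigma) ∝ exp(-sum_{i<=j} J_ij sigma_i sigma_j),

the least-biased distribution reproducing all single-variable means and
pairwise co-occurrence moments.  Because sigma_i^2 = sigma_i, the diagonal
entries J_ii act as single-variable fields, so the model has N(N+1)/2 free
parameters: C(N,2) couplings plus N fields.

Everything here is computed by exhaustive enumeration of the 2^N states
(hard cap N <= 20), which makes moment matching exact rather than
MCMC-approximate.  This module is the independent yardstick against which
the low-rank logistic model is compared on small systems; it is not meant
to scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .datatypes import BinaryDataset, FeatureMatrix, LatentMatrix, ValidationError
from .model import compute_probabilities

MAX_ENUM_N = 20

__all__ = [
    "CouplingMatrix",
    "StateDistribution",
    "enumerate_states",
    "maxent_distribution",
    "fit_maxent",
    "distribution_summaries",
    "three_body_correlations",
    "sigmoid_state_distribution",
    "configuration_mae",
]


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric N x N coupling matrix; diagonal entries are fields."""

    values: np.ndarray
    variable_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError("coupling matrix must be square")
        if not np.isfinite(values).all():
            raise ValidationError("coupling matrix contains non-finite entries")
        if values.size and np.abs(values - values.T).max() > 1e-12:
            raise ValidationError("coupling matrix must be symmetric")
        object.__setattr__(self, "values", values)
        ids = self.variable_ids
        if ids is None:
            ids = tuple(f"v{i}" for i in range(values.shape[0]))
        object.__setattr__(self, "variable_ids", tuple(ids))

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_pair_couplings(self) -> int:
        """Number of off-diagonal couplings, C(N, 2)."""
        n = self.n_variables
        return n * (n - 1) // 2

    @property
    def n_parameters(self) -> int:
        """Total free parameters including fields, N(N+1)/2."""
        n = self.n_variables
        return n * (n + 1) // 2


@dataclass(frozen=True)
class StateDistribution:
    """Exact probability vector over all 2^N configurations.

    Configurations are ordered lexicographically: state index m maps to the
    binary expansion of m with variable 0 as the most significant bit, so
    index 0 is all-zeros and index 2^N - 1 is all-ones.
    """

    probs: np.ndarray
    N: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if self.N > MAX_ENUM_N:
            raise ValidationError(f"enumeration capped at N={MAX_ENUM_N}")
        if probs.shape != (2**self.N,):
            raise ValidationError("probability vector must have length 2^N")
        if (probs < -1e-15).any() or abs(probs.sum() - 1.0) > 1e-10:
            raise ValidationError("state probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probs", np.maximum(probs, 0.0))


def enumerate_states(N: int) -> np.ndarray:
    """All 2^N configurations, lexicographic, as a (2^N, N) 0/1 array."""
    if N < 0:
        raise ValidationError("N must be non-negative")
    if N > MAX_ENUM_N:
        raise ValidationError(
            f"N={N} exceeds the exhaustive-enumeration cap of {MAX_ENUM_N}"
        )
    if N == 0:
        return np.zeros((1, 0), dtype=np.int8)
    codes = np.arange(2**N, dtype=np.int64)[:, None]
    shifts = np.arange(N - 1, -1, -1, dtype=np.int64)
    return ((codes >> shifts) & 1).astype(np.int8)


def _state_energies(states: np.ndarray, J: np.ndarray) -> np.ndarray:
    # unordered-pair sum incl. diagonal: (sigma J sigma^T + sigma . diag J) / 2
    s = states.astype(float)
    quad = np.einsum("si,ij,sj->s", s, J, s)
    return 0.5 * (quad + s @ np.diag(J))


def maxent_distribution(J: CouplingMatrix) -> StateDistribution:
    """Exact Boltzmann distribution of the pairwise model by enumeration."""
    states = enumerate_states(J.n_variables)
    log_w = -_state_energies(states, J.values)
    log_z = logsumexp(log_w)
    return StateDistribution(np.exp(log_w - log_z), J.n_variables)


def _empirical_moments(
    data: BinaryDataset, regularize: bool = True
) -> np.ndarray:
    """Upper-triangular (incl. diagonal) empirical moment matrix <sigma_i sigma_j>."""
    sigma = data.values.astype(float)
    S = sigma.shape[0]
    moments = (sigma.T @ sigma) / S
    np.fill_diagonal(moments, sigma.mean(axis=0))
    if regularize:
        extreme = (moments <= 0.0) | (moments >= 1.0)
        iu = np.triu_indices_from(moments)
        if extreme[iu].any():
            warnings.warn(
                "some empirical moments are exactly 0 or 1; applying a Laplace "
                "pseudocount of 0.5 to keep the couplings finite",
                stacklevel=3,
            )
            counts = moments * S
            reg = (counts + 0.5) / (S + 1.0)
            moments = np.where(extreme, reg, moments)
            moments = 0.5 * (moments + moments.T)
    return moments


def fit_maxent(
    data: BinaryDataset,
    step_size: float = 1.0,
    tol: float = 1e-6,
    max_iters: int = 2000,
) -> CouplingMatrix:
    """Fit couplings so model moments match empirical moments (within tol).

    The average negative log-likelihood log Z(J) + sum_{i<=j} J_ij m_ij is
    convex in J with gradient (model moments - empirical moments), computed
    exactly by enumeration; it is minimised by L-BFGS-B.  ``step_size`` is
    accepted for interface compatibility but the quasi-Newton line search
    controls the actual steps.
    """
    N = data.n_variables
    if N > MAX_ENUM_N:
        raise ValidationError(f"exact fitting capped at N={MAX_ENUM_N}")
    target = _empirical_moments(data)
    states = enumerate_states(N)
    s = states.astype(float)
    iu = np.triu_indices(N)
    # per-state sufficient statistics for each unordered pair (i<=j)
    stats = s[:, iu[0]] * s[:, iu[1]]  # (2^N, P)
    target_vec = target[iu]

    def objective(j_vec: np.ndarray) -> tuple[float, np.ndarray]:
        log_w = -stats @ j_vec
        log_z = logsumexp(log_w)
        p = np.exp(log_w - log_z)
        model_vec = p @ stats
        f = log_z + float(j_vec @ target_vec)
        return f, target_vec - model_vec

    res = minimize(
        objective,
        np.zeros(len(target_vec)),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iters, "ftol": 1e-15, "gtol": tol * 1e-2},
    )
    _, grad = objective(res.x)
    if np.abs(grad).max() > tol:
        warnings.warn(
            f"moment matching reached max residual {np.abs(grad).max():.2e} > tol={tol}",
            stacklevel=2,
        )
    J = np.zeros((N, N))
    J[iu] = res.x
    J = J + J.T - np.diag(np.diag(J))
    return CouplingMatrix(J, data.variable_ids)


def distribution_summaries(
    dist: StateDistribution,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact means <sigma_i>, pair moments <sigma_i sigma_j>, and P(n active)."""
    states = enumerate_states(dist.N).astype(float)
    p = dist.probs
    means = states.T @ p
    pair = states.T @ (p[:, None] * states)
    counts = states.sum(axis=1).astype(int)
    p_n = np.bincount(counts, weights=p, minlength=dist.N + 1)
    return means, pair, p_n


def three_body_correlations(
    dist_or_data: StateDistribution | BinaryDataset,
) -> dict[tuple[int, int, int], float]:
    """Central third cross-moments <dsigma_i dsigma_j dsigma_k> for all i<j<k.

    Exact for a StateDistribution; the plug-in estimate for a BinaryDataset.
    These are not fitted by pairwise constraints, which makes them a genuine
    out-of-sample check of either model.
    """
    if isinstance(dist_or_data, StateDistribution):
        states = enumerate_states(dist_or_data.N).astype(float)
        weights = dist_or_data.probs
        N = dist_or_data.N
    else:
        states = dist_or_data.values.astype(float)
        weights = np.full(states.shape[0], 1.0 / states.shape[0])
        N = dist_or_data.n_variables
    if N < 3:
        return {}
    mu = weights @ states
    centered = states - mu
    out: dict[tuple[int, int, int], float] = {}
    for i, j, k in combinations(range(N), 3):
        out[(i, j, k)] = float(
            np.sum(weights * centered[:, i] * centered[:, j] * centered[:, k])
        )
    return out


def sigmoid_state_distribution(
    latents: LatentMatrix, features: FeatureMatrix
) -> StateDistribution:
    """Exact state distribution of the logistic mixture model by enumeration."""
    N = features.n_variables
    if N > MAX_ENUM_N:
        raise ValidationError(f"enumeration capped at N={MAX_ENUM_N}")
    states = enumerate_states(N).astype(float)
    pi = compute_probabilities(latents, features)
    log_pi, log_1m = np.log(pi), np.log1p(-pi)
    # (2^N, S) matrix of per-sample log Bernoulli products
    log_terms = states @ log_pi.T + (1.0 - states) @ log_1m.T
    log_p = logsumexp(log_terms, axis=1) - np.log(latents.n_samples)
    p = np.exp(log_p)
    return StateDistribution(p / p.sum(), N)


def empirical_state_counts(data: BinaryDataset) -> np.ndarray:
    """Observation count of each of the 2^N configurations (lexicographic)."""
    N = data.n_variables
    if N > MAX_ENUM_N:
        raise ValidationError(f"enumeration capped at N={MAX_ENUM_N}")
    shifts = np.arange(N - 1, -1, -1, dtype=np.int64)
    codes = data.values.astype(np.int64) @ (1 << shifts)
    return np.bincount(codes, minlength=2**N)


def configuration_mae(data: BinaryDataset, dist: StateDistribution) -> float:
    """Mean |empirical - model| frequency over configurations seen in the data."""
    counts = empirical_state_counts(data)
    observed = counts > 0
    p_emp = counts[observed] / data.n_samples
    return float(np.mean(np.abs(p_emp - dist.probs[observed])))
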