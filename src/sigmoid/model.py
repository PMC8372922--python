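"""Super-statistical logistic model for binary matrices.

Each sample ``s`` carries a K-vector of intensive variables (latents)
``beta_s`` and each binary variable ``i`` a K-vector of energies (features)
``E_.i``.  The probability that variable ``i`` is active in sample ``s`` is
the Gibbs-Boltzmann / logistic link

    pi_si = exp(-sum_k beta_sk E_ki) / (1 + exp(-sum_k beta_sk E_ki)),

i.e. the maximum-entropy distribution when the K energy averages are
constrained per sample.  Parameters are estimated by full-batch gradient
ascent on the Bernoulli log-likelihood with backtracking step control, so
the likelihood trajectory is non-decreasing at every accepted step.

The parameterisation is degenerate: for any invertible K x K matrix M the
pair (beta M, M^-1 E) yields identical probabilities.  Comparisons between
fits are therefore made in probability space, never parameter space.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, logsumexp

from .datatypes import (
    BinaryDataset,
    FeatureMatrix,
    FitConfig,
    FitResult,
    LatentMatrix,
    ShapeError,
    ValidationError,
)

__all__ = [
    "compute_probabilities",
    "log_likelihood",
    "gradients",
    "fit",
    "embed_samples",
    "sample_data",
    "predictive_probability",
    "log_predictive_probability",
    "gauge_transform",
]


def _probability_values(beta: np.ndarray, energies: np.ndarray, clamp_eps: float) -> np.ndarray:
    # expit(-x) is the numerically stable form of exp(-x)/(1+exp(-x))
    pi = expit(-(beta @ energies))
    return np.clip(pi, clamp_eps, 1.0 - clamp_eps)


def compute_probabilities(
    latents: LatentMatrix, features: FeatureMatrix, clamp_eps: float = 1e-12
) -> np.ndarray:
    """Activation probabilities pi_si of the logistic link, clamped away from {0, 1}.

    Returns an S x N array with every entry in [clamp_eps, 1 - clamp_eps].
    """
    if latents.k != features.k:
        raise ShapeError(
            f"latents have K={latents.k} but features have K={features.k}"
        )
    if not (0.0 < clamp_eps < 0.5):
        raise ValidationError("clamp_eps must lie in (0, 0.5)")
    return _probability_values(latents.values, features.values, clamp_eps)


def log_likelihood(data: BinaryDataset, probs: np.ndarray) -> float:
    """Bernoulli log-likelihood L = sum_si [sigma log pi + (1-sigma) log(1-pi)]."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != data.values.shape:
        raise ShapeError(
            f"probability matrix shape {probs.shape} != data shape {data.values.shape}"
        )
    sigma = data.values
    return float(np.sum(sigma * np.log(probs) + (1 - sigma) * np.log1p(-probs)))


def gradients(
    data: BinaryDataset,
    probs: np.ndarray,
    latents: LatentMatrix,
    features: FeatureMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact gradients of the log-likelihood.

    dL/dbeta_sk = sum_i (pi_si - sigma_si) E_ki and
    dL/dE_ki    = sum_s (pi_si - sigma_si) beta_sk.
    With the minus sign inside the exponent of the link these are the true
    ascent directions (verified against finite differences in the test suite).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != data.values.shape:
        raise ShapeError("probability matrix does not match data shape")
    if latents.n_samples != data.n_samples or features.n_variables != data.n_variables:
        raise ShapeError("parameter shapes do not match data")
    residual = probs - data.values
    grad_beta = residual @ features.values.T
    grad_energy = latents.values.T @ residual
    return grad_beta, grad_energy


def _ascend(
    sigma: np.ndarray,
    beta: np.ndarray,
    energies: np.ndarray,
    config: FitConfig,
    update_features: bool = True,
    frozen_cols: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    """Backtracking gradient ascent; ``frozen_cols`` trailing latent columns stay fixed."""
    eps = config.clamp_eps

    def objective(b: np.ndarray, e: np.ndarray) -> float:
        pi = _probability_values(b, e, eps)
        return float(np.sum(sigma * np.log(pi) + (1 - sigma) * np.log1p(-pi)))

    step = config.step_size
    L = objective(beta, energies)
    trajectory = [L]
    converged = False
    n_iters = 0
    for n_iters in range(1, config.max_iters + 1):
        pi = _probability_values(beta, energies, eps)
        residual = pi - sigma
        grad_beta = residual @ energies.T
        if frozen_cols:
            grad_beta[:, -frozen_cols:] = 0.0
        grad_energy = beta.T @ residual if update_features else None

        accepted = False
        for _ in range(60):
            beta_new = beta + step * grad_beta
            energies_new = (
                energies + step * grad_energy if update_features else energies
            )
            L_new = objective(beta_new, energies_new)
            if L_new >= L:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no ascent direction at machine precision
            break
        beta, energies = beta_new, energies_new
        improvement = L_new - L
        L = L_new
        trajectory.append(L)
        step *= 1.2
        if improvement <= config.tol * max(1.0, abs(L)):
            converged = True
            break
    return beta, energies, trajectory, converged, n_iters


def fit(
    data: BinaryDataset,
    config: FitConfig,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Maximum-likelihood estimate of (latents, features) by gradient ascent.

    Initialisation is i.i.d. N(0, init_scale^2) from ``config.seed`` unless an
    explicit ``init=(beta0, E0)`` warm start is given.  With ``intercept=True``
    a frozen all-ones latent column is appended, giving every variable a bias
    energy; the reported K then counts only the free components.
    """
    S, N = data.values.shape
    if S == 0 or N == 0:
        raise ValidationError("cannot fit an empty dataset")
    K = config.K
    if K > min(S, N):
        warnings.warn(
            f"K={K} exceeds min(S, N)={min(S, N)}; the model is over-parameterised",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    k_total = K + (1 if config.intercept else 0)
    if init is not None:
        beta = np.array(init[0], dtype=float, copy=True)
        energies = np.array(init[1], dtype=float, copy=True)
        if beta.shape != (S, k_total) or energies.shape != (k_total, N):
            raise ShapeError("warm-start shapes do not match data and K")
    else:
        beta = rng.normal(0.0, config.init_scale, size=(S, k_total))
        energies = rng.normal(0.0, config.init_scale, size=(k_total, N))
        if config.intercept:
            beta[:, -1] = 1.0

    sigma = data.values.astype(float)
    beta, energies, trajectory, converged, n_iters = _ascend(
        sigma, beta, energies, config, frozen_cols=1 if config.intercept else 0
    )
    return FitResult(
        latents=LatentMatrix(beta, data.sample_ids),
        features=FeatureMatrix(energies, data.variable_ids),
        log_likelihood=trajectory[-1],
        trajectory=np.asarray(trajectory),
        converged=converged,
        n_iters=n_iters,
        config=config,
    )


def embed_samples(
    new_data: BinaryDataset, features: FeatureMatrix, config: FitConfig
) -> LatentMatrix:
    """Out-of-sample embedding: per-sample ML latents with the features frozen."""
    if new_data.variable_ids != features.variable_ids:
        raise ValidationError("variable identifiers of new data do not match features")
    S = new_data.n_samples
    k_total = features.k
    if S == 0:
        return LatentMatrix(np.zeros((0, k_total)), ())
    rng = np.random.default_rng(config.seed)
    beta0 = rng.normal(0.0, config.init_scale, size=(S, k_total))
    if config.intercept:
        beta0[:, -1] = 1.0
    beta, _, _, _, _ = _ascend(
        new_data.values.astype(float),
        beta0,
        features.values,
        config,
        update_features=False,
        frozen_cols=1 if config.intercept else 0,
    )
    return LatentMatrix(beta, new_data.sample_ids)


def sample_data(
    latents: LatentMatrix, features: FeatureMatrix, seed: int
) -> BinaryDataset:
    """Generative draw: sigma_si ~ Bernoulli(pi_si), independently."""
    pi = compute_probabilities(latents, features)
    rng = np.random.default_rng(seed)
    values = (rng.random(pi.shape) < pi).astype(np.int8)
    return BinaryDataset(values, latents.sample_ids, features.variable_ids)


def log_predictive_probability(
    config_vector: np.ndarray, latents: LatentMatrix, features: FeatureMatrix
) -> float:
    """log of the S-component Bernoulli-mixture probability of a configuration.

    p(sigma) = (1/S) sum_s prod_i pi_si^sigma_i (1-pi_si)^(1-sigma_i),
    evaluated with a log-sum-exp over samples.
    """
    sigma = np.asarray(config_vector)
    if sigma.ndim != 1 or sigma.shape[0] != features.n_variables:
        raise ShapeError(
            f"configuration must be a length-{features.n_variables} vector"
        )
    if sigma.size and not np.isin(sigma, (0, 1)).all():
        raise ValidationError("configuration entries must be 0 or 1")
    pi = compute_probabilities(latents, features)
    log_terms = sigma * np.log(pi) + (1 - sigma) * np.log1p(-pi)  # S x N
    return float(logsumexp(log_terms.sum(axis=1)) - np.log(latents.n_samples))


def predictive_probability(
    config_vector: np.ndarray, latents: LatentMatrix, features: FeatureMatrix
) -> float:
    return float(np.exp(log_predictive_probability(config_vector, latents, features)))


def gauge_transform(
    latents: LatentMatrix,
    features: FeatureMatrix,
    M: np.ndarray,
    cond_threshold: float = 1e12,
) -> tuple[LatentMatrix, FeatureMatrix]:
    """Apply the prediction-preserving reparameterisation (beta M, M^-1 E)."""
    M = np.asarray(M, dtype=float)
    if M.shape != (latents.k, latents.k):
        raise ShapeError(f"M must be {latents.k} x {latents.k}")
    if not np.isfinite(M).all() or np.linalg.cond(M) > cond_threshold:
        raise ValidationError("M is singular or too ill-conditioned to invert")
    M_inv = np.linalg.inv(M)
    return (
        LatentMatrix(latents.values @ M, latents.sample_ids),
        FeatureMatrix(M_inv @ features.values, features.variable_ids),
    )
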