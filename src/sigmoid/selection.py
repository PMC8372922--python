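"""Choosing the latent dimension K.

Two routes: the Akaike information criterion on the training fit, and
held-out predictive probability when samples may be correlated.  The AIC
parameter count is ambiguous for this model because of the K x K gauge
degeneracy; both conventions are computed:

    full            P = K (S + N)        (literal free-parameter count)
    gauge_corrected P = K (S + N) - K^2  (modulo the invertible-matrix orbit)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BinaryDataset, FitConfig, FitResult, ValidationError
from .model import compute_probabilities, fit, log_predictive_probability

__all__ = ["aic", "aic_scan", "cross_validate"]

_CONVENTIONS = ("full", "gauge_corrected")


def parameter_count(K: int, S: int, N: int, convention: str = "full") -> int:
    if convention not in _CONVENTIONS:
        raise ValidationError(f"unknown parameter convention {convention!r}")
    P = K * (S + N)
    if convention == "gauge_corrected":
        P -= K * K
    return P


def aic(fit_result: FitResult, data: BinaryDataset, param_convention: str = "full") -> float:
    """AIC = 2 P - 2 L for the given parameter-count convention."""
    K = fit_result.latents.k
    P = parameter_count(K, data.n_samples, data.n_variables, param_convention)
    return 2.0 * P - 2.0 * fit_result.log_likelihood


def aic_scan(
    data: BinaryDataset,
    K_values: list[int],
    config: FitConfig,
    n_restarts: int = 2,
) -> pd.DataFrame:
    """Fit each K with seeded restarts (plus a warm start grown from the
    previous K's best solution) and tabulate the best log-likelihood and AIC.

    Returns a DataFrame with columns K, log_likelihood, aic_full,
    aic_gauge_corrected, sorted by K; ``df.attrs["best_K"]`` holds the
    argmin-AIC K under the full convention.
    """
    if not K_values:
        raise ValidationError("K_values must be non-empty")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    S, N = data.n_samples, data.n_variables
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(K_values) * n_restarts + len(K_values)
    )
    rows = []
    prev_best: FitResult | None = None
    si = 0
    for K in sorted(K_values):
        cfg_k = config.replace(K=K)
        candidates = []
        for _ in range(n_restarts):
            candidates.append(fit(data, cfg_k.replace(seed=int(seeds[si]))))
            si += 1
        if prev_best is not None and prev_best.latents.k < K:
            rng = np.random.default_rng(int(seeds[si]))
            pad = K - prev_best.latents.k
            beta0 = np.hstack(
                [prev_best.latents.values, rng.normal(0, config.init_scale, (S, pad))]
            )
            e0 = np.vstack(
                [prev_best.features.values, rng.normal(0, config.init_scale, (pad, N))]
            )
            candidates.append(fit(data, cfg_k, init=(beta0, e0)))
        si += 1
        best = max(candidates, key=lambda r: r.log_likelihood)
        prev_best = best
        rows.append(
            {
                "K": K,
                "log_likelihood": best.log_likelihood,
                "aic_full": aic(best, data, "full"),
                "aic_gauge_corrected": aic(best, data, "gauge_corrected"),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["best_K"] = int(table.loc[table["aic_full"].idxmin(), "K"])
    return table


def cross_validate(
    data: BinaryDataset,
    K: int,
    val_fraction: float,
    config: FitConfig,
    seed: int,
) -> tuple[np.ndarray, float]:
    """Train/validation split scored by the mixture predictive probability.

    Fits on the training split, then scores each held-out sample with the log
    of the S_train-component Bernoulli mixture built from the *training*
    latents (no re-embedding).  Returns (per-training-sample log-likelihood,
    mean held-out log-probability).
    """
    if not (0.0 < val_fraction < 1.0):
        raise ValidationError("val_fraction must lie in (0, 1)")
    S = data.n_samples
    n_val = int(round(val_fraction * S))
    if n_val == 0 or n_val == S:
        raise ValidationError(
            f"val_fraction={val_fraction} leaves an empty split for S={S}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(S)
    val_idx, train_idx = order[:n_val], order[n_val:]
    train = data.subset_samples(train_idx)
    val = data.subset_samples(val_idx)

    result = fit(train, config.replace(K=K))
    pi = compute_probabilities(result.latents, result.features, config.clamp_eps)
    sigma = train.values
    per_sample_L = (sigma * np.log(pi) + (1 - sigma) * np.log1p(-pi)).sum(axis=1)
    held_out = np.array(
        [
            log_predictive_probability(v, result.latents, result.features)
            for v in val.values
        ]
    )
    return per_sample_L, float(held_out.mean())
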