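"""MCMC convergence diagnostics: split potential scale reduction and a
basic autocorrelation-based effective-sample-size proxy."""

from __future__ import annotations

import numpy as np

__all__ = ["rhat", "ess"]


def rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    ``chains`` has shape (m, n): m >= 2 chains of equal length. Each chain is
    split in half before comparing between- and within-chain variance.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D (m, n) array")
    m, n = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 4:
        raise ValueError("chains too short to split")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    b = half * split.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))


def ess(chains: np.ndarray) -> float:
    """Crude effective sample size from pooled autocorrelations.

    Sums sample autocorrelations (averaged over chains) until the first
    negative value — a light version of the usual initial-sequence rule.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    m, n = chains.shape
    total = m * n
    centered = chains - chains.mean(axis=1, keepdims=True)
    denom = (centered**2).sum()
    if denom == 0.0:
        return float(total)
    rho_sum = 0.0
    for lag in range(1, n // 2):
        acov = sum(
            float(centered[c, :-lag] @ centered[c, lag:]) for c in range(m)
        )
        rho = acov / denom
        if rho < 0.0:
            break
        rho_sum += rho
    return float(total / (1.0 + 2.0 * rho_sum))
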