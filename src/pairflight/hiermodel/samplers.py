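"""Low-level sampling utilities shared by the model fitters.

The fitters are blocked Gibbs samplers: linear-Gaussian blocks are drawn
exactly from their conditional (via the precision-matrix Cholesky factor),
while scale and sigmoid parameters take adaptive random-walk
Metropolis-within-Gibbs steps on an unconstrained scale.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import linalg

__all__ = [
    "draw_gaussian_from_precision",
    "update_scale",
    "AdaptiveScale",
    "halfnormal_logpdf",
    "logit",
    "inv_logit",
]


def draw_gaussian_from_precision(Q: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """One draw from N(Q^-1 b, Q^-1) using a Cholesky factor of Q."""
    u = linalg.cholesky(Q, lower=False, check_finite=False)
    mean = linalg.cho_solve((u, False), b, check_finite=False)
    z = rng.standard_normal(len(b))
    return mean + linalg.solve_triangular(u, z, lower=False, check_finite=False)


def halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0 or scale <= 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2 - math.log(scale)


def update_scale(
    cur: float, ss: float, count: int, hn_scale: float, rng
) -> float:
    """Metropolis update of a normal scale with a half-normal prior.

    The likelihood is that of ``count`` centred normal observations with
    summed squares ``ss``. Proposes the variance from the conjugate
    inverse-gamma, so the acceptance ratio reduces to the half-normal prior
    factor alone — this mixes well even when the posterior piles up near
    zero, where a log random walk stalls.
    """
    alpha = (count - 1) / 2.0
    ss = max(ss, 1e-300)
    if alpha <= 0:
        # A single observation: fall back to a prior-dominated log walk.
        prop = cur * math.exp(0.5 * rng.standard_normal())
        lp = (
            -count * math.log(prop)
            - 0.5 * ss / prop**2
            + halfnormal_logpdf(prop, hn_scale)
            + math.log(prop)
        ) - (
            -count * math.log(cur)
            - 0.5 * ss / cur**2
            + halfnormal_logpdf(cur, hn_scale)
            + math.log(cur)
        )
        return prop if math.log(rng.uniform()) < lp else cur
    v_prop = (ss / 2.0) / rng.gamma(alpha)
    log_acc = -(v_prop - cur**2) / (2.0 * hn_scale**2)
    if math.log(rng.uniform()) < log_acc:
        return math.sqrt(v_prop)
    return cur


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


class AdaptiveScale:
    """Robbins–Monro step-size adaptation toward a target acceptance rate.

    Adapts only while ``adapting`` is true (warm-up); frozen afterwards so
    the kept draws come from a fixed kernel.
    """

    def __init__(self, scale: float = 0.5, target: float = 0.35):
        self.log_scale = math.log(scale)
        self.target = target
        self._i = 0
        self.adapting = True

    @property
    def scale(self) -> float:
        return math.exp(self.log_scale)

    def update(self, accepted: bool) -> None:
        if not self.adapting:
            return
        self._i += 1
        step = 1.0 / math.sqrt(self._i)
        self.log_scale += step * ((1.0 if accepted else 0.0) - self.target)
        self.log_scale = min(max(self.log_scale, -10.0), 5.0)
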