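"""Posterior draw container with summaries and convergence reporting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import ess, rhat

__all__ = ["PosteriorSummary"]

RHAT_THRESHOLD = 1.1


@dataclass
class PosteriorSummary:
    """Draws per parameter (chains x kept iterations) plus diagnostics."""

    draws: dict  # name -> ndarray (m, n)
    flags: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rhat = {k: rhat(v) for k, v in self.draws.items()}
        self.converged = all(r <= RHAT_THRESHOLD for r in self._rhat.values())
        if not self.converged:
            bad = [k for k, r in self._rhat.items() if r > RHAT_THRESHOLD]
            self.flags = list(self.flags) + ["non_converged"]
            warnings.warn(
                f"R-hat above {RHAT_THRESHOLD} for: {', '.join(sorted(bad))}",
                stacklevel=2,
            )

    def parameters(self) -> list:
        return list(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).ravel()

    def mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    def sd(self, name: str) -> float:
        return float(self.pooled(name).std(ddof=1))

    def ci(self, name: str, level: float = 0.95) -> tuple:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.pooled(name), [a, 1.0 - a])
        return float(lo), float(hi)

    def rhat_of(self, name: str) -> float:
        return self._rhat[name]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            lo, hi = self.ci(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.mean(name),
                    "sd": self.sd(name),
                    "q2.5": lo,
                    "q97.5": hi,
                    "rhat": self._rhat[name],
                    "ess": ess(arr),
                }
            )
        return pd.DataFrame(rows)
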