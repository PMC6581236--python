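"""Bird registry generation."""

from __future__ import annotations

import numpy as np

from .config import BirdRecord, PopulationConfig


def make_birds(
    n: int, seed: int, pop: PopulationConfig | None = None
) -> list[BirdRecord]:
    """Draw n birds from configurable normal laws; reproducible under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = pop or PopulationConfig()
    rng = np.random.default_rng(seed)
    freqs = rng.normal(pop.freq_mean_hz, pop.freq_sd_hz, size=n)
    tarsi = rng.normal(pop.tarsus_mean_mm, pop.tarsus_sd_mm, size=n)
    masses = rng.normal(pop.mass_mean_g, pop.mass_sd_g, size=n)
    return [
        BirdRecord(
            bird_id=f"B{i + 1:02d}",
            tarsus_mm=float(tarsi[i]),
            mass_g=float(masses[i]),
            solo_freq_hz=float(freqs[i]),
        )
        for i in range(n)
    ]
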