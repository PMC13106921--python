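"""Converting diversity to effective population size.

Under neutral equilibrium theta = 4 Ne mu with mu the mutation rate per
site per generation, so Ne = theta / (4 mu). Mutation rates are commonly
published per year; the per-generation rate is mu_per_year x generation
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError


@dataclass(frozen=True)
class RateSpec:
    """Mutation rate (substitutions/site/year) and generation time (years)."""

    mu_per_year: float
    generation_time: float

    def __post_init__(self) -> None:
        if self.mu_per_year <= 0 or self.generation_time <= 0:
            raise ParameterError(
                "mutation rate and generation time must both be positive"
            )

    @property
    def mu_per_generation(self) -> float:
        return self.mu_per_year * self.generation_time


def effective_population_size(theta: float, rates: RateSpec) -> float:
    """Ne = theta / (4 mu_per_generation); linear in theta."""
    if theta < 0:
        raise ParameterError(f"theta must be >= 0, got {theta}")
    return theta / (4.0 * rates.mu_per_generation)


def format_ne_k(ne: float) -> str:
    """Round half-up to the nearest thousand with a "k" suffix, e.g. "64 k"."""
    thousands = math.floor(ne / 1000.0 + 0.5)
    return f"{thousands} k"
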