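"""Post-hoc power for a two-sample MR design.

Uses the standard asymptotic non-centrality approximation: the z
statistic for the causal effect is approximately normal with mean
|effect|·sqrt(n·R²) for a continuous outcome, with an extra
case-fraction·(1−case-fraction) factor for a binary outcome analysed on
the log-odds scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ConfigError

__all__ = ["PowerSpec", "mr_power"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the power approximation.

    ``effect`` is the hypothesized causal effect: standardized for a
    continuous outcome, log-odds-ratio for a binary one.
    """

    n_outcome: int
    r2_gx: float
    effect: float
    alpha: float = 0.05
    outcome_type: str = "continuous"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_gx < 1.0):
            raise ConfigError(f"r2_gx must lie in (0, 1); got {self.r2_gx}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1); got {self.alpha}")
        if self.n_outcome < 1:
            raise ConfigError("n_outcome must be positive")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary":
            if self.case_fraction is None:
                raise ConfigError("binary outcome requires case_fraction")
            if not (0.0 < self.case_fraction < 1.0):
                raise ConfigError("case_fraction must lie in (0, 1)")


def mr_power(spec: PowerSpec) -> float:
    """Power of the two-sided alpha-level causal test under ``spec``."""
    ncp = abs(spec.effect) * math.sqrt(spec.n_outcome * spec.r2_gx)
    if spec.outcome_type == "binary":
        ncp *= math.sqrt(spec.case_fraction * (1.0 - spec.case_fraction))
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))
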