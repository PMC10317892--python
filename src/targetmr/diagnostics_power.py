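"""Statistical power for two-sample MR with a binary outcome.

Uses the asymptotic standard error of the IVW ratio estimate with a binary
outcome on the log-odds scale,

    se_inf = 1 / sqrt(N * r2 * phi * (1 - phi)),

where N is total outcome sample size, phi the case fraction and r2 the
variance of the exposure explained by the instrument. Power at a true odds
ratio uses the one-tailed rejection approximation

    power = Phi(|log OR| / se_inf - z_{1-alpha/2}),

which ignores the negligible far-tail rejection mass (the convention for MR
power calculators; exact two-tailed power available via ``two_tailed=True``).
Under this convention power at OR = 1 equals alpha/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class PowerSpec:
    """Outcome sample composition, instrument strength and design levels."""

    n_cases: int
    n_controls: int
    r2: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target_power must lie in (0, 1)")

    @property
    def se_asymptotic(self) -> float:
        n = self.n_cases + self.n_controls
        phi = self.n_cases / n
        return 1.0 / np.sqrt(n * self.r2 * phi * (1 - phi))


def mr_power_binary(spec: PowerSpec, odds_ratio: float,
                    two_tailed: bool = False) -> float:
    """Power to detect ``odds_ratio`` at the spec's alpha."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    b = abs(np.log(odds_ratio))
    z_crit = norm.ppf(1 - spec.alpha / 2)
    shift = b / spec.se_asymptotic
    power = norm.cdf(shift - z_crit)
    if two_tailed:
        power += norm.cdf(-shift - z_crit)
    return float(power)


def detectable_or(spec: PowerSpec) -> tuple[float, float]:
    """(OR above 1, OR below 1) detectable at the spec's target power.

    Inverts the power formula: |log OR| = (z_{1-alpha/2} + z_power) * se_inf.
    """
    b = (norm.ppf(1 - spec.alpha / 2)
         + norm.ppf(spec.target_power)) * spec.se_asymptotic
    return float(np.exp(b)), float(np.exp(-b))
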