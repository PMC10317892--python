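"""Bayesian colocalisation of two traits via Wakefield approximate Bayes
factors.

Under a normal prior N(0, W) on a variant's true effect and sampling model
N(beta_hat; beta, V), the Bayes factor against the null has the closed form

    log ABF = 0.5*log(1 - r) + z^2 * r / 2,   r = W/(V+W), z = beta_hat/se.

Assuming at most one causal variant per trait in the region, the five
configuration hypotheses are H0 (no association), H1/H2 (only trait 1/2),
H3 (both, distinct variants) and H4 (both, one shared variant). Posterior
probabilities follow from per-variant ABFs and per-configuration priors
p1, p2, p12; all accumulation is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

#: established effect-size prior SDs: quantitative traits on a standardised
#: scale, binary traits on the log-odds scale
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.20

#: posterior probability above which a configuration is called 'supported'
SUPPORT_THRESHOLD = 0.50

DEFAULT_P12_GRID = (1e-5, 5e-6, 5e-5)


class AlignmentError(ValueError):
    """The two traits' variant sets are not aligned."""


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant configuration priors.

    p1/p2: probability a variant associates with trait 1/2 only;
    p12: probability it associates with both.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (self.p1 > 0 and self.p2 > 0):
            raise ValueError("p1 and p2 must be positive")
        if self.p12 < 0:
            raise ValueError("p12 must be non-negative")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")

    def check_region_size(self, m: int) -> None:
        import warnings
        if m * (self.p1 + self.p2 + self.p12) >= 1:
            warnings.warn(
                f"priors sum to >= 1 over {m} variants; posteriors may be "
                "distorted", stacklevel=2)


@dataclass
class RegionalDataset:
    """One trait's per-variant estimates over a region, aligned by id order."""

    trait_name: str
    trait_type: str  # 'binary' | 'quantitative'
    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        m = len(self.variant_ids)
        if not (self.beta.size == self.se.size == m):
            raise ValueError("beta/se length mismatch with variant ids")
        if np.any(self.se <= 0):
            raise ValueError("SEs must be positive")
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    @property
    def default_prior_sd(self) -> float:
        return (PRIOR_SD_BINARY if self.trait_type == "binary"
                else PRIOR_SD_QUANTITATIVE)


@dataclass
class ColocResult:
    """Five-configuration posterior with its priors and diagnostics."""

    pp: np.ndarray  # PP0..PP4
    n_variants: int
    priors: ColocPriors
    log_abf_sums: dict[str, float]
    label_a: str = "marginal"
    label_b: str = "marginal"

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("pp must have five entries")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def supported(self) -> int | None:
        """Index of the supported hypothesis (posterior > 50%), if any."""
        best = int(np.argmax(self.pp))
        return best if self.pp[best] > SUPPORT_THRESHOLD else None

    def as_dict(self) -> dict[str, float]:
        return {f"pp{i}": float(p) for i, p in enumerate(self.pp)}


def log_abf_wakefield(beta: np.ndarray, se: np.ndarray,
                      prior_sd: float) -> np.ndarray:
    """Per-variant log approximate Bayes factor against the null."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    z = beta / se
    return 0.5 * np.log1p(-r) + (z ** 2) * r / 2.0


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b; -inf when they cancel."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    data1: RegionalDataset,
    data2: RegionalDataset,
    priors: ColocPriors | None = None,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
    label_a: str = "marginal",
    label_b: str = "marginal",
) -> ColocResult:
    """Five-hypothesis posterior for one region.

    With per-variant logABF vectors a (trait 1) and b (trait 2):

        L0 = 1
        L1 = p1 * sum_i e^{a_i}
        L2 = p2 * sum_i e^{b_i}
        L3 = p1*p2 * (sum_i e^{a_i} * sum_j e^{b_j} - sum_i e^{a_i+b_i})
        L4 = p12 * sum_i e^{a_i+b_i}

    PPk = Lk / sum(L), evaluated with log-sum-exp throughout. PP3 is exactly
    zero for a single-variant region (the subtraction cancels) and PP4 is
    exactly zero when p12 = 0.
    """
    if data1.variant_ids != data2.variant_ids:
        raise AlignmentError("variant ids differ between the two traits")
    if priors is None:
        priors = ColocPriors()
    m = len(data1.variant_ids)
    if m < 1:
        raise AlignmentError("no shared variants")
    priors.check_region_size(m)

    sd1 = prior_sd1 if prior_sd1 is not None else data1.default_prior_sd
    sd2 = prior_sd2 if prior_sd2 is not None else data2.default_prior_sd
    a = log_abf_wakefield(data1.beta, data1.se, sd1)
    b = log_abf_wakefield(data2.beta, data2.se, sd2)

    lse_a = float(logsumexp(a))
    lse_b = float(logsumexp(b))
    lse_ab = float(logsumexp(a + b))

    log_l = np.empty(5)
    log_l[0] = 0.0
    log_l[1] = np.log(priors.p1) + lse_a
    log_l[2] = np.log(priors.p2) + lse_b
    log_l[3] = (np.log(priors.p1) + np.log(priors.p2)
                + _log_diff_exp(lse_a + lse_b, lse_ab))
    log_l[4] = (np.log(priors.p12) + lse_ab if priors.p12 > 0 else -np.inf)

    log_total = logsumexp(log_l)
    pp = np.exp(log_l - log_total)
    return ColocResult(
        pp=pp, n_variants=m, priors=priors,
        log_abf_sums={"trait1": lse_a, "trait2": lse_b, "joint": lse_ab},
        label_a=label_a, label_b=label_b)


def prior_sensitivity(
    data1: RegionalDataset,
    data2: RegionalDataset,
    p12_grid: tuple[float, ...] = DEFAULT_P12_GRID,
    p1: float = 1e-4,
    p2: float = 1e-4,
    **kwargs,
) -> list[ColocResult]:
    """Re-run colocalisation over a grid of p12 values at fixed p1/p2."""
    if not p12_grid:
        raise ValueError("p12 grid is empty")
    return [coloc_abf(data1, data2, ColocPriors(p1, p2, p12), **kwargs)
            for p12 in p12_grid]
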