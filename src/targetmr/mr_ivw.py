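"""Inverse-variance-weighted MR for correlated instruments.

With exposure effects omega, outcome effects gamma and outcome SEs s over k
variants with LD correlation R, the causal slope is the generalised
least-squares fit of gamma on omega under Sigma_ij = s_i s_j R_ij:

    beta = (omega' Sigma^-1 omega)^-1 omega' Sigma^-1 gamma

Overdispersion (multiplicative random effects) scales the variance by
phi = max(1, residual dispersion with denominator k-1); flooring at 1 is the
fixed-effects-equivalent behaviour when estimates are under-dispersed.
A single variant reduces exactly to the Wald ratio. Evidence labelling uses
the Bonferroni heuristic: 'strong' below alpha/n_tests, 'weak' below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gwas_io import IllConditionedLDError, LDMatrix
from .instruments import Instrument

#: condition-number ceiling for the outcome covariance; weak-LD instruments
#: (pairwise r^2 < 0.2) stay far below it, so exceeding it flags bad input
CONDITION_LIMIT = 1e12

DEFAULT_N_TESTS = 27
DEFAULT_ALPHA = 0.05


class EmptyInstrumentError(ValueError):
    pass


class InsufficientVariantsError(ValueError):
    pass


@dataclass
class MRResult:
    """Causal estimate of one target-outcome analysis."""

    target: str
    outcome: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    phi: float        # overdispersion multiplier applied (>= 1)
    phi_raw: float    # unfloored estimate (nan for k = 1)
    k: int
    model: str        # 're_floored' | 'fe'
    omitted_variant: str | None = None

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) on the exponentiated scale."""
        return (float(np.exp(self.beta)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))


def wald_ratio(exposure_beta: float, outcome_beta: float,
               outcome_se: float) -> tuple[float, float]:
    """Single-variant ratio estimate with first-order delta-method SE."""
    if exposure_beta == 0:
        raise ZeroDivisionError("undefined ratio: exposure beta is zero")
    return (outcome_beta / exposure_beta,
            outcome_se / abs(exposure_beta))


def ivw_correlated(
    omega: np.ndarray,
    gamma: np.ndarray,
    se_out: np.ndarray,
    ld: LDMatrix,
    target: str = "",
    outcome: str = "",
    use_t: bool = False,
) -> MRResult:
    """GLS IVW estimate with LD-aware weights and overdispersion floor.

    ``use_t`` switches CI/p quantiles from normal to t with k-1 df
    (normal is the default convention).
    """
    omega = np.asarray(omega, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    k = omega.size
    if k == 0:
        raise EmptyInstrumentError("no variants")
    if not (gamma.size == se_out.size == k == len(ld)):
        raise ValueError("length mismatch between effects, SEs and LD")
    if np.any(se_out <= 0):
        raise ValueError("outcome SEs must be positive")

    if k == 1:
        beta, se = wald_ratio(float(omega[0]), float(gamma[0]),
                              float(se_out[0]))
        phi_raw = float("nan")
        phi = 1.0
        model = "fe"
    else:
        sigma = np.outer(se_out, se_out) * ld.r
        cond = np.linalg.cond(sigma)
        if not np.isfinite(cond) or cond > CONDITION_LIMIT:
            raise IllConditionedLDError(
                f"outcome covariance condition number {cond:.3g} exceeds "
                f"{CONDITION_LIMIT:g}")
        sig_inv_omega = np.linalg.solve(sigma, omega)
        sig_inv_gamma = np.linalg.solve(sigma, gamma)
        var_fe = 1.0 / float(omega @ sig_inv_omega)
        beta = var_fe * float(omega @ sig_inv_gamma)
        resid = gamma - omega * beta
        phi_raw = float(resid @ np.linalg.solve(sigma, resid)) / (k - 1)
        phi = max(1.0, phi_raw)
        model = "re_floored" if phi_raw > 1.0 else "fe"
        se = float(np.sqrt(phi * var_fe))

    if use_t and k > 1:
        q = stats.t.ppf(0.975, df=k - 1)
        pval = float(2 * stats.t.sf(abs(beta / se), df=k - 1))
    else:
        q = stats.norm.ppf(0.975)
        pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MRResult(
        target=target, outcome=outcome, beta=float(beta), se=se,
        ci_low=float(beta - q * se), ci_high=float(beta + q * se),
        pval=max(pval, np.finfo(float).tiny), phi=phi, phi_raw=phi_raw,
        k=k, model=model)


def mr_instrument(
    instrument: Instrument,
    gamma: np.ndarray,
    se_out: np.ndarray,
    outcome: str = "",
    use_t: bool = False,
) -> MRResult:
    """IVW fit of an :class:`~targetmr.instruments.Instrument` against
    harmonised outcome effects (aligned to the instrument's effect alleles).

    Under 'lowering' orientation exposure and outcome betas are jointly
    negated, so the slope reads per 1-unit biomarker lowering.
    """
    sign = -1.0 if instrument.orientation == "lowering" else 1.0
    return ivw_correlated(
        instrument.exposure_betas, sign * np.asarray(gamma, dtype=float),
        se_out, instrument.ld, target=instrument.target, outcome=outcome,
        use_t=use_t)


def leave_one_out(
    omega: np.ndarray,
    gamma: np.ndarray,
    se_out: np.ndarray,
    ld: LDMatrix,
    target: str = "",
    outcome: str = "",
) -> list[MRResult]:
    """One IVW refit per omitted variant, annotated with the omitted id."""
    omega = np.asarray(omega, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    k = omega.size
    if k < 2:
        raise InsufficientVariantsError("leave-one-out needs k >= 2")
    results = []
    for i in range(k):
        keep = [j for j in range(k) if j != i]
        ids = [ld.variant_ids[j] for j in keep]
        res = ivw_correlated(omega[keep], gamma[keep], se_out[keep],
                             ld.submatrix(ids), target=target,
                             outcome=outcome)
        res.omitted_variant = ld.variant_ids[i]
        results.append(res)
    return results


def evidence_label(pval: float, n_tests: int = DEFAULT_N_TESTS,
                   alpha: float = DEFAULT_ALPHA) -> str:
    """Bonferroni evidence heuristic: 'strong' | 'weak' | 'none'."""
    if not (0 < pval <= 1):
        raise ValueError("p-value must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    if pval < threshold:
        return "strong"
    if pval < alpha:
        return "weak"
    return "none"
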