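"""Synthetic cis-region GWAS data with block or autoregressive LD.

Generates individual-level genotypes and the derived marginal summary
statistics so that every analysis stage (instrument construction, IVW,
colocalisation, conditional analysis) is testable without consortium data.

Genotypes: each variant's two haplotype alleles are Bernoulli(MAF)
indicators obtained by thresholding a latent Gaussian vector, giving
Hardy-Weinberg genotypes in {0,1,2}. Because thresholding attenuates
correlation, latent pairwise correlations are tetrachorically adjusted
(via the Owen's-T bivariate-normal CDF) so the realized dosage Pearson LD
matches the requested target matrix.

Phenotypes: quantitative traits are linear in genotype with residual noise
chosen so the trait has unit variance (IRNT-like scale); binary traits use
a liability threshold at the configured prevalence, with marginal per-variant
effects reported as log-odds from logistic fits, so binary summary
statistics carry realistic finite-sample noise. Exposure and outcome cohorts
are always non-overlapping draws.

Causal architectures cover the five colocalisation configurations plus MR
scenarios (a causal slope routing outcome effects through the exposure's
variants, optionally with one directly pleiotropic variant). Default effect
magnitudes are drawn from the per-allele ranges observed for type 2
diabetes / HbA1c drug-target loci: log-odds in [0.026, 0.140] and
biomarker (variance-1 trait) effects in [0.004, 0.035].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm

from .gwas_io import (GenotypeDosageMatrix, LDMatrix, SummaryStatRecord,
                      SummaryStatsTable, compute_ld)

#: per-allele effect ranges matching the published instrument table
LOG_ODDS_RANGE = (0.026, 0.140)
BIOMARKER_RANGE = (0.004, 0.035)

DEFAULT_PREVALENCE = 0.10
DEFAULT_MAF_RANGE = (0.05, 0.5)

SCENARIOS = ("H0", "H1", "H2", "H3", "H4",
             "mr-null", "mr-causal", "pleiotropy-one-snp")


@dataclass(frozen=True)
class AR1:
    """First-order autoregressive LD: r_ij = rho^|i-j|."""
    rho: float

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class Blocks:
    """Constant within-block correlation, independence across blocks."""
    sizes: tuple[int, ...]
    rho: float

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if any(s < 1 for s in self.sizes):
            raise ValueError("block sizes must be positive")


LDStructure = Union[AR1, Blocks]


def simulate_ld(m: int, structure: LDStructure) -> np.ndarray:
    """Target correlation matrix for ``m`` variants (PSD by construction)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if isinstance(structure, AR1):
        idx = np.arange(m)
        return structure.rho ** np.abs(idx[:, None] - idx[None, :])
    if sum(structure.sizes) != m:
        raise ValueError("block sizes must sum to m")
    r = np.zeros((m, m))
    start = 0
    for size in structure.sizes:
        r[start:start + size, start:start + size] = structure.rho
        start += size
    np.fill_diagonal(r, 1.0)
    return r


@dataclass(frozen=True)
class SimulationConfig:
    """Fully specified generating model for one cis region.

    ``exposure_causal`` maps variant index -> per-allele effect on the
    exposure (liability scale for binary exposures). ``outcome_direct`` maps
    variant index -> direct (pleiotropic) effect on the outcome.
    ``causal_slope`` routes the exposure into the outcome, so a variant's
    total outcome effect is slope * exposure effect + direct effect.
    """

    seed: int
    m_variants: int
    ld_structure: LDStructure
    n_exposure: int
    n_outcome: int
    exposure_type: str = "quantitative"   # 'binary-liability'|'quantitative'
    outcome_type: str = "quantitative"
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE
    exposure_causal: dict[int, float] = field(default_factory=dict)
    outcome_direct: dict[int, float] = field(default_factory=dict)
    causal_slope: float = 0.0
    prevalence: float = DEFAULT_PREVALENCE
    scenario: str = "custom"

    def __post_init__(self) -> None:
        if self.m_variants < 1:
            raise ValueError("need at least one variant")
        if min(self.n_exposure, self.n_outcome) < 100:
            raise ValueError("cohort sizes must be >= 100")
        for t in (self.exposure_type, self.outcome_type):
            if t not in ("binary-liability", "quantitative"):
                raise ValueError(f"unknown trait type {t!r}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for idx in list(self.exposure_causal) + list(self.outcome_direct):
            if not (0 <= idx < self.m_variants):
                raise ValueError(f"causal index {idx} outside region")


@dataclass
class SimulatedRegion:
    """One draw of the region: truth, summary tables and sample LD."""

    config: SimulationConfig
    truth: dict
    exposure_stats: SummaryStatsTable
    outcome_stats: SummaryStatsTable
    ld: LDMatrix
    genotypes: GenotypeDosageMatrix | None = None
    exposure_phenotype: np.ndarray | None = None


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal via Owen's T."""
    if abs(rho) < 1e-14:
        return norm.cdf(h) * norm.cdf(k)
    if abs(rho) > 1 - 1e-12:
        rho = np.sign(rho) * (1 - 1e-12)
    hh = h if abs(h) > 1e-10 else 1e-10
    kk = k if abs(k) > 1e-10 else 1e-10
    denom = np.sqrt(1 - rho * rho)
    a_h = (kk - rho * hh) / (hh * denom)
    a_k = (hh - rho * kk) / (kk * denom)
    beta = 0.5 if hh * kk < 0 else 0.0
    return float(norm.cdf(hh) / 2 + norm.cdf(kk) / 2
                 - owens_t(hh, a_h) - owens_t(kk, a_k) - beta)


def _latent_rho(target_r: float, p_i: float, p_j: float) -> float:
    """Latent Gaussian correlation whose thresholded Bernoulli indicators
    at frequencies p_i, p_j have Pearson correlation ``target_r``."""
    if target_r == 0.0:
        return 0.0
    h, k = norm.ppf(p_i), norm.ppf(p_j)
    sd = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    target_cov = target_r * sd

    def gap(rho: float) -> float:
        return _bvn_cdf(h, k, rho) - p_i * p_j - target_cov

    lo, hi = -0.9999, 0.9999
    if gap(hi) < 0:     # target unreachable; saturate
        return hi
    if gap(lo) > 0:
        return lo
    return float(brentq(gap, lo, hi, xtol=1e-10))


class RegionSimulator:
    """Precomputes the latent copula for a config; cheap repeated draws.

    The region (MAFs, target LD, causal truth) is fixed by the config seed;
    :meth:`simulate` draws fresh non-overlapping exposure and outcome
    cohorts, so replicate loops re-sample cohorts over a constant region.
    """

    def __init__(self, config: SimulationConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        m = config.m_variants
        lo, hi = config.maf_range
        self.maf = rng.uniform(lo, hi, size=m)
        self.target_r = simulate_ld(m, config.ld_structure)
        latent = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                latent[i, j] = latent[j, i] = _latent_rho(
                    self.target_r[i, j], self.maf[i], self.maf[j])
        # adjustment can break PSD: clip eigenvalues, restore unit diagonal
        lam, vec = np.linalg.eigh(latent)
        if lam[0] < 1e-10:
            latent = (vec * np.clip(lam, 1e-10, None)) @ vec.T
            d = np.sqrt(np.diag(latent))
            latent = latent / np.outer(d, d)
        self._chol = np.linalg.cholesky(latent)
        self._thresholds = norm.ppf(self.maf)
        self.variant_ids = [f"sv{i + 1}" for i in range(m)]
        self.positions = [1_000_000 + 5_000 * i for i in range(m)]
        self._resample_log: list[str] = []

    # -- genotype and phenotype machinery -------------------------------

    def _draw_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        m = self.config.m_variants
        g = np.zeros((n, m))
        for _hap in range(2):
            z = rng.standard_normal((n, m)) @ self._chol.T
            g += z < self._thresholds
        # guard: a monomorphic column breaks per-variant regression
        for attempt in range(5):
            mono = np.flatnonzero(g.std(axis=0) == 0)
            if mono.size == 0:
                break
            self._resample_log.append(
                f"resampled monomorphic column(s) {mono.tolist()}")
            z1 = rng.standard_normal((n, mono.size))
            z2 = rng.standard_normal((n, mono.size))
            g[:, mono] = ((z1 < self._thresholds[mono]).astype(float)
                          + (z2 < self._thresholds[mono]))
        return g

    def _phenotype(self, g: np.ndarray, betas: dict[int, float],
                   extra: np.ndarray | None, slope: float,
                   rng: np.random.Generator) -> np.ndarray:
        """Continuous trait/liability ~ genotype effects (+ slope * upstream
        trait), residual scaled towards unit total variance."""
        n = g.shape[0]
        genetic = np.zeros(n)
        var_g = 0.0
        if betas:
            idx = np.fromiter(betas.keys(), dtype=int)
            b = np.fromiter(betas.values(), dtype=float)
            centred = g[:, idx] - g[:, idx].mean(axis=0)
            genetic = centred @ b
            var_g = float(np.var(genetic))
        upstream = slope * extra if extra is not None else 0.0
        var_up = slope ** 2 if extra is not None else 0.0
        resid_var = max(1.0 - var_g - var_up, 0.05)
        return genetic + upstream + rng.standard_normal(n) * np.sqrt(resid_var)

    @staticmethod
    def _marginal_linear(g: np.ndarray, y: np.ndarray):
        """Vectorised per-variant simple linear regression."""
        n = g.shape[0]
        gc = g - g.mean(axis=0)
        yc = y - y.mean()
        sxx = np.einsum("ij,ij->j", gc, gc)
        sxy = gc.T @ yc
        beta = sxy / sxx
        syy = float(yc @ yc)
        sse = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(sse / (n - 2) / sxx)
        z = beta / se
        pval = 2 * norm.sf(np.abs(z))
        return beta, se, np.maximum(pval, 1e-300)

    @staticmethod
    def _marginal_logistic(g: np.ndarray, y: np.ndarray,
                           max_iter: int = 25, tol: float = 1e-10):
        """Vectorised per-variant logistic regression (intercept + dosage),
        Newton-Raphson run for all variants simultaneously."""
        n, m = g.shape
        ybar = y.mean()
        a = np.full(m, np.log(ybar / (1 - ybar)))
        b = np.zeros(m)
        for _ in range(max_iter):
            eta = a[None, :] + g * b[None, :]
            p = 1.0 / (1.0 + np.exp(-eta))
            resid = y[:, None] - p
            grad_a = resid.sum(axis=0)
            grad_b = np.einsum("ij,ij->j", g, resid)
            w = p * (1.0 - p)
            saa = w.sum(axis=0)
            sab = np.einsum("ij,ij->j", w, g)
            sbb = np.einsum("ij,ij,ij->j", w, g, g)
            det = saa * sbb - sab ** 2
            da = (sbb * grad_a - sab * grad_b) / det
            db = (saa * grad_b - sab * grad_a) / det
            a += da
            b += db
            if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
                break
        eta = a[None, :] + g * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        saa = w.sum(axis=0)
        sab = np.einsum("ij,ij->j", w, g)
        sbb = np.einsum("ij,ij,ij->j", w, g, g)
        se = np.sqrt(saa / (saa * sbb - sab ** 2))
        z = b / se
        pval = 2 * norm.sf(np.abs(z))
        return b, se, np.maximum(pval, 1e-300)

    def _summary_table(self, g: np.ndarray, y: np.ndarray, trait_name: str,
                       trait_type: str, binary: bool) -> SummaryStatsTable:
        n = g.shape[0]
        if binary:
            beta, se, pval = self._marginal_logistic(g, y)
            n_cases = int(y.sum())
        else:
            beta, se, pval = self._marginal_linear(g, y)
            n_cases = None
        eaf = g.mean(axis=0) / 2.0
        records = [
            SummaryStatRecord(
                variant_id=self.variant_ids[j], chrom="1",
                pos=self.positions[j], ea="A", nea="G",
                eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
                pval=float(pval[j]), n=n, n_cases=n_cases)
            for j in range(g.shape[1])
        ]
        return SummaryStatsTable(trait_name, trait_type, records)

    # -- public API ------------------------------------------------------

    def simulate(self, rng: np.random.Generator | None = None,
                 keep_genotypes: bool = False) -> SimulatedRegion:
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(cfg.seed + 1)

        results = {}
        g_exp = self._draw_genotypes(cfg.n_exposure, rng)
        exp_binary = cfg.exposure_type == "binary-liability"
        liab_exp = self._phenotype(g_exp, cfg.exposure_causal, None, 0.0, rng)
        y_exp = ((liab_exp > norm.ppf(1 - cfg.prevalence)).astype(float)
                 if exp_binary else liab_exp)
        results["exposure"] = self._summary_table(
            g_exp, y_exp, "exposure",
            "binary" if exp_binary else "quantitative", exp_binary)

        g_out = self._draw_genotypes(cfg.n_outcome, rng)
        out_binary = cfg.outcome_type == "binary-liability"
        # outcome liability: direct variant effects plus the causal route
        # through the exposure trait realised in the outcome cohort
        x_in_outcome = self._phenotype(g_out, cfg.exposure_causal, None,
                                       0.0, rng)
        liab_out = self._phenotype(g_out, cfg.outcome_direct, x_in_outcome,
                                   cfg.causal_slope, rng)
        y_out = ((liab_out > norm.ppf(1 - cfg.prevalence)).astype(float)
                 if out_binary else liab_out)
        results["outcome"] = self._summary_table(
            g_out, y_out, "outcome",
            "binary" if out_binary else "quantitative", out_binary)

        ld = compute_ld(GenotypeDosageMatrix(
            [f"s{i}" for i in range(cfg.n_exposure)], self.variant_ids,
            g_exp))
        truth = {
            "scenario": cfg.scenario,
            "causal_slope": cfg.causal_slope,
            "exposure_causal": {self.variant_ids[i]: b
                                for i, b in cfg.exposure_causal.items()},
            "outcome_direct": {self.variant_ids[i]: b
                               for i, b in cfg.outcome_direct.items()},
            "maf": dict(zip(self.variant_ids, self.maf.tolist())),
        }
        genotypes = (GenotypeDosageMatrix(
            [f"s{i}" for i in range(cfg.n_exposure)], self.variant_ids,
            g_exp) if keep_genotypes else None)
        return SimulatedRegion(
            config=cfg, truth=truth,
            exposure_stats=results["exposure"],
            outcome_stats=results["outcome"],
            ld=ld, genotypes=genotypes,
            exposure_phenotype=y_exp if keep_genotypes else None)


def simulate_region(config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    keep_genotypes: bool = False) -> SimulatedRegion:
    """One-shot convenience wrapper around :class:`RegionSimulator`."""
    return RegionSimulator(config).simulate(rng, keep_genotypes)


def _z_to_beta(z: float, n: int, maf: float) -> float:
    """Per-allele effect on a variance-1 trait giving expected z at n."""
    return z / np.sqrt(n * 2 * maf * (1 - maf))


def make_scenario(name: str, seed: int) -> SimulationConfig:
    """Deterministic preset configs for the standard study conditions.

    Colocalisation scenarios (H0-H4) use 50-variant regions with AR(1)
    LD (rho 0.6) and 50,000-sample cohorts (20,000 under the null); causal
    variants are placed mid-region with effects sized for a per-trait
    z of ~8. MR scenarios use 5 instrument variants in weak AR(1) LD
    (rho 0.3), a 400,000-sample biomarker-scale exposure GWAS and a
    100,000-sample outcome cohort with true slope 0.5 (0 for mr-null);
    the pleiotropy scenario adds one variant with a direct outcome effect.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; one of {SCENARIOS}")
    rng = np.random.default_rng(seed)

    if name in ("H0", "H1", "H2", "H3", "H4"):
        m = 50
        n = 20_000 if name == "H0" else 50_000
        maf_causal = 0.30
        beta = _z_to_beta(8.0, n, maf_causal)
        exposure_causal: dict[int, float] = {}
        outcome_direct: dict[int, float] = {}
        if name in ("H1", "H4"):
            exposure_causal = {25: beta}
        if name == "H2":
            outcome_direct = {25: beta}
        if name == "H4":
            outcome_direct = {25: beta}
        if name == "H3":
            # distinct causal variants; AR(1) 0.6^30 makes their r^2 < 0.05
            exposure_causal = {10: beta}
            outcome_direct = {40: beta}
        return SimulationConfig(
            seed=seed, m_variants=m, ld_structure=AR1(0.6),
            n_exposure=n, n_outcome=n,
            maf_range=(maf_causal, maf_causal + 0.15),
            exposure_causal=exposure_causal, outcome_direct=outcome_direct,
            causal_slope=0.0, scenario=name)

    # MR scenarios: 5 instrument variants, strong biomarker-scale effects
    m = 5
    slopes = {"mr-null": 0.0, "mr-causal": 0.5, "pleiotropy-one-snp": 0.5}
    betas = rng.uniform(0.020, 0.035, size=m) * rng.choice([-1, 1], size=m)
    exposure_causal = dict(enumerate(betas.tolist()))
    outcome_direct = {}
    if name == "pleiotropy-one-snp":
        outcome_direct = {m - 1: 0.05}   # direct effect bypassing exposure
    return SimulationConfig(
        seed=seed, m_variants=m, ld_structure=AR1(0.3),
        n_exposure=400_000, n_outcome=100_000,
        maf_range=(0.15, 0.5),
        exposure_causal=exposure_causal, outcome_direct=outcome_direct,
        causal_slope=slopes[name], scenario=name)


def make_secondary_sharing_config(seed: int, n: int = 50_000
                                  ) -> SimulationConfig:
    """Region where trait 1 carries two conditionally independent signals
    and trait 2 shares only the secondary one.

    Trait 1: strong causal at variant 10 (z ~ 12) plus a secondary causal at
    variant 30 (z ~ 9); trait 2: causal at variant 30 only. The marginal
    pair therefore fails to colocalise while the pair conditioning trait 1
    on its primary signal does — the case pairwise conditional
    colocalisation exists to detect.
    """
    m = 40
    maf = 0.30
    return SimulationConfig(
        seed=seed, m_variants=m, ld_structure=AR1(0.5),
        n_exposure=n, n_outcome=n, maf_range=(maf, maf + 0.15),
        exposure_causal={10: _z_to_beta(12.0, n, maf),
                         30: _z_to_beta(9.0, n, maf)},
        outcome_direct={30: _z_to_beta(9.0, n, maf)},
        causal_slope=0.0, scenario="secondary-sharing")
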