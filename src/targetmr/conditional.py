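"""Summary-level conditional analysis and pairwise conditional colocalisation.

Individual-level regression moments are reconstructed from marginal summary
statistics, allele frequencies, sample size and reference LD:

    (X'X)_jk ~= n * sqrt(v_j v_k) * r_jk,   v_j = 2*eaf_j*(1-eaf_j)
    (X'y)_j  ~= n * v_j * beta_j

with phenotypic variance 1 (IRNT scale). Joint fits over a variant subset
then follow from partitioned least squares; the residual variance is refit
from the median per-variant implied y'y. Stepwise selection adds the variant
with the smallest conditional p below the entry threshold each round
(collinearity-guarded), yielding conditionally independent signals; pairwise
conditional colocalisation (pwCoCo) then runs colocalisation across every
marginal/conditional dataset pair of two traits.

Binary traits are conditioned on the log-odds scale with effective sample
size n_eff = 4/(1/n_cases + 1/n_controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .coloc_abf import ColocPriors, ColocResult, RegionalDataset, coloc_abf
from .gwas_io import LDMatrix, SummaryStatsTable

DEFAULT_P_ENTRY = 5e-8
DEFAULT_COLLINEARITY_R2 = 0.9

#: relative floor on the refit residual variance, guarding degenerate input
_SIGMA2_FLOOR = 1e-12


class ConditioningError(ValueError):
    """Reconstructed design is ill-conditioned or inconsistent."""


@dataclass(frozen=True)
class ConditionalSignal:
    """A conditionally independent index variant with its joint-model
    effect (conditional on the other selected indices)."""

    index_variant: str
    joint_beta: float
    joint_se: float
    joint_pval: float
    selection_order: int


@dataclass
class ConditionalDataset:
    """Per-variant effects adjusted for a conditioning set.

    ``conditioning_set`` empty means the marginal dataset. Variants inside
    the conditioning set carry beta 0 (no residual association) with their
    marginal SE retained.
    """

    trait_name: str
    trait_type: str
    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    conditioning_set: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        if not self.conditioning_set:
            return "marginal"
        return "conditional-on:" + "+".join(self.conditioning_set)

    def to_regional(self) -> RegionalDataset:
        return RegionalDataset(self.trait_name, self.trait_type,
                               list(self.variant_ids),
                               np.asarray(self.beta), np.asarray(self.se))


def effective_sample_size(n: int, n_cases: int | None) -> float:
    """n for quantitative traits; 4/(1/cases + 1/controls) for binary."""
    if n_cases is None:
        return float(n)
    n_controls = n - n_cases
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("binary trait needs positive case and control counts")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def _moments(stats: SummaryStatsTable, ld: LDMatrix, n: float):
    """(variant ids, X'X, X'y, median implied y'y) for the region."""
    ids = stats.variant_ids
    sub = ld.submatrix(ids)
    eaf = np.array([r.eaf for r in stats.records])
    beta = np.array([r.beta for r in stats.records])
    se = np.array([r.se for r in stats.records])
    v = 2.0 * eaf * (1.0 - eaf)
    if np.any(v <= 0):
        bad = [i for i, vv in zip(ids, v) if vv <= 0]
        raise ConditioningError(f"fixed variant(s) in region: {bad}")
    sqrt_d = np.sqrt(n * v)
    xtx = np.outer(sqrt_d, sqrt_d) * sub.r
    xty = n * v * beta
    # implied phenotype sum of squares per variant, from the marginal fit
    yty_j = n * v * beta ** 2 + se ** 2 * (n * v) * (n - 2)
    return ids, xtx, xty, float(np.median(yty_j))


def _joint_fit(xtx: np.ndarray, xty: np.ndarray, yty: float, n: float,
               idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Joint coefficients and SEs for design columns ``idx``."""
    sub_xtx = xtx[np.ix_(idx, idx)]
    sub_xty = xty[idx]
    cond = np.linalg.cond(sub_xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise ConditioningError(
            f"reconstructed design condition number {cond:.3g}")
    coef = np.linalg.solve(sub_xtx, sub_xty)
    dof = n - len(idx) - 1
    if dof <= 0:
        raise ConditioningError("sample size too small for conditioning set")
    sigma2 = max((yty - float(coef @ sub_xty)) / dof, _SIGMA2_FLOOR * yty / n)
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(sub_xtx)))
    return coef, se


def conditional_stats(
    stats: SummaryStatsTable,
    ld: LDMatrix,
    n: float,
    conditioning_set: list[str],
) -> ConditionalDataset:
    """Per-variant effects adjusted for ``conditioning_set``.

    An empty set is the identity on (beta, se). Each remaining variant's
    conditional estimate is its coefficient in the joint fit with the
    conditioning variants.
    """
    ids, xtx, xty, yty = _moments(stats, ld, n)
    index = {v: i for i, v in enumerate(ids)}
    missing = [v for v in conditioning_set if v not in index]
    if missing:
        raise KeyError(f"conditioning variant(s) absent from region: {missing}")
    if not conditioning_set:
        return ConditionalDataset(
            stats.trait_name, stats.trait_type, list(ids),
            np.array([r.beta for r in stats.records]),
            np.array([r.se for r in stats.records]))

    cond_idx = [index[v] for v in conditioning_set]
    beta_out = np.empty(len(ids))
    se_out = np.empty(len(ids))
    for j, vid in enumerate(ids):
        if vid in conditioning_set:
            beta_out[j] = 0.0           # no residual self-association
            se_out[j] = stats.records[j].se
            continue
        coef, se = _joint_fit(xtx, xty, yty, n, [j] + cond_idx)
        beta_out[j] = coef[0]
        se_out[j] = se[0]
    return ConditionalDataset(stats.trait_name, stats.trait_type, list(ids),
                              beta_out, se_out, tuple(conditioning_set))


def stepwise_select(
    stats: SummaryStatsTable,
    ld: LDMatrix,
    n: float,
    p_entry: float = DEFAULT_P_ENTRY,
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
) -> list[ConditionalSignal]:
    """Forward stepwise selection of conditionally independent signals.

    Each round adds the variant with the smallest conditional p-value below
    ``p_entry`` (ties: ascending position, then id), skipping variants with
    r^2 above the collinearity guard to any selected index; the joint model
    is refit every round. Returns the selected indices with their
    final joint-model effects.
    """
    ids, xtx, xty, yty = _moments(stats, ld, n)
    index = {v: i for i, v in enumerate(ids)}
    sub_r = ld.submatrix(ids).r
    pos = {r.variant_id: r.pos for r in stats.records}

    selected: list[str] = []
    while True:
        best: tuple | None = None
        for vid in ids:
            if vid in selected:
                continue
            j = index[vid]
            if any(sub_r[j, index[s]] ** 2 > collinearity_r2
                   for s in selected):
                continue
            try:
                coef, se = _joint_fit(xtx, xty, yty, n,
                                      [j] + [index[s] for s in selected])
            except ConditioningError:
                continue
            z = coef[0] / se[0]
            p = float(2 * sps.norm.sf(abs(z)))
            key = (p, pos[vid], vid)
            if p < p_entry and (best is None or key < best[0]):
                best = (key, vid)
        if best is None:
            break
        selected.append(best[1])

    if not selected:
        return []
    joint_idx = [index[v] for v in selected]
    coef, se = _joint_fit(xtx, xty, yty, n, joint_idx)
    signals = []
    for order, (vid, b, s) in enumerate(zip(selected, coef, se), start=1):
        p = float(2 * sps.norm.sf(abs(b / s)))
        signals.append(ConditionalSignal(vid, float(b), float(s), p, order))
    return signals


def _dataset_list(
    stats: SummaryStatsTable,
    ld: LDMatrix,
    n: float,
    p_entry: float,
    collinearity_r2: float,
) -> tuple[list[ConditionalDataset], list[ConditionalSignal]]:
    """Marginal dataset plus, when >= 2 signals, one conditional dataset per
    signal (conditioning on all *other* signals of the trait)."""
    marginal = conditional_stats(stats, ld, n, [])
    signals = stepwise_select(stats, ld, n, p_entry, collinearity_r2)
    datasets = [marginal]
    if len(signals) >= 2:
        for sig in signals:
            others = [s.index_variant for s in signals
                      if s.index_variant != sig.index_variant]
            datasets.append(conditional_stats(stats, ld, n, others))
    return datasets, signals


@dataclass
class PwcocoResult:
    """Full marginal/conditional colocalisation grid for a trait pair."""

    grid: list[ColocResult] = field(default_factory=list)
    signals_a: list[ConditionalSignal] = field(default_factory=list)
    signals_b: list[ConditionalSignal] = field(default_factory=list)

    @property
    def best_pp4(self) -> ColocResult:
        return max(self.grid, key=lambda r: r.pp4)


def pwcoco(
    stats_a: SummaryStatsTable,
    stats_b: SummaryStatsTable,
    ld: LDMatrix,
    n_a: float,
    n_b: float,
    priors: ColocPriors | None = None,
    p_entry: float = DEFAULT_P_ENTRY,
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
) -> PwcocoResult:
    """Colocalisation across all marginal/conditional dataset pairs.

    Both traits must be aligned to the same shared-variant order. With a
    single signal per trait the grid degenerates to one marginal x marginal
    result identical to plain colocalisation.
    """
    if stats_a.variant_ids != stats_b.variant_ids:
        shared = [v for v in stats_a.variant_ids
                  if v in set(stats_b.variant_ids)]
        if not shared:
            raise ValueError("no shared variants between the two traits")
        stats_a = stats_a.subset(shared)
        stats_b = stats_b.subset(shared)
    datasets_a, signals_a = _dataset_list(stats_a, ld, n_a, p_entry,
                                          collinearity_r2)
    datasets_b, signals_b = _dataset_list(stats_b, ld, n_b, p_entry,
                                          collinearity_r2)

    grid = []
    for da in datasets_a:
        for db in datasets_b:
            res = coloc_abf(da.to_regional(), db.to_regional(), priors,
                            label_a=da.label, label_b=db.label)
            grid.append(res)
    return PwcocoResult(grid=grid, signals_a=signals_a, signals_b=signals_b)
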