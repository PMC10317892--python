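"""Construction and strength diagnostics of cis-acting drug-target instruments.

An instrument proxies pharmacological perturbation of a drug target with
variants in or near the encoding gene: genome-wide significant
(p < 5e-8) selection-trait associations within +/-500 kb of the gene,
greedily pruned to pairwise r^2 < 0.20, filtered for direction concordance
between the selection trait (type 2 diabetes log-odds) and the scaling
trait (IRNT HbA1c), and finally expressed on the biomarker scale so the MR
slope reads per 1-unit change of the scaling trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gwas_io import LDMatrix, SummaryStatsTable

DEFAULT_WINDOW = 500_000
DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_MAX = 0.20


class NoInstrumentError(ValueError):
    """No variant survives the construction cascade (reported, not fatal)."""


class CoverageError(KeyError):
    """A candidate variant is missing from the LD matrix."""


@dataclass(frozen=True)
class GeneRegion:
    """Gene body on GRCh37 plus the flanking cis window (1-based, inclusive)."""

    gene_name: str
    chrom: str
    start: int
    end: int
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must precede end")
        if self.window < 0:
            raise ValueError("window must be non-negative")

    @property
    def cis_start(self) -> int:
        return self.start - self.window

    @property
    def cis_end(self) -> int:
        return self.end + self.window

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.cis_start <= pos <= self.cis_end


@dataclass(frozen=True)
class InstrumentVariant:
    """One instrument SNP carrying both selection- and scaling-trait effects
    on the same effect allele."""

    variant_id: str
    ea: str
    nea: str
    eaf: float
    beta_selection: float
    se_selection: float
    pval_selection: float
    beta_scaling: float
    se_scaling: float


@dataclass
class Instrument:
    """Pruned, concordance-filtered, biomarker-scaled variant set for one
    target, with its LD submatrix and strength diagnostics."""

    target: str
    variants: list[InstrumentVariant]
    ld: LDMatrix
    r2_explained: float
    f_statistic: float
    orientation: str  # 'lowering' | 'raising'
    per_variant_f: dict[str, float] = field(default_factory=dict)
    removal_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation not in ("lowering", "raising"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if list(self.ld.variant_ids) != [v.variant_id for v in self.variants]:
            raise ValueError("LD matrix does not match instrument variants")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def exposure_betas(self) -> np.ndarray:
        """Scaling-trait effects under the stored orientation convention."""
        sign = -1.0 if self.orientation == "lowering" else 1.0
        return sign * np.array([v.beta_scaling for v in self.variants])

    def drop(self, variant_id: str) -> "Instrument":
        keep = [v for v in self.variants if v.variant_id != variant_id]
        if len(keep) == len(self.variants):
            raise KeyError(variant_id)
        return Instrument(
            self.target, keep, self.ld.submatrix([v.variant_id for v in keep]),
            self.r2_explained, self.f_statistic, self.orientation,
            self.per_variant_f, self.removal_log)


def select_cis_snps(
    stats: SummaryStatsTable,
    region: GeneRegion,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> SummaryStatsTable:
    """Genome-wide significant variants within the closed cis interval,
    sorted by ascending p-value.

    An empty result raises :class:`NoInstrumentError` — the no-instrument
    condition a caller should report rather than treat as fatal.
    """
    hits = [r for r in stats.records
            if region.contains(r.chrom, r.pos) and r.pval < p_threshold]
    if not hits:
        raise NoInstrumentError(
            f"no variant at p<{p_threshold:g} within +/-{region.window} bp "
            f"of {region.gene_name}")
    hits.sort(key=lambda r: (r.pval, r.pos, r.variant_id))
    return SummaryStatsTable(stats.trait_name, stats.trait_type, hits,
                             stats.genome_build)


def ld_prune(
    candidates: SummaryStatsTable,
    ld: LDMatrix,
    r2_max: float = DEFAULT_R2_MAX,
) -> SummaryStatsTable:
    """Greedy pruning in ascending p-value order.

    A candidate is kept iff its squared correlation with every already-kept
    variant is below ``r2_max``. Deterministic: p ties break by position,
    then id (the order produced by :func:`select_cis_snps`).
    """
    index = {v: i for i, v in enumerate(ld.variant_ids)}
    missing = [r.variant_id for r in candidates.records
               if r.variant_id not in index]
    if missing:
        raise CoverageError(f"variants missing from LD matrix: {missing}")
    ordered = sorted(candidates.records,
                     key=lambda r: (r.pval, r.pos, r.variant_id))
    kept = []
    for rec in ordered:
        i = index[rec.variant_id]
        if all(ld.r[i, index[k.variant_id]] ** 2 < r2_max for k in kept):
            kept.append(rec)
    return SummaryStatsTable(candidates.trait_name, candidates.trait_type,
                             kept, candidates.genome_build)


def concordance_filter(
    variants: list[InstrumentVariant],
) -> tuple[list[InstrumentVariant], list[tuple[str, str]]]:
    """Remove variants whose scaling-trait effect opposes (or has undefined
    direction relative to) their selection-trait effect.

    Discordant direction flags a likely pleiotropic mechanism: a variant that
    raises disease liability but lowers the biomarker cannot proxy target
    perturbation on the biomarker scale.
    """
    kept: list[InstrumentVariant] = []
    removed: list[tuple[str, str]] = []
    for v in variants:
        if v.beta_scaling == 0.0:
            removed.append((v.variant_id, "undefined direction"))
        elif np.sign(v.beta_selection) != np.sign(v.beta_scaling):
            removed.append((v.variant_id, "discordant direction"))
        else:
            kept.append(v)
    return kept, removed


def pair_selection_scaling(
    selection: SummaryStatsTable,
    scaling: SummaryStatsTable,
) -> list[InstrumentVariant]:
    """Zip harmonised selection- and scaling-trait tables into paired
    instrument variants (both tables must carry the same effect alleles)."""
    by_id = {r.variant_id: r for r in scaling.records}
    out = []
    for sel in selection.records:
        sca = by_id.get(sel.variant_id)
        if sca is None:
            continue
        if (sca.ea, sca.nea) != (sel.ea, sel.nea):
            raise ValueError(
                f"{sel.variant_id}: selection/scaling tables are not "
                "harmonised to the same effect allele")
        out.append(InstrumentVariant(
            variant_id=sel.variant_id, ea=sel.ea, nea=sel.nea, eaf=sel.eaf,
            beta_selection=sel.beta, se_selection=sel.se,
            pval_selection=sel.pval,
            beta_scaling=sca.beta, se_scaling=sca.se))
    return out


def instrument_strength(
    variants: list[InstrumentVariant],
    ld: LDMatrix,
    n_exposure: int,
    ld_corrected: bool = True,
) -> tuple[float, float, dict[str, float]]:
    """(r2_explained, instrument F, per-variant F) on the scaling trait.

    The scaling trait is variance-1 (IRNT), so a variant's marginal explained
    variance is 2*eaf*(1-eaf)*beta^2. Under weak LD the marginal effects
    double-count shared signal; with standardized effects
    w_i = beta_i*sqrt(2*eaf_i*(1-eaf_i)) the joint variance explained is the
    quadratic form w' R^-1 w (equals the naive sum when R = I). Set
    ``ld_corrected=False`` for the naive independent sum.

    Instrument F uses the k-instrument formula
    F = (n-k-1)/k * r2/(1-r2); per-variant F is (beta/se)^2.
    """
    k = len(variants)
    if k == 0:
        raise NoInstrumentError("empty instrument")
    if n_exposure <= k + 1:
        raise ValueError("F undefined: n_exposure <= k+1")
    for v in variants:
        if not (0.0 < v.eaf < 1.0):
            raise ValueError(f"{v.variant_id}: fixed variant (eaf={v.eaf})")
    w = np.array([v.beta_scaling * np.sqrt(2 * v.eaf * (1 - v.eaf))
                  for v in variants])
    if ld_corrected:
        sub = ld.submatrix([v.variant_id for v in variants])
        r2 = float(w @ np.linalg.solve(sub.r, w))
    else:
        r2 = float(w @ w)
    r2 = min(max(r2, 0.0), 1.0 - 1e-12)
    f_stat = (n_exposure - k - 1) / k * r2 / (1 - r2)
    per_variant = {v.variant_id: (v.beta_scaling / v.se_scaling) ** 2
                   for v in variants}
    return r2, f_stat, per_variant


def build_instrument(
    target: str,
    variants: list[InstrumentVariant],
    ld: LDMatrix,
    orientation: str = "lowering",
    n_exposure: int = 407_766,
    removal_log: list[tuple[str, str]] | None = None,
    ld_corrected_r2: bool = True,
) -> Instrument:
    """Assemble the final instrument from concordance-filtered variants.

    Exposure effects are the scaling-trait (biomarker) per-allele betas.
    Under ``orientation='lowering'`` exposure and outcome betas are jointly
    negated downstream so the causal slope reads per 1-unit biomarker
    lowering; the IVW slope magnitude is invariant to this convention.
    """
    if not variants:
        raise NoInstrumentError(f"{target}: no concordant variants")
    ids = [v.variant_id for v in variants]
    try:
        sub = ld.submatrix(ids)
    except KeyError as exc:
        raise CoverageError(str(exc)) from exc
    r2, f_stat, per_f = instrument_strength(
        variants, sub, n_exposure, ld_corrected=ld_corrected_r2)
    return Instrument(
        target=target, variants=variants, ld=sub, r2_explained=r2,
        f_statistic=f_stat, orientation=orientation, per_variant_f=per_f,
        removal_log=list(removal_log or []))


def construct_instrument(
    target: str,
    selection: SummaryStatsTable,
    scaling: SummaryStatsTable,
    region: GeneRegion,
    ld: LDMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_R2_MAX,
    orientation: str = "lowering",
    n_exposure: int | None = None,
) -> Instrument:
    """Full construction cascade: cis window -> significance -> LD pruning ->
    concordance filter -> biomarker scaling."""
    cis = select_cis_snps(selection, region, p_threshold)
    pruned = ld_prune(cis, ld, r2_max)
    paired = pair_selection_scaling(pruned, scaling)
    if not paired:
        raise NoInstrumentError(
            f"{target}: no pruned variant has scaling-trait estimates")
    kept, removed = concordance_filter(paired)
    n_exp = n_exposure if n_exposure is not None else scaling.records[0].n
    return build_instrument(target, kept, ld, orientation=orientation,
                            n_exposure=n_exp, removal_log=removed)
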