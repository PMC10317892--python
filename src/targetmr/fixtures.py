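"""Published per-variant instrument characteristics for the three targets.

The study's exposure GWAS (type 2 diabetes in the Million Veteran Program,
148,726 cases / 965,732 controls) and scaling GWAS (IRNT HbA1c in 407,766
UK Biobank participants) are consortium datasets; what is public is the
final instrument table: for each SNP its effect allele, frequency, per-allele
log-odds of type 2 diabetes with SE and p, and per-allele effect on inverse
rank normal transformed HbA1c with SE. Those numbers are encoded here
verbatim and exposed as :class:`~targetmr.gwas_io.SummaryStatsTable` pairs.

Genomic positions and pairwise LD of these SNPs are not part of the printed
table; :func:`instrument_tables` assigns synthetic evenly spaced positions
inside each gene body and :func:`weak_ld_matrix` returns a synthetic
constant weak-LD matrix (r = 0.1), both clearly stand-ins that preserve the
properties the construction pipeline filters on (cis location, pairwise
r^2 < 0.20).
"""

from __future__ import annotations

import numpy as np

from .gwas_io import LDMatrix, SummaryStatRecord, SummaryStatsTable
from .instruments import GeneRegion

N_T2D = 148_726 + 965_732
N_T2D_CASES = 148_726
N_HBA1C = 407_766

#: GRCh37 gene body coordinates used to define the cis windows
GENE_REGIONS: dict[str, GeneRegion] = {
    "PPARG": GeneRegion("PPARG", "3", 12_328_867, 12_475_855),
    "ABCC8": GeneRegion("ABCC8", "11", 17_414_432, 17_498_449),
    "GLP1R": GeneRegion("GLP1R", "6", 39_016_574, 39_055_519),
}

# (snp, ea, nea, eaf, beta_t2d, se_t2d, p_t2d, beta_hba1c, se_hba1c)
INSTRUMENT_TABLE: dict[str, list[tuple]] = {
    "ABCC8": [
        ("rs5219",     "C", "T", 0.63, -0.069, 0.005, 3.15e-48, -0.016, 0.002),
        ("rs4148640",  "T", "G", 0.27, -0.045, 0.007, 4.47e-11, -0.009, 0.002),
        ("rs61880293", "T", "C", 0.92, -0.058, 0.009, 8.13e-10, -0.015, 0.004),
        ("rs7130826",  "T", "G", 0.73, -0.031, 0.005, 1.94e-09, -0.004, 0.002),
        ("rs10832783", "G", "A", 0.92, -0.055, 0.009, 4.63e-09, -0.011, 0.004),
        ("rs214080",   "A", "G", 0.41, -0.026, 0.005, 1.96e-08, -0.007, 0.002),
    ],
    "GLP1R": [
        ("rs10305420", "T", "C", 0.38, -0.032, 0.005, 2.69e-11, -0.011, 0.002),
        ("rs34179517", "A", "C", 0.87, -0.044, 0.007, 3.09e-10, -0.007, 0.003),
        ("rs9296291",  "C", "T", 0.23, -0.033, 0.006, 3.42e-09, -0.013, 0.002),
        ("rs10305457", "C", "T", 0.90, -0.044, 0.008, 3.04e-08, -0.018, 0.003),
    ],
    "PPARG": [
        ("rs7637403",    "A", "G", 0.11, -0.074, 0.007, 1.03e-24, -0.007, 0.003),
        ("rs4135247",    "A", "G", 0.57, -0.042, 0.005, 2.23e-19, -0.035, 0.002),
        ("rs598747",     "A", "G", 0.84, -0.052, 0.007, 9.51e-15, -0.022, 0.003),
        ("rs150535373",  "A", "G", 0.02, -0.140, 0.019, 5.38e-13, -0.005, 0.009),
        ("rs143888770",  "T", "C", 0.02, -0.106, 0.016, 1.21e-10, -0.015, 0.007),
        ("rs17819328",   "T", "G", 0.58, -0.028, 0.005, 9.56e-10, -0.023, 0.002),
        ("rs4135300",    "C", "T", 0.89, -0.045, 0.008, 5.50e-09, -0.013, 0.003),
    ],
}

#: two SNPs removed from the PPARG instrument because their HbA1c effect
#: opposed their type 2 diabetes effect (their estimates are unpublished)
REMOVED_DISCORDANT_SNPS = ("rs17036160", "rs11712085")


def _synthetic_positions(target: str, k: int) -> list[int]:
    region = GENE_REGIONS[target]
    return list(np.linspace(region.start, region.end, k).astype(int))


def instrument_tables(target: str) -> tuple[SummaryStatsTable, SummaryStatsTable]:
    """(selection-trait table, scaling-trait table) for one target.

    Selection trait: type 2 diabetes log-odds; scaling trait: IRNT HbA1c.
    Positions are synthetic placements inside the gene body.
    """
    rows = INSTRUMENT_TABLE[target]
    region = GENE_REGIONS[target]
    positions = _synthetic_positions(target, len(rows))
    t2d, hba1c = [], []
    for pos, (snp, ea, nea, eaf, b_t, se_t, p_t, b_h, se_h) in zip(positions, rows):
        t2d.append(SummaryStatRecord(
            variant_id=snp, chrom=region.chrom, pos=pos, ea=ea, nea=nea,
            eaf=eaf, beta=b_t, se=se_t, pval=p_t, n=N_T2D,
            n_cases=N_T2D_CASES))
        z = b_h / se_h
        from scipy.stats import norm
        p_h = float(2 * norm.sf(abs(z)))
        hba1c.append(SummaryStatRecord(
            variant_id=snp, chrom=region.chrom, pos=pos, ea=ea, nea=nea,
            eaf=eaf, beta=b_h, se=se_h, pval=max(p_h, 1e-300), n=N_HBA1C))
    return (
        SummaryStatsTable("type_2_diabetes", "binary", t2d),
        SummaryStatsTable("irnt_hba1c", "quantitative", hba1c),
    )


def weak_ld_matrix(target: str, r: float = 0.1) -> LDMatrix:
    """Synthetic stand-in LD: constant weak correlation between the SNPs.

    The published instruments only guarantee pairwise r^2 < 0.20; this matrix
    realises that property with a constant r (equicorrelation is positive
    definite for r in (-1/(m-1), 1)).
    """
    ids = [row[0] for row in INSTRUMENT_TABLE[target]]
    m = len(ids)
    mat = np.full((m, m), r, dtype=float)
    np.fill_diagonal(mat, 1.0)
    return LDMatrix(ids, mat)
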