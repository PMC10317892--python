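"""Reading, validation and harmonisation of GWAS summary statistics and LD.

All downstream analysis modules consume the containers defined here:
:class:`SummaryStatsTable` (per-variant marginal association records for one
trait), :class:`LDMatrix` (signed pairwise Pearson correlations) and
:class:`GenotypeDosageMatrix` (samples x variants dosages in [0, 2], the
stand-in for a reference genotype panel).

Summary statistics are tab-separated text with a header; the default column
names are ``snp chr pos ea nea eaf beta se pval n n_cases`` and ``#`` lines
are ignored. Gzip is handled transparently by pandas via the file extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: default file dialect: our column name -> column name in the file
DEFAULT_DIALECT: dict[str, str] = {
    "variant_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "ea": "ea",
    "nea": "nea",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "n_cases": "n_cases",
}

MANDATORY_FIELDS = (
    "variant_id", "chrom", "pos", "ea", "nea", "eaf", "beta", "se", "pval", "n",
)


class FormatError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class EmptyInputError(ValueError):
    """No valid rows survived validation."""


class EmptyIntersectionError(ValueError):
    """Two tables share no variants."""


class DegenerateVariantError(ValueError):
    """A requested variant has zero variance in the genotype panel."""


class IllConditionedLDError(ValueError):
    """LD matrix is not positive semi-definite within tolerance."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's marginal association with one trait.

    ``beta`` is the per-effect-allele estimate: log-odds for binary traits,
    trait units for quantitative traits. Positions are 1-based GRCh37.
    """

    variant_id: str
    chrom: str
    pos: int
    ea: str
    nea: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    n_cases: int | None = None

    def validate(self) -> str | None:
        """Return a rejection reason, or None if the record is valid."""
        if not np.isfinite(self.se) or self.se <= 0:
            return "nonpositive SE"
        if not np.isfinite(self.eaf) or not (0.0 <= self.eaf <= 1.0):
            return "EAF out of range"
        if self.ea == self.nea:
            return "identical alleles"
        for allele in (self.ea, self.nea):
            if not allele or (len(allele) == 1 and allele not in VALID_BASES):
                return f"invalid allele {allele!r}"
        if not np.isfinite(self.beta):
            return "non-finite beta"
        if not (0.0 < self.pval <= 1.0):
            return "p-value outside (0,1]"
        if self.pos <= 0:
            return "nonpositive position"
        if self.n <= 0:
            return "nonpositive sample size"
        if self.n_cases is not None and self.n_cases > self.n:
            return "n_cases exceeds n"
        return None

    def is_palindromic(self) -> bool:
        complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
        return (
            len(self.ea) == 1
            and len(self.nea) == 1
            and complement.get(self.ea) == self.nea
        )


@dataclass
class LoadReport:
    """Per-file account of accepted and rejected rows."""

    path: str
    n_accepted: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


@dataclass
class SummaryStatsTable:
    """Validated, de-duplicated marginal summary statistics for one trait."""

    trait_name: str
    trait_type: str  # 'binary' | 'quantitative'
    records: list[SummaryStatRecord]
    genome_build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate variant_id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def get(self, variant_id: str) -> SummaryStatRecord:
        for r in self.records:
            if r.variant_id == variant_id:
                return r
        raise KeyError(variant_id)

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStatsTable":
        """Rows for ``variant_ids`` in the requested order."""
        by_id = {r.variant_id: r for r in self.records}
        missing = [v for v in variant_ids if v not in by_id]
        if missing:
            raise KeyError(f"variants not in table: {missing}")
        return SummaryStatsTable(
            self.trait_name, self.trait_type,
            [by_id[v] for v in variant_ids], self.genome_build,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "snp": r.variant_id, "chr": r.chrom, "pos": r.pos,
                "ea": r.ea, "nea": r.nea, "eaf": r.eaf, "beta": r.beta,
                "se": r.se, "pval": r.pval, "n": r.n, "n_cases": r.n_cases,
            })
        return pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values()))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, trait_name: str, trait_type: str,
        genome_build: str = "GRCh37",
    ) -> "SummaryStatsTable":
        records = []
        for row in df.itertuples(index=False):
            n_cases = getattr(row, "n_cases", None)
            if n_cases is not None and (n_cases != n_cases):  # NaN
                n_cases = None
            records.append(SummaryStatRecord(
                variant_id=str(row.snp), chrom=str(row.chr), pos=int(row.pos),
                ea=str(row.ea), nea=str(row.nea), eaf=float(row.eaf),
                beta=float(row.beta), se=float(row.se), pval=float(row.pval),
                n=int(row.n),
                n_cases=None if n_cases is None else int(n_cases),
            ))
        return cls(trait_name, trait_type, records, genome_build)


@dataclass
class LDMatrix:
    """Signed pairwise Pearson correlations between variants (not r^2)."""

    variant_ids: list[str]
    r: np.ndarray

    #: eigenvalues above this are accepted as PSD without repair
    PSD_TOL = -1e-8
    #: eigenvalues in (REPAIR_FLOOR, 0) are clipped to 0; below raises
    REPAIR_FLOOR = -1e-6

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError(
                f"LD matrix shape {self.r.shape} != ({m}, {m})")
        if m == 0:
            return
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("LD entries exceed |r| = 1")
        lam_min = float(np.linalg.eigvalsh(self.r)[0])
        if lam_min < self.PSD_TOL:
            if lam_min <= self.REPAIR_FLOOR:
                raise IllConditionedLDError(
                    f"smallest eigenvalue {lam_min:.3e} below repair floor; "
                    "malformed LD input")
            # mild negativity from rounding: clip, then rescale back to a
            # correlation matrix (rescaling preserves PSD; overwriting the
            # diagonal would not)
            lam, vec = np.linalg.eigh(self.r)
            repaired = (vec * np.clip(lam, 0.0, None)) @ vec.T
            repaired = (repaired + repaired.T) / 2.0
            d = np.sqrt(np.diag(repaired))
            repaired = repaired / np.outer(d, d)
            self.r = np.clip(repaired, -1.0, 1.0)
            logger.info("LD matrix repaired: eigenvalue %.3e clipped to 0",
                        lam_min)

    def __len__(self) -> int:
        return len(self.variant_ids)

    def submatrix(self, variant_ids: Sequence[str]) -> "LDMatrix":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise KeyError(f"variants not in LD matrix: {missing}")
        idx = [index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variant_ids,
                            columns=self.variant_ids)


@dataclass
class GenotypeDosageMatrix:
    """Dosage panel: samples x variants, values in [0, 2]."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage matrix dimensions inconsistent with ids")
        if np.any(self.dosages < -1e-9) or np.any(self.dosages > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")


def _coerce_row(raw: Mapping[str, object]) -> SummaryStatRecord:
    n_cases_val = raw.get("n_cases")
    n_cases: int | None
    if n_cases_val is None or (isinstance(n_cases_val, float)
                               and np.isnan(n_cases_val)):
        n_cases = None
    else:
        n_cases = int(float(n_cases_val))  # type: ignore[arg-type]
    return SummaryStatRecord(
        variant_id=str(raw["variant_id"]),
        chrom=str(raw["chrom"]),
        pos=int(float(raw["pos"])),  # type: ignore[arg-type]
        ea=str(raw["ea"]).upper(),
        nea=str(raw["nea"]).upper(),
        eaf=float(raw["eaf"]),  # type: ignore[arg-type]
        beta=float(raw["beta"]),  # type: ignore[arg-type]
        se=float(raw["se"]),  # type: ignore[arg-type]
        pval=float(raw["pval"]),  # type: ignore[arg-type]
        n=int(float(raw["n"])),  # type: ignore[arg-type]
        n_cases=n_cases,
    )


def read_summary_stats(
    path: str,
    trait_name: str,
    trait_type: str,
    dialect: Mapping[str, str] | None = None,
) -> tuple[SummaryStatsTable, LoadReport]:
    """Read a tab-separated summary-statistics file.

    Rows failing record invariants are rejected with a per-row reason in the
    returned :class:`LoadReport`; a missing mandatory column raises
    :class:`FormatError` and zero valid rows raises :class:`EmptyInputError`.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [colmap[f] for f in MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")

    report = LoadReport(path=str(path))
    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        raw = {field: row.get(colmap[field]) for field in colmap}
        vid = str(raw.get("variant_id"))
        try:
            rec = _coerce_row(raw)
        except (TypeError, ValueError):
            report.rejections.append((vid, "unparseable row"))
            continue
        reason = rec.validate()
        if reason is not None:
            report.rejections.append((vid, reason))
            continue
        if rec.variant_id in seen:
            report.rejections.append((vid, "duplicate variant_id"))
            continue
        seen.add(rec.variant_id)
        records.append(rec)
    report.n_accepted = len(records)
    logger.info("%s: accepted %d rows, rejected %d",
                path, report.n_accepted, report.n_rejected)
    if not records:
        raise EmptyInputError(f"{path}: no valid rows")
    return SummaryStatsTable(trait_name, trait_type, records), report


def write_summary_stats(table: SummaryStatsTable, path: str) -> None:
    """Write a table in the default dialect, 10-significant-digit precision."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _flip(rec: SummaryStatRecord) -> SummaryStatRecord:
    """Express a record on the opposite effect allele."""
    return replace(rec, ea=rec.nea, nea=rec.ea, beta=-rec.beta,
                   eaf=1.0 - rec.eaf)


#: palindromic variants are alignable by frequency only outside this band
PALINDROMIC_EAF_BAND = (0.42, 0.58)


def harmonise_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
) -> tuple[SummaryStatsTable, SummaryStatsTable, list[tuple[str, str]]]:
    """Align outcome effects to the exposure's effect allele.

    Returns (exposure subset, harmonised outcome subset, drop log). Variants
    absent from either table are silently restricted away; allele-set
    mismatches are dropped and logged. Palindromic (A/T, C/G) variants are
    aligned by effect-allele frequency when both frequencies lie outside
    [0.42, 0.58] and dropped otherwise — frequency cannot resolve strand for
    near-50% variants.
    """
    out_by_id = {r.variant_id: r for r in outcome.records}
    shared = [r for r in exposure.records if r.variant_id in out_by_id]
    if not shared:
        raise EmptyIntersectionError(
            f"no shared variants between {exposure.trait_name!r} "
            f"and {outcome.trait_name!r}")

    kept_exp: list[SummaryStatRecord] = []
    kept_out: list[SummaryStatRecord] = []
    dropped: list[tuple[str, str]] = []
    for exp in shared:
        out = out_by_id[exp.variant_id]
        if exp.is_palindromic() and out.is_palindromic():
            lo, hi = PALINDROMIC_EAF_BAND
            if (lo <= exp.eaf <= hi) or (lo <= out.eaf <= hi):
                dropped.append((exp.variant_id, "palindromic, ambiguous EAF"))
                continue
            # align by frequency: same minor/major side on both traits
            aligned = out if (exp.eaf < 0.5) == (out.eaf < 0.5) else _flip(out)
            kept_exp.append(exp)
            kept_out.append(aligned)
            continue
        if (out.ea, out.nea) == (exp.ea, exp.nea):
            kept_exp.append(exp)
            kept_out.append(out)
        elif (out.ea, out.nea) == (exp.nea, exp.ea):
            kept_exp.append(exp)
            kept_out.append(_flip(out))
        else:
            dropped.append((exp.variant_id, "allele mismatch"))
    for vid, reason in dropped:
        logger.info("harmonise: dropped %s (%s)", vid, reason)
    if not kept_exp:
        raise EmptyIntersectionError("no variants survived harmonisation")
    return (
        SummaryStatsTable(exposure.trait_name, exposure.trait_type, kept_exp,
                          exposure.genome_build),
        SummaryStatsTable(outcome.trait_name, outcome.trait_type, kept_out,
                          outcome.genome_build),
        dropped,
    )


def compute_ld(
    genotypes: GenotypeDosageMatrix,
    variant_subset: Iterable[str] | None = None,
) -> LDMatrix:
    """Signed Pearson correlation of dosage columns."""
    ids = list(variant_subset) if variant_subset is not None \
        else list(genotypes.variant_ids)
    index = {v: i for i, v in enumerate(genotypes.variant_ids)}
    missing = [v for v in ids if v not in index]
    if missing:
        raise KeyError(f"variants not in genotype panel: {missing}")
    cols = genotypes.dosages[:, [index[v] for v in ids]]
    sd = cols.std(axis=0)
    degenerate = [v for v, s in zip(ids, sd) if s == 0]
    if degenerate:
        raise DegenerateVariantError(
            f"monomorphic variant(s) in subset: {degenerate}")
    r = np.corrcoef(cols, rowvar=False)
    r = np.atleast_2d(r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return LDMatrix(ids, np.clip(r, -1.0, 1.0))


def read_ld_matrix(path: str) -> LDMatrix:
    """Square TSV with variant ids as first row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column variant ids differ")
    return LDMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str) -> None:
    ld.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_dosages(path: str) -> GenotypeDosageMatrix:
    """Samples x variants dosage TSV; first column holds sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeDosageMatrix(
        sample_ids=list(df.index.astype(str)),
        variant_ids=list(df.columns.astype(str)),
        dosages=df.to_numpy(dtype=float),
    )


def write_dosages(genotypes: GenotypeDosageMatrix, path: str) -> None:
    pd.DataFrame(genotypes.dosages, index=genotypes.sample_ids,
                 columns=genotypes.variant_ids).to_csv(
        path, sep="\t", float_format="%.10g")
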