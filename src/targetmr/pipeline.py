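"""End-to-end study orchestration from one declarative run configuration.

Stage order mirrors the study design: per-target instrument construction
(cis window -> significance -> LD pruning -> concordance -> biomarker
scaling), positive-control and cancer-outcome IVW MR with leave-one-out and
Bonferroni evidence labels, colocalisation of the selection trait against
each nominally associated outcome with a p12 prior grid (escalating to
pairwise conditional colocalisation when the marginal pair is unsupported),
and binary-outcome power. A target whose region yields no instrument is
reported as such and does not abort the other targets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coloc_abf import ColocPriors, RegionalDataset, coloc_abf, prior_sensitivity
from .conditional import effective_sample_size, pwcoco
from .diagnostics_power import PowerSpec, detectable_or, mr_power_binary
from .gwas_io import (LDMatrix, SummaryStatsTable, harmonise_pair,
                      read_ld_matrix, read_summary_stats)
from .instruments import (DEFAULT_P_THRESHOLD, DEFAULT_R2_MAX, DEFAULT_WINDOW,
                          GeneRegion, Instrument, NoInstrumentError,
                          concordance_filter, ld_prune, pair_selection_scaling,
                          build_instrument, select_cis_snps)
from .mr_ivw import (DEFAULT_ALPHA, DEFAULT_N_TESTS, MRResult, evidence_label,
                     leave_one_out, mr_instrument)

logger = logging.getLogger(__name__)


@dataclass
class OutcomeSpec:
    name: str
    file: str
    trait_type: str
    n_cases: int | None = None
    n_controls: int | None = None
    expected_direction: int | None = None   # positive controls only
    positive_control: bool = False


@dataclass
class TargetSpec:
    gene: str
    region: GeneRegion
    orientation: str = "lowering"


@dataclass
class RunConfig:
    """Declarative study configuration (normally loaded from YAML)."""

    targets: list[TargetSpec]
    selection_file: str
    scaling_file: str
    ld_file: str
    outcomes: list[OutcomeSpec]
    output_dir: str = "targetmr-out"
    seed: int = 0
    window: int = DEFAULT_WINDOW
    p_threshold: float = DEFAULT_P_THRESHOLD
    r2_max: float = DEFAULT_R2_MAX
    priors: ColocPriors = field(default_factory=ColocPriors)
    p12_grid: tuple[float, ...] = (1e-5, 5e-6, 5e-5)
    n_tests: int = DEFAULT_N_TESTS
    alpha: float = DEFAULT_ALPHA
    coloc_nominal_p: float = 0.05
    run_pwcoco: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        except (OSError, yaml.YAMLError) as exc:
            raise ValueError(f"unreadable config {path}: {exc}") from exc
        thresholds = raw.get("thresholds", {})
        priors_raw = raw.get("priors", {})
        targets = []
        window = int(thresholds.get("window", DEFAULT_WINDOW))
        for t in raw["targets"]:
            targets.append(TargetSpec(
                gene=t["gene"],
                region=GeneRegion(t["gene"], str(t["chrom"]), int(t["start"]),
                                  int(t["end"]), window),
                orientation=t.get("orientation", "lowering")))
        outcomes = []
        for o in raw.get("positive_controls", []):
            outcomes.append(OutcomeSpec(
                name=o["name"], file=o["file"],
                trait_type=o.get("trait_type", "quantitative"),
                n_cases=o.get("n_cases"), n_controls=o.get("n_controls"),
                expected_direction=o.get("expected_direction"),
                positive_control=True))
        for o in raw.get("outcomes", []):
            outcomes.append(OutcomeSpec(
                name=o["name"], file=o["file"],
                trait_type=o.get("trait_type", "binary"),
                n_cases=o.get("n_cases"), n_controls=o.get("n_controls")))
        cfg = cls(
            targets=targets,
            selection_file=raw["exposure"]["selection_file"],
            scaling_file=raw["exposure"]["scaling_file"],
            ld_file=raw["exposure"]["ld_file"],
            outcomes=outcomes,
            output_dir=raw.get("output_dir", "targetmr-out"),
            seed=int(raw.get("seed", 0)),
            window=window,
            p_threshold=float(thresholds.get("p_threshold",
                                             DEFAULT_P_THRESHOLD)),
            r2_max=float(thresholds.get("r2_max", DEFAULT_R2_MAX)),
            priors=ColocPriors(
                p1=float(priors_raw.get("p1", 1e-4)),
                p2=float(priors_raw.get("p2", 1e-4)),
                p12=float(priors_raw.get("p12", 1e-5))),
            p12_grid=tuple(float(x) for x in priors_raw.get(
                "p12_grid", (1e-5, 5e-6, 5e-5))),
            n_tests=int(raw.get("n_tests", DEFAULT_N_TESTS)),
            alpha=float(raw.get("alpha", DEFAULT_ALPHA)),
            run_pwcoco=bool(raw.get("run_pwcoco", True)),
        )
        missing = [p for p in (cfg.selection_file, cfg.scaling_file,
                               cfg.ld_file)
                   + tuple(o.file for o in cfg.outcomes)
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: "
                                    f"{missing}")
        return cfg


@dataclass
class StudyReport:
    """All computed results for one run, serialisable to JSON/TSV/markdown."""

    provenance: dict
    instruments: dict[str, dict] = field(default_factory=dict)
    mr_rows: list[dict] = field(default_factory=list)
    loo_rows: list[dict] = field(default_factory=list)
    coloc_rows: list[dict] = field(default_factory=list)
    power_rows: list[dict] = field(default_factory=list)
    errors: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(config).items()},
        sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _mr_row(res: MRResult, n_tests: int, alpha: float,
            spec: OutcomeSpec) -> dict:
    or_, lo, hi = res.or_scale
    return {
        "target": res.target, "outcome": res.outcome,
        "n_cases": spec.n_cases, "n_controls": spec.n_controls,
        "beta": res.beta, "se": res.se, "or": or_,
        "ci_low": lo, "ci_high": hi, "pval": res.pval,
        "evidence": evidence_label(res.pval, n_tests, alpha),
        "phi": res.phi, "k": res.k, "model": res.model,
    }


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute the full replica and return the assembled report."""
    selection, _ = read_summary_stats(config.selection_file,
                                      "selection_trait", "binary")
    scaling, _ = read_summary_stats(config.scaling_file,
                                    "scaling_trait", "quantitative")
    ld = read_ld_matrix(config.ld_file)
    outcome_tables: dict[str, SummaryStatsTable] = {}
    for spec in config.outcomes:
        table, _ = read_summary_stats(
            spec.file, spec.name,
            "binary" if spec.trait_type == "binary" else "quantitative")
        outcome_tables[spec.name] = table

    report = StudyReport(provenance={
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "n_tests": config.n_tests,
        "alpha": config.alpha,
    })

    for target in config.targets:
        try:
            instrument = _construct(target, selection, scaling, ld, config)
        except NoInstrumentError as exc:
            report.instruments[target.gene] = {"status": "no-instrument",
                                               "detail": str(exc)}
            logger.warning("%s: %s", target.gene, exc)
            continue
        except Exception as exc:   # keep other targets alive
            report.errors.append({"stage": "instrument",
                                  "target": target.gene, "error": str(exc)})
            continue
        report.instruments[target.gene] = {
            "status": "ok",
            "k": len(instrument),
            "variants": instrument.variant_ids,
            "r2_explained": instrument.r2_explained,
            "f_statistic": instrument.f_statistic,
            "per_variant_f": instrument.per_variant_f,
            "removals": instrument.removal_log,
            "orientation": instrument.orientation,
        }
        for spec in config.outcomes:
            try:
                _analyse_outcome(target, instrument, selection,
                                 outcome_tables[spec.name], spec, ld,
                                 config, report)
            except Exception as exc:
                report.errors.append({
                    "stage": "mr", "target": target.gene,
                    "outcome": spec.name, "error": str(exc)})
    return report


def _construct(target: TargetSpec, selection: SummaryStatsTable,
               scaling: SummaryStatsTable, ld: LDMatrix,
               config: RunConfig) -> Instrument:
    region = dataclasses.replace(target.region, window=config.window)
    cis = select_cis_snps(selection, region, config.p_threshold)
    covered = [r.variant_id for r in cis.records
               if r.variant_id in set(ld.variant_ids)]
    pruned = ld_prune(cis.subset(covered), ld, config.r2_max)
    sel_h, sca_h, _ = harmonise_pair(pruned, scaling)
    paired = pair_selection_scaling(sel_h, sca_h)
    kept, removed = concordance_filter(paired)
    return build_instrument(
        target.gene, kept, ld, orientation=target.orientation,
        n_exposure=scaling.records[0].n, removal_log=removed)


def _analyse_outcome(target: TargetSpec, instrument: Instrument,
                     selection: SummaryStatsTable,
                     outcome: SummaryStatsTable, spec: OutcomeSpec,
                     ld: LDMatrix, config: RunConfig,
                     report: StudyReport) -> None:
    inst_sel = selection.subset(
        [v for v in instrument.variant_ids
         if v in set(outcome.variant_ids)])
    if len(inst_sel) == 0:
        raise NoInstrumentError(
            f"{spec.name}: no instrument variant present in outcome data")
    _, out_h, _ = harmonise_pair(inst_sel, outcome)
    sub = instrument
    if len(inst_sel) < len(instrument):
        keep = set(inst_sel.variant_ids)
        for vid in instrument.variant_ids:
            if vid not in keep:
                sub = sub.drop(vid)
    gamma = np.array([r.beta for r in out_h.records])
    se_out = np.array([r.se for r in out_h.records])
    res = mr_instrument(sub, gamma, se_out, outcome=spec.name)
    row = _mr_row(res, config.n_tests, config.alpha, spec)
    if spec.positive_control:
        row["positive_control"] = True
        if spec.expected_direction is not None:
            row["direction_consistent"] = bool(
                np.sign(res.beta) == np.sign(spec.expected_direction))
    report.mr_rows.append(row)

    if res.k >= 2:
        sign = -1.0 if sub.orientation == "lowering" else 1.0
        for loo in leave_one_out(sub.exposure_betas, sign * gamma, se_out,
                                 sub.ld, target=target.gene,
                                 outcome=spec.name):
            report.loo_rows.append({
                "target": target.gene, "outcome": spec.name,
                "omitted": loo.omitted_variant, "beta": loo.beta,
                "se": loo.se, "or": loo.or_scale[0], "pval": loo.pval})

    # exclusion-restriction check: colocalise the selection trait with any
    # nominally associated outcome over the cis window
    if res.pval < config.coloc_nominal_p:
        _colocalise(target, selection, outcome, spec, ld, config, report)

    if spec.trait_type == "binary" and spec.n_cases and spec.n_controls:
        pspec = PowerSpec(spec.n_cases, spec.n_controls,
                          max(instrument.r2_explained, 1e-6),
                          alpha=config.alpha)
        or_hi, or_lo = detectable_or(pspec)
        report.power_rows.append({
            "target": target.gene, "outcome": spec.name,
            "r2": instrument.r2_explained,
            "detectable_or_above_1": or_hi,
            "detectable_or_below_1": or_lo,
            "power_at_or_1.5": mr_power_binary(pspec, 1.5),
        })


def _colocalise(target: TargetSpec, selection: SummaryStatsTable,
                outcome: SummaryStatsTable, spec: OutcomeSpec,
                ld: LDMatrix, config: RunConfig,
                report: StudyReport) -> None:
    region = dataclasses.replace(target.region, window=config.window)
    cis_ids = [r.variant_id for r in selection.records
               if region.contains(r.chrom, r.pos)
               and r.variant_id in set(outcome.variant_ids)
               and r.variant_id in set(ld.variant_ids)]
    if not cis_ids:
        return
    sel_h, out_h, _ = harmonise_pair(selection.subset(cis_ids),
                                     outcome.subset(cis_ids))
    shared = sel_h.variant_ids
    data1 = RegionalDataset(
        "selection_trait", sel_h.trait_type, shared,
        np.array([r.beta for r in sel_h.records]),
        np.array([r.se for r in sel_h.records]))
    data2 = RegionalDataset(
        spec.name, out_h.trait_type, shared,
        np.array([r.beta for r in out_h.records]),
        np.array([r.se for r in out_h.records]))
    grid = (config.priors.p12,) + tuple(
        p for p in config.p12_grid if p != config.priors.p12)
    results = prior_sensitivity(data1, data2, p12_grid=grid,
                                p1=config.priors.p1, p2=config.priors.p2)
    for cres in results:
        report.coloc_rows.append({
            "target": target.gene, "outcome": spec.name,
            "analysis": "marginal", "p12": cres.priors.p12,
            **cres.as_dict(), "n_variants": cres.n_variants})
    # escalate to pairwise conditional coloc when marginal H4 is unsupported
    marginal_pp4 = results[0].pp4
    if config.run_pwcoco and marginal_pp4 <= 0.5 and len(shared) >= 2:
        n1 = effective_sample_size(sel_h.records[0].n,
                                   sel_h.records[0].n_cases)
        n2 = effective_sample_size(out_h.records[0].n,
                                   out_h.records[0].n_cases)
        try:
            pw = pwcoco(sel_h, out_h, ld.submatrix(shared), n1, n2,
                        priors=config.priors)
        except Exception as exc:
            report.errors.append({"stage": "pwcoco", "target": target.gene,
                                  "outcome": spec.name, "error": str(exc)})
            return
        for cres in pw.grid:
            report.coloc_rows.append({
                "target": target.gene, "outcome": spec.name,
                "analysis": f"pwcoco[{cres.label_a}|{cres.label_b}]",
                "p12": cres.priors.p12, **cres.as_dict(),
                "n_variants": cres.n_variants})


MR_TSV_COLUMNS = ("target", "outcome", "n_cases", "n_controls", "or",
                  "ci_low", "ci_high", "pval", "evidence", "phi", "k",
                  "model")


def write_report(report: StudyReport, out_dir: str,
                 formats: tuple[str, ...] = ("tsv", "json", "markdown"),
                 ) -> list[Path]:
    """Serialise a report; TSV uses the outcome-table layout (OR, 95% CI,
    p, evidence label), JSON carries everything, markdown is a summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(report.as_dict(), indent=2,
                                   default=float))
        written.append(path)
    if "tsv" in formats:
        path = out / "mr_results.tsv"
        lines = ["\t".join(MR_TSV_COLUMNS)]
        for row in report.mr_rows:
            lines.append("\t".join(
                _fmt(row.get(c)) for c in MR_TSV_COLUMNS))
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
        if report.coloc_rows:
            cpath = out / "coloc_results.tsv"
            cols = ("target", "outcome", "analysis", "p12", "pp0", "pp1",
                    "pp2", "pp3", "pp4", "n_variants")
            clines = ["\t".join(cols)]
            for row in report.coloc_rows:
                clines.append("\t".join(_fmt(row.get(c)) for c in cols))
            cpath.write_text("\n".join(clines) + "\n")
            written.append(cpath)
    if "markdown" in formats:
        path = out / "report.md"
        path.write_text(_markdown(report))
        written.append(path)
    return written


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.4g}"
    return str(value)


def _markdown(report: StudyReport) -> str:
    lines = ["# Drug-target MR study report", ""]
    lines.append(f"Provenance: `{report.provenance}`")
    lines.append("")
    lines.append("## Instruments")
    for gene, info in report.instruments.items():
        if info.get("status") == "no-instrument":
            lines.append(f"- **{gene}**: no instrument ({info['detail']})")
        else:
            lines.append(
                f"- **{gene}**: k={info['k']}, r2={info['r2_explained']:.4g},"
                f" F={info['f_statistic']:.4g}")
    lines.append("")
    lines.append("## MR estimates")
    lines.append("| target | outcome | OR (95% CI) | p | evidence |")
    lines.append("|---|---|---|---|---|")
    for row in report.mr_rows:
        lines.append(
            f"| {row['target']} | {row['outcome']} "
            f"| {row['or']:.2f} ({row['ci_low']:.2f}, {row['ci_high']:.2f}) "
            f"| {row['pval']:.3g} | {row['evidence']} |")
    lines.append("")
    return "\n".join(lines) + "\n"
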