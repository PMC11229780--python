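"""Study orchestration: forward MR screen, reverse MR, mediation, reports.

The screen mirrors a gut-microbiome → blood-mediator → disease study
design: every candidate exposure is instrumented and tested against the
outcome with the full estimator battery and sensitivity suite, p-values
are FDR-adjusted within the exposure family (Benjamini–Hochberg),
exposures with uncorrectable heterogeneity are gated out, reverse MR
checks for outcome→exposure effects, and screened exposure/mediator
pairs enter the mediation decomposition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .estimators import all_estimates, ivw
from .instruments import LDMatrix, clump, f_statistics, select_by_pvalue
from .mediation import MediationStageError, bh_adjust, mediate
from .sensitivity import mr_presso, steiger, coloc_abf, DegenerateCorrectionError
from .sumstats import (HarmonizationError, SumstatRecord, harmonize,
                       read_sumstats)

logger = logging.getLogger("mrmediate")


@dataclass
class PipelineConfig:
    """All knobs of a study run; loadable from YAML or JSON.

    ``p_threshold_microbial`` applies to microbial-trait exposures (the
    looser 1e-5 threshold used when genome-wide hits are scarce);
    ``p_threshold_default`` (5e-8) applies to every other trait class,
    including instruments for reverse MR.
    """

    exposure_paths: dict[str, str] = field(default_factory=dict)
    mediator_paths: dict[str, str] = field(default_factory=dict)
    outcome_path: str = ""
    ld_path: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    p_threshold_microbial: float = 1e-5
    p_threshold_default: float = 5e-8
    microbial_exposures: list[str] = field(default_factory=list)
    clump_r2: float = 0.01
    clump_window_kb: int = 10_000
    min_f: float = 10.0
    presso_n_sim: int = 1000
    coloc_priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5)
    coloc_sd_quant: float = 0.15
    coloc_sd_binary: float = 0.2
    bh_alpha: float = 0.05
    heterogeneity_gate_p: float = 0.05
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name, v in [("p_threshold_microbial", self.p_threshold_microbial),
                        ("p_threshold_default", self.p_threshold_default),
                        ("bh_alpha", self.bh_alpha)]:
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    def p_threshold_for(self, exposure_name: str) -> float:
        if exposure_name in self.microbial_exposures:
            return self.p_threshold_microbial
        return self.p_threshold_default

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = (json.loads(path.read_text()) if path.suffix == ".json"
               else yaml.safe_load(path.read_text()))
        if "coloc_priors" in raw:
            raw["coloc_priors"] = tuple(raw["coloc_priors"])
        return cls(**raw)


@dataclass
class StudyReport:
    """Forest, sensitivity, and mediation tables plus the audit log."""

    forest: pd.DataFrame = field(default_factory=pd.DataFrame)
    sensitivity: pd.DataFrame = field(default_factory=pd.DataFrame)
    mediation: pd.DataFrame = field(default_factory=pd.DataFrame)
    audit: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def note(self, kind: str, ident: str, reason: str) -> None:
        self.audit.append({"kind": kind, "id": ident, "reason": reason})

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.forest.to_csv(outdir / "forest.tsv", sep="\t", index=False)
        self.sensitivity.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
        self.mediation.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
        with open(outdir / "audit.log", "w") as fh:
            for entry in self.audit:
                fh.write(f"{entry['kind']}\t{entry['id']}\t{entry['reason']}\n")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1,
                                                         sort_keys=True))


def _instrument(records: Sequence[SumstatRecord], ld: LDMatrix | None,
                threshold: float, config: PipelineConfig):
    sel = select_by_pvalue(records, threshold)
    if ld is not None and sel:
        sel = clump(sel, ld, r2_threshold=config.clump_r2,
                    window_kb=config.clump_window_kb)
    return f_statistics(sel, min_f=config.min_f)


def _screen_one(name: str, records: Sequence[SumstatRecord],
                outcome: Sequence[SumstatRecord], ld: LDMatrix | None,
                config: PipelineConfig, report: StudyReport,
                direction: str = "forward") -> dict | None:
    """Instrument one exposure and run the estimator + sensitivity suite.

    Returns a summary dict for the forest table or None if no usable IVs.
    """
    iv, diag = _instrument(records, ld, config.p_threshold_for(name), config)
    if not iv:
        report.note("exposure", name, "no-IV")
        return None
    try:
        h = harmonize(iv, outcome, exposure_name=name, outcome_name="outcome")
    except HarmonizationError as exc:
        report.note("exposure", name, f"harmonization-failed:{exc}")
        return None
    for snp_id, reason in h.dropped:
        report.note("snp", f"{name}:{snp_id}", reason)

    estimates, het = all_estimates(h, seed=config.seed)
    primary = estimates[0]

    sens: dict = {"exposure": name, "direction": direction,
                  "nsnp": h.n_snp, "mean_f": diag.mean_f,
                  "q": het.q, "q_df": het.df, "q_pvalue": het.pvalue}
    excluded = False
    if h.n_snp >= 3:
        egger_int = next(e for e in estimates if e.method == "egger_intercept")
        sens["egger_intercept"] = egger_int.beta
        sens["egger_intercept_p"] = egger_int.pvalue
    if h.n_snp >= 4:
        try:
            presso = mr_presso(h, n_sim=config.presso_n_sim, seed=config.seed)
            sens["presso_global_p"] = presso.global_p
            sens["presso_outliers"] = ",".join(presso.outliers) or "none"
            for snp in presso.outliers:
                report.note("snp", f"{name}:{snp}", "presso-outlier")
            # gate: heterogeneity attributable to pleiotropy (PRESSO global
            # significant) that outlier removal cannot correct
            if (het.pvalue < config.heterogeneity_gate_p
                    and presso.global_p < config.heterogeneity_gate_p):
                if presso.outliers:
                    keep = [p for p in h.records if p.snp_id not in presso.outliers]
                    h_corr = harmonize_subset(h, keep)
                    _, het_corr = ivw(h_corr)
                    excluded = het_corr.pvalue < config.heterogeneity_gate_p
                else:
                    excluded = True
        except DegenerateCorrectionError:
            sens["presso_global_p"] = float("nan")
            excluded = het.pvalue < config.heterogeneity_gate_p
    elif het.pvalue < config.heterogeneity_gate_p:
        excluded = True
    sens["excluded_heterogeneity"] = excluded
    if excluded:
        report.note("exposure", name, "heterogeneity-uncorrectable")

    st = steiger(h)
    sens["steiger_direction"] = st.direction
    sens["steiger_p"] = st.pvalue

    try:
        cl = coloc_abf(records, outcome, priors=config.coloc_priors,
                       sd_prior1=config.coloc_sd_quant,
                       sd_prior2=config.coloc_sd_binary)
        sens["coloc_pp_h4"] = cl.pp_h4
    except Exception as exc:  # region may be unusable; never fatal
        logger.warning("coloc failed for %s: %s", name, exc)
        sens["coloc_pp_h4"] = float("nan")

    rows = []
    for est in estimates:
        row = est.row()
        row["exposure"] = name
        row["direction"] = direction
        rows.append(row)
    return {"name": name, "primary": primary, "rows": rows,
            "sens": sens, "excluded": excluded}


def harmonize_subset(h, records):
    from .sumstats import HarmonizedInstrumentSet
    return HarmonizedInstrumentSet(exposure_name=h.exposure_name,
                                   outcome_name=h.outcome_name,
                                   records=list(records))


def run_forward_screen(
    exposures: Mapping[str, Sequence[SumstatRecord]],
    outcome: Sequence[SumstatRecord],
    ld: LDMatrix | None,
    config: PipelineConfig,
) -> StudyReport:
    """Screen every exposure against the outcome with BH control.

    Per-exposure failures are logged in the audit, never fatal.  The
    ``p_adjust`` column holds BH-adjusted primary (IVW / Wald-ratio)
    p-values across the exposure family; ``passes_screen`` marks
    exposures significant at ``bh_alpha`` and not gated out for
    uncorrectable heterogeneity.
    """
    report = StudyReport()
    results = []
    for name in exposures:
        res = _screen_one(name, exposures[name], outcome, ld, config, report)
        if res is not None:
            results.append(res)

    if results:
        padj = bh_adjust([r["primary"].pvalue for r in results])
        forest_rows, sens_rows = [], []
        for r, pa in zip(results, padj):
            r["p_adjust"] = pa
            r["passes"] = (pa < config.bh_alpha) and not r["excluded"]
            for row in r["rows"]:
                row["p_adjust"] = pa if row["method"] in ("ivw_mre", "wald_ratio") else float("nan")
                row["passes_screen"] = r["passes"]
                forest_rows.append(row)
            sens_rows.append(r["sens"])
        report.forest = pd.DataFrame(forest_rows)
        report.sensitivity = pd.DataFrame(sens_rows)
    report.manifest["screened"] = [r["name"] for r in results]
    report.manifest["passed"] = [r["name"] for r in results if r["passes"]]
    return report


def run_reverse_mr(
    exposures: Mapping[str, Sequence[SumstatRecord]],
    outcome: Sequence[SumstatRecord],
    ld: LDMatrix | None,
    config: PipelineConfig,
) -> StudyReport:
    """Reverse MR: outcome instrumented as the exposure, per original trait.

    Uses the genome-wide threshold for outcome instruments.  When the
    outcome has no significant instruments (or no matching SNPs in a
    trait file), that trait is reported "not-assessable".
    """
    report = StudyReport()
    iv, _ = _instrument(outcome, ld, config.p_threshold_default, config)
    if not iv:
        for name in exposures:
            report.note("reverse", name, "not-assessable:no-outcome-instruments")
        report.manifest["reverse_assessed"] = []
        return report
    rows, sens_rows, assessed = [], [], []
    for name, records in exposures.items():
        try:
            h = harmonize(iv, records, exposure_name="outcome", outcome_name=name)
        except HarmonizationError:
            report.note("reverse", name, "not-assessable:no-matching-snps")
            continue
        estimates, het = all_estimates(h, seed=config.seed)
        st = steiger(h)
        for est in estimates:
            row = est.row()
            row["exposure"] = "outcome"
            row["outcome"] = name
            row["direction"] = "reverse"
            rows.append(row)
        sens_rows.append({"exposure": name, "direction": "reverse",
                          "nsnp": h.n_snp, "q": het.q, "q_pvalue": het.pvalue,
                          "steiger_direction": st.direction, "steiger_p": st.pvalue})
        assessed.append(name)
    report.forest = pd.DataFrame(rows)
    report.sensitivity = pd.DataFrame(sens_rows)
    report.manifest["reverse_assessed"] = assessed
    return report


def run_mediation(
    exposures: Mapping[str, Sequence[SumstatRecord]],
    mediators: Mapping[str, Sequence[SumstatRecord]],
    outcome: Sequence[SumstatRecord],
    ld: LDMatrix | None,
    config: PipelineConfig,
    pairs: Sequence[tuple[str, str]],
) -> StudyReport:
    """Run the mediation decomposition for each screened pair."""
    report = StudyReport()
    rows = []
    for exp_name, med_name in pairs:
        try:
            res = mediate(
                exposures[exp_name], mediators[med_name], outcome, ld,
                exposure_name=exp_name, mediator_name=med_name,
                outcome_name="outcome",
                p_threshold_exposure=config.p_threshold_for(exp_name),
                p_threshold_mediator=config.p_threshold_default,
                clump_r2=config.clump_r2, clump_window_kb=config.clump_window_kb,
                min_f=config.min_f,
            )
            rows.append(res.row())
        except MediationStageError as exc:
            report.note("mediation", f"{exp_name}->{med_name}", f"failed:{exc.stage}")
            rows.append({"exposure": exp_name, "mediator": med_name,
                         "outcome": "outcome", "total_effect": float("nan"),
                         "two_step_prop_mediated_pct": "NA",
                         "mvmr_prop_mediated_pct": "NA"})
    report.mediation = pd.DataFrame(rows)
    report.manifest["mediation_pairs"] = [f"{a}->{b}" for a, b in pairs]
    return report


def merge_reports(*reports: StudyReport) -> StudyReport:
    out = StudyReport()
    out.forest = pd.concat([r.forest for r in reports if not r.forest.empty],
                           ignore_index=True) if any(not r.forest.empty for r in reports) else pd.DataFrame()
    out.sensitivity = pd.concat([r.sensitivity for r in reports if not r.sensitivity.empty],
                                ignore_index=True) if any(not r.sensitivity.empty for r in reports) else pd.DataFrame()
    out.mediation = pd.concat([r.mediation for r in reports if not r.mediation.empty],
                              ignore_index=True) if any(not r.mediation.empty for r in reports) else pd.DataFrame()
    for r in reports:
        out.audit.extend(r.audit)
        out.manifest.update(r.manifest)
    return out


def load_inputs(config: PipelineConfig):
    """Read all trait files and the LD matrix named in the config."""
    cmap = config.column_map or None
    exposures = {n: read_sumstats(p, cmap) for n, p in config.exposure_paths.items()}
    mediators = {n: read_sumstats(p, cmap) for n, p in config.mediator_paths.items()}
    outcome = read_sumstats(config.outcome_path, cmap)
    ld = None
    if config.ld_path:
        positions = {r.snp_id: r.pos for recs in
                     [*exposures.values(), *mediators.values(), [outcome][0]]
                     for r in recs}
        ld = LDMatrix.read(config.ld_path, positions=positions)
    return exposures, mediators, outcome, ld


def run_all(config: PipelineConfig) -> StudyReport:
    """Forward screen, reverse MR, and mediation for all screened pairs."""
    exposures, mediators, outcome, ld = load_inputs(config)
    fwd = run_forward_screen(exposures, outcome, ld, config)
    rev = run_reverse_mr(exposures, outcome, ld, config)
    passed = fwd.manifest.get("passed", [])
    pairs = [(e, m) for e in passed for m in mediators]
    med = run_mediation(exposures, mediators, outcome, ld, config, pairs)
    report = merge_reports(fwd, rev, med)
    report.manifest["seed"] = config.seed
    return report
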