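"""End-to-end pipeline: simulate -> quantify -> group stats -> expression -> splice.

One root seed drives named substreams for every stage, so a run is fully
reproducible; every output directory gets a ``report.json`` carrying the
seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr_mod
from . import simulate as sim_mod
from . import splice as splice_mod
from . import stats as stats_mod
from .panel import AmpliconPanel, load_default_panel
from .quantify import MethylationMatrix, quantify_samples


@dataclass
class RunConfig:
    panel_path: str | None = None   # None -> bundled default panel
    seed: int = 0
    outdir: str | None = None
    coverage_per_amplicon: int = 200
    conversion_failure_rate: float = 0.005
    sequencing_error_rate: float = 0.001
    read_length: int = 300
    cpg_jitter_sd: float = 2.0
    min_coverage: int = 100
    amplicon_alpha: float = 0.01    # letter display on amplicon summaries
    cpg_alpha: float = 0.05         # letter display per CpG
    qpcr_fold_change: float = 1.9
    qpcr_ct_noise_sd: float = 0.2
    qpcr_n_per_sex: int = 10
    simulate_only: bool = False
    write_fastq: bool = False

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: sim_mod.SimulatedCohort
    matrix: MethylationMatrix | None = None
    amplicon_summary: pd.DataFrame | None = None
    cpg_tests: pd.DataFrame | None = None
    sex_differences: pd.DataFrame | None = None
    density_fit: stats_mod.DensityFit | None = None
    expression: expr_mod.ExpressionResult | None = None
    splice_events: dict[str, list] | None = None
    sex_typing: dict[str, str] | None = None
    report: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # halt with a stage-named error
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(config: RunConfig, panel: AmpliconPanel) -> sim_mod.SimulatedCohort:
    sim_cfg = sim_mod.SimulationConfig(
        coverage_per_amplicon=config.coverage_per_amplicon,
        conversion_failure_rate=config.conversion_failure_rate,
        sequencing_error_rate=config.sequencing_error_rate,
        read_length=config.read_length,
        cpg_jitter_sd=config.cpg_jitter_sd,
        seed=config.seed,
    )
    return sim_mod.simulate_cohort(sim_cfg, panel)


@_stage("quantify")
def _run_quantify(config: RunConfig, cohort: sim_mod.SimulatedCohort) -> MethylationMatrix:
    return quantify_samples(
        cohort.sample_reads(), cohort.panel, min_coverage=config.min_coverage
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full synthetic-cohort analysis.

    Stages run in order and halt on the first failure with a stage-named
    error; outputs produced before the failure are retained on the result.
    Deterministic given ``config.seed``.
    """
    panel = (
        AmpliconPanel.from_yaml(config.panel_path)
        if config.panel_path
        else load_default_panel()
    )
    cohort = _run_simulate(config, panel)
    result = PipelineResult(config=config, cohort=cohort)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        cohort.design.sample_table().to_csv(outdir / "design.tsv", sep="\t", index=False)
        if config.write_fastq:
            cohort.write_fastq(outdir / "fastq")
    if config.simulate_only:
        result.report = _report(result)
        if outdir:
            _write_outputs(result, outdir)
        return result

    design = cohort.design.sample_table()
    result.matrix = _run_quantify(config, cohort)

    @_stage("group_stats")
    def _run_stats():
        summary = stats_mod.amplicon_group_summary(
            result.matrix.long, design, alpha=config.amplicon_alpha
        )
        cpg = stats_mod.kruskal_wallis_per_cpg(
            result.matrix.long, design, alpha=config.cpg_alpha
        )
        sexdiff = stats_mod.sex_difference_table(result.matrix.long, design)
        dens, meth = stats_mod.panel_density_points(
            cohort.panel,
            dict(zip(summary["amplicon_id"], summary["overall_mean"])),
        )
        fit = stats_mod.density_methylation_fit(dens, meth)
        return summary, cpg, sexdiff, fit

    (result.amplicon_summary, result.cpg_tests,
     result.sex_differences, result.density_fit) = _run_stats()

    @_stage("expression")
    def _run_expression():
        qtruth = sim_mod.QpcrTruth(
            fold_change=config.qpcr_fold_change, ct_noise_sd=config.qpcr_ct_noise_sd
        )
        ct = sim_mod.simulate_qpcr(
            qtruth,
            {"testes": config.qpcr_n_per_sex, "ovaries": config.qpcr_n_per_sex},
            seed=config.seed,
        )
        _, res = expr_mod.expression_pipeline(ct, qtruth.target_gene, qtruth.reference_gene)
        return res

    result.expression = _run_expression()

    @_stage("splice")
    def _run_splice():
        toys = sim_mod.simulate_isoforms(config.seed)
        events = {
            name: splice_mod.exon_diff(iso, toys.models[name.split("_")[0]])
            for name, iso in toys.isoforms.items()
        }
        typing = {
            "testis_set": splice_mod.sex_type_transcripts(
                [toys.transcripts["dmrt1_testis"], toys.transcripts["cyp19a1_testis_a"]],
                toys.assay_primers["dmrt1_male"],
                toys.assay_primers["cyp19a1_female"],
            ),
            "ovary_set": splice_mod.sex_type_transcripts(
                [toys.transcripts["dmrt1_ovary"], toys.transcripts["cyp19a1_ovary"]],
                toys.assay_primers["dmrt1_male"],
                toys.assay_primers["cyp19a1_female"],
            ),
        }
        return events, typing

    result.splice_events, result.sex_typing = _run_splice()
    result.report = _report(result)
    if outdir:
        _write_outputs(result, outdir)
    return result


def _report(result: PipelineResult) -> dict:
    config = result.config
    design = result.cohort.design.sample_table()
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_samples": int(len(design)),
        "n_testes": int((design.sex == "testes").sum()),
        "n_ovaries": int((design.sex == "ovaries").sum()),
        "n_amplicons": len(result.cohort.panel),
        "n_cpg_sites": result.cohort.panel.total_cpg_count,
        "total_reads": result.cohort.n_reads,
    }
    if result.matrix is not None and result.matrix.qc is not None:
        qc = result.matrix.qc.merge(design, on="sample")
        report["read_accounting"] = (
            qc.groupby("group")[["reads_in", "too_short", "unassigned",
                                 "align_rejected", "aligned"]]
            .sum().astype(int).reset_index().to_dict(orient="records")
        )
        report["mean_conversion_efficiency_pct"] = float(
            result.matrix.conversion["efficiency_pct"].mean()
        )
    if result.amplicon_summary is not None:
        report["amplicon_summary"] = json.loads(
            result.amplicon_summary.round(3).to_json(orient="records")
        )
    if result.sex_differences is not None:
        report["sex_differences"] = json.loads(
            result.sex_differences.round(4).to_json(orient="records")
        )
    if result.density_fit is not None:
        report["density_fit"] = {
            "a": round(result.density_fit.a, 4),
            "b": round(result.density_fit.b, 4),
            "r_squared": round(result.density_fit.r_squared, 4),
        }
    if result.expression is not None:
        e = result.expression
        report["expression"] = {
            "fold_change_testes_over_ovaries": round(e.fold_change, 4),
            "t_statistic": None if np.isnan(e.t_statistic) else round(e.t_statistic, 4),
            "p_value": None if np.isnan(e.p_value) else round(e.p_value, 6),
        }
    if result.sex_typing is not None:
        report["sex_typing"] = result.sex_typing
        report["splice_events"] = {
            name: [dataclasses.asdict(ev) for ev in events]
            for name, events in (result.splice_events or {}).items()
        }
    return report


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    header = f"# seed={result.config.seed} config_hash={result.config.config_hash()}\n"
    def _tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    if result.matrix is not None:
        _tsv(result.matrix.long, "methylation_matrix.tsv")
        _tsv(result.matrix.conversion, "conversion_efficiency.tsv")
        if result.matrix.qc is not None:
            _tsv(result.matrix.qc, "qc.tsv")
    if result.amplicon_summary is not None:
        _tsv(result.amplicon_summary, "amplicon_summary.tsv")
    if result.cpg_tests is not None:
        _tsv(result.cpg_tests, "cpg_tests.tsv")
    if result.sex_differences is not None:
        _tsv(result.sex_differences, "sex_differences.tsv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
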