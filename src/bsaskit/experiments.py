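"""Parameter-recovery experiments: simulate under known truth, re-estimate.

These are the package's self-checks: simulate one cohort group for one
amplicon under the study's group mean/SD, push the reads through the full
quantification pipeline and recover the group mean; or simulate qPCR Ct
tables with a known fold change and recover it with the 2^-dCt analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .expression import compare_groups, relative_expression
from .panel import AmpliconPanel, load_default_panel
from .quantify import quantify_samples
from .simulate import (
    CohortDesign,
    GroupSpec,
    MethylationTruth,
    QpcrTruth,
    SimulationConfig,
    simulate_cohort,
    simulate_qpcr,
)


@dataclass
class MethylationRecovery:
    amplicon_id: str
    group: str
    truth_mean_pct: float
    truth_sd_pct: float
    estimate_pct: float      # mean over samples of per-sample amplicon means
    se_pct: float            # standard error of that mean over samples
    n_samples: int
    n_cpg: int


def recover_group_methylation(
    amplicon_id: str,
    group: str = "captive_testes",
    n_samples: int = 14,
    coverage: int = 2000,
    conversion_failure_rate: float = 0.005,
    sequencing_error_rate: float = 0.001,
    cpg_jitter_sd: float = 2.0,
    seed: int = 0,
    panel: AmpliconPanel | None = None,
) -> MethylationRecovery:
    """Simulate one group for one amplicon and recover its mean methylation.

    The per-sample true methylation is Beta-distributed with the group's
    configured mean/SD; the estimate is the mean over samples of each
    sample's amplicon-level methylation (mean over CpGs of the called
    percentages), with its standard error over samples.
    """
    panel = panel or load_default_panel()
    amp = panel.get(amplicon_id)
    origin, sex = group.split("_", 1)
    sub_panel = replace(
        panel,
        amplicons=[amp],
        group_methylation={amplicon_id: dict(panel.group_methylation[amplicon_id])},
    )
    design = CohortDesign([GroupSpec(sex, origin, n_samples)])
    config = SimulationConfig(
        design=design,
        coverage_per_amplicon=coverage,
        conversion_failure_rate=conversion_failure_rate,
        sequencing_error_rate=sequencing_error_rate,
        cpg_jitter_sd=cpg_jitter_sd,
        seed=seed,
    )
    cohort = simulate_cohort(config, sub_panel)
    matrix = quantify_samples(cohort.sample_reads(), cohort.panel, min_coverage=100)
    per_sample = matrix.long.groupby("sample")["pct_meth"].mean()
    mean, sd = panel.group_methylation[amplicon_id][group]
    return MethylationRecovery(
        amplicon_id=amplicon_id,
        group=group,
        truth_mean_pct=mean,
        truth_sd_pct=sd,
        estimate_pct=float(per_sample.mean()),
        se_pct=float(per_sample.std(ddof=1) / np.sqrt(len(per_sample))),
        n_samples=len(per_sample),
        n_cpg=amp.declared_cpg_count,
    )


@dataclass
class FoldChangeRecovery:
    truth_fold: float
    estimate: float          # mean over replicate simulations
    mc_se: float             # Monte-Carlo standard error over replicates
    n_reps: int
    n_per_sex: int


def recover_fold_change(
    truth_fold: float = 1.9,
    n_per_sex: int = 10,
    ct_noise_sd: float = 0.2,
    n_reps: int = 100,
    seed: int = 0,
    target_gene: str = "dmrt1",
) -> FoldChangeRecovery:
    """Simulate qPCR cohorts repeatedly and recover the fold change.

    Each replicate simulates triplicate Ct values for the target and the
    reference gene in both sexes, runs the 2^-dCt normalisation and the
    two-group comparison, and records the estimated testes/ovaries fold
    change; the estimate is averaged over replicates with its Monte-Carlo
    standard error.
    """
    qtruth = QpcrTruth(
        target_gene=target_gene, fold_change=truth_fold, ct_noise_sd=ct_noise_sd
    )
    design = {"testes": n_per_sex, "ovaries": n_per_sex}
    estimates = []
    for rep in range(n_reps):
        ct = simulate_qpcr(qtruth, design, seed=(seed * 100003 + rep) % (2**31))
        rel = relative_expression(ct, target_gene, qtruth.reference_gene)
        res = compare_groups(rel, gene=target_gene)
        estimates.append(res.fold_change)
    est = np.asarray(estimates)
    return FoldChangeRecovery(
        truth_fold=truth_fold,
        estimate=float(est.mean()),
        mc_se=float(est.std(ddof=1) / np.sqrt(len(est))),
        n_reps=n_reps,
        n_per_sex=n_per_sex,
    )
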