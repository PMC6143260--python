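"""Simulate a small bisulfite amplicon cohort and recover its methylation.

Per-sample amplicon methylation is Beta-distributed around each group's
configured mean/SD; reads carry incomplete conversion (0.5%) and
sequencing errors (0.1%).  The quantifier trims, filters, assigns reads
to amplicons by primer, aligns with bisulfite-aware scoring and reports
per-CpG percent methylation (the fraction of unconverted cytosines).
"""

import pandas as pd

from bsaskit import quantify_samples
from bsaskit.panel import load_default_panel
from bsaskit.simulate import (
    CohortDesign, GroupSpec, SimulationConfig, simulate_cohort,
)

design = CohortDesign([
    GroupSpec("testes", "captive", 4),
    GroupSpec("ovaries", "captive", 4),
])
config = SimulationConfig(design=design, coverage_per_amplicon=300, seed=42)
cohort = simulate_cohort(config, load_default_panel())
print(f"simulated {cohort.n_reads} reads "
      f"({design.n_samples} samples x {len(cohort.panel)} amplicons x "
      f"{config.coverage_per_amplicon} pairs)")

matrix = quantify_samples(cohort.sample_reads(), cohort.panel, min_coverage=100)
print("\nread accounting (first samples):")
print(matrix.qc.head(3).to_string(index=False))
print(f"\nmean conversion efficiency: {matrix.conversion.efficiency_pct.mean():.2f}% "
      f"(simulated failure rate 0.5% -> ~99.5% expected)")

truth = cohort.truth.groupby("amplicon_id").true_meth.mean() * 100
called = matrix.long.groupby("amplicon_id").pct_meth.mean()
comparison = pd.concat([truth, called], axis=1, keys=["truth_%", "called_%"]).round(2)
print("\nsimulated truth vs recovered methylation per amplicon:")
print(comparison.to_string())
print("\nthe called percentages track the simulated truth to within "
      "binomial sampling noise at this coverage.")
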