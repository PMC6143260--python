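"""Group-level statistics on the methylation matrix.

Four-group (sex x origin) comparisons use Kruskal–Wallis tests —
methylation percentages routinely violate homoscedasticity — followed by
Dunn pairwise z-tests with Holm adjustment summarised as a compact letter
display.  Amplicon summaries report each group's mean ± SD of per-sample
amplicon methylation, an "overall" column defined as the unweighted mean
of the four group means with the SD taken over all samples pooled, and
gene-level testes-minus-ovaries differences.  The relationship between
CpG density and methylation is modelled as a decaying exponential.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .panel import AmpliconPanel, cpg_density


def _sample_amplicon_values(matrix_long: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-sample amplicon-level methylation: mean over the amplicon's CpGs."""
    vals = (
        matrix_long.dropna(subset=["pct_meth"])
        .groupby(["sample", "gene", "amplicon_id"], as_index=False)["pct_meth"]
        .mean()
    )
    return vals.merge(design, on="sample", how="left")


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p (k-1 df).

    Identical values across all groups give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_pairwise(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum pairwise z-tests with Holm-adjusted p values.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    the tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(values_by_group)
    sizes = {g: len(values_by_group[g]) for g in names}
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    i = 0
    for g in names:
        mean_rank[g] = float(ranks[i : i + sizes[g]].mean())
        i += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        denom = base_var * (1.0 / sizes[a] + 1.0 / sizes[b])
        if denom <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / math.sqrt(denom)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    else:
        out["p_adj"] = []
    return out


def compact_letter_display(
    groups: list[str], significant_pairs: set[frozenset]
) -> dict[str, str]:
    """Insertion-algorithm compact letter display.

    Groups share a letter exactly when they are *not* significantly
    different; the output is invariant to relabeling the same partition
    of pairwise decisions.
    """
    columns: list[set[str]] = [set(groups)]
    for pair in sorted(significant_pairs, key=lambda p: tuple(sorted(p))):
        a, b = tuple(sorted(pair))
        for col in list(columns):
            if a in col and b in col:
                col_a, col_b = col - {b}, col - {a}
                columns.remove(col)
                for new in (col_a, col_b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # drop absorbed duplicates, order columns by their first group
    columns = [c for i, c in enumerate(columns) if not any(c < o or (c == o and j < i) for j, o in enumerate(columns))]
    order = {g: k for k, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    for k, col in enumerate(columns):
        ch = chr(ord("a") + k)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


def compact_letters(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> dict[str, str]:
    """Letter display from Dunn + Holm pairwise decisions at ``alpha``."""
    pairs = dunn_pairwise(values_by_group)
    sig = {
        frozenset((r.group_a, r.group_b))
        for r in pairs.itertuples()
        if r.p_adj < alpha
    }
    return compact_letter_display(list(values_by_group), sig)


def amplicon_group_summary(
    matrix_long: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.01,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Amplicon-level summary: group mean ± SD, overall column, letters.

    The per-sample amplicon value is the mean over the amplicon's CpGs;
    the overall mean is the *unweighted* mean of the group means while the
    overall SD pools all samples.  Empty groups produce missing cells with
    a warning.
    """
    vals = _sample_amplicon_values(matrix_long, design)
    groups = group_order or sorted(design["group"].unique())
    rows = []
    for (gene, amp_id), sub in vals.groupby(["gene", "amplicon_id"], sort=False):
        by_group = {g: sub.loc[sub.group == g, "pct_meth"].to_numpy() for g in groups}
        empties = [g for g, v in by_group.items() if len(v) == 0]
        if empties:
            warnings.warn(f"{amp_id}: empty group(s) {empties}")
        present = {g: v for g, v in by_group.items() if len(v)}
        letters = (
            compact_letters(present, alpha) if len(present) >= 2 else {g: "a" for g in present}
        )
        row: dict = {"gene": gene, "amplicon_id": amp_id}
        means = []
        for g in groups:
            v = by_group[g]
            row[f"{g}_mean"] = float(np.mean(v)) if len(v) else np.nan
            row[f"{g}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else (0.0 if len(v) else np.nan)
            row[f"{g}_n"] = len(v)
            row[f"{g}_letters"] = letters.get(g, "")
            if len(v):
                means.append(row[f"{g}_mean"])
        row["overall_mean"] = overall_mean(means)
        pooled = sub["pct_meth"].to_numpy()
        row["overall_sd"] = float(np.std(pooled, ddof=1)) if len(pooled) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def round_printed(value: float, ndigits: int = 1) -> float:
    """Round to printed table precision (decimal half-even, not float round).

    69.65 prints as 69.6 and 69.025 as 69.0; binary-float ``round`` would
    give 69.7 for the former.
    """
    from decimal import ROUND_HALF_EVEN, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(round(value, ndigits + 6))).quantize(q, ROUND_HALF_EVEN))


def overall_mean(group_means: list[float]) -> float:
    """Unweighted mean of group means (the 'Overall' column definition)."""
    clean = [m for m in group_means if not (m is None or np.isnan(m))]
    return float(np.mean(clean)) if clean else float("nan")


@dataclass
class CpGTestResult:
    gene: str
    amplicon_id: str
    position: int
    h_statistic: float
    p_value: float
    letters: dict[str, str]


def kruskal_wallis_per_cpg(
    matrix_long: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    with_letters: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-CpG four-group Kruskal–Wallis tests.

    No cross-CpG multiple-testing correction is applied by default (each
    site is tested on its own); pass ``fdr=True`` for an optional
    Benjamini–Hochberg column.  Letters come from Dunn + Holm at ``alpha``.
    """
    merged = matrix_long.dropna(subset=["pct_meth"]).merge(design, on="sample", how="left")
    groups = sorted(design["group"].unique())
    rows = []
    for (gene, amp_id, position), sub in merged.groupby(
        ["gene", "amplicon_id", "position"], sort=False
    ):
        by_group = [sub.loc[sub.group == g, "pct_meth"].to_numpy() for g in groups]
        by_group_named = {g: v for g, v in zip(groups, by_group) if len(v)}
        if len(by_group_named) < 2:
            continue
        h, p = kruskal_wallis(list(by_group_named.values()))
        letters = compact_letters(by_group_named, alpha) if with_letters else {}
        rows.append(
            {
                "gene": gene, "amplicon_id": amp_id, "position": position,
                "H": h, "p_value": p,
                **{f"letters_{g}": letters.get(g, "") for g in groups},
            }
        )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def sex_difference_table(
    matrix_long: pd.DataFrame,
    design: pd.DataFrame,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-gene testes-minus-ovaries methylation difference (points).

    ``pooled`` (default) averages all testes sample x CpG values against
    all ovary values; ``group_mean`` averages the per-origin group means
    instead.  The p value is a Mann–Whitney test across sexes on
    per-sample gene-level means.
    """
    if mode not in {"pooled", "group_mean"}:
        raise ValueError("mode must be 'pooled' or 'group_mean'")
    merged = matrix_long.dropna(subset=["pct_meth"]).merge(design, on="sample", how="left")
    rows = []
    for gene, sub in merged.groupby("gene", sort=False):
        per_sample = sub.groupby(["sample", "sex"], as_index=False)["pct_meth"].mean()
        t_vals = per_sample.loc[per_sample.sex == "testes", "pct_meth"].to_numpy()
        o_vals = per_sample.loc[per_sample.sex == "ovaries", "pct_meth"].to_numpy()
        if mode == "pooled":
            t_mean = float(sub.loc[sub.sex == "testes", "pct_meth"].mean())
            o_mean = float(sub.loc[sub.sex == "ovaries", "pct_meth"].mean())
        else:
            t_mean = float(
                sub[sub.sex == "testes"].groupby("group")["pct_meth"].mean().mean()
            )
            o_mean = float(
                sub[sub.sex == "ovaries"].groupby("group")["pct_meth"].mean().mean()
            )
        if len(t_vals) and len(o_vals) and not (
            np.all(np.concatenate([t_vals, o_vals]) == t_vals[0])
        ):
            _, p = stats.mannwhitneyu(t_vals, o_vals, alternative="two-sided")
        else:
            p = 1.0
        rows.append((gene, t_mean - o_mean, float(p)))
    return pd.DataFrame(rows, columns=["gene", "testes_minus_ovaries", "p_value"])


@dataclass
class DensityFit:
    a: float
    b: float
    r_squared: float
    residuals: np.ndarray

    def predict(self, density: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(density, float))


def density_methylation_fit(
    density: np.ndarray, methylation: np.ndarray
) -> DensityFit:
    """Least-squares fit of methylation = a * exp(-b * density).

    Initialised from a log-linear regression; a decaying relationship
    (b > 0) is the expected direction on promoter panels, where CpG-dense
    (island-like) amplicons are hypomethylated.
    """
    x = np.asarray(density, float)
    y = np.asarray(methylation, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("densities must be positive")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        p0 = (math.exp(intercept), -slope)
    else:
        p0 = (max(y.max(), 1.0), 0.1)
    try:
        (a, b), _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(-b * t), x, y, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    resid = y - a * np.exp(-b * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DensityFit(a=float(a), b=float(b), r_squared=r2, residuals=resid)


def panel_density_points(
    panel: AmpliconPanel, amplicon_means: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """(CpG density, methylation) points for a panel's amplicons."""
    dens, meth = [], []
    for a in panel:
        if a.amplicon_id in amplicon_means:
            dens.append(cpg_density(a))
            meth.append(amplicon_means[a.amplicon_id])
    return np.asarray(dens), np.asarray(meth)
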