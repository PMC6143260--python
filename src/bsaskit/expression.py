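"""RT-qPCR relative expression: standard curves, 2^-dCt, two-group tests.

Amplification efficiency is estimated from a serial-dilution standard
curve (E = 10^(-1/slope) - 1); relative expression uses the Livak 2^-dCt
normalisation against a reference gene; group comparison log-transforms
the 2^-dCt values, reports Lilliefors-corrected Kolmogorov–Smirnov and
Levene diagnostics, and applies a two-sample t-test.  Fold change is the
ratio of arithmetic group means of 2^-dCt (a geometric-mean option is
available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class StandardCurve:
    dilutions: np.ndarray
    mean_ct: np.ndarray
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    efficiency_ok: bool  # within the conventional [0.9, 1.1] band
    r_squared_ok: bool   # > 0.99


def standard_curve(
    ct_by_dilution: dict[float, list[float]] | pd.DataFrame,
    efficiency_band: tuple[float, float] = (0.9, 1.1),
    min_r_squared: float = 0.99,
) -> StandardCurve:
    """Efficiency and R^2 from a serial-dilution standard curve.

    Ordinary least squares of mean Ct on log10(dilution); efficiency
    E = 10^(-1/slope) - 1, so the perfect-doubling slope -3.3219 gives
    E = 1.  Needs at least 3 dilution points.
    """
    if isinstance(ct_by_dilution, pd.DataFrame):
        grouped = ct_by_dilution.groupby("dilution")["ct"].mean()
        dilutions = grouped.index.to_numpy(dtype=float)
        mean_ct = grouped.to_numpy(dtype=float)
    else:
        dilutions = np.array(sorted(ct_by_dilution), dtype=float)
        mean_ct = np.array([np.mean(ct_by_dilution[d]) for d in dilutions])
    if len(dilutions) < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    res = stats.linregress(np.log10(dilutions), mean_ct)
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    r2 = float(res.rvalue**2)
    return StandardCurve(
        dilutions=dilutions,
        mean_ct=mean_ct,
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=r2,
        efficiency_ok=efficiency_band[0] <= efficiency <= efficiency_band[1],
        r_squared_ok=r2 > min_r_squared,
    )


def relative_expression(
    ct_table: pd.DataFrame, target_gene: str, reference_gene: str = "ubq"
) -> pd.DataFrame:
    """Per-sample 2^-dCt of a target gene against the reference.

    Replicate Ct values are averaged per sample and gene before
    dCt = Ct(target) - Ct(reference); samples missing either gene are
    dropped with a warning.
    """
    means = (
        ct_table.groupby(["sample", "gene"], as_index=False)["ct"].mean()
        .pivot(index="sample", columns="gene", values="ct")
    )
    meta = ct_table[["sample", "group"]].drop_duplicates().set_index("sample")
    for gene in (target_gene, reference_gene):
        if gene not in means.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    ok = means[[target_gene, reference_gene]].notna().all(axis=1)
    dropped = means.index[~ok].tolist()
    if dropped:
        warnings.warn(f"samples missing {target_gene}/{reference_gene} Ct dropped: {dropped}")
    sub = means.loc[ok]
    delta_ct = sub[target_gene] - sub[reference_gene]
    out = pd.DataFrame(
        {
            "sample": sub.index,
            "group": meta.loc[sub.index, "group"].to_numpy(),
            "delta_ct": delta_ct.to_numpy(),
            "rel_expr": np.power(2.0, -delta_ct.to_numpy()),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class ExpressionResult:
    gene: str
    group_means: dict[str, float]
    fold_change: float  # testes / ovaries
    t_statistic: float
    p_value: float
    normality_p: dict[str, float]
    levene_p: float
    log_transformed: bool = True


def compare_groups(
    values: pd.DataFrame,
    gene: str = "",
    numerator: str = "testes",
    denominator: str = "ovaries",
    equal_var: bool = False,
    geometric: bool = False,
) -> ExpressionResult:
    """Two-group expression comparison on log-transformed 2^-dCt values.

    Normality (Lilliefors KS) and variance-homogeneity (Levene) checks on
    the log values are reported but do not gate the t-test (Welch by
    default; pass ``equal_var=True`` for Student's t).  Fold change is the
    ratio of arithmetic group means of 2^-dCt unless ``geometric``.
    """
    groups = {g: sub["rel_expr"].to_numpy() for g, sub in values.groupby("group")}
    for g in (numerator, denominator):
        if g not in groups or len(groups[g]) < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    a, b = groups[numerator], groups[denominator]
    log_a, log_b = np.log(a), np.log(b)
    normality = {}
    for name, lv in ((numerator, log_a), (denominator, log_b)):
        if np.ptp(lv) == 0:
            normality[name] = np.nan
        else:
            normality[name] = float(lilliefors(lv, dist="norm")[1])
    if np.ptp(log_a) == 0 and np.ptp(log_b) == 0:
        levene_p = np.nan
        t_stat, p = np.nan, (1.0 if np.mean(log_a) == np.mean(log_b) else np.nan)
        warnings.warn("degenerate variances: t-test p undefined")
    else:
        levene_p = float(stats.levene(log_a, log_b).pvalue)
        t_stat, p = stats.ttest_ind(log_a, log_b, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    if geometric:
        fold = float(np.exp(np.mean(log_a) - np.mean(log_b)))
    else:
        fold = float(np.mean(a) / np.mean(b))
    return ExpressionResult(
        gene=gene,
        group_means={numerator: float(np.mean(a)), denominator: float(np.mean(b))},
        fold_change=fold,
        t_statistic=t_stat,
        p_value=p,
        normality_p=normality,
        levene_p=levene_p,
    )


def expression_pipeline(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "ubq",
    **kwargs,
) -> tuple[pd.DataFrame, ExpressionResult]:
    """relative_expression + compare_groups in one call."""
    rel = relative_expression(ct_table, target_gene, reference_gene)
    return rel, compare_groups(rel, gene=target_gene, **kwargs)
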