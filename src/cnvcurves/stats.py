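"""Per-gene differential statistics for CNV and expression matrices.

Covers the statistics behind the volcano plot (log2 fold change vs
-log10 p), the regular and directional Manhattan plots (-log10 Q per gene,
optionally signed by the group-median difference), the deflection plot
(signed -log10 Q tracks of two cancer types vs their nonmalignant
controls), bee-swarm point layout, and CNV-expression Pearson/OLS
regression.

Multiple testing across genes is controlled with Benjamini-Hochberg
q-values by default (the volcano plot keeps raw p-values, as is customary);
a Bonferroni threshold alpha/n is available as the conservative
family-wise alternative.  The two-group test is Welch's unequal-variance t
by default, with a Mann-Whitney rank test as the option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gene_test",
    "adjust_pvalues",
    "bonferroni_threshold",
    "directional_sign",
    "manhattan_stats",
    "deflection_stats",
    "volcano_stats",
    "cnv_expression_correlation",
    "CorrelationResult",
    "beeswarm_layout",
]

_TINY_P = float(np.nextafter(0, 1))


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def gene_test(values1, values2, method: str = "t") -> float:
    """Two-sided p-value comparing two sample groups for one gene.

    ``method="t"`` is Welch's unequal-variance t-test; ``method="rank"`` is
    the Mann-Whitney U test.  Two identical constant groups give p = 1;
    constant-but-different groups (zero variance) give the smallest
    representable positive p with a warning.
    """
    a, b = _clean(values1), _clean(values2)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    if a.std() == 0 and b.std() == 0:
        if a[0] == b[0]:
            return 1.0
        warnings.warn(
            "zero variance in both groups with different values: p set to "
            "the smallest positive float"
        )
        return _TINY_P
    if method == "t":
        p = sps.ttest_ind(a, b, equal_var=False).pvalue
    elif method == "rank":
        p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test method {method!r}")
    return float(min(max(p, _TINY_P), 1.0))


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j >= i of (p_(j) * n / j) on the sorted p-values,
    capped at 1.  Input p-values must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n under Bonferroni control."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def directional_sign(median1: float, median2: float) -> int:
    """Direction of a gene's group difference for the directional Manhattan
    plot: -1 if the group-1 median is smaller (bar below the baseline),
    +1 if larger, 0 on a tie (plotted on the baseline)."""
    if not (math.isfinite(median1) and math.isfinite(median2)):
        raise ValueError("medians must be finite")
    if median1 < median2:
        return -1
    if median1 > median2:
        return 1
    return 0


def _two_group_table(
    matrix: pd.DataFrame, group1, group2, test: str
) -> pd.DataFrame:
    """Per-gene medians and p-values for two disjoint sample groups."""
    g1, g2 = list(group1), list(group2)
    if set(g1) & set(g2):
        raise ValueError("sample groups overlap")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for symbol, row in matrix.iterrows():
        v1 = _clean(row[g1])
        v2 = _clean(row[g2])
        if v1.size < 2 or v2.size < 2:
            continue
        rows.append(
            {
                "symbol": symbol,
                "median1": float(np.median(v1)),
                "median2": float(np.median(v2)),
                "mean1": float(np.mean(v1)),
                "mean2": float(np.mean(v2)),
                "p_value": gene_test(v1, v2, method=test),
            }
        )
    return pd.DataFrame(
        rows, columns=["symbol", "median1", "median2", "mean1", "mean2", "p_value"]
    )


def manhattan_stats(
    matrix: pd.DataFrame,
    group1,
    group2,
    directional: bool = False,
    test: str = "t",
    fdr: str = "bh",
) -> pd.DataFrame:
    """Per-gene -log10 q-values for a gene-level Manhattan plot.

    Q-values are computed by ``fdr`` over exactly the tested gene set.  In
    regular mode every sign is +1; in directional mode the sign follows
    :func:`directional_sign` of the group medians.
    """
    table = _two_group_table(matrix, group1, group2, test)
    if table.empty:
        raise ValueError("no gene is testable in both groups")
    table["q_value"] = adjust_pvalues(table["p_value"].to_numpy(), method=fdr)
    table["neg_log10_q"] = -np.log10(table["q_value"])
    if directional:
        table["sign"] = [
            directional_sign(m1, m2)
            for m1, m2 in zip(table["median1"], table["median2"])
        ]
    else:
        table["sign"] = 1
    return table[
        ["symbol", "median1", "median2", "p_value", "q_value", "neg_log10_q", "sign"]
    ]


def deflection_stats(
    tumor1: pd.DataFrame,
    normal1: pd.DataFrame,
    tumor2: pd.DataFrame,
    normal2: pd.DataFrame,
    test: str = "t",
    fdr: str = "bh",
) -> pd.DataFrame:
    """Signed -log10 Q deflection amplitudes of two cancer types.

    For cancer type k, ``amplitude_k = sign(tumor median - nonmalignant
    median) * (-log10 q_k)``; a gene deflecting downward has a smaller
    tumor median than its nonmalignant controls.  ``winner`` names the type
    with the larger absolute amplitude ("tie" on equality).
    """

    def one_type(tumor, normal):
        t_cols = list(tumor.columns)
        n_cols = list(normal.columns)
        mat = pd.concat([tumor, normal], axis=1, join="inner")
        table = _two_group_table(mat, t_cols, n_cols, test)
        table["q_value"] = adjust_pvalues(table["p_value"].to_numpy(), method=fdr)
        sign = np.sign(table["median1"] - table["median2"])
        table["amplitude"] = sign * (-np.log10(table["q_value"]))
        return table.set_index("symbol")[["q_value", "amplitude"]]

    t1 = one_type(tumor1, normal1)
    t2 = one_type(tumor2, normal2)
    common = t1.index.intersection(t2.index)
    if common.empty:
        raise ValueError("empty common gene set between the two cancer types")
    out = pd.DataFrame(
        {
            "symbol": common,
            "q1": t1.loc[common, "q_value"].to_numpy(),
            "amplitude1": t1.loc[common, "amplitude"].to_numpy(),
            "q2": t2.loc[common, "q_value"].to_numpy(),
            "amplitude2": t2.loc[common, "amplitude"].to_numpy(),
        }
    )
    a1, a2 = np.abs(out["amplitude1"]), np.abs(out["amplitude2"])
    out["winner"] = np.where(a1 > a2, "type1", np.where(a2 > a1, "type2", "tie"))
    return out.reset_index(drop=True)


def volcano_stats(
    matrix1: pd.DataFrame,
    matrix2: pd.DataFrame,
    cutoff: float = 0.05,
    value_kind: str = "expression",
    test: str = "t",
    pseudo_count: float = 1.0,
) -> pd.DataFrame:
    """Fold change and significance per gene for a volcano plot.

    In expression mode the effect is ``log2((mean1 + eps) / (mean2 + eps))``
    with pseudo-count eps (default 1.0 on RSEM-normalized counts); negative
    expression values are an error.  In CNV mode — where values are already
    log2 ratios, so a ratio of ratios would be meaningless — the effect is
    the difference of group means, still reported in the
    ``log2_fold_change`` column.  Significance uses the raw p-value (not Q),
    with ``significant`` true iff p < cutoff strictly.
    """
    mat = pd.concat([matrix1, matrix2], axis=1, join="inner")
    if value_kind == "expression" and (mat.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative values in expression mode")
    table = _two_group_table(mat, list(matrix1.columns), list(matrix2.columns), test)
    if value_kind == "expression":
        table["log2_fold_change"] = np.log2(
            (table["mean1"] + pseudo_count) / (table["mean2"] + pseudo_count)
        )
    elif value_kind == "cnv":
        table["log2_fold_change"] = table["mean1"] - table["mean2"]
    else:
        raise ValueError(f"unknown value_kind {value_kind!r}")
    table["neg_log10_p"] = -np.log10(table["p_value"])
    table["significant"] = table["p_value"] < cutoff
    return table[
        ["symbol", "log2_fold_change", "p_value", "neg_log10_p", "significant"]
    ]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation and OLS fit of expression on CNV for one gene."""

    symbol: str
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def cnv_expression_correlation(
    symbol: str,
    cnv: pd.DataFrame,
    expression: pd.DataFrame,
    sample_ids=None,
) -> CorrelationResult:
    """Pearson r and least-squares line of expression against CNV.

    Pairs the two matrices on shared samples (optionally restricted to
    ``sample_ids``), dropping pairs with a missing value; needs >= 3 pairs
    and non-constant vectors.
    """
    if symbol not in cnv.index or symbol not in expression.index:
        raise KeyError(f"gene {symbol!r} absent from one of the matrices")
    samples = [s for s in cnv.columns if s in set(expression.columns)]
    if sample_ids is not None:
        wanted = set(sample_ids)
        samples = [s for s in samples if s in wanted]
    x = cnv.loc[symbol, samples].to_numpy(dtype=float)
    y = expression.loc[symbol, samples].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 samples with both CNV and expression")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"undefined correlation for {symbol!r}: constant vector")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(
        symbol=symbol,
        pearson_r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )


def beeswarm_layout(values, point_diameter: float) -> np.ndarray:
    """Deterministic lateral offsets for a bee-swarm (packed strip) plot.

    Points are processed in sorted value order; each receives the
    smallest-magnitude lateral offset such that it sits at least one
    diameter (in the plane spanned by the value axis and the offset axis)
    from every previously placed point.  Offsets are symmetric around 0,
    positive side first on ties.
    """
    if point_diameter <= 0:
        raise ValueError("point_diameter must be positive")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return np.empty(0)
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    d = float(point_diameter)
    d2 = d * d
    eps = 1e-9 * d
    order = np.argsort(arr, kind="stable")
    offsets = np.empty(arr.size)
    placed: list = []  # (value, offset) of already-laid points
    for idx in order:
        v = arr[idx]
        near = [(pv, po) for pv, po in placed if (pv - v) ** 2 < d2]
        candidates = [0.0]
        for pv, po in near:
            dx = math.sqrt(max(d2 - (pv - v) ** 2, 0.0))
            candidates.extend((po + dx, po - dx))
        feasible = [
            c
            for c in candidates
            if all((pv - v) ** 2 + (po - c) ** 2 >= d2 - eps for pv, po in near)
        ]
        off = min(feasible, key=lambda c: (abs(c), -c))
        offsets[idx] = off
        placed.append((v, off))
    return offsets
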