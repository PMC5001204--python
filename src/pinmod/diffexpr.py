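"""Two-condition differential expression and significance filters.

Gene-level statistics are tidy :class:`pandas.DataFrame` tables:

* ``GeneStats``  — columns ``gene``, ``p_value``, ``log_fc`` (+ optional ``fdr``)
* ``MirnaStats`` — columns ``mirna``, ``p_value``, ``fold_change``

Expression matrices are log2-scale DataFrames (genes × samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "de_test",
    "select_sdgs",
    "select_significant_mirnas",
    "read_expression",
    "write_gene_stats",
    "read_gene_stats",
]


def read_expression(path) -> pd.DataFrame:
    """Read a genes × samples TSV (first column gene symbols, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return df


def de_test(
    control: pd.DataFrame, treated: pd.DataFrame, method: str = "welch"
) -> pd.DataFrame:
    """Per-gene two-sample test between log2 expression arms.

    Welch's unequal-variance t-test is the default; ``method="ranksum"``
    swaps in a Mann–Whitney U test without touching anything downstream.
    ``log_fc`` is mean(treated) − mean(control) on the log2 scale in either
    case. Genes with zero variance in both arms and equal means get p = 1
    (no evidence of change, rather than an undefined statistic).
    """
    if list(control.index) != list(treated.index):
        raise ValueError("control and treated gene lists differ")
    if control.shape[1] < 2 or treated.shape[1] < 2:
        raise ValueError("need >= 2 samples per arm")

    c = control.to_numpy(dtype=float)
    t = treated.to_numpy(dtype=float)
    log_fc = t.mean(axis=1) - c.mean(axis=1)

    if method == "welch":
        res = stats.ttest_ind(t, c, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    elif method == "ranksum":
        p = np.array(
            [stats.mannwhitneyu(t[i], c[i], alternative="two-sided").pvalue
             if (t[i].std() or c[i].std() or t[i].mean() != c[i].mean()) else 1.0
             for i in range(t.shape[0])]
        )
    else:
        raise ValueError(f"unknown DE method: {method!r}")

    degenerate = np.isnan(p)
    if degenerate.any():
        # zero variance in both arms: p=1 when means agree, p~0 otherwise
        eq = np.isclose(log_fc, 0.0)
        p[degenerate & eq] = 1.0
        p[degenerate & ~eq] = np.finfo(float).tiny
    # a p-value of exactly 0 breaks downstream log-scoring; clamp into (0,1]
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {"gene": control.index, "p_value": p, "log_fc": log_fc}
    ).reset_index(drop=True)


def select_sdgs(stats_table: pd.DataFrame, alpha: float = 0.01) -> set[str]:
    """Significantly differentially expressed genes: strict p < alpha.

    Deliberately applies no multiple-testing correction — the loose
    uncorrected threshold pre-selects candidates whose false positives the
    downstream network-module search is designed to absorb.
    """
    return set(stats_table.loc[stats_table["p_value"] < alpha, "gene"])


def select_significant_mirnas(
    stats_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """miRNAs with strict p < alpha, annotated with a regulation direction.

    Direction derives from the expression ratio (treated/control): ``up``
    for fold change > 1, ``down`` for < 1, ``ambiguous`` at exactly 1 (a
    significant p with no direction is kept and flagged, not dropped).
    """
    if (stats_table["fold_change"] <= 0).any():
        raise ValueError("fold_change must be positive")
    out = stats_table.loc[stats_table["p_value"] < alpha].copy()
    out["direction"] = np.select(
        [out["fold_change"] > 1, out["fold_change"] < 1],
        ["up", "down"],
        default="ambiguous",
    )
    return out.reset_index(drop=True)


def write_gene_stats(stats_table: pd.DataFrame, path) -> None:
    stats_table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "p_value"}
    if not required <= set(df.columns):
        raise ValueError(f"gene stats file lacks columns {required - set(df.columns)}")
    return df
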