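"""Expression normalization and two-condition differential expression.

Values are assumed pre-normalized intensities on a roughly log scale. The
z-transformation standardizes across genes within one condition (sample sd,
n−1); differential calls use the two-sided two-sample Student t-test with
pooled variance at P < 0.05, with Welch and Benjamini–Hochberg variants
available behind flags.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_ALPHA = 0.05


def z_transform(values: Sequence[float]) -> np.ndarray:
    """Standardize across genes: (x − mean) / sd with the n−1 denominator."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-transform undefined")
    return (x - x.mean()) / sd


def split_conditions(
    table: pd.DataFrame, sample_conditions: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a gene × sample table into its before/after replicate blocks."""
    before_cols = [c for c in table.columns if sample_conditions[c] == "before"]
    after_cols = [c for c in table.columns if sample_conditions[c] == "after"]
    if len(before_cols) < 2 or len(after_cols) < 2:
        raise ValueError("need >= 2 replicates per condition for a t-test")
    return table[before_cols], table[after_cols]


def differential_expression(
    table: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    alpha: float = DE_ALPHA,
    equal_var: bool = True,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided t-test between condition replicate sets.

    Pooled-variance Student t by default (``equal_var=False`` gives Welch);
    raw p-values against ``alpha`` by default, Benjamini–Hochberg-adjusted
    when ``bh_correct``. Returns gene_id-indexed mean_before, mean_after,
    t, pvalue, de (flag) and direction ('up'/'down', after vs before).
    """
    before, after = split_conditions(table, sample_conditions)
    b = before.to_numpy(float)
    a = after.to_numpy(float)
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    mean_b = b.mean(axis=1)
    mean_a = a.mean(axis=1)
    pvals = np.asarray(p, dtype=float)
    if bh_correct:
        pvals = multipletests(pvals, method="fdr_bh")[1]
    res = pd.DataFrame(
        {
            "mean_before": mean_b,
            "mean_after": mean_a,
            "t": np.asarray(t, dtype=float),
            "pvalue": pvals,
            "de": pvals < alpha,
            "direction": np.where(mean_a >= mean_b, "up", "down"),
        },
        index=table.index,
    )
    res.index.name = "gene_id"
    return res


def de_flags(de_table: pd.DataFrame) -> dict[str, bool]:
    """gene_id → DE flag mapping for the classification stage."""
    return {str(g): bool(f) for g, f in de_table["de"].items()}


def condition_mean_z(table: pd.DataFrame, sample_conditions: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene mean expression per condition, z-transformed across genes."""
    out = {}
    for cond in sorted(set(sample_conditions.values())):
        cols = [c for c in table.columns if sample_conditions[c] == cond]
        out[cond] = z_transform(table[cols].mean(axis=1).to_numpy())
    return pd.DataFrame(out, index=table.index)
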