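"""Nucleosome repositioning calls between two cellular states.

Each promoter nucleosome of the "before" map is paired with the nearest
"after"-map dyad center in the same promoter window; the center-to-center
distance is the displacement ΔN. A nucleosome is called repositioned when no
after-map partner lies within the threshold (300 bp, i.e. ±150 bp of a
placement able to cover the same linker); an empty after-window yields a
censored (infinite) displacement, counted as repositioned.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phasing import assign_to_windows

REPOSITION_THRESHOLD = 300

DISPLACEMENT_BINS = ("0", "(0,100]", "(100,200]", "(200,300]", ">300")


def match_and_call(
    before, after, windows: pd.DataFrame, threshold: int = REPOSITION_THRESHOLD
) -> pd.DataFrame:
    """Nearest-neighbor before→after matching within promoter windows.

    Returns one row per (before nucleosome, containing window): gene_id,
    chrom, before_center, rel_pos (TSS-relative before position),
    after_center (NaN when the after-window is empty), delta (bp; inf when
    censored) and status ('stable' / 'repositioned'). Matching is many-to-one:
    several before-nucleosomes may share an after partner.
    """
    b = assign_to_windows(before, windows)
    a = assign_to_windows(after, windows)
    if b.empty:
        return pd.DataFrame(
            columns=["gene_id", "chrom", "before_center", "rel_pos",
                     "after_center", "delta", "status"]
        )
    b = b.sort_values("gene_id", kind="stable").reset_index(drop=True)
    a_sorted = a.sort_values(["gene_id", "center"], kind="stable")
    after_by_gene = {
        g: grp["center"].to_numpy(np.int64) for g, grp in a_sorted.groupby("gene_id", sort=False)
    }
    deltas = np.empty(len(b), dtype=float)
    partners = np.full(len(b), np.nan)
    centers = b["center"].to_numpy(np.int64)
    genes = b["gene_id"].to_numpy()
    # contiguous per-gene segments after the sort
    seg_starts = np.flatnonzero(np.r_[True, genes[1:] != genes[:-1]])
    seg_ends = np.r_[seg_starts[1:], len(b)]
    for s, e in zip(seg_starts, seg_ends):
        cand = after_by_gene.get(genes[s])
        bc = centers[s:e]
        if cand is None or len(cand) == 0:
            deltas[s:e] = math.inf
            continue
        j = np.searchsorted(cand, bc)
        left = cand[np.clip(j - 1, 0, len(cand) - 1)]
        right = cand[np.clip(j, 0, len(cand) - 1)]
        use_left = np.abs(left - bc) <= np.abs(right - bc)
        nearest = np.where(use_left, left, right)
        deltas[s:e] = np.abs(nearest - bc)
        partners[s:e] = nearest
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "chrom": b["chrom"].to_numpy(),
            "before_center": centers,
            "rel_pos": b["rel_pos"].to_numpy(np.int64),
            "after_center": partners,
            "delta": deltas,
        }
    )
    out["status"] = np.where(out["delta"] > threshold, "repositioned", "stable")
    return out


def repositioned_fraction(calls: pd.DataFrame) -> float:
    """Fraction of before-map promoter nucleosomes called repositioned."""
    if calls.empty:
        raise ValueError("no repositioning calls")
    return float((calls["status"] == "repositioned").mean())


def displacement_distribution(calls) -> pd.Series:
    """Percentage of calls per displacement bin: {0}, (0,100], (100,200], (200,300], >300.

    Censored (infinite) displacements count in the >300 bin.
    """
    deltas = calls["delta"].to_numpy(float) if isinstance(calls, pd.DataFrame) \
        else np.asarray(calls, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty displacement sample")
    counts = np.array(
        [
            int((deltas == 0).sum()),
            int(((deltas > 0) & (deltas <= 100)).sum()),
            int(((deltas > 100) & (deltas <= 200)).sum()),
            int(((deltas > 200) & (deltas <= 300)).sum()),
            int((deltas > 300).sum()),
        ]
    )
    return pd.Series(100.0 * counts / deltas.size, index=list(DISPLACEMENT_BINS),
                     name="percent")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    Exact permutation enumeration when both samples have n ≤ 10 (two-sided
    p = probability of a rank-sum deviation from its permutation mean at
    least as large as observed); tie-corrected normal approximation
    otherwise. Returns (rank-sum statistic of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = float(ranks[: x.size].sum())
    if x.size <= 10 and y.size <= 10:
        n = x.size + y.size
        mu = x.size * ranks.mean()
        obs_dev = abs(w_obs - mu)
        hits = total = 0
        for comb in itertools.combinations(range(n), x.size):
            w = ranks[list(comb)].sum()
            total += 1
            if abs(w - mu) >= obs_dev - 1e-9:
                hits += 1
        return w_obs, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)


def compare_displacements(calls_a, calls_b) -> tuple[float, float, int, int]:
    """Compare two displacement distributions (Wilcoxon rank-sum, two-sided).

    Censored (infinite) displacements cannot be ranked and are excluded; the
    counts of excluded values are returned alongside (statistic, p-value).
    """
    da = calls_a["delta"].to_numpy(float) if isinstance(calls_a, pd.DataFrame) \
        else np.asarray(calls_a, dtype=float)
    db = calls_b["delta"].to_numpy(float) if isinstance(calls_b, pd.DataFrame) \
        else np.asarray(calls_b, dtype=float)
    censored_a = int(np.isinf(da).sum())
    censored_b = int(np.isinf(db).sum())
    da = da[np.isfinite(da)]
    db = db[np.isfinite(db)]
    if da.size == 0 or db.size == 0:
        raise ValueError("a sample has zero finite displacements")
    w, p = rank_sum_test(da, db)
    return w, p, censored_a, censored_b
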