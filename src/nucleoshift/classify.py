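"""TF binding-site × nucleosome co-occupancy classification.

Each binding site unique to the induced condition is anchored at its summit
and related to the nearest nucleosome dyad in each condition using the same
300-bp vicinity rule as the repositioning caller:

========================  ==========  =========
category                  d_before    d_after
========================  ==========  =========
repositioning_coupled     ≤ 300       > 300
co_occupied               ≤ 300       ≤ 300
nucleosome_independent    > 300       > 300
nucleosome_gained         > 300       ≤ 300
========================  ==========  =========

The fourth quadrant (a nucleosome arriving at a previously free site) is
reported as its own category rather than merged elsewhere. Sites map to
genes whose promoter window contains the summit; a gene reached by sites of
several categories is counted in every one of them.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import nucleosome_frame, peak_frame
from .phasing import assign_to_windows
from .repositioning import REPOSITION_THRESHOLD

CATEGORIES = (
    "repositioning_coupled",
    "co_occupied",
    "nucleosome_independent",
    "nucleosome_gained",
)


def unique_induced_peaks(after_peaks, before_peaks) -> pd.DataFrame:
    """After-condition peaks whose interval overlaps no before-condition peak."""
    a = peak_frame(after_peaks)
    b = peak_frame(before_peaks)
    keep = np.ones(len(a), dtype=bool)
    for chrom, bsub in b.groupby("chrom", sort=False):
        mask = (a["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = np.sort(bsub["start"].to_numpy(np.int64))
        # sort ends consistently with their own order for the sweep below
        ends = np.sort(bsub["end"].to_numpy(np.int64))
        a_start = a.loc[mask, "start"].to_numpy(np.int64)
        a_end = a.loc[mask, "end"].to_numpy(np.int64)
        # overlap exists iff some before-peak has start < a_end and end > a_start;
        # count before-peaks with start < a_end minus those with end <= a_start
        n_start_lt = np.searchsorted(starts, a_end, side="left")
        n_end_le = np.searchsorted(ends, a_start, side="right")
        keep[mask] = (n_start_lt - n_end_le) == 0
    return a[keep].reset_index(drop=True)


def nearest_nucleosome_distance(
    summits, nucleosomes, summit_chroms=None, footprint: int = 147
) -> np.ndarray:
    """Distance (bp) from each summit to the nearest nucleosome dyad center.

    Distance is |summit − center|, floored to 0 when the summit falls inside
    the nucleosome's footprint; inf when the chromosome holds no nucleosome.
    Accepts a peak table (chrom/summit columns) or parallel arrays.
    """
    if isinstance(summits, pd.DataFrame):
        chroms = summits["chrom"].to_numpy()
        pos = summits["summit"].to_numpy(np.int64)
    else:
        pos = np.asarray(summits, dtype=np.int64)
        chroms = np.asarray(summit_chroms)
    nuc = nucleosome_frame(nucleosomes)
    out = np.full(len(pos), math.inf)
    for chrom, sub in nuc.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        centers = np.sort(sub["center"].to_numpy(np.int64))
        p = pos[mask]
        j = np.searchsorted(centers, p)
        left = np.clip(j - 1, 0, len(centers) - 1)
        right = np.clip(j, 0, len(centers) - 1)
        d = np.minimum(np.abs(centers[left] - p), np.abs(centers[right] - p))
        d = np.where(d <= footprint // 2, np.maximum(d - footprint // 2, 0), d)
        out[mask] = d
    return out


def classify_sites(
    peaks,
    before_nucleosomes,
    after_nucleosomes,
    threshold: int = REPOSITION_THRESHOLD,
) -> pd.DataFrame:
    """Classify each peak by its nearest-nucleosome distances in both states.

    Returns the peak table with d_before, d_after and category columns. The
    category depends only on the two distances and the threshold, never on
    the peak's interval width.
    """
    p = peak_frame(peaks).reset_index(drop=True).copy()
    d_before = nearest_nucleosome_distance(p, before_nucleosomes)
    d_after = nearest_nucleosome_distance(p, after_nucleosomes)
    near_b = d_before <= threshold
    near_a = d_after <= threshold
    category = np.empty(len(p), dtype=object)
    category[near_b & ~near_a] = "repositioning_coupled"
    category[near_b & near_a] = "co_occupied"
    category[~near_b & ~near_a] = "nucleosome_independent"
    category[~near_b & near_a] = "nucleosome_gained"
    p["d_before"] = d_before
    p["d_after"] = d_after
    p["category"] = category
    return p


def depletion_ratio_profile(
    before_nucleosomes,
    after_nucleosomes,
    peaks,
    window: int = 300,
    span: int = 3000,
) -> pd.DataFrame:
    """After/before nucleosome-count ratio vs distance to the nearest summit.

    Every nucleosome of either map is assigned its distance to the nearest
    peak summit; counts fall in ``window``-bp distance bins over [0, span).
    Bins with a zero before-count have an undefined (NaN) ratio.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    p = peak_frame(peaks)
    if p.empty:
        raise ValueError("peak set is empty")
    edges = np.arange(0, span + window, window)

    def _counts(nucs) -> np.ndarray:
        nuc = nucleosome_frame(nucs)
        d = nearest_nucleosome_distance(
            nuc["center"].to_numpy(np.int64), p.rename(columns={"summit": "center"}),
            summit_chroms=nuc["chrom"].to_numpy(), footprint=0,
        )
        d = d[np.isfinite(d) & (d < edges[-1])]  # bins are half-open throughout
        counts, _ = np.histogram(d, bins=edges)
        return counts

    before_counts = _counts(before_nucleosomes)
    after_counts = _counts(after_nucleosomes)
    ratio = np.where(before_counts > 0, after_counts / np.maximum(before_counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "n_before": before_counts,
            "n_after": after_counts,
            "ratio": ratio,
        }
    )


def peaks_near_tss(peaks, annotation, max_dist: int = 10_000) -> dict[str, list[int]]:
    """Genes with >= 1 peak summit within ``max_dist`` bp (unsigned) of the TSS.

    Returns gene_id → row indices of the assigned peaks.
    """
    p = peak_frame(peaks).reset_index(drop=True)
    hits: dict[str, list[int]] = {}
    for t in annotation:
        mask = (p["chrom"] == t.chrom).to_numpy()
        if not mask.any():
            continue
        d = np.abs(p.loc[mask, "summit"].to_numpy(np.int64) - t.tss)
        idx = p.index[mask][d <= max_dist]
        if len(idx):
            hits[t.gene_id] = [int(i) for i in idx]
    return hits


def aggregate_genes(
    classified: pd.DataFrame,
    windows: pd.DataFrame,
    de_flags: Mapping[str, bool],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-site categories to genes and cross with DE status.

    A site maps to every gene whose promoter window contains its summit; a
    gene reached by several categories appears in each of them. Returns
    ``(gene_records, summary)``: one row per gene with its category set and
    DE flag, and a per-category summary (n_sites, n_genes, n_de, de_percent).
    """
    cls = classified.reset_index(drop=True).copy()
    cls["center"] = cls["summit"]
    assigned = assign_to_windows(cls[["chrom", "center", "category"]], windows)
    pairs = assigned[["gene_id", "category"]].drop_duplicates()
    gene_rows = (
        pairs.groupby("gene_id")["category"].apply(lambda s: sorted(set(s))).reset_index()
        .rename(columns={"category": "categories"})
    )
    gene_rows["de"] = gene_rows["gene_id"].map(lambda g: bool(de_flags.get(g, False)))
    summary = category_summary(
        {
            cat: (
                int((pairs["category"] == cat).sum()),
                int(gene_rows[gene_rows["categories"].map(lambda c: cat in c) & gene_rows["de"]].shape[0]),
            )
            for cat in CATEGORIES
        },
        n_sites={cat: int((cls["category"] == cat).sum()) for cat in CATEGORIES},
    )
    return gene_rows, summary


def category_summary(
    gene_counts: Mapping[str, tuple[int, int]],
    n_sites: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Build the per-category summary table from (n_genes, n_de) counts.

    ``de_percent`` is the exact percentage 100·n_de/n_genes (0 when the
    category is empty). This is the single code path every report-style
    percentage goes through.
    """
    rows = []
    for cat, (n_genes, n_de) in gene_counts.items():
        pct = 100.0 * n_de / n_genes if n_genes else 0.0
        rows.append(
            {
                "category": cat,
                "n_sites": (n_sites or {}).get(cat, np.nan),
                "n_genes": n_genes,
                "n_de": n_de,
                "de_percent": pct,
            }
        )
    return pd.DataFrame(rows)


def percent_of(numerator: int, denominator: int) -> float:
    """Exact percentage 100·k/n used throughout summary tables."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


def minus_one_shift(
    before_phased: pd.DataFrame,
    after_phased: pd.DataFrame,
    gene_ids: Iterable[str],
) -> float:
    """Mean −1-nucleosome displacement (bp) over genes, after − before rel_pos.

    Positive values move the −1 nucleosome toward the TSS. Genes lacking a −1
    nucleosome in either state are ignored; no eligible gene is an error.
    """
    genes = set(gene_ids)
    b = before_phased[(before_phased["label"] == -1) & before_phased["gene_id"].isin(genes)]
    a = after_phased[(after_phased["label"] == -1) & after_phased["gene_id"].isin(genes)]
    merged = b.merge(a, on="gene_id", suffixes=("_before", "_after"))
    if merged.empty:
        raise ValueError("no gene has a -1 nucleosome in both conditions")
    return float((merged["rel_pos_after"] - merged["rel_pos_before"]).mean())
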