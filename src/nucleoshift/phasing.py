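"""Promoter windows, TSS-anchored nucleosome phasing, and NFR geometry.

Promoters span −7.5 kb to +2.5 kb of the TSS in transcription direction.
Nucleosomes whose dyad center falls inside a window are assigned to that
gene and labeled sequentially outward from the TSS: the −1 nucleosome is the
one with the greatest negative TSS-relative position, +1 the smallest
non-negative one (a dyad exactly on the TSS counts as +1). The nucleosome-
free region (NFR) is the edge-to-edge gap between the −1 and +1 footprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import NUCLEOSOME_FOOTPRINT, GenomicInterval, Nucleosome, TSSRecord
from .io import nucleosome_frame

PROMOTER_UPSTREAM = 7500
PROMOTER_DOWNSTREAM = 2500


@dataclass(frozen=True)
class PromoterWindow:
    """A strand-aware promoter interval anchored at (and containing) its TSS."""

    gene_id: str
    interval: GenomicInterval
    tss: int
    strand: str


def promoter_window(
    tss: TSSRecord,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PromoterWindow:
    """[tss−upstream, tss+downstream) in transcription direction, clipped at 0."""
    if tss.strand == "+":
        start, end = tss.tss - upstream, tss.tss + downstream
    else:
        start, end = tss.tss - downstream, tss.tss + upstream
    start = max(0, start)
    return PromoterWindow(tss.gene_id, GenomicInterval(tss.chrom, start, end), tss.tss, tss.strand)


def promoter_windows_frame(
    annotation: Iterable[TSSRecord],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.DataFrame:
    """Flat table of promoter windows (gene_id, chrom, start, end, tss, strand)."""
    rows = []
    for t in annotation:
        w = promoter_window(t, upstream, downstream)
        rows.append((w.gene_id, w.interval.chrom, w.interval.start, w.interval.end, w.tss, w.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "tss", "strand"])


def tss_relative_position(center: Union[int, Nucleosome], tss: TSSRecord) -> int:
    """Signed bp from the TSS, transcription direction positive."""
    if isinstance(center, Nucleosome):
        if center.chrom != tss.chrom:
            raise ValueError(
                f"chromosome mismatch: nucleosome on {center.chrom}, TSS on {tss.chrom}"
            )
        center = center.center
    return center - tss.tss if tss.strand == "+" else tss.tss - center


def assign_to_windows(positions, windows: pd.DataFrame, pos_col: str = "center") -> pd.DataFrame:
    """Assign point positions to every promoter window containing them.

    Returns one row per (position, window) pair with the window's gene_id and
    the strand-aware TSS-relative position. Positions outside all windows are
    dropped; overlapping windows multiply-assign.
    """
    df = positions if isinstance(positions, pd.DataFrame) else nucleosome_frame(positions)
    take: list[np.ndarray] = []     # positional indices into df
    gene_ids: list[np.ndarray] = []
    rels: list[np.ndarray] = []
    pos_all = df[pos_col].to_numpy(np.int64)
    for chrom, wchrom in windows.groupby("chrom", sort=False):
        sub_idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        if sub_idx.size == 0:
            continue
        pos = pos_all[sub_idx]
        order = np.argsort(pos, kind="stable")
        sorted_pos = pos[order]
        for w in wchrom.itertuples(index=False):
            lo = np.searchsorted(sorted_pos, w.start, side="left")
            hi = np.searchsorted(sorted_pos, w.end, side="left")
            if hi <= lo:
                continue
            idx = sub_idx[order[lo:hi]]
            take.append(idx)
            gene_ids.append(np.repeat(w.gene_id, hi - lo))
            rel = pos_all[idx] - w.tss
            if w.strand == "-":
                rel = -rel
            rels.append(rel)
    if not take:
        res = df.iloc[0:0].copy()
        res["_src"] = pd.Series(dtype=np.int64)
        res["gene_id"] = pd.Series(dtype=object)
        res["rel_pos"] = pd.Series(dtype=np.int64)
        return res
    idx = np.concatenate(take)
    res = df.iloc[idx].reset_index(drop=True)
    res["_src"] = idx
    res["gene_id"] = np.concatenate(gene_ids)
    res["rel_pos"] = np.concatenate(rels)
    return res


def assign_and_label(nucleosomes, windows: pd.DataFrame):
    """Assign nucleosomes to promoters and label phased positions.

    Returns ``(phased, label_freq, n_dropped)`` where ``phased`` has one row
    per assigned nucleosome with columns gene_id, chrom, center, rel_pos and
    label (…,−2,−1,+1,+2,…), and ``label_freq`` gives the percentage of all
    assigned nucleosomes per label.
    """
    df = nucleosome_frame(nucleosomes)
    phased = assign_to_windows(df, windows)
    n_dropped = len(df) - (phased["_src"].nunique() if "_src" in phased else 0)
    phased = phased.drop(columns=["_src"], errors="ignore")
    if phased.empty:
        phased["label"] = pd.Series(dtype=np.int64)
        return phased, pd.Series(dtype=float), n_dropped
    phased = phased.sort_values(["gene_id", "rel_pos"], kind="stable").reset_index(drop=True)
    grp = phased.groupby("gene_id", sort=False)
    pos_in_group = grp.cumcount().to_numpy()
    n_upstream = grp["rel_pos"].transform(lambda r: int((r.to_numpy() < 0).sum())).to_numpy()
    label = np.where(
        pos_in_group < n_upstream,
        pos_in_group - n_upstream,        # …,-2,-1 ordered by rel_pos
        pos_in_group - n_upstream + 1,    # +1,+2,… (rel_pos >= 0)
    )
    phased["label"] = label.astype(np.int64)
    label_freq = 100.0 * phased["label"].value_counts().sort_index() / len(phased)
    return phased, label_freq, n_dropped


def nfr_width(
    phased_gene: pd.DataFrame, footprint: int = NUCLEOSOME_FOOTPRINT
) -> Optional[int]:
    """Edge-to-edge −1/+1 gap: max(0, rel(+1) − rel(−1) − footprint).

    ``None`` (undefined) when the gene lacks a −1 or a +1 nucleosome.
    """
    lab = phased_gene.set_index("label")["rel_pos"]
    if -1 not in lab.index or 1 not in lab.index:
        return None
    return int(max(0, int(lab.loc[1]) - int(lab.loc[-1]) - footprint))


def nfr_table(phased: pd.DataFrame, footprint: int = NUCLEOSOME_FOOTPRINT) -> pd.Series:
    """Per-gene NFR width (NaN where −1 or +1 is missing)."""
    anchors = phased[phased["label"].isin([-1, 1])]
    piv = anchors.pivot_table(index="gene_id", columns="label", values="rel_pos")
    if piv.empty or -1 not in piv.columns or 1 not in piv.columns:
        return pd.Series(dtype=float, name="nfr_width")
    width = (piv[1] - piv[-1] - footprint).clip(lower=0)
    width.name = "nfr_width"
    return width


def occupancy_expression_correlation(
    counts: Sequence[float], expression_z: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (+ p-value) of per-promoter nucleosome count vs mean z-expression."""
    x = np.asarray(counts, dtype=float)
    y = np.asarray(expression_z, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in counts or expression")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def repositioned_tss_profile(
    calls: pd.DataFrame,
    windows: pd.DataFrame,
    bin_size: int = 100,
    span: tuple[int, int] = (-PROMOTER_UPSTREAM, PROMOTER_DOWNSTREAM),
) -> pd.Series:
    """Histogram of repositioned-nucleosome TSS-relative positions.

    ``calls`` is the repositioning module's call table; counts are of calls
    with status 'repositioned', binned by the before-nucleosome rel_pos in
    ``bin_size``-bp bins over ``span``.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    lo, hi = span
    edges = np.arange(lo, hi + bin_size, bin_size)
    repositioned = calls[calls["status"] == "repositioned"]
    if repositioned.empty:
        counts = np.zeros(len(edges) - 1, dtype=np.int64)
    else:
        rel = repositioned["rel_pos"].to_numpy(float)
        rel = rel[rel < edges[-1]]  # keep every bin half-open
        counts, _ = np.histogram(rel, bins=edges)
    return pd.Series(counts, index=pd.IntervalIndex.from_breaks(edges, closed="left"),
                     name="n_repositioned")
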