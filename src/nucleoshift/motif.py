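"""Fixed-width Gibbs-sampling motif discovery and PWM scanning.

The classical site sampler: every sequence contributes exactly one motif
site. One sweep holds each sequence out in turn, builds the position weight
matrix (PWM) from the remaining sites with 0.5 pseudocounts, and re-samples
the held-out site proportional to the PWM/background likelihood ratio. The
best-scoring alignment over a fixed iteration budget and several random
restarts is returned; runs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

MOTIF_WIDTH = 12
PSEUDOCOUNT = 0.5


def encode(seq) -> np.ndarray:
    """Sequence (str / SeqRecord) → int8 array over A=0, C=1, G=2, T=3."""
    s = str(getattr(seq, "seq", seq)).upper()
    try:
        return np.array([_INDEX[b] for b in s], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from None


@dataclass
class PWM:
    """Per-position nucleotide frequencies plus the background they are scored against."""

    probs: np.ndarray          # (width, 4), rows sum to 1
    background: np.ndarray     # (4,), sums to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("each PWM position must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background), the scanning score matrix (bits)."""
        return np.log2(self.probs / self.background[None, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs.T, index=list(ALPHABET),
                            columns=[f"pos{i+1}" for i in range(self.width)])


def information_content(pwm: PWM) -> tuple[np.ndarray, float]:
    """Bits per position (2 + Σ f·log2 f, uniform background) and their sum."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm.probs > 0, pwm.probs * np.log2(pwm.probs), 0.0)
    per_pos = 2.0 + plogp.sum(axis=1)
    return per_pos, float(per_pos.sum())


def _window_matrix(enc: np.ndarray, width: int) -> np.ndarray:
    """(n_windows, width) view of all length-`width` windows."""
    n = enc.size - width + 1
    return np.lib.stride_tricks.sliding_window_view(enc, width)[:n]


def _counts_from_sites(encs, offsets, width: int) -> np.ndarray:
    counts = np.zeros((width, 4), dtype=float)
    for enc, off in zip(encs, offsets):
        if off >= 0:
            np.add.at(counts, (np.arange(width), enc[off:off + width]), 1.0)
    return counts


def _background(encs) -> np.ndarray:
    counts = np.bincount(np.concatenate(encs), minlength=4).astype(float)
    counts += 1.0  # never zero, even for degenerate compositions
    return counts / counts.sum()


def _state_score(encs, offsets, width: int, background: np.ndarray,
                 pseudocount: float) -> float:
    counts = _counts_from_sites(encs, offsets, width)
    probs = (counts + pseudocount) / (counts.sum(axis=1)[:, None] + 4 * pseudocount)
    lo = np.log2(probs / background[None, :])
    return float(sum(lo[np.arange(width), enc[o:o + width]].sum()
                     for enc, o in zip(encs, offsets)))


def gibbs_sample_motif(
    sequences: Iterable,
    width: int = MOTIF_WIDTH,
    iterations: int = 150,
    restarts: int = 3,
    seed: Optional[int] = None,
    pseudocount: float = PSEUDOCOUNT,
):
    """Discover one fixed-width motif; returns (PWM, per-sequence offsets, score).

    The score is the summed log2 likelihood ratio of the chosen sites under
    the final alignment's PWM; the best state seen across all iterations and
    restarts is kept.
    """
    seq_list = list(sequences)
    ids = [getattr(s, "id", f"seq{i}") for i, s in enumerate(seq_list)]
    encs = [encode(s) for s in seq_list]
    if len(encs) < 5:
        raise ValueError("need >= 5 sequences for motif discovery")
    for sid, enc in zip(ids, encs):
        if enc.size < width:
            raise ValueError(f"sequence {sid!r} shorter than motif width {width}")
    background = _background(encs)
    log_bg = np.log2(background)
    windows = [_window_matrix(enc, width) for enc in encs]
    bg_win = [log_bg[w].sum(axis=1) for w in windows]

    best_offsets = None
    best_score = -np.inf
    for child in np.random.SeedSequence(seed).spawn(max(1, restarts)):
        rng = np.random.default_rng(child)
        offsets = np.array([rng.integers(0, enc.size - width + 1) for enc in encs])
        counts = _counts_from_sites(encs, offsets, width)
        pos_idx = np.arange(width)
        for _ in range(iterations):
            for i, enc in enumerate(encs):
                np.add.at(counts, (pos_idx, enc[offsets[i]:offsets[i] + width]), -1.0)
                probs = (counts + pseudocount) / (len(encs) - 1 + 4 * pseudocount)
                lo = np.log2(probs)
                scores = lo[pos_idx, windows[i]].sum(axis=1) - bg_win[i]
                w = np.exp2(scores - scores.max())
                offsets[i] = rng.choice(len(w), p=w / w.sum())
                np.add.at(counts, (pos_idx, enc[offsets[i]:offsets[i] + width]), 1.0)
            # phase-shift move: sliding the whole alignment fixes the register
            # errors a per-sequence sampler cannot escape on its own
            score = _state_score(encs, offsets, width, background, pseudocount)
            best_delta = 0
            for delta in (-3, -2, -1, 1, 2, 3):
                cand = offsets + delta
                if all(0 <= cand[i] <= encs[i].size - width for i in range(len(encs))):
                    s = _state_score(encs, cand, width, background, pseudocount)
                    if s > score:
                        best_delta, score = delta, s
            if best_delta:
                offsets = offsets + best_delta
                counts = _counts_from_sites(encs, offsets, width)
            if score > best_score:
                best_score = score
                best_offsets = offsets.copy()
    counts = _counts_from_sites(encs, best_offsets, width)
    probs = (counts + pseudocount) / (len(encs) + 4 * pseudocount)
    pwm = PWM(probs, background)
    sites = pd.DataFrame({"seq_id": ids, "offset": best_offsets.astype(int)})
    return pwm, sites, best_score


def _revcomp(enc: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[enc[::-1]]


def motif_scan(
    pwm: PWM,
    sequences: Iterable,
    threshold: Optional[float] = None,
    center_window: int = 50,
):
    """Best log-odds window per sequence on both strands.

    Returns ``(hits, summary)``: per-sequence best offset/strand/score (bits)
    and distance of the hit center to the sequence center, plus the fraction
    of sequences whose best score reaches ``threshold`` and the fraction of
    those hits within ``center_window`` bp of the sequence center. The
    default threshold is half the PWM's maximal attainable log-odds, which
    separates degenerate matches from the best window of a random sequence.
    """
    if threshold is None:
        threshold = 0.5 * float(pwm.log_odds.max(axis=1).sum())
    seq_list = list(sequences)
    ids = [getattr(s, "id", f"seq{i}") for i, s in enumerate(seq_list)]
    lo = pwm.log_odds
    pos_idx = np.arange(pwm.width)
    rows = []
    for sid, s in zip(ids, seq_list):
        enc = encode(s)
        if enc.size < pwm.width:
            raise ValueError(f"sequence {sid!r} shorter than motif width")
        best_score, best_off, best_strand = -np.inf, 0, "+"
        for strand, e in (("+", enc), ("-", _revcomp(enc))):
            scores = lo[pos_idx, _window_matrix(e, pwm.width)].sum(axis=1)
            k = int(scores.argmax())
            if scores[k] > best_score:
                best_score = float(scores[k])
                # minus-strand windows are reported in forward coordinates
                best_off = k if strand == "+" else enc.size - pwm.width - k
                best_strand = strand
        center_dist = (best_off + pwm.width / 2.0) - enc.size / 2.0
        rows.append(
            {
                "seq_id": sid,
                "offset": best_off,
                "strand": best_strand,
                "score": best_score,
                "center_distance": center_dist,
                "hit": best_score >= threshold,
            }
        )
    hits = pd.DataFrame(rows)
    n_hit = int(hits["hit"].sum())
    frac_with_hit = n_hit / len(hits) if len(hits) else 0.0
    near = hits.loc[hits["hit"], "center_distance"].abs() <= center_window
    frac_central = float(near.mean()) if n_hit else 0.0
    summary = {
        "n_sequences": len(hits),
        "fraction_with_hit": float(frac_with_hit),
        "fraction_hits_within_center_window": frac_central,
        "center_window": center_window,
        "threshold": threshold,
    }
    return hits, summary
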