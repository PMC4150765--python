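"""Coordinate model and domain records.

All genomic arithmetic in this package is 0-based, half-open (BED native).
A nucleosome is represented by its dyad center plus a fixed footprint
(147 bp by default); a TF peak by its interval plus a point summit. Strand
is carried only by TSS records — every signed distance in the pipeline is
measured in the transcription direction of the anchoring gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

NUCLEOSOME_FOOTPRINT = 147  # bp of DNA wrapped around the histone octamer

#: conditions a record may be tagged with (before/after TF induction, TF-depleted)
CONDITIONS = ("before", "after", "depleted")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint; the dyad center of a 147-bp footprint interval."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site; the origin of all promoter-relative coordinates."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass(frozen=True)
class Nucleosome:
    """A positioned nucleosome: dyad center + footprint extent."""

    chrom: str
    center: int
    footprint: int = NUCLEOSOME_FOOTPRINT
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.footprint <= 0:
            raise ValueError("footprint must be positive")

    @property
    def interval(self) -> GenomicInterval:
        start = self.center - self.footprint // 2
        return GenomicInterval(self.chrom, max(0, start), max(0, start) + self.footprint)


@dataclass(frozen=True)
class Peak:
    """A TF binding interval with a point summit (defaults to the midpoint)."""

    chrom: str
    start: int
    end: int
    summit: Optional[int] = None
    condition: Optional[str] = None
    score: Optional[float] = None
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.summit is None:
            object.__setattr__(self, "summit", (self.start + self.end) // 2)
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside interval [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)
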