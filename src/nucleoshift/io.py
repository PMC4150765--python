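"""Readers/writers for the plain-text formats the pipeline touches.

BED3/BED6 for nucleosome footprints and TF peaks (an optional 7th column
carries the summit offset from the interval start), BED6 or 4-column TSV for
TSS annotations, TSV for replicate expression, FASTA (via Biopython) for peak
sequences. Tabular in-memory containers are pandas DataFrames; small record
collections are lists of the dataclasses in :mod:`nucleoshift.core`.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import NUCLEOSOME_FOOTPRINT, Nucleosome, Peak, TSSRecord


class FormatError(ValueError):
    """A malformed input line; the message names the offending line number."""


def _split_line(line: str, path: str, lineno: int, min_cols: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise FormatError(
            f"{path}:{lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    return fields


def _parse_coords(fields: Sequence[str], path: str, lineno: int) -> tuple[str, int, int]:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    if not chrom:
        raise FormatError(f"{path}:{lineno}: empty chromosome name")
    if start < 0 or end <= start:
        raise FormatError(
            f"{path}:{lineno}: invalid interval [{start}, {end}) (end <= start?)"
        )
    return chrom, start, end


def read_bed(
    path: Union[str, os.PathLike],
    record_kind: str,
    condition: Optional[str] = None,
    footprint: int = NUCLEOSOME_FOOTPRINT,
) -> list:
    """Read a BED3/BED6 file as nucleosomes or peaks.

    Nucleosome center = interval midpoint (floor). Peak summit = midpoint
    unless a 7th column gives the summit offset from ``start``.
    """
    if record_kind not in ("nucleosome", "peak"):
        raise ValueError(f"record_kind must be 'nucleosome' or 'peak', got {record_kind!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, str(path), lineno, 3)
            chrom, start, end = _parse_coords(fields, str(path), lineno)
            if record_kind == "nucleosome":
                records.append(
                    Nucleosome(chrom, (start + end) // 2, footprint, condition)
                )
            else:
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = None
                if len(fields) > 4 and fields[4] not in (".", ""):
                    try:
                        score = float(fields[4])
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
                summit = None
                if len(fields) > 6 and fields[6] not in (".", ""):
                    try:
                        summit = start + int(fields[6])
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: non-integer summit offset") from exc
                records.append(
                    Peak(chrom, start, end, summit=summit, condition=condition,
                         score=score, name=name)
                )
    return records


def write_bed(records: Iterable[Union[Nucleosome, Peak]], path: Union[str, os.PathLike]) -> None:
    """Write nucleosomes (BED3) or peaks (BED6 + summit-offset column)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, Nucleosome):
                iv = rec.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "." if rec.score is None else f"{rec.score:g}"
                name = rec.name or "."
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t{score}\t.\t"
                    f"{rec.summit - rec.start}\n"
                )


def read_tss(path: Union[str, os.PathLike]) -> list[TSSRecord]:
    """Read a TSS annotation from BED6 or from a 4-column TSV.

    BED6: TSS = start for '+' genes, end − 1 for '−' genes; name column is the
    gene id. TSV: columns gene_id, chrom, position, strand. Duplicate gene ids
    are an error.
    """
    records: list[TSSRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 6 and fields[1].lstrip("-").isdigit() and fields[2].lstrip("-").isdigit():
                chrom, start, end = _parse_coords(fields, str(path), lineno)
                gene_id, strand = fields[3], fields[5]
                tss = start if strand == "+" else end - 1
            elif len(fields) == 4:
                gene_id, chrom, pos, strand = fields
                try:
                    tss = int(pos)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer TSS position") from exc
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected BED6 or 4-column TSV (gene, chrom, pos, strand)"
                )
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicated gene_id {gene_id!r}")
            seen.add(gene_id)
            records.append(TSSRecord(gene_id, chrom, tss, strand))
    return records


def write_tss(records: Iterable[TSSRecord], path: Union[str, os.PathLike]) -> None:
    """Write a TSS annotation as BED6 (one 1-bp feature per gene)."""
    with open(path, "w") as fh:
        for rec in records:
            # 1-bp feature: start = tss and end-1 = tss hold on both strands
            fh.write(
                f"{rec.chrom}\t{rec.tss}\t{rec.tss + 1}\t{rec.gene_id}\t0\t{rec.strand}\n"
            )


def read_expression(
    path: Union[str, os.PathLike],
    sample_conditions: Mapping[str, str],
    annotation: Optional[Iterable[TSSRecord]] = None,
) -> pd.DataFrame:
    """Read a gene × sample expression TSV.

    The header row names the samples; ``sample_conditions`` maps each sample
    to its condition and must cover the header exactly. If an annotation is
    given, genes absent from it are retained and flagged in
    ``df.attrs['unannotated']``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression table")
    missing = set(df.columns) - set(sample_conditions)
    extra = set(sample_conditions) - set(df.columns)
    if missing or extra:
        raise FormatError(
            f"{path}: header/sample-map mismatch "
            f"(unmapped samples: {sorted(missing)}; absent samples: {sorted(extra)})"
        )
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise FormatError(f"{path}: non-numeric values in column(s) {list(non_numeric)}")
    if df.isna().any().any():
        raise FormatError(f"{path}: non-numeric or missing cells")
    df.attrs["sample_conditions"] = dict(sample_conditions)
    if annotation is not None:
        known = {t.gene_id for t in annotation}
        df.attrs["unannotated"] = [g for g in df.index if g not in known]
    return df


def write_expression(df: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_fasta(path: Union[str, os.PathLike]) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord], path: Union[str, os.PathLike]) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def make_seq_record(seq: str, seq_id: str, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(seq), id=seq_id, description=description)


# ---------------------------------------------------------------------------
# DataFrame views: the analysis modules operate on flat tables.

def nucleosome_frame(nucleosomes) -> pd.DataFrame:
    """Normalize a nucleosome collection to a (chrom, center, footprint) table."""
    if isinstance(nucleosomes, pd.DataFrame):
        return nucleosomes
    rows = [(n.chrom, n.center, n.footprint) for n in nucleosomes]
    return pd.DataFrame(rows, columns=["chrom", "center", "footprint"]).astype(
        {"center": np.int64, "footprint": np.int64}
    )


def peak_frame(peaks) -> pd.DataFrame:
    """Normalize a peak collection to a (chrom, start, end, summit) table."""
    if isinstance(peaks, pd.DataFrame):
        return peaks
    rows = [(p.chrom, p.start, p.end, p.summit) for p in peaks]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"]).astype(
        {"start": np.int64, "end": np.int64, "summit": np.int64}
    )
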