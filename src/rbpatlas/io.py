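"""Readers and writers: BED, FASTA, read-record TSV, typed tables.

All coordinates are 0-based half-open and round-trip bit-exactly through
every reader/writer pair.  Malformed records raise errors that name the
offending line; schema mismatches name the missing column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .reads import ReadRecord, TSV_COLUMNS

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
#: BED6+4 extension for replicate peak scores
PEAK_EXTRA_COLUMNS = ["l2fc_rep1", "nlp_rep1", "l2fc_rep2", "nlp_rep2"]


class FormatError(ValueError):
    pass


def read_bed(path: str | Path, extra_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read BED3/BED6(+extras) with validation; extra columns are floats."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            row = {"chrom": fields[0], "start": start, "end": end}
            if len(fields) >= 6:
                row["name"] = fields[3]
                row["score"] = fields[4]
                row["strand"] = fields[5]
                if row["strand"] not in "+-.":
                    raise FormatError(f"{path}:{lineno}: bad strand {row['strand']!r}")
            for i, col in enumerate(extra_columns):
                if 6 + i >= len(fields):
                    raise FormatError(f"{path}:{lineno}: missing column {col!r}")
                row[col] = float(fields[6 + i])
            rows.append(row)
    cols = ["chrom", "start", "end"]
    if rows and "name" in rows[0]:
        cols = BED6_COLUMNS + list(extra_columns)
    return pd.DataFrame(rows, columns=cols if rows else cols)


def write_bed(df: pd.DataFrame, path: str | Path,
              extra_columns: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            d = row._asdict()
            fields = [str(d["chrom"]), str(d["start"]), str(d["end"])]
            if "name" in d or extra_columns:
                fields += [
                    str(d.get("name", f"region_{i}")),
                    str(d.get("score", 0)),
                    str(d.get("strand", ".")),
                ]
            fields += [repr(float(d[c])) for c in extra_columns]
            fh.write("\t".join(fields) + "\n")


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """BED6+4 peaks with per-replicate log2FC and -log10 p columns."""
    return read_bed(path, extra_columns=PEAK_EXTRA_COLUMNS)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]


def read_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    """TSV reader with explicit column checks and dtype coercion."""
    df = pd.read_csv(path, sep="\t")
    for col, dtype in schema.items():
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        df[col] = df[col].astype(dtype)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_read_records(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.read_id, r.umi, r.start, r.stop, r.strand,
                        r.target, r.alignment_score, r.mismatches,
                    )
                )
                + "\n"
            )


def read_read_records(path: str | Path) -> list[ReadRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise FormatError(f"{path}: unexpected read-record header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(TSV_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong field count")
            try:
                out.append(
                    ReadRecord(
                        read_id=f[0], umi=f[1], start=int(f[2]), stop=int(f[3]),
                        strand=f[4], target=f[5],
                        alignment_score=int(f[6]), mismatches=int(f[7]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def read_sam_records(path: str | Path, umi_tag: str = "UB") -> list[ReadRecord]:
    """Optional SAM/BAM ingestion (UMI from a tag or read-name suffix)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.has_tag(umi_tag):
                umi = aln.get_tag(umi_tag)
            else:
                umi = aln.query_name.rsplit(":", 1)[-1]
            out.append(
                ReadRecord(
                    read_id=aln.query_name,
                    umi=str(umi),
                    start=aln.reference_start,
                    stop=aln.reference_end or aln.reference_start + 1,
                    strand="-" if aln.is_reverse else "+",
                    target=aln.reference_name or "*",
                    alignment_score=int(aln.get_tag("AS")) if aln.has_tag("AS") else 0,
                    mismatches=int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
                )
            )
    return out


def write_bedgraph(values, path: str | Path, chrom: str = "chrS") -> None:
    """Piecewise-constant track as bedGraph-like TSV (run-length encoded)."""
    import numpy as np

    values = np.asarray(values)
    if len(values) == 0:
        Path(path).write_text("")
        return
    change = np.nonzero(np.diff(values))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{float(values[s])!r}\n")


def read_bedgraph(path: str | Path, length: Optional[int] = None):
    import numpy as np

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    if not rows:
        return np.zeros(length or 0)
    n = length or max(e for _, _, e, _ in rows)
    out = np.zeros(n)
    for _, s, e, v in rows:
        out[s:e] = v
    return out
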