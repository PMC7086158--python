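"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED12/BED3/refFlat/GTF/bedGraph/narrowPeak are parsed line-by-line; BAM goes
through pysam. All parsers accept a file path, an open file object, or an
iterable of lines, and report the offending line number on malformed input.
"""

from __future__ import annotations

import contextlib
import re
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Malformed record in a text format, annotated with its line number."""


@contextlib.contextmanager
def _as_lines(source):
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield fh
    elif hasattr(source, "read"):
        yield source
    else:  # iterable of lines
        yield iter(source)


def _skip(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


# ---------------------------------------------------------------------------
# gene annotations


def iter_bed12_transcripts(source) -> Iterator[dict]:
    """Yield transcript dicts from BED12; block coordinates become exons."""
    with _as_lines(source) as lines:
        for lineno, line in enumerate(lines, start=1):
            if _skip(line):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"line {lineno}: block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            if exons[0][0] != start or exons[-1][1] != end:
                raise ParseError(
                    f"line {lineno}: blocks do not span the record ({name})"
                )
            yield {
                "gene_id": name,
                "transcript_id": name,
                "chrom": chrom,
                "strand": strand,
                "tx_start": start,
                "tx_end": end,
                "exons": exons,
            }


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def iter_gtf_transcripts(source) -> Iterator[dict]:
    """Yield transcript dicts from GTF exon records (ensembl attribute dialect).

    GTF is 1-based inclusive; coordinates are converted to 0-based half-open.
    The transcript span is the exon envelope.
    """
    exons: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with _as_lines(source) as lines:
        for lineno, line in enumerate(lines, start=1):
            if _skip(line):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"line {lineno}: GTF needs 9 fields, got {len(f)}")
            if f[2] != "exon":
                continue
            try:
                start, end = int(f[3]) - 1, int(f[4])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gid, tid = attrs.get("gene_id"), attrs.get("transcript_id")
            if not gid or not tid:
                raise ParseError(f"line {lineno}: missing gene_id/transcript_id")
            key = (gid, tid)
            if key not in exons:
                exons[key] = {
                    "gene_id": gid,
                    "transcript_id": tid,
                    "chrom": f[0],
                    "strand": f[6],
                    "exons": [],
                }
                order.append(key)
            exons[key]["exons"].append((start, end))
    for key in order:
        t = exons[key]
        t["exons"] = sorted(t["exons"])
        t["tx_start"] = t["exons"][0][0]
        t["tx_end"] = t["exons"][-1][1]
        yield t


def iter_refflat_transcripts(source) -> Iterator[dict]:
    """Yield transcript dicts from a refFlat/refGene-style TSV."""
    with _as_lines(source) as lines:
        for lineno, line in enumerate(lines, start=1):
            if _skip(line):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise ParseError(f"line {lineno}: refFlat needs 11 fields, got {len(f)}")
            try:
                starts = [int(x) for x in f[9].rstrip(",").split(",")]
                ends = [int(x) for x in f[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            yield {
                "gene_id": f[0],
                "transcript_id": f[1],
                "chrom": f[2],
                "strand": f[3],
                "tx_start": int(f[4]),
                "tx_end": int(f[5]),
                "exons": list(zip(starts, ends)),
            }


def write_bed12_genes(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_bed3(source) -> list[tuple[str, int, int]]:
    out = []
    with _as_lines(source) as lines:
        for lineno, line in enumerate(lines, start=1):
            if _skip(line):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"line {lineno}: BED3 needs 3 fields")
            try:
                out.append((f[0], int(f[1]), int(f[2])))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# aligned reads


def iter_bed12_reads(source, sample_id: str):
    """Yield AlignedRead from BED12 where blocks are aligned segments."""
    from .classify import AlignedRead

    for t in iter_bed12_transcripts(source):
        yield AlignedRead(
            chrom=t["chrom"],
            strand=t["strand"],
            blocks=tuple(t["exons"]),
            sample_id=sample_id,
            name=t["gene_id"],
        )


def iter_bam_reads(path, sample_id: str, min_gap: int = 20):
    """Yield AlignedRead from a BAM/SAM file (mapped, primary records only).

    pysam splits aligned blocks on both N (splice) and D (deletion) cigar
    operations; blocks separated by less than ``min_gap`` bp are re-merged so
    that small deletions do not masquerade as splice gaps.
    """
    import pysam

    from .classify import AlignedRead

    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            blocks: list[list[int]] = []
            for s, e in rec.get_blocks():
                if blocks and s - blocks[-1][1] < min_gap:
                    blocks[-1][1] = max(blocks[-1][1], e)
                else:
                    blocks.append([s, e])
            yield AlignedRead(
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                blocks=tuple((s, e) for s, e in blocks),
                sample_id=sample_id,
                name=rec.query_name,
            )


def write_bed12_reads(reads, path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            start, end = r.blocks[0][0], r.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            offsets = ",".join(str(s - start) for s, _ in r.blocks)
            name = r.name or f"read{i}"
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(start),
                        str(end),
                        name,
                        "0",
                        r.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(r.blocks)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# coverage tracks (bedGraph) and peaks (narrowPeak)


def read_bedgraph(source, contig_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    cov = {c: np.zeros(n, dtype=float) for c, n in contig_lengths.items()}
    with _as_lines(source) as lines:
        for lineno, line in enumerate(lines, start=1):
            if _skip(line):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ParseError(f"line {lineno}: bedGraph needs 4 fields")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in cov:
                raise ParseError(f"line {lineno}: unknown contig {chrom!r}")
            cov[chrom][start:end] += value
    return cov


def write_bedgraph(cov: Mapping[str, np.ndarray], path) -> None:
    """Run-length encode per-base coverage; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(cov):
            arr = np.asarray(cov[chrom], dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


NARROWPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signal",
    "pvalue",
    "qvalue",
    "peak",
]


def read_narrowpeak(source) -> pd.DataFrame:
    """Read narrowPeak (or BED with >=3 columns) into a peak table.

    The returned frame carries an absolute ``summit`` column: ``start + peak``
    when a summit offset is present, else the interval midpoint.
    """
    rows = []
    with _as_lines(source) as lines:
        for lineno, line in enumerate(lines, start=1):
            if _skip(line):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"line {lineno}: need at least 3 fields")
            row = dict.fromkeys(NARROWPEAK_COLUMNS)
            row["chrom"], row["start"], row["end"] = f[0], int(f[1]), int(f[2])
            row["name"] = f[3] if len(f) > 3 else f"peak{lineno}"
            row["score"] = float(f[4]) if len(f) > 4 else 0.0
            row["strand"] = f[5] if len(f) > 5 else "."
            row["signal"] = float(f[6]) if len(f) > 6 else 0.0
            row["pvalue"] = float(f[7]) if len(f) > 7 else -1.0
            row["qvalue"] = float(f[8]) if len(f) > 8 else -1.0
            row["peak"] = int(f[9]) if len(f) > 9 else -1
            rows.append(row)
    df = pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)
    if len(df):
        mid = (df["start"] + df["end"]) // 2
        df["summit"] = np.where(df["peak"] >= 0, df["start"] + df["peak"], mid)
    else:
        df["summit"] = pd.Series(dtype=int)
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a TSV with a fixed float format so runs are byte-reproducible."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")
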