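"""Gene models and the genomic regions derived from them.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based inclusive, is converted on read. A :class:`GeneModel` is a single
collapsed transcript per gene; every region the downstream analyses use
(introns, first intron, promoter, pause window, TES window) is derived from it
by :func:`derive_regions` with fixed strand conventions:

* TSS is ``tx_start`` on ``+`` and ``tx_end`` on ``-``;
* TES is ``tx_end`` on ``+`` and ``tx_start`` on ``-``;
* "first intron" is the intron nearest the TSS in transcription direction;
* the TES window extends 20 kb downstream of the TES (clipped at contig ends);
* the pause window covers TSS to TSS+250 bp downstream;
* the promoter covers TSS ± 1 kb.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from . import io as _io

Interval = tuple[int, int]

#: default extent of the transcription-termination readthrough window (bp)
TES_WINDOW = 20_000
#: promoter half-width around the TSS (bp)
PROMOTER_HALFWIDTH = 1_000
#: extent of the promoter-proximal pause window downstream of the TSS (bp)
PAUSE_EXTENT = 250


@dataclass(frozen=True)
class GeneModel:
    """One gene's collapsed transcript: span, strand and exon blocks."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        strand = {"−": "-"}.get(self.strand, self.strand)
        object.__setattr__(self, "strand", strand)
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if not start < end:
                raise ValueError(f"{self.gene_id}: empty or inverted exon ({start},{end})")
            if start < self.tx_start or end > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon ({start},{end}) outside transcript span")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping at ({start},{end})")
            prev_end = end
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError(
                f"{self.gene_id}: transcript span must equal the exon envelope"
            )

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons, in coordinate order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass(frozen=True)
class DerivedRegions:
    """Every region class the read classification and ChIP analyses use."""

    gene: GeneModel
    introns: tuple[Interval, ...]
    first_intron: Optional[Interval]
    tes_window: Interval
    promoter: Interval
    pause_window: Interval

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def chrom(self) -> str:
        return self.gene.chrom

    @property
    def strand(self) -> str:
        return self.gene.strand

    @property
    def exons(self) -> tuple[Interval, ...]:
        return self.gene.exons

    @property
    def tss(self) -> int:
        return self.gene.tss

    @property
    def tes(self) -> int:
        return self.gene.tes

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.introns)

    @property
    def total_intron_length(self) -> int:
        return sum(self.intron_lengths)


def derive_regions(
    gene: GeneModel,
    contig_lengths: Optional[Mapping[str, int]] = None,
    tes_extent: int = TES_WINDOW,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    pause_extent: int = PAUSE_EXTENT,
) -> DerivedRegions:
    """Derive intron/promoter/pause/TES-window regions for one gene.

    ``contig_lengths`` bounds right-clipping; when absent only the left edge
    (coordinate 0) is clipped. A single-exon gene has no introns and
    ``first_intron`` is ``None`` (not an error).
    """
    clen = None
    if contig_lengths is not None:
        if gene.chrom not in contig_lengths:
            raise KeyError(f"unknown contig {gene.chrom!r} for gene {gene.gene_id}")
        clen = contig_lengths[gene.chrom]
        if gene.tx_end > clen:
            raise ValueError(f"{gene.gene_id} extends past contig end {clen}")

    def clip(start: int, end: int) -> Interval:
        start = max(0, start)
        if clen is not None:
            end = min(end, clen)
        return (start, max(start, end))

    introns = gene.introns
    if introns:
        first_intron = introns[0] if gene.strand == "+" else introns[-1]
    else:
        first_intron = None
    if gene.strand == "+":
        tes_window = clip(gene.tx_end, gene.tx_end + tes_extent)
        pause_window = (gene.tx_start, gene.tx_start + pause_extent)
    else:
        tes_window = clip(gene.tx_start - tes_extent, gene.tx_start)
        pause_window = (gene.tx_end - pause_extent, gene.tx_end)
    promoter = clip(gene.tss - promoter_halfwidth, gene.tss + promoter_halfwidth)
    return DerivedRegions(
        gene=gene,
        introns=introns,
        first_intron=first_intron,
        tes_window=tes_window,
        promoter=promoter,
        pause_window=pause_window,
    )


class MaskSet:
    """A merged set of genomic intervals to exclude (e.g. rRNA repeats)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[Interval]] = {}
        for chrom, start, end in intervals:
            if not 0 <= start < end:
                raise ValueError(f"invalid mask interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [m[0] for m in merged]
            self._ends[chrom] = [m[1] for m in merged]

    @classmethod
    def from_bed3(cls, source) -> "MaskSet":
        return cls(_io.read_bed3(source))

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts):
            out.extend(
                (chrom, s, e) for s, e in zip(self._starts[chrom], self._ends[chrom])
            )
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any masked interval by >= 1 bp."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        ends = self._ends[chrom]
        i = bisect.bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end


def _collapse_longest(transcripts: Sequence[dict]) -> list[GeneModel]:
    """One GeneModel per gene_id: the transcript with the longest genomic span.

    Ties break on transcript id, then coordinates, for determinism.
    """
    best: dict[str, dict] = {}
    order: list[str] = []
    for t in transcripts:
        gid = t["gene_id"]
        if gid not in best:
            best[gid] = t
            order.append(gid)
        else:
            cur = best[gid]
            key = lambda x: (
                -(x["tx_end"] - x["tx_start"]),
                x.get("transcript_id", ""),
                x["tx_start"],
            )
            if key(t) < key(cur):
                best[gid] = t
    return [
        GeneModel(
            gene_id=gid,
            chrom=best[gid]["chrom"],
            strand=best[gid]["strand"],
            tx_start=best[gid]["tx_start"],
            tx_end=best[gid]["tx_end"],
            exons=tuple(best[gid]["exons"]),
        )
        for gid in order
    ]


def load_gene_models(source, fmt: Optional[str] = None) -> list[GeneModel]:
    """Load gene models from BED12, GTF or refFlat.

    ``fmt`` is one of ``bed12``, ``gtf``, ``refflat``; when ``None`` it is
    inferred from the file extension. When a gene id carries several
    transcripts the one with the longest genomic span is kept.
    """
    if fmt is None:
        name = str(source).lower()
        if name.endswith((".gtf", ".gff")):
            fmt = "gtf"
        elif name.endswith((".refflat", ".txt")):
            fmt = "refflat"
        else:
            fmt = "bed12"
    if fmt == "bed12":
        transcripts = list(_io.iter_bed12_transcripts(source))
    elif fmt == "gtf":
        transcripts = list(_io.iter_gtf_transcripts(source))
    elif fmt == "refflat":
        transcripts = list(_io.iter_refflat_transcripts(source))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return _collapse_longest(transcripts)


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    """Serialize gene models as BED12 (one line per gene)."""
    _io.write_bed12_genes(genes, path)
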