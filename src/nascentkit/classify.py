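"""Assignment of aligned reads to per-gene categories.

Each retained read is assigned to exactly one of six per-gene categories, or
to ``intergenic``/``ambiguous``. The decision cascade per candidate gene is
fixed — junction evidence outranks pre-mRNA evidence, which outranks mature
evidence, which outranks downstream-of-gene evidence:

1. ``spliced``     — an alignment gap matches an annotated intron (both ends
                     within ``junction_tol`` bp of the intron ends);
2. ``exon_intron`` — a block crosses an exon–intron boundary (overlaps both);
3. ``intronic``    — all blocks fall within introns (sub-tallied to the first
                     intron when fully inside it);
4. ``exonic``      — all blocks fall within exons;
5. ``tes``         — all blocks fall within the TES+20kb window;
6. ``tes_rt``      — a block spans the TES coordinate itself (readthrough).

Reads compatible with more than one gene are ``ambiguous`` and excluded from
per-gene counts; reads matching no gene (including reads that overlap a gene
but fit none of the six rules, e.g. a block straddling the TSS) count as
``intergenic`` so that the conservation invariant

    sum(per-gene categories) + intergenic + ambiguous + rrna_removed == input

holds exactly for every sample.

Strandedness follows the fr-firststrand chemistry by default (a single-end
read aligns antisense to its gene); ``orientation="unstranded"`` disables the
check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import DerivedRegions, MaskSet

Interval = tuple[int, int]

#: per-gene read categories, in cascade order
CATEGORIES = ("spliced", "exon_intron", "intronic", "exonic", "tes", "tes_rt")
#: categories whose reads are pre-mRNA evidence
PRE_MRNA_CATEGORIES = ("intronic", "exon_intron")
#: default tolerance (bp) for matching an alignment gap to an intron
JUNCTION_TOL = 5


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read as ordered aligned blocks on one contig."""

    chrom: str
    strand: str
    blocks: tuple[Interval, ...]
    sample_id: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        if not self.blocks:
            raise ValueError("a read needs at least one aligned block")
        prev = None
        for s, e in self.blocks:
            if not s < e:
                raise ValueError(f"empty or inverted block ({s},{e})")
            if prev is not None and s < prev:
                raise ValueError("blocks unsorted or overlapping")
            prev = e

    @property
    def gaps(self) -> tuple[Interval, ...]:
        """Inter-block intervals (candidate splice gaps)."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class Assignment:
    """Outcome of classifying one read."""

    category: str  # one of CATEGORIES, or "intergenic"/"ambiguous"
    gene_id: Optional[str] = None
    first_intron: bool = False


class GeneIndex:
    """Per-chromosome interval index over gene footprints (span + TES window)."""

    def __init__(self, regions: Iterable[DerivedRegions]):
        self.by_gene: dict[str, DerivedRegions] = {}
        self._trees: dict[str, IntervalTree] = {}
        for dr in regions:
            if dr.gene_id in self.by_gene:
                raise ValueError(f"duplicate gene_id {dr.gene_id!r}")
            self.by_gene[dr.gene_id] = dr
            lo = min(dr.gene.tx_start, dr.tes_window[0])
            hi = max(dr.gene.tx_end, dr.tes_window[1])
            self._trees.setdefault(dr.chrom, IntervalTree()).addi(lo, hi, dr)

    def __len__(self) -> int:
        return len(self.by_gene)

    @property
    def regions(self) -> list[DerivedRegions]:
        return list(self.by_gene.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.by_gene)

    def candidates(self, chrom: str, start: int, end: int) -> list[DerivedRegions]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def _within(block: Interval, ivs: Sequence[Interval]) -> bool:
    return any(s <= block[0] and block[1] <= e for s, e in ivs)


def _overlaps(block: Interval, iv: Interval) -> bool:
    return block[0] < iv[1] and iv[0] < block[1]


def _classify_against_gene(
    read: AlignedRead, dr: DerivedRegions, junction_tol: int
) -> Optional[tuple[str, bool]]:
    """Apply the category cascade for one candidate gene.

    Returns ``(category, in_first_intron)`` or ``None`` when the read fits no
    rule for this gene.
    """
    gene = dr.gene
    blocks = read.blocks
    for gs, ge in read.gaps:
        for is_, ie in dr.introns:
            if abs(gs - is_) <= junction_tol and abs(ge - ie) <= junction_tol:
                return ("spliced", False)
    for b in blocks:
        if any(_overlaps(b, e) for e in gene.exons) and any(
            _overlaps(b, i) for i in dr.introns
        ):
            return ("exon_intron", False)
    if dr.introns and all(_within(b, dr.introns) for b in blocks):
        fi = dr.first_intron
        in_first = fi is not None and all(
            fi[0] <= b[0] and b[1] <= fi[1] for b in blocks
        )
        return ("intronic", in_first)
    if all(_within(b, gene.exons) for b in blocks):
        return ("exonic", False)
    tw = dr.tes_window
    if tw[0] < tw[1] and all(tw[0] <= b[0] and b[1] <= tw[1] for b in blocks):
        return ("tes", False)
    tes = dr.tes
    if any(b[0] < tes < b[1] for b in blocks):
        return ("tes_rt", False)
    return None


_warned_contigs: set[str] = set()


def classify_read(
    read: AlignedRead,
    index: GeneIndex,
    orientation: str = "frf",
    junction_tol: int = JUNCTION_TOL,
) -> Assignment:
    """Classify one read against the gene index.

    ``orientation="frf"`` (fr-firststrand) requires the read strand to be
    opposite the gene strand; ``"unstranded"`` accepts either.
    """
    if orientation not in ("frf", "unstranded"):
        raise ValueError(f"unknown orientation {orientation!r}")
    span = read.span
    cands = index.candidates(read.chrom, span[0], span[1])
    if not cands and read.chrom not in {
        dr.chrom for dr in index.by_gene.values()
    }:
        if read.chrom not in _warned_contigs:
            _warned_contigs.add(read.chrom)
            warnings.warn(f"read on unknown contig {read.chrom!r}; treated as intergenic")
    hits: list[tuple[str, str, bool]] = []
    for dr in cands:
        if orientation == "frf" and read.strand == dr.strand:
            continue
        res = _classify_against_gene(read, dr, junction_tol)
        if res is not None:
            hits.append((dr.gene_id, res[0], res[1]))
    if not hits:
        return Assignment("intergenic")
    if len({gid for gid, _, _ in hits}) > 1:
        return Assignment("ambiguous")
    gid, cat, first = hits[0]
    return Assignment(cat, gene_id=gid, first_intron=first)


def filter_rrna(
    reads: Iterable[AlignedRead], mask: MaskSet
) -> tuple[list[AlignedRead], int]:
    """Drop reads whose any block overlaps the mask; report how many."""
    kept: list[AlignedRead] = []
    removed = 0
    for r in reads:
        if any(mask.overlaps(r.chrom, s, e) for s, e in r.blocks):
            removed += 1
        else:
            kept.append(r)
    return kept, removed


@dataclass
class ReadCategoryCounts:
    """Raw per-gene x sample category tallies plus per-sample accounting.

    ``per_gene`` is indexed by (gene_id, sample) with one column per category
    plus ``first_intron`` (a sub-count of ``intronic``, not a partition
    member). ``per_sample`` carries ``intergenic``, ``ambiguous``,
    ``rrna_removed``, ``retained`` (reads surviving the mask) and
    ``total_input``.
    """

    per_gene: pd.DataFrame
    per_sample: pd.DataFrame

    def gene_totals(self) -> pd.Series:
        """Per (gene, sample) sum over the six partition categories."""
        return self.per_gene[list(CATEGORIES)].sum(axis=1)

    def conservation_ok(self) -> bool:
        """Check tallies + intergenic + ambiguous + rrna_removed == input."""
        assigned = (
            self.per_gene[list(CATEGORIES)]
            .groupby(level="sample")
            .sum()
            .sum(axis=1)
            .reindex(self.per_sample.index, fill_value=0)
        )
        total = (
            assigned
            + self.per_sample["intergenic"]
            + self.per_sample["ambiguous"]
            + self.per_sample["rrna_removed"]
        )
        return bool((total == self.per_sample["total_input"]).all())


def count_categories(
    reads: Sequence[AlignedRead],
    assignments: Sequence[Assignment],
    gene_ids: Optional[Sequence[str]] = None,
    rrna_removed: Optional[Mapping[str, int]] = None,
    samples: Optional[Sequence[str]] = None,
) -> ReadCategoryCounts:
    """Aggregate per-read assignments into ReadCategoryCounts.

    ``rrna_removed`` gives per-sample counts of reads dropped by the mask
    before classification (they enter the conservation accounting).
    """
    if len(reads) != len(assignments):
        raise ValueError("reads and assignments differ in length")
    rrna_removed = dict(rrna_removed or {})
    sample_set = sorted(
        {r.sample_id for r in reads} | set(rrna_removed) | set(samples or [])
    )
    gene_set = sorted(
        set(gene_ids or [])
        | {a.gene_id for a in assignments if a.gene_id is not None}
    )
    cols = list(CATEGORIES) + ["first_intron"]
    col_pos = {c: i for i, c in enumerate(cols)}
    idx = pd.MultiIndex.from_product(
        [gene_set, sample_set], names=["gene_id", "sample"]
    )
    n_samples = len(sample_set)
    row_pos = {
        (g, s): i * n_samples + j
        for i, g in enumerate(gene_set)
        for j, s in enumerate(sample_set)
    }
    gene_mat = np.zeros((len(gene_set) * n_samples, len(cols)), dtype=np.int64)
    sample_pos = {s: j for j, s in enumerate(sample_set)}
    intergenic = np.zeros(n_samples, dtype=np.int64)
    ambiguous = np.zeros(n_samples, dtype=np.int64)
    retained = np.zeros(n_samples, dtype=np.int64)
    for r, a in zip(reads, assignments):
        j = sample_pos[r.sample_id]
        retained[j] += 1
        if a.category == "intergenic":
            intergenic[j] += 1
        elif a.category == "ambiguous":
            ambiguous[j] += 1
        else:
            row = row_pos[(a.gene_id, r.sample_id)]
            gene_mat[row, col_pos[a.category]] += 1
            if a.first_intron:
                gene_mat[row, col_pos["first_intron"]] += 1
    per_gene = pd.DataFrame(gene_mat, index=idx, columns=cols)
    removed = np.array(
        [rrna_removed.get(s, 0) for s in sample_set], dtype=np.int64
    )
    per_sample = pd.DataFrame(
        {
            "intergenic": intergenic,
            "ambiguous": ambiguous,
            "rrna_removed": removed,
            "retained": retained,
            "total_input": retained + removed,
        },
        index=pd.Index(sample_set, name="sample"),
    )
    return ReadCategoryCounts(per_gene=per_gene, per_sample=per_sample)


@dataclass
class NormalizedCounts:
    """Category counts after per-gene and library-size normalization.

    ``intronic`` is per kb of total intron length, ``spliced`` per exon, and
    every column is scaled by the per-sample library factor
    ``min_j(retained_j) / retained_s`` so the smallest library has factor 1.
    Single-exon genes get ``spliced = 0`` and ``intronic = NaN`` (no introns;
    excluded downstream). ``first_intron`` is per kb of first-intron length.
    """

    table: pd.DataFrame
    library_factor: pd.Series


def normalize_counts(
    counts: ReadCategoryCounts,
    regions: Mapping[str, DerivedRegions] | Iterable[DerivedRegions],
    intron_norm_unit: float = 1000.0,
) -> NormalizedCounts:
    """Apply intron-length, exon-count and library-size normalization."""
    if not isinstance(regions, Mapping):
        regions = {dr.gene_id: dr for dr in regions}
    totals = counts.per_sample["retained"]
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"samples with zero retained reads: {bad}")
    factor = totals.min() / totals.astype(float)

    per_gene = counts.per_gene.astype(float).copy()
    gene_order = per_gene.index.get_level_values("gene_id")
    intron_kb = np.array(
        [regions[g].total_intron_length / intron_norm_unit for g in gene_order]
    )
    first_kb = np.array(
        [
            (regions[g].first_intron[1] - regions[g].first_intron[0])
            / intron_norm_unit
            if regions[g].first_intron is not None
            else np.nan
            for g in gene_order
        ]
    )
    n_exons = np.array([len(regions[g].exons) for g in gene_order], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_gene["intronic"] = np.where(
            intron_kb > 0, per_gene["intronic"] / intron_kb, np.nan
        )
        per_gene["first_intron"] = np.where(
            first_kb > 0, per_gene["first_intron"] / first_kb, np.nan
        )
    per_gene["spliced"] = np.where(
        n_exons > 1, per_gene["spliced"] / n_exons, 0.0
    )
    f = factor.reindex(per_gene.index.get_level_values("sample")).to_numpy()
    for col in per_gene.columns:
        per_gene[col] = per_gene[col] * f
    return NormalizedCounts(table=per_gene, library_factor=factor)


def category_fractions(
    counts: ReadCategoryCounts,
    conditions: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Per-sample category percentages over retained reads.

    Returns ``(per_sample_percent, summary)`` where ``summary`` holds the
    mean and SD across replicate samples of each condition (``None`` when no
    sample->condition map is given). Percentages cover the six gene
    categories plus ``intergenic`` and ``ambiguous`` and sum to 100.
    """
    assigned = counts.per_gene[list(CATEGORIES)].groupby(level="sample").sum()
    assigned = assigned.reindex(counts.per_sample.index, fill_value=0).astype(float)
    assigned["intergenic"] = counts.per_sample["intergenic"].astype(float)
    assigned["ambiguous"] = counts.per_sample["ambiguous"].astype(float)
    retained = counts.per_sample["retained"].astype(float)
    pct = assigned.div(retained, axis=0) * 100.0
    if conditions is None:
        return pct, None
    cond = pd.Series({s: conditions[s] for s in pct.index}, name="condition")
    grouped = pct.groupby(cond)
    summary = pd.concat(
        {"mean": grouped.mean(), "sd": grouped.std(ddof=1).fillna(0.0)},
        names=["stat", "condition"],
    )
    return pct, summary


def coverage_track(
    reads: Sequence[AlignedRead],
    contig_lengths: Mapping[str, int],
    exclude_exonic: bool = False,
    assignments: Optional[Sequence[Assignment]] = None,
    index: Optional[GeneIndex] = None,
    orientation: str = "frf",
) -> dict[str, np.ndarray]:
    """Per-base coverage from read blocks, optionally dropping exonic reads.

    With ``exclude_exonic``, reads classified ``exonic`` are omitted before
    pileup (precomputed ``assignments`` are used when given, otherwise reads
    are classified against ``index``). Coverage is conserved: the track total
    equals the summed block lengths of the retained reads.
    """
    if exclude_exonic and assignments is None:
        if index is None:
            raise ValueError("exclude_exonic requires assignments or a GeneIndex")
        assignments = [classify_read(r, index, orientation=orientation) for r in reads]
    cov = {c: np.zeros(n, dtype=float) for c, n in contig_lengths.items()}
    for i, r in enumerate(reads):
        if exclude_exonic and assignments[i].category == "exonic":
            continue
        arr = cov.get(r.chrom)
        if arr is None:
            continue
        for s, e in r.blocks:
            arr[s:e] += 1.0
    return cov


def subsample_reads(
    reads: Sequence[AlignedRead],
    target_count: int,
    seed: int | np.random.Generator,
) -> list[AlignedRead]:
    """Uniform subsample without replacement, order-preserving, seeded.

    This is the "normalize to the smallest library by randomly picking reads"
    operation; ``target_count`` larger than the library is an error.
    """
    if target_count > len(reads):
        raise ValueError(
            f"target {target_count} exceeds available reads {len(reads)}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    keep = np.sort(rng.choice(len(reads), size=target_count, replace=False))
    return [reads[i] for i in keep]
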