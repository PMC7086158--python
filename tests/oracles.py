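"""Independent brute-force oracles used to validate the implementation.

These deliberately use different mechanics from the package (position sets
and exhaustive loops instead of interval indexes and cascades) so agreement
is informative.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def _positions(intervals) -> set[int]:
    out: set[int] = set()
    for s, e in intervals:
        out.update(range(s, e))
    return out


_SET_CACHE: dict[int, tuple] = {}


def _gene_sets(dr):
    """Per-gene position sets, cached per DerivedRegions object.

    The cache stores ``dr`` itself so its ``id`` can never be recycled for a
    different object.
    """
    key = id(dr)
    if key not in _SET_CACHE:
        _SET_CACHE[key] = (
            dr,
            _positions(dr.exons),
            _positions(dr.introns),
            _positions([dr.tes_window]),
        )
    return _SET_CACHE[key][1:]


def oracle_classify_gene(read, dr, tol=5):
    """Set-arithmetic re-derivation of the per-gene category cascade."""
    exon_pos, intron_pos, tes_pos = _gene_sets(dr)
    read_pos = _positions(read.blocks)
    for gs, ge in read.gaps:
        for is_, ie in dr.introns:
            if abs(gs - is_) <= tol and abs(ge - ie) <= tol:
                return "spliced"
    for b in read.blocks:
        bp = _positions([b])
        if bp & exon_pos and bp & intron_pos:
            return "exon_intron"
    if intron_pos and read_pos <= intron_pos:
        return "intronic"
    if read_pos <= exon_pos:
        return "exonic"
    if tes_pos and read_pos <= tes_pos:
        return "tes"
    if any(b[0] < dr.tes < b[1] for b in read.blocks):
        return "tes_rt"
    return None


def oracle_classify(read, regions_list, orientation="frf", tol=5):
    """All-pairs read x gene classification; returns (category, gene_id)."""
    hits = []
    for dr in regions_list:
        if dr.chrom != read.chrom:
            continue
        if orientation == "frf" and read.strand == dr.strand:
            continue
        cat = oracle_classify_gene(read, dr, tol)
        if cat is not None:
            hits.append((dr.gene_id, cat))
    if not hits:
        return ("intergenic", None)
    if len({g for g, _ in hits}) > 1:
        return ("ambiguous", None)
    return (hits[0][1], hits[0][0])


def oracle_in_first_intron(read, dr) -> bool:
    if dr.first_intron is None:
        return False
    fi_pos = _positions([dr.first_intron])
    return _positions(read.blocks) <= fi_pos


def oracle_pileup(reads, contig_lengths):
    """Naive per-base pileup by incrementing every covered position."""
    cov = {c: np.zeros(n) for c, n in contig_lengths.items()}
    for r in reads:
        for s, e in r.blocks:
            for p in range(s, e):
                cov[r.chrom][p] += 1
    return cov


def oracle_kde(values, grid, bandwidth):
    """Direct sum-of-Gaussians density evaluation, one loop per data point."""
    dens = np.zeros(len(grid))
    for v in values:
        dens += np.exp(-0.5 * ((grid - v) / bandwidth) ** 2) / (
            bandwidth * np.sqrt(2 * np.pi)
        )
    return dens / len(values)


def oracle_binned_boxplot(intensity, ratio, min_bin=300, k_pot=1.5, k_ext=3.0):
    """Per-bin boxplot outlier calls via explicit sorting and slicing."""
    n = len(ratio)
    n_bins = max(1, n // min_bin)
    size = int(np.ceil(n / n_bins))
    order = sorted(range(n), key=lambda i: (-intensity[i], i))
    status = ["none"] * n
    for b in range(n_bins):
        members = order[b * size : (b + 1) * size]
        vals = sorted(ratio[i] for i in members)
        q1 = np.percentile(vals, 25)
        q3 = np.percentile(vals, 75)
        iqr = q3 - q1
        for i in members:
            if ratio[i] > q3 + k_ext * iqr or ratio[i] < q1 - k_ext * iqr:
                status[i] = "extreme"
            elif ratio[i] > q3 + k_pot * iqr or ratio[i] < q1 - k_pot * iqr:
                status[i] = "potential"
    return status


def oracle_metagene(coverage, anchors, window):
    """Per-anchor vector extraction with explicit python loops."""
    lo, hi = window
    mat = []
    for chrom, pos, strand in anchors:
        cov = coverage[chrom]
        row = []
        for off in range(lo, hi):
            p = pos + off if strand == "+" else pos - off
            row.append(cov[p] if 0 <= p < len(cov) else 0.0)
        mat.append(row)
    mat = np.array(mat)
    return mat.mean(axis=0), mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])


def oracle_hypergeom_tail(universe: int, n_a: int, n_b: int, k: int) -> float:
    """P[|A & B| >= k] by enumeration over all C(universe, n_b) draws."""
    total = comb(universe, n_b)
    hits = 0
    items = range(universe)
    a = set(range(n_a))
    for draw in combinations(items, n_b):
        if len(a & set(draw)) >= k:
            hits += 1
    return hits / total


def random_toy_genome(rng, contig_length=60_000, max_genes=5):
    """A small random genome, possibly with overlapping genes."""
    from nascentkit.genome import GeneModel, derive_regions

    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    for i in range(n_genes):
        n_exons = int(rng.integers(1, 5))
        pos = int(rng.integers(0, 40_000))
        start = pos
        exons = []
        for j in range(n_exons):
            length = int(rng.integers(50, 301))
            exons.append((pos, pos + length))
            pos += length
            if j < n_exons - 1:
                pos += int(rng.integers(60, 401))
        genes.append(
            GeneModel(
                gene_id=f"T{i + 1}",
                chrom="toy",
                strand="+" if rng.random() < 0.5 else "-",
                tx_start=start,
                tx_end=pos,
                exons=tuple(exons),
            )
        )
    contig_lengths = {"toy": contig_length}
    regions = [derive_regions(g, contig_lengths) for g in genes]
    return genes, regions, contig_lengths


def random_toy_reads(rng, genes, contig_lengths, n_reads=1000):
    """Reads stressing every classification rule, including edge jitter."""
    from nascentkit.classify import AlignedRead

    clen = contig_lengths["toy"]
    reads = []
    while len(reads) < n_reads:
        strand = "+" if rng.random() < 0.5 else "-"
        kind = rng.random()
        gene = genes[int(rng.integers(0, len(genes)))]
        if kind < 0.45:  # random single block anywhere near genes
            length = int(rng.integers(30, 81))
            center = int(
                np.clip(
                    rng.normal(
                        (gene.tx_start + gene.tx_end) / 2,
                        (gene.tx_end - gene.tx_start),
                    ),
                    0,
                    clen - length - 1,
                )
            )
            blocks = ((center, center + length),)
        elif kind < 0.7 and gene.introns:  # near-junction gapped read
            intr = gene.introns[int(rng.integers(0, len(gene.introns)))]
            j1 = int(intr[0] + rng.integers(-8, 9))
            j2 = int(intr[1] + rng.integers(-8, 9))
            k1, k2 = int(rng.integers(15, 40)), int(rng.integers(15, 40))
            if j1 - k1 <= 0 or j2 + k2 >= clen or j1 >= j2:
                continue
            blocks = ((j1 - k1, j1), (j2, j2 + k2))
        elif kind < 0.85:  # TES straddler / downstream read
            tes = gene.tx_end if gene.strand == "+" else gene.tx_start
            length = int(rng.integers(30, 81))
            s = int(np.clip(tes + rng.integers(-length, 1_000), 0, clen - length - 1))
            blocks = ((s, s + length),)
        else:  # far intergenic
            length = int(rng.integers(30, 81))
            s = int(rng.integers(0, clen - length - 1))
            blocks = ((s, s + length),)
        reads.append(AlignedRead("toy", strand, blocks, "s1"))
    return reads
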