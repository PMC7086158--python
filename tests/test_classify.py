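import numpy as np
import pytest

from nascentkit.classify import (
    AlignedRead,
    GeneIndex,
    CATEGORIES,
    classify_read,
    count_categories,
    category_fractions,
    coverage_track,
    filter_rrna,
    normalize_counts,
    subsample_reads,
)
from nascentkit.genome import GeneModel, MaskSet, derive_regions

from oracles import (
    oracle_classify,
    oracle_pileup,
    random_toy_genome,
    random_toy_reads,
)


def _read(blocks, strand="-", sample="s1", chrom="chr1"):
    return AlignedRead(chrom, strand, tuple(blocks), sample)


class TestCascade:
    """Spot checks of each rule against gA (+, exons 30000-30500,
    31000-31600, 32500-33000) from the three-gene fixture."""

    def test_exonic_read_inside_second_exon(self, three_gene_index):
        index, _ = three_gene_index
        a = classify_read(_read([(31_100, 31_175)]), index)
        assert (a.category, a.gene_id) == ("exonic", "gA")

    def test_gap_matching_intron_is_spliced(self, three_gene_index):
        index, _ = three_gene_index
        a = classify_read(_read([(30_450, 30_500), (31_000, 31_030)]), index)
        assert (a.category, a.gene_id) == ("spliced", "gA")

    def test_gap_matching_within_tolerance_is_spliced(self, three_gene_index):
        index, _ = three_gene_index
        a = classify_read(_read([(30_450, 30_504), (30_996, 31_030)]), index)
        assert a.category == "spliced"
        b = classify_read(_read([(30_450, 30_506), (30_994, 31_030)]), index)
        assert b.category != "spliced"  # 6 bp off both ends

    def test_block_straddling_boundary_is_exon_intron(self, three_gene_index):
        index, _ = three_gene_index
        a = classify_read(_read([(30_480, 30_550)]), index)
        assert (a.category, a.gene_id) == ("exon_intron", "gA")

    def test_intronic_and_first_intron_subcount(self, three_gene_index):
        index, _ = three_gene_index
        a = classify_read(_read([(30_600, 30_675)]), index)
        assert (a.category, a.first_intron) == ("intronic", True)
        b = classify_read(_read([(31_700, 31_775)]), index)
        assert (b.category, b.first_intron) == ("intronic", False)

    def test_first_intron_is_strand_aware(self, three_gene_index):
        index, _ = three_gene_index
        # gB is minus strand: its first intron is the gap nearest TSS=124000
        a = classify_read(_read([(121_000, 121_075)], strand="+"), index)
        assert (a.category, a.gene_id, a.first_intron) == ("intronic", "gB", True)

    def test_tes_window_and_readthrough(self, three_gene_index):
        index, _ = three_gene_index
        a = classify_read(_read([(40_000, 40_075)]), index)
        assert (a.category, a.gene_id) == ("tes", "gA")
        b = classify_read(_read([(32_980, 33_050)]), index)
        assert (b.category, b.gene_id) == ("tes_rt", "gA")

    def test_intergenic_far_from_genes(self, three_gene_index):
        index, _ = three_gene_index
        assert classify_read(_read([(200_000, 200_075)]), index).category == "intergenic"

    def test_orientation_rule(self, three_gene_index):
        index, _ = three_gene_index
        sense = classify_read(_read([(31_100, 31_175)], strand="+"), index)
        assert sense.category == "intergenic"  # same strand as gA: rejected by frf
        both = classify_read(
            _read([(31_100, 31_175)], strand="+"), index, orientation="unstranded"
        )
        assert both.category == "exonic"

    def test_unknown_contig_warns_and_is_intergenic(self, three_gene_index):
        index, _ = three_gene_index
        with pytest.warns(UserWarning, match="unknown contig"):
            a = classify_read(_read([(0, 75)], chrom="chrUn"), index)
        assert a.category == "intergenic"


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_toy_genomes(self):
        """Implementation and all-pairs set-arithmetic oracle must agree on
        every read of random (possibly overlapping) toy genomes."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            genes, regions, contigs = random_toy_genome(rng)
            index = GeneIndex(regions)
            reads = random_toy_reads(rng, genes, contigs, n_reads=300)
            for r in reads:
                got = classify_read(r, index)
                want_cat, want_gene = oracle_classify(r, regions)
                assert (got.category, got.gene_id) == (want_cat, want_gene)


class TestCountsAndConservation:
    def test_conservation_and_first_intron_bound(self, three_gene_index, rng):
        index, contigs = three_gene_index
        genes = [index.by_gene[g].gene for g in index.gene_ids]
        reads = random_toy_reads(rng, genes, {"toy": contigs["chr1"]}, n_reads=400)
        reads = [AlignedRead("chr1", r.strand, r.blocks, "s1") for r in reads]
        mask = MaskSet([("chr1", 300_000, 305_000)])
        kept, removed = filter_rrna(reads, mask)
        asg = [classify_read(r, index) for r in kept]
        counts = count_categories(
            kept, asg, gene_ids=index.gene_ids, rrna_removed={"s1": removed}
        )
        assert counts.conservation_ok()
        assert counts.per_sample.loc["s1", "total_input"] == len(reads)
        pg = counts.per_gene
        assert (pg["first_intron"] <= pg["intronic"]).all()

    def test_doubling_reads_doubles_raw_counts(self, three_gene_index, rng):
        index, contigs = three_gene_index
        genes = [index.by_gene[g].gene for g in index.gene_ids]
        reads = random_toy_reads(rng, genes, {"toy": contigs["chr1"]}, n_reads=200)
        reads = [AlignedRead("chr1", r.strand, r.blocks, "s1") for r in reads]
        asg = [classify_read(r, index) for r in reads]
        once = count_categories(reads, asg, gene_ids=index.gene_ids)
        twice = count_categories(reads + reads, asg + asg, gene_ids=index.gene_ids)
        assert (twice.per_gene[list(CATEGORIES)] == 2 * once.per_gene[list(CATEGORIES)]).all().all()


class TestRrnaFilter:
    def test_any_overlap_removes(self):
        mask = MaskSet([("chr1", 1000, 2000)])
        inside = _read([(1200, 1275)])
        edge = _read([(1999, 2074)])  # 1 bp overlap
        outside = _read([(2000, 2075)])
        kept, removed = filter_rrna([inside, edge, outside], mask)
        assert removed == 2
        assert kept == [outside]

    def test_empty_mask_is_identity(self):
        reads = [_read([(0, 75)])]
        kept, removed = filter_rrna(reads, MaskSet([]))
        assert (kept, removed) == (reads, 0)


class TestNormalization:
    def test_stated_arithmetic(self, three_gene_index):
        index, _ = three_gene_index
        # gA: introns (30500,31000)+(31600,32500) = 1400 bp; 3 exons
        reads = (
            [_read([(30_600, 30_675)], sample="s1")] * 8  # intronic
            + [_read([(30_450, 30_500), (31_000, 31_030)], sample="s1")] * 6  # spliced
            + [_read([(31_100, 31_175)], sample="s1")] * 6  # exonic filler
        )
        reads2 = [AlignedRead(r.chrom, r.strand, r.blocks, "s2") for r in reads[:10]]
        allr = reads + reads2
        asg = [classify_read(r, index) for r in allr]
        counts = count_categories(allr, asg, gene_ids=index.gene_ids)
        norm = normalize_counts(counts, index.by_gene)
        t = norm.table
        # library factors: totals 20 and 10 -> 0.5 and 1
        assert norm.library_factor["s2"] == 1.0
        assert norm.library_factor["s1"] == 0.5
        # intronic: 8 / 1.4 kb, then x 0.5; spliced: 6 / 3 exons, then x 0.5
        assert t.loc[("gA", "s1"), "intronic"] == pytest.approx(8 / 1.4 * 0.5)
        assert t.loc[("gA", "s1"), "spliced"] == pytest.approx(6 / 3 * 0.5)

    def test_single_exon_gene_conventions(self, three_gene_index):
        index, _ = three_gene_index
        reads = [_read([(250_100, 250_175)], sample="s1")]
        asg = [classify_read(r, index) for r in reads]
        counts = count_categories(reads, asg, gene_ids=index.gene_ids)
        norm = normalize_counts(counts, index.by_gene)
        assert norm.table.loc[("gC", "s1"), "spliced"] == 0.0
        assert np.isnan(norm.table.loc[("gC", "s1"), "intronic"])

    def test_zero_read_sample_is_an_error(self, three_gene_index):
        index, _ = three_gene_index
        counts = count_categories([], [], gene_ids=index.gene_ids, samples=["empty"])
        with pytest.raises(ValueError, match="zero retained"):
            normalize_counts(counts, index.by_gene)


class TestFractions:
    def test_percentages_sum_to_100_and_replicate_sd(self, three_gene_index):
        index, _ = three_gene_index
        reads = [
            _read([(31_100, 31_175)], sample=s) for s in ("r1", "r1", "r2", "r2")
        ] + [_read([(30_600, 30_675)], sample=s) for s in ("r1", "r2")]
        asg = [classify_read(r, index) for r in reads]
        counts = count_categories(reads, asg, gene_ids=index.gene_ids)
        pct, summary = category_fractions(counts, {"r1": "cond", "r2": "cond"})
        assert pct.sum(axis=1).to_numpy() == pytest.approx([100.0, 100.0])
        assert pct.loc["r1", "exonic"] == pytest.approx(200 / 3)
        # identical replicates: zero SD everywhere
        assert summary.xs("sd", level="stat").to_numpy() == pytest.approx(0.0)


class TestCoverage:
    def test_single_intronic_read_pileup(self, three_gene_index):
        index, contigs = three_gene_index
        reads = [_read([(30_600, 30_650)])]
        cov = coverage_track(reads, contigs)
        assert cov["chr1"].sum() == 50
        assert (cov["chr1"][30_600:30_650] == 1).all()

    def test_exonic_excluded_when_flagged(self, three_gene_index):
        index, contigs = three_gene_index
        reads = [_read([(31_100, 31_175)])]
        cov = coverage_track(reads, contigs, exclude_exonic=True, index=index)
        assert cov["chr1"].sum() == 0

    def test_matches_naive_pileup_oracle(self, rng):
        genes, regions, contigs = random_toy_genome(rng)
        reads = random_toy_reads(rng, genes, contigs, n_reads=150)
        cov = coverage_track(reads, contigs)
        want = oracle_pileup(reads, contigs)
        np.testing.assert_array_equal(cov["toy"], want["toy"])
        # conservation of coverage mass
        assert cov["toy"].sum() == sum(r.aligned_length for r in reads)


class TestSubsampling:
    def test_identity_determinism_and_errors(self):
        reads = [_read([(i * 100, i * 100 + 50)]) for i in range(20)]
        assert subsample_reads(reads, 20, seed=1) == reads
        a = subsample_reads(reads, 7, seed=42)
        b = subsample_reads(reads, 7, seed=42)
        assert a == b and len(a) == 7
        with pytest.raises(ValueError, match="exceeds"):
            subsample_reads(reads, 21, seed=0)

    def test_selection_is_uniform_over_reads(self):
        reads = [_read([(i * 100, i * 100 + 50)]) for i in range(10)]
        hits = np.zeros(10)
        for seed in range(400):
            for r in subsample_reads(reads, 5, seed=seed):
                hits[r.blocks[0][0] // 100] += 1
        freq = hits / 400
        # each read kept with probability 1/2; binomial 3 sigma ~ 0.075
        assert np.abs(freq - 0.5).max() < 0.08
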