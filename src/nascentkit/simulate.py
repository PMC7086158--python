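"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study designs the analyses were built for:

* a synthetic genome of non-overlapping multi-exon genes with >= 20 kb of
  clearance around each gene so TES windows never touch a neighbor;
* metabolic-labeling (pulse/chase) nascent-RNA reads, where each read is
  mature (exonic or junction-spanning) with probability equal to the
  condition's splicing efficiency, pre-mRNA (intronic or boundary-crossing)
  otherwise, and placed downstream of the TES with probability equal to the
  readthrough fraction; the chase boosts the effective efficiency, emulating
  maturation after label withdrawal;
* dual-genome ChIP accounting and promoter-shaped coverage with a constant
  spike-in and a per-condition global signal factor;
* MaxQuant-style intensity tables with planted interactors, control
  missingness and quality columns, and phosphosite tables with planted
  differential effects.

Everything is driven by seeded numpy Generators and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import AlignedRead
from .genome import GeneModel, MaskSet, derive_regions

# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeConfig:
    """Layout of the synthetic genome.

    Genes are placed left to right with inter-gene gaps larger than two TES
    windows (so readthrough windows of adjacent genes never overlap) plus an
    ``intergenic zone`` in the middle of each gap where background reads can
    land without touching any gene-derived region. rRNA intervals live in a
    reserved tail region of each contig.
    """

    n_genes: int = 200
    genes_per_contig: int = 50
    exon_count_range: tuple[int, int] = (2, 8)
    single_exon_fraction: float = 0.03
    exon_length_log_mean: float = 5.2  # ~180 bp median
    exon_length_log_sd: float = 0.4
    min_exon_length: int = 120
    intron_length_log_mean: float = 6.8  # ~900 bp median
    intron_length_log_sd: float = 0.6
    min_intron_length: int = 200
    gap: int = 45_000
    tes_extent: int = 20_000
    n_rrna: int = 3
    rrna_length: int = 5_000
    expression_log_sd: float = 1.0


@dataclass
class SimulatedGenome:
    genes: list[GeneModel]
    contig_lengths: dict[str, int]
    rrna: MaskSet
    intergenic_zones: list[tuple[str, int, int]]
    expression: pd.Series  # per-gene sampling weight, sums to 1

    @property
    def regions(self):
        return [derive_regions(g, self.contig_lengths) for g in self.genes]


def _lognormal_int(rng, log_mean, log_sd, minimum, size=None):
    v = np.exp(rng.normal(log_mean, log_sd, size=size))
    return np.maximum(np.rint(v).astype(int), minimum)


def simulate_genome(
    config: GenomeConfig = GenomeConfig(), seed: int | np.random.Generator = 0
) -> SimulatedGenome:
    """Build a seeded synthetic genome satisfying all gene-model invariants."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cfg = config
    genes: list[GeneModel] = []
    contig_lengths: dict[str, int] = {}
    zones: list[tuple[str, int, int]] = []
    rrna: list[tuple[str, int, int]] = []

    n_contigs = max(1, -(-cfg.n_genes // cfg.genes_per_contig))
    gene_no = 0
    for ci in range(n_contigs):
        chrom = f"chrS{ci + 1}"
        cursor = cfg.tes_extent + cfg.gap // 2  # head room for a leading - gene
        n_here = min(cfg.genes_per_contig, cfg.n_genes - gene_no)
        for _ in range(n_here):
            gid = f"G{gene_no + 1:04d}"
            gene_no += 1
            if rng.random() < cfg.single_exon_fraction:
                n_exons = 1
            else:
                n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
            exon_lens = _lognormal_int(
                rng, cfg.exon_length_log_mean, cfg.exon_length_log_sd,
                cfg.min_exon_length, n_exons,
            )
            intron_lens = _lognormal_int(
                rng, cfg.intron_length_log_mean, cfg.intron_length_log_sd,
                cfg.min_intron_length, max(0, n_exons - 1),
            )
            exons = []
            pos = cursor
            for i in range(n_exons):
                exons.append((pos, pos + int(exon_lens[i])))
                pos += int(exon_lens[i])
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    tx_start=cursor,
                    tx_end=pos,
                    exons=tuple(exons),
                )
            )
            # gap after the gene; the middle slice (clear of both flanking
            # TES windows) is a safe intergenic zone
            gap = cfg.gap + int(rng.integers(0, 5_000))
            zone_lo = pos + cfg.tes_extent + 1_000
            zone_hi = pos + gap - cfg.tes_extent - 1_000
            if zone_hi - zone_lo > 500:
                zones.append((chrom, zone_lo, zone_hi))
            cursor = pos + gap
        # reserved tail for rRNA repeats
        tail = cursor + cfg.gap
        n_rrna_here = cfg.n_rrna if ci == 0 else 0
        for _ in range(n_rrna_here):
            rrna.append((chrom, tail, tail + cfg.rrna_length))
            tail += cfg.rrna_length + 2_000
        contig_lengths[chrom] = tail + cfg.gap
    expr = np.exp(rng.normal(0.0, cfg.expression_log_sd, size=len(genes)))
    expression = pd.Series(
        expr / expr.sum(), index=[g.gene_id for g in genes], name="expression"
    )
    return SimulatedGenome(
        genes=genes,
        contig_lengths=contig_lengths,
        rrna=MaskSet(rrna),
        intergenic_zones=zones,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# nascent reads


@dataclass
class ConditionParams:
    """Ground-truth parameters of one experimental condition."""

    splicing_efficiency: float = 0.55
    readthrough_fraction: float = 0.05
    phase: str = "chase"  # "pulse" or "chase"

    def __post_init__(self):
        for p in (self.splicing_efficiency, self.readthrough_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.phase not in ("pulse", "chase"):
            raise ValueError("phase must be 'pulse' or 'chase'")


@dataclass
class NascentConfig:
    """Study conditions for the pulse/chase nascent-RNA simulation.

    Defaults emulate the study design: a solvent control with efficient
    splicing and little readthrough, a kinase-inhibitor arm with impaired
    splicing and increased readthrough, and a splicing-inhibitor arm with
    strongly impaired splicing; a pulse sample of the control shows the
    maturation gain of the chase.
    """

    conditions: dict[str, ConditionParams] = field(
        default_factory=lambda: {
            "DMSO_pulse": ConditionParams(0.55, 0.05, phase="pulse"),
            "DMSO": ConditionParams(0.55, 0.05, phase="chase"),
            "BAY-880": ConditionParams(0.40, 0.15, phase="chase"),
            "PlaB": ConditionParams(0.15, 0.08, phase="chase"),
        }
    )
    n_replicates: int = 3
    reads_per_sample: int = 100_000
    read_length: int = 75
    chase_gain: float = 0.5  # chase efficiency = eff + gain * (1 - eff)
    junction_fraction: float = 0.4  # mature reads that span a junction
    boundary_fraction: float = 0.3  # pre-mRNA reads that cross a boundary
    intergenic_fraction: float = 0.02
    rrna_fraction: float = 0.01
    orientation: str = "frf"


def effective_efficiency(params: ConditionParams, chase_gain: float) -> float:
    """Splicing efficiency after optional chase maturation."""
    eff = params.splicing_efficiency
    if params.phase == "chase":
        eff = eff + chase_gain * (1.0 - eff)
    return min(eff, 1.0)


def _read_strand(gene_strand: str, orientation: str, rng) -> str:
    if orientation == "frf":
        return "-" if gene_strand == "+" else "+"
    return "+" if rng.random() < 0.5 else "-"


def _junction_read(gene: GeneModel, rl: int, rng) -> Optional[tuple]:
    introns = gene.introns
    i = int(rng.integers(0, len(introns)))
    left, right = gene.exons[i], gene.exons[i + 1]
    max_left = min(rl - 10, left[1] - left[0])
    min_left = max(10, rl - (right[1] - right[0]))
    if min_left > max_left:
        return None
    k1 = int(rng.integers(min_left, max_left + 1))
    k2 = rl - k1
    return ((left[1] - k1, left[1]), (right[0], right[0] + k2))


def _exonic_read(gene: GeneModel, rl: int, rng) -> Optional[tuple]:
    fits = [e for e in gene.exons if e[1] - e[0] >= rl]
    if not fits:
        return None
    lens = np.array([e[1] - e[0] - rl + 1 for e in fits], dtype=float)
    e = fits[rng.choice(len(fits), p=lens / lens.sum())]
    s = int(rng.integers(e[0], e[1] - rl + 1))
    return ((s, s + rl),)


def _intronic_read(gene: GeneModel, rl: int, rng) -> Optional[tuple]:
    fits = [i for i in gene.introns if i[1] - i[0] >= rl]
    if not fits:
        return None
    lens = np.array([i[1] - i[0] - rl + 1 for i in fits], dtype=float)
    iv = fits[rng.choice(len(fits), p=lens / lens.sum())]
    s = int(rng.integers(iv[0], iv[1] - rl + 1))
    return ((s, s + rl),)


def _boundary_read(gene: GeneModel, rl: int, rng) -> Optional[tuple]:
    # cross a random exon/intron boundary with 10..rl-10 bp on each side,
    # staying inside the transcript span
    bounds = []
    for i, intron in enumerate(gene.introns):
        bounds.append(intron[0])  # exon_i end
        bounds.append(intron[1])  # exon_{i+1} start
    if not bounds:
        return None
    b = int(bounds[rng.integers(0, len(bounds))])
    k = int(rng.integers(10, rl - 9))
    s = b - k
    if s < gene.tx_start or s + rl > gene.tx_end:
        return None
    return ((s, s + rl),)


def _readthrough_read(regions, rl: int, rng) -> Optional[tuple]:
    lo, hi = regions.tes_window
    if hi - lo < rl + 2:
        return None
    if regions.strand == "+":
        s = int(rng.integers(lo - rl + 1, hi - rl + 1))
    else:
        s = int(rng.integers(lo, hi))
    return ((s, s + rl),)


def simulate_nascent_reads(
    genome: SimulatedGenome,
    params: ConditionParams,
    n_reads: int,
    sample_id: str,
    config: NascentConfig = NascentConfig(),
    seed: int | np.random.Generator = 0,
) -> list[AlignedRead]:
    """Sample one library of nascent-RNA reads for one condition/replicate."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rl = config.read_length
    eff = effective_efficiency(params, config.chase_gain)
    regions = {r.gene_id: r for r in genome.regions}
    gene_by_id = {g.gene_id: g for g in genome.genes}
    gene_ids = list(genome.expression.index)
    cum_weights = np.cumsum(genome.expression.to_numpy())
    cum_weights[-1] = 1.0  # guard against float round-off
    rrna_ivs = genome.rrna.intervals
    reads: list[AlignedRead] = []
    while len(reads) < n_reads:
        u = rng.random()
        if rrna_ivs and u < config.rrna_fraction:
            chrom, lo, hi = rrna_ivs[int(rng.integers(0, len(rrna_ivs)))]
            s = int(rng.integers(lo, hi - rl))
            blocks = ((s, s + rl),)
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(AlignedRead(chrom, strand, blocks, sample_id))
            continue
        if genome.intergenic_zones and u < config.rrna_fraction + config.intergenic_fraction:
            chrom, lo, hi = genome.intergenic_zones[
                int(rng.integers(0, len(genome.intergenic_zones)))
            ]
            s = int(rng.integers(lo, hi - rl))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(AlignedRead(chrom, strand, ((s, s + rl),), sample_id))
            continue
        gid = gene_ids[int(np.searchsorted(cum_weights, rng.random(), side="right"))]
        gene = gene_by_id[gid]
        dr = regions[gid]
        blocks = None
        if rng.random() < params.readthrough_fraction:
            blocks = _readthrough_read(dr, rl, rng)
        elif len(gene.exons) == 1 or rng.random() < eff:
            if len(gene.exons) > 1 and rng.random() < config.junction_fraction:
                blocks = _junction_read(gene, rl, rng)
            if blocks is None:
                blocks = _exonic_read(gene, rl, rng)
        else:
            if rng.random() < config.boundary_fraction:
                blocks = _boundary_read(gene, rl, rng)
            if blocks is None:
                blocks = _intronic_read(gene, rl, rng)
        if blocks is None:
            continue  # geometry did not fit; resample
        strand = _read_strand(gene.strand, config.orientation, rng)
        reads.append(AlignedRead(gene.chrom, strand, blocks, sample_id))
    return reads


def simulate_nascent_experiment(
    genome: SimulatedGenome,
    config: NascentConfig = NascentConfig(),
    seed: int = 0,
) -> tuple[dict[str, list[AlignedRead]], dict[str, str]]:
    """All samples of a multi-condition, multi-replicate experiment.

    Returns ``(reads_by_sample, sample_to_condition)``; sample ids are
    ``{condition}_rep{r}``. Each sample draws from an independent stream
    seeded from ``seed``.
    """
    root = np.random.default_rng(seed)
    reads_by_sample: dict[str, list[AlignedRead]] = {}
    sample_condition: dict[str, str] = {}
    for cond in sorted(config.conditions):
        params = config.conditions[cond]
        for rep in range(1, config.n_replicates + 1):
            sid = f"{cond}_rep{rep}"
            child = np.random.default_rng(root.integers(2**31))
            reads_by_sample[sid] = simulate_nascent_reads(
                genome, params, config.reads_per_sample, sid, config, child
            )
            sample_condition[sid] = cond
    return reads_by_sample, sample_condition


# ---------------------------------------------------------------------------
# ChIP-RX


@dataclass
class ChipConfig:
    """Dual-genome ChIP simulation: constant spike-in, variable signal.

    ``signal_factors`` scales the genome-wide occupancy of each condition
    relative to the reference; the spike-in depth is the same for all
    samples, which is what makes the RX factor informative.
    """

    signal_factors: dict[str, float] = field(
        default_factory=lambda: {"DMSO": 1.0, "BAY-880": 0.5}
    )
    n_replicates: int = 2
    peak_height: float = 60.0  # mean promoter peak coverage depth
    peak_sd: float = 150.0  # Gaussian peak width (bp)
    background: float = 0.5  # uniform genomic background depth
    spikein_depth: int = 1_000_000
    read_length: int = 75


@dataclass
class SimulatedChip:
    genome: SimulatedGenome
    accounting: pd.DataFrame  # sample, primary_mapped, spikein_mapped
    tracks: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> coverage
    sample_condition: dict[str, str]


def simulate_spikein(
    genome: SimulatedGenome,
    config: ChipConfig = ChipConfig(),
    seed: int = 0,
) -> SimulatedChip:
    """Promoter-shaped ChIP coverage plus dual-genome read accounting.

    Every sample shares the same underlying per-gene peak strengths; a
    condition's ``signal_factor`` scales its whole primary-genome signal
    (peaks and background alike), emulating a global occupancy change. The
    spike-in read count is Poisson around a constant depth.
    """
    rng = np.random.default_rng(seed)
    regs = genome.regions
    strengths = np.exp(rng.normal(0.0, 0.5, size=len(regs)))
    rows = []
    tracks: dict[str, dict[str, np.ndarray]] = {}
    sample_condition: dict[str, str] = {}
    for cond in sorted(config.signal_factors):
        factor = config.signal_factors[cond]
        for rep in range(1, config.n_replicates + 1):
            sid = f"{cond}_rep{rep}"
            sample_condition[sid] = cond
            cov = {
                chrom: np.full(clen, config.background * factor, dtype=float)
                for chrom, clen in genome.contig_lengths.items()
            }
            for dr, strength in zip(regs, strengths):
                arr = cov[dr.chrom]
                center = dr.tss
                lo = max(0, center - 4 * int(config.peak_sd))
                hi = min(len(arr), center + 4 * int(config.peak_sd))
                x = np.arange(lo, hi)
                arr[lo:hi] += (
                    config.peak_height
                    * factor
                    * strength
                    * np.exp(-0.5 * ((x - center) / config.peak_sd) ** 2)
                )
            primary = int(
                round(sum(a.sum() for a in cov.values()) / config.read_length)
            )
            spike = int(rng.poisson(config.spikein_depth))
            rows.append(
                {
                    "sample": sid,
                    "primary_mapped": primary,
                    "spikein_mapped": spike,
                }
            )
            tracks[sid] = cov
    accounting = pd.DataFrame(rows)
    return SimulatedChip(
        genome=genome,
        accounting=accounting,
        tracks=tracks,
        sample_condition=sample_condition,
    )


# ---------------------------------------------------------------------------
# proteomics


@dataclass
class ApmsConfig:
    """AP-MS (bait vs control co-IP) intensity-table simulation."""

    n_proteins: int = 2_000
    n_true_interactors: int = 25
    effect_log2: float = 8.0
    n_replicates: int = 2
    base_log10_mean: float = 6.5
    base_log10_sd: float = 0.9
    replicate_log10_sd: float = 0.15
    control_missing_rate: float = 0.25
    censoring_sd: float = 0.2  # softness of the detection-limit censoring
    contaminant_fraction: float = 0.01
    reverse_fraction: float = 0.01
    low_peptide_fraction: float = 0.05


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    true_interactors: list[str] = field(default_factory=list)
    differential_sites: list[str] = field(default_factory=list)
    effect_sizes: dict[str, float] = field(default_factory=dict)


def simulate_intensity_table(
    config: ApmsConfig = ApmsConfig(), seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """MaxQuant-style LFQ table with planted bait interactors.

    True interactors get their bait intensities shifted by ``effect_log2``;
    control cells go missing (NaN) at the configured overall rate through
    soft detection-limit censoring — low-abundance measurements drop out
    preferentially, as in real label-free MS, so that imputation near the
    baseline stands in for values that truly were near the baseline.
    Quality columns are drawn so small fractions of rows fail each filter.
    Bait and control columns are ``bait_1..n`` / ``ctrl_1..n``.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    ids = [f"P{i + 1:05d}" for i in range(cfg.n_proteins)]
    base = rng.normal(cfg.base_log10_mean, cfg.base_log10_sd, cfg.n_proteins)
    truth = GroundTruth(true_interactors=ids[: cfg.n_true_interactors])
    shift = np.zeros(cfg.n_proteins)
    shift[: cfg.n_true_interactors] = cfg.effect_log2 * np.log10(2.0)
    data: dict[str, np.ndarray] = {}
    for r in range(1, cfg.n_replicates + 1):
        data[f"bait_{r}"] = 10.0 ** (
            base + shift + rng.normal(0, cfg.replicate_log10_sd, cfg.n_proteins)
        )
        log_ctrl = base + rng.normal(0, cfg.replicate_log10_sd, cfg.n_proteins)
        ctrl = 10.0**log_ctrl
        if cfg.control_missing_rate > 0:
            thresh = np.quantile(log_ctrl, cfg.control_missing_rate)
            missing = (
                log_ctrl + rng.normal(0, cfg.censoring_sd, cfg.n_proteins) < thresh
            )
            ctrl[missing] = np.nan
        data[f"ctrl_{r}"] = ctrl
    table = pd.DataFrame(data, index=pd.Index(ids, name="protein_id"))
    table["Razor + unique peptides"] = np.where(
        rng.random(cfg.n_proteins) < cfg.low_peptide_fraction,
        rng.integers(0, 2, cfg.n_proteins),
        rng.integers(2, 30, cfg.n_proteins),
    )
    table["Score"] = rng.uniform(35.0, 300.0, cfg.n_proteins)
    table["Reverse"] = np.where(
        rng.random(cfg.n_proteins) < cfg.reverse_fraction, "+", ""
    )
    table["Potential contaminant"] = np.where(
        rng.random(cfg.n_proteins) < cfg.contaminant_fraction, "+", ""
    )
    # planted rows always clear the quality filters, so recovery measures
    # the statistic and not the row filter
    head = slice(0, cfg.n_true_interactors)
    table.loc[table.index[head], "Razor + unique peptides"] = 10
    table.loc[table.index[head], "Score"] = 200.0
    table.loc[table.index[head], "Reverse"] = ""
    table.loc[table.index[head], "Potential contaminant"] = ""
    truth.effect_sizes = {pid: cfg.effect_log2 for pid in truth.true_interactors}
    return table, truth


@dataclass
class PhosphoConfig:
    """Phosphosite table simulation for the permutation-FDR test."""

    n_sites: int = 5_000
    n_differential: int = 100
    effect_sd_multiple: float = 3.0
    n_replicates: int = 4
    noise_sd: float = 1.0


def simulate_phospho_table(
    config: PhosphoConfig = PhosphoConfig(), seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Log-scale phosphosite table with planted group differences.

    Columns are ``treat_1..n`` / ``ctrl_1..n`` on a log2-like scale with
    N(0, noise_sd) replicate noise; the first ``n_differential`` sites get a
    mean shift of ``effect_sd_multiple * noise_sd`` in the treatment group.
    Quality columns are drawn so a small fraction fails each filter and the
    planted rows always pass.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    ids = [f"S{i + 1:05d}" for i in range(cfg.n_sites)]
    effect = np.zeros(cfg.n_sites)
    effect[: cfg.n_differential] = cfg.effect_sd_multiple * cfg.noise_sd
    data = {}
    for r in range(1, cfg.n_replicates + 1):
        data[f"treat_{r}"] = effect + rng.normal(0, cfg.noise_sd, cfg.n_sites)
        data[f"ctrl_{r}"] = rng.normal(0, cfg.noise_sd, cfg.n_sites)
    table = pd.DataFrame(data, index=pd.Index(ids, name="site_id"))
    table["Score"] = rng.uniform(35.0, 300.0, cfg.n_sites)
    table["Localization prob"] = rng.uniform(0.5, 1.0, cfg.n_sites)
    table["PEP"] = 10.0 ** rng.uniform(-6.0, -1.0, cfg.n_sites)
    table["Reverse"] = np.where(rng.random(cfg.n_sites) < 0.01, "+", "")
    table["Potential contaminant"] = np.where(
        rng.random(cfg.n_sites) < 0.01, "+", ""
    )
    head = table.index[: cfg.n_differential]
    table.loc[head, "Score"] = 200.0
    table.loc[head, "Localization prob"] = 0.99
    table.loc[head, "PEP"] = 1e-4
    table.loc[head, "Reverse"] = ""
    table.loc[head, "Potential contaminant"] = ""
    truth = GroundTruth(
        differential_sites=list(head),
        effect_sizes={s: cfg.effect_sd_multiple * cfg.noise_sd for s in head},
    )
    return table, truth
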