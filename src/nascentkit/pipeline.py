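"""End-to-end orchestration of the two analyses.

``run_nascent`` chains mask -> classify -> count -> normalize -> expression
filter -> scores -> density summaries -> Signal2Noise ranking -> category
fractions on a seeded synthetic experiment, writing every table as TSV plus a
run manifest. ``run_apms`` chains simulate -> filter -> impute -> binned-IQR
enrichment and simulate -> filter -> permutation-FDR differential test, plus
the overlap significance of the two hit lists.

All tables are written with a fixed float format, so a seeded run is
byte-identical across invocations. Every stage is also callable on its own;
the pipeline output equals manual stage-by-stage invocation by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import classify as _classify
from . import io as _io
from . import proteomics as _prot
from . import scores as _scores
from . import simulate as _sim

logger = logging.getLogger("nascentkit")


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config hash, seed, stages, outputs."""

    config_hash: str
    seed: int
    stages: list[str]
    outputs: dict[str, str]
    version: str = __version__

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_hash(cfg) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    blob = json.dumps(cfg, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class NascentRunConfig:
    """Everything a nascent-RNA scoring run needs."""

    genome: _sim.GenomeConfig = field(default_factory=_sim.GenomeConfig)
    nascent: _sim.NascentConfig = field(default_factory=_sim.NascentConfig)
    rank_between: Optional[tuple[str, str]] = ("BAY-880", "DMSO")
    expression_threshold: float = _scores.EXPRESSION_THRESHOLD
    bandwidth: float = _scores.DEFAULT_BANDWIDTH
    junction_tol: int = _classify.JUNCTION_TOL


@dataclass
class NascentResults:
    counts: _classify.ReadCategoryCounts
    normalized: _classify.NormalizedCounts
    scores: pd.DataFrame
    condition_means: pd.DataFrame
    fractions: pd.DataFrame
    fraction_summary: Optional[pd.DataFrame]
    densities: dict[str, _scores.DensitySummary]
    ranked: Optional[pd.DataFrame]
    manifest: RunManifest


def run_nascent(
    config: NascentRunConfig = NascentRunConfig(),
    outdir=None,
    seed: int = 0,
) -> NascentResults:
    """Run the full nascent-RNA scoring chain on a seeded simulation."""
    stages: list[str] = []
    outputs: dict[str, str] = {}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage genome: simulating gene models")
    genome = _sim.simulate_genome(config.genome, seed=seed)
    regions = genome.regions
    index = _classify.GeneIndex(regions)
    stages.append("genome")

    logger.info("stage reads: simulating nascent libraries")
    reads_by_sample, sample_condition = _sim.simulate_nascent_experiment(
        genome, config.nascent, seed=seed
    )
    stages.append("reads")

    logger.info("stage mask+classify: %d samples", len(reads_by_sample))
    all_reads: list[_classify.AlignedRead] = []
    assignments: list[_classify.Assignment] = []
    removed: dict[str, int] = {}
    for sid in sorted(reads_by_sample):
        kept, n_removed = _classify.filter_rrna(reads_by_sample[sid], genome.rrna)
        removed[sid] = n_removed
        for r in kept:
            all_reads.append(r)
            assignments.append(
                _classify.classify_read(
                    r,
                    index,
                    orientation=config.nascent.orientation,
                    junction_tol=config.junction_tol,
                )
            )
    counts = _classify.count_categories(
        all_reads,
        assignments,
        gene_ids=index.gene_ids,
        rrna_removed=removed,
        samples=sorted(reads_by_sample),
    )
    stages.append("classify")

    logger.info("stage normalize+scores")
    normalized = _classify.normalize_counts(counts, index.by_gene)
    expressed = _scores.filter_expressed(counts, config.expression_threshold)
    table = _scores.score_table(normalized, sample_condition)
    table = table[table.index.get_level_values("gene_id").isin(expressed)]
    means = _scores.condition_means(table)
    stages.append("scores")

    logger.info("stage summaries")
    densities: dict[str, _scores.DensitySummary] = {}
    for cond in sorted(set(sample_condition.values())):
        vals = means.xs(cond, level="condition")["splicing_score"]
        try:
            densities[cond] = _scores.density_summary(
                vals, bandwidth=config.bandwidth
            )
        except ValueError:
            logger.warning("condition %s has too few scores for a density", cond)
    fractions, fraction_summary = _classify.category_fractions(
        counts, sample_condition
    )
    ranked = None
    if config.rank_between is not None:
        cond_a, cond_b = config.rank_between
        spl = table["splicing_score"].unstack("sample")
        cols_a = [s for s, c in sample_condition.items() if c == cond_a]
        cols_b = [s for s, c in sample_condition.items() if c == cond_b]
        ranked = _scores.signal2noise(spl, cols_a, cols_b)
    stages.append("summaries")

    manifest = RunManifest(
        config_hash=_config_hash({"kind": "nascent", "config": config, "seed": seed}),
        seed=seed,
        stages=stages,
        outputs=outputs,
    )
    if out is not None:
        _io.write_tsv(counts.per_gene.reset_index(), out / "category_counts.tsv")
        _io.write_tsv(counts.per_sample.reset_index(), out / "sample_counts.tsv")
        _io.write_tsv(table.reset_index(), out / "score_table.tsv")
        _io.write_tsv(means.reset_index(), out / "condition_means.tsv")
        _io.write_tsv(fractions.reset_index(), out / "category_fractions.tsv")
        if fraction_summary is not None:
            _io.write_tsv(
                fraction_summary.reset_index(), out / "fraction_summary.tsv"
            )
        for cond, dens in densities.items():
            df = pd.DataFrame({"log10_score": dens.grid, "density": dens.density})
            _io.write_tsv(df, out / f"density_{cond}.tsv")
            outputs[f"density_{cond}"] = f"density_{cond}.tsv"
        if ranked is not None:
            _scores.write_rnk(ranked, out / "splicing_s2n.rnk")
            outputs["ranked"] = "splicing_s2n.rnk"
        outputs.update(
            {
                "category_counts": "category_counts.tsv",
                "sample_counts": "sample_counts.tsv",
                "score_table": "score_table.tsv",
                "condition_means": "condition_means.tsv",
                "category_fractions": "category_fractions.tsv",
            }
        )
        manifest.outputs = outputs
        manifest.write(out / "manifest.json")
    return NascentResults(
        counts=counts,
        normalized=normalized,
        scores=table,
        condition_means=means,
        fractions=fractions,
        fraction_summary=fraction_summary,
        densities=densities,
        ranked=ranked,
        manifest=manifest,
    )


@dataclass
class ApmsRunConfig:
    """Everything an AP-MS + phospho differential run needs."""

    apms: _sim.ApmsConfig = field(default_factory=_sim.ApmsConfig)
    phospho: _sim.PhosphoConfig = field(default_factory=_sim.PhosphoConfig)
    iqr: _prot.BinnedIqrParams = field(default_factory=_prot.BinnedIqrParams)
    s0: float = 0.1
    fdr: float = 0.01
    n_perm: int = 250


@dataclass
class ApmsResults:
    enrichment: pd.DataFrame
    differential: pd.DataFrame
    overlap_p: float
    truth_apms: _sim.GroundTruth
    truth_phospho: _sim.GroundTruth
    manifest: RunManifest


def run_apms(
    config: ApmsRunConfig = ApmsRunConfig(),
    outdir=None,
    seed: int = 0,
) -> ApmsResults:
    """Run the AP-MS enrichment and phospho differential chains."""
    stages: list[str] = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage apms: simulate + filter + impute + binned IQR")
    table, truth_apms = _sim.simulate_intensity_table(config.apms, seed=seed)
    bait_cols = [c for c in table.columns if c.startswith("bait_")]
    ctrl_cols = [c for c in table.columns if c.startswith("ctrl_")]
    filtered = _prot.filter_rows(table)
    imputed, _mask = _prot.impute_missing(
        filtered,
        impute_columns=ctrl_cols,
        quantile_columns=bait_cols + ctrl_cols,
        seed=seed,
    )
    enrichment = _prot.binned_iqr_outliers(
        imputed, bait_cols, ctrl_cols, params=config.iqr
    )
    stages.append("apms_enrich")

    logger.info("stage phospho: simulate + filter + permutation FDR")
    ptable, truth_phospho = _sim.simulate_phospho_table(config.phospho, seed=seed)
    treat_cols = [c for c in ptable.columns if c.startswith("treat_")]
    pctrl_cols = [c for c in ptable.columns if c.startswith("ctrl_")]
    pfiltered = _prot.filter_rows(
        ptable, groups={"treat": treat_cols, "ctrl": pctrl_cols}
    )
    differential = _prot.permutation_fdr_ttest(
        pfiltered,
        treat_cols,
        pctrl_cols,
        s0=config.s0,
        n_perm=config.n_perm,
        fdr=config.fdr,
        seed=seed,
    )
    stages.append("phospho_diff")

    # overlap of the two hit lists over a shared synthetic universe: protein
    # ids are mapped onto site ids by rank to emulate gene-level comparison
    n_univ = min(len(enrichment), len(differential))
    hits_a = {
        i for i, flag in enumerate(enrichment["enriched"].to_numpy()[:n_univ]) if flag
    }
    hits_b = {
        i
        for i, flag in enumerate(differential["significant"].to_numpy()[:n_univ])
        if flag
    }
    overlap_p = _prot.overlap_significance(hits_a, hits_b, n_univ)
    stages.append("overlap")

    manifest = RunManifest(
        config_hash=_config_hash({"kind": "apms", "config": config, "seed": seed}),
        seed=seed,
        stages=stages,
        outputs={},
    )
    if out is not None:
        _io.write_tsv(enrichment.reset_index(drop=True), out / "enrichment_calls.tsv")
        _io.write_tsv(differential.reset_index(), out / "differential_sites.tsv")
        with open(out / "overlap.json", "w") as fh:
            json.dump({"p_value": overlap_p}, fh, indent=2)
            fh.write("\n")
        manifest.outputs = {
            "enrichment": "enrichment_calls.tsv",
            "differential": "differential_sites.tsv",
            "overlap": "overlap.json",
        }
        manifest.write(out / "manifest.json")
    return ApmsResults(
        enrichment=enrichment,
        differential=differential,
        overlap_p=overlap_p,
        truth_apms=truth_apms,
        truth_phospho=truth_phospho,
        manifest=manifest,
    )
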