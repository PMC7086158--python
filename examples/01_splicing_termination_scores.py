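"""Score splicing and termination on a simulated three-condition experiment.

Builds a small synthetic genome, simulates nascent-RNA libraries for a
control, a splicing-impaired and a readthrough-prone condition, classifies
every read, and prints the per-condition median scores. Higher splicing
scores mean more junction reads per unit of pre-mRNA signal; higher
termination scores mean more signal downstream of the TES.
"""

from nascentkit import simulate as sim
from nascentkit.pipeline import NascentRunConfig, run_nascent

config = NascentRunConfig(
    genome=sim.GenomeConfig(n_genes=60),
    nascent=sim.NascentConfig(
        conditions={
            "control": sim.ConditionParams(splicing_efficiency=0.7, readthrough_fraction=0.05),
            "splicing_impaired": sim.ConditionParams(0.3, 0.05),
            "readthrough_prone": sim.ConditionParams(0.7, 0.25),
        },
        n_replicates=3,
        reads_per_sample=20_000,
    ),
    rank_between=("splicing_impaired", "control"),
)
results = run_nascent(config, seed=42)

medians = results.condition_means.groupby(level="condition").median()
print(medians.round(3))
print()
print("Genes scored:", results.scores.index.get_level_values("gene_id").nunique())
print("Top of the Signal2Noise ranking (impaired vs control):")
print(results.ranked.head(3).round(3))
print()
print(
    "The splicing-impaired condition shows the lowest median splicing score;\n"
    "the readthrough-prone condition shows the highest termination score.\n"
    "The ranked list orders genes by how strongly their per-replicate\n"
    "splicing scores separate the two conditions (input for GSEA)."
)
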