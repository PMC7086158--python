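"""Why spike-in normalization matters: a global occupancy loss.

Simulates ChIP coverage for a control and a condition with a genome-wide 2x
signal loss, with the same amount of spike-in chromatin in both. Library-size
normalization erases the difference; the spike-in (RX) factor preserves it.
"""

from nascentkit import simulate as sim
from nascentkit.chiprx import library_size_factors, metagene, rx_factors

genome = sim.simulate_genome(sim.GenomeConfig(n_genes=40), seed=3)
chip = sim.simulate_spikein(
    genome, sim.ChipConfig(signal_factors={"control": 1.0, "treated": 0.5}), seed=3
)

rx = rx_factors(chip.accounting)
lib = library_size_factors(chip.accounting)
anchors = [(dr.chrom, dr.tss, dr.strand) for dr in genome.regions]


def promoter_signal(sample, factors):
    prof = metagene(chip.tracks[sample], anchors, window=(-500, 500),
                    scale=factors[sample])
    return prof.mean.sum()


for name, factors in (("RX (spike-in)", rx), ("library-size", lib)):
    ratio = promoter_signal("treated_rep1", factors) / promoter_signal(
        "control_rep1", factors
    )
    print(f"{name:>15} normalization: treated/control promoter signal = {ratio:.3f}")
print()
print(
    "The simulation planted a true 2x global loss (ratio 0.5). Spike-in\n"
    "normalization recovers it; scaling by primary-genome library size\n"
    "reports ~1.0, i.e. no change — the classic blind spot it was built to fix."
)
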