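"""Differential phosphosites by moderated t-test with permutation FDR.

Simulates a 4 vs 4 phosphosite table with 100 planted shifts, runs the
s0-moderated two-sided t-test with permutation-based FDR truncation, and
compares nominal flags with a simple ranking view. With only four replicates
a 3-sd shift is strong evidence per site but rarely clears a 1% FDR over
5,000 tests — the ranking, not the flag count, carries the biology.
"""

import numpy as np

from nascentkit import simulate as sim
from nascentkit.proteomics import overlap_significance, permutation_fdr_ttest

table, truth = sim.simulate_phospho_table(
    sim.PhosphoConfig(n_sites=5_000, n_differential=100), seed=11
)
res = permutation_fdr_ttest(
    table,
    [f"treat_{i}" for i in range(1, 5)],
    [f"ctrl_{i}" for i in range(1, 5)],
    s0=0.1,
    fdr=0.01,
    seed=11,
)

top = res.reindex(res["t_s0"].abs().sort_values(ascending=False).index)
top100 = set(top.index[:100])
planted = set(truth.differential_sites)
print(f"sites tested            : {len(res)}")
print(f"flagged at 1% FDR       : {int(res['significant'].sum())}")
print(f"planted in |t| top 100  : {len(top100 & planted)} / 100")
print(f"median |t| planted/null : "
      f"{res.loc[list(planted), 't_s0'].abs().median():.2f} vs "
      f"{res.drop(index=list(planted))['t_s0'].abs().median():.2f}")

p = overlap_significance(top100, planted, len(res))
print(f"top-100 vs planted overlap, hypergeometric p = {p:.3g}")
print()
print(
    "The permutation FDR is deliberately conservative at this design point;\n"
    "planted sites still dominate the top of the ranking, and the overlap\n"
    "test quantifies how unlikely that concentration is by chance."
)
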