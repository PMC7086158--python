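"""Call bait interactors from a simulated co-IP intensity table.

The table mimics a label-free AP-MS screen: two bait and two control runs,
detection-limit dropout in the controls, and 25 planted true interactors.
Missing control values are imputed near the intensity floor, and proteins
whose mean log2 bait/control ratio falls outside 1.5x (potential) or 3x
(extreme) the interquartile range of their abundance bin are called.
"""

from nascentkit import simulate as sim
from nascentkit.proteomics import binned_iqr_outliers, filter_rows, impute_missing

table, truth = sim.simulate_intensity_table(sim.ApmsConfig(), seed=11)
bait, ctrl = ["bait_1", "bait_2"], ["ctrl_1", "ctrl_2"]

filtered = filter_rows(table)
imputed, mask = impute_missing(filtered, ctrl, quantile_columns=bait + ctrl, seed=11)
calls = binned_iqr_outliers(imputed, bait, ctrl).set_index("protein_id")

planted = [p for p in truth.true_interactors if p in calls.index]
print(f"proteins after quality filters : {len(calls)}")
print(f"imputed control cells          : {int(mask.values.sum())}")
print(f"enriched calls (upper tail)    : {int(calls['enriched'].sum())}")
print(f"planted interactors recovered  : {int(calls.loc[planted, 'enriched'].sum())}"
      f" / {len(planted)}")
print(f"  of which extreme             : "
      f"{int((calls.loc[planted, 'status'] == 'extreme').sum())}")
print()
print(
    "Recovered interactors sit far outside their bin's ratio distribution;\n"
    "the remaining enriched calls are the expected boxplot false-positive\n"
    "tail (~0.7% of proteins beyond 1.5x IQR per side under the null)."
)
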