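"""Rank the 7 inputs by leave-one-input-out sensitivity (VSE / VSR).

For each input the GRNN is retrained without that column and re-scored
on the held-out subset; VSR = reduced-model RMSE / full-model RMSE.
VSR near 1 means the input carried no information; larger means more
important.  Note that removing a concentration column makes that
disinfectant's rows indistinguishable from untreated controls, so
concentration removals carry the control contrast as well.
"""

from sterilopt import ReplicateConfig, expand_replicates, load_treatment_tables
from sterilopt.sensitivity import sensitivity_analysis

records = load_treatment_tables()
table = expand_replicates(records, ReplicateConfig(8, seed=0))
report = sensitivity_analysis("GRNN", table, seed=0)
print(report.table[["response", "feature", "VSE", "VSR", "rank"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nfull-model test RMSE: "
      f"contamination {report.full_rmse['contamination']:.2f}%, "
      f"germination {report.full_rmse['germination']:.2f}%")
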