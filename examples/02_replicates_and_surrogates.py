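"""Expand the printed means into synthetic replicates and score the three
surrogates (MLP, RBF, GRNN) on a stratified 80/20 split.

Each treatment's mean +/- SE row becomes 8 noisy replicates
(sd = SE * sqrt(8), truncated to [0, 100]).  The printed grid mirrors the
study's model-comparison table: R^2 / RMSE / MBE per model, response and
subset, and the best model by mean test R^2.
"""

from sterilopt import (
    ReplicateConfig,
    compare_models,
    expand_replicates,
    load_treatment_tables,
    split_train_test,
)
from sterilopt.workflow import train_surrogates

records = load_treatment_tables()
table = expand_replicates(records, ReplicateConfig(replicates_per_treatment=8, seed=0))
print(f"replicate-level dataset: {len(table)} rows (90 treatments x 8)")

train, test = split_train_test(table, train_fraction=0.8, seed=0)
models, scaler = train_surrogates(train, seed=0)
report = compare_models(models, train, test, scaler)
print(report.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nbest model by mean test R^2: {report.best_model}")
print("RMSE/MBE are on the raw percent scale of the responses.")
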