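"""Search one disinfectant's tested range with NSGA-II over the GRNN pair.

The optimizer minimizes predicted contamination and maximizes predicted
germination over (concentration, immersion time) for Ca(ClO)2; the
reported solution is the Pareto-front member closest to the utopia point
(minimum observed contamination, maximum observed germination of the
Ca(ClO)2 subset).
"""

from sterilopt import (
    DisinfectantKind,
    GAConfig,
    ReplicateConfig,
    apply_scaler,
    evolve,
    expand_replicates,
    fit_scaler,
    load_treatment_tables,
    scenario_for,
    train_grnn,
)

records = load_treatment_tables()
table = expand_replicates(records, ReplicateConfig(8, seed=0))
scaler = fit_scaler(table.X)
Xs = apply_scaler(scaler, table.X)
cont_model = train_grnn(Xs, table.contamination)
germ_model = train_grnn(Xs, table.germination)

scenario = scenario_for(DisinfectantKind.CaClO2, records)
print(f"scenario: Ca(ClO)2 in {scenario.concentration_bounds}%, "
      f"time in {scenario.time_bounds} min; utopia (m, n) = ({scenario.m}, {scenario.n})")

result = evolve(cont_model, germ_model, scenario, GAConfig(seed=0), scaler=scaler)
print(f"final front: {len(result.front_X)} non-dominated solutions")
print(f"ideal point: {result.ideal_concentration:.2f}% for {result.ideal_time:.2f} min "
      f"-> predicted contamination {result.ideal_objectives[0]:.2f}%, "
      f"germination {result.ideal_objectives[1]:.2f}%")
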