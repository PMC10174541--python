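"""Validate the surrogate + optimizer stack on a synthetic ground truth.

A benchmark surface with a known best input (germination peak at
concentration 7, time 12) is sampled on a grid with noise; the GRNN is
fitted to the samples and NSGA-II searches the box.  The ideal point
should land near the true optimum — a parameter-recovery check that the
real experiment cannot provide.
"""

from sterilopt import (
    DisinfectantKind,
    GAConfig,
    Scenario,
    apply_scaler,
    evolve,
    fit_scaler,
    make_benchmark_surface,
    train_grnn,
)

table, surface = make_benchmark_surface("sharp-peak", noise_sd=1.0, seed=0)
print(f"sampled {len(table)} grid points; true optimum at "
      f"(c*, t*) = {surface.ideal_input}")

scaler = fit_scaler(table.X)
Xs = apply_scaler(scaler, table.X)
cont = train_grnn(Xs, table.contamination)
germ = train_grnn(Xs, table.germination)
(clo, chi), (tlo, thi) = surface.bounds
scenario = Scenario(DisinfectantKind.NaOCl, (clo, chi), (tlo, thi),
                    m=float(table.contamination.min()),
                    n=float(table.germination.max()))
res = evolve(cont, germ, scenario, GAConfig(generations=300, seed=0), scaler=scaler)
c_err = abs(res.ideal_concentration - surface.ideal_input[0]) / (chi - clo)
t_err = abs(res.ideal_time - surface.ideal_input[1]) / (thi - tlo)
print(f"recovered optimum: ({res.ideal_concentration:.2f}, {res.ideal_time:.2f})")
print(f"relative error: {100 * c_err:.1f}% of the concentration range, "
      f"{100 * t_err:.1f}% of the time range")
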