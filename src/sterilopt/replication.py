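"""Multi-seed replications of the headline analyses.

These drive the full study conditions — 8 synthetic replicates per
treatment with sd = SE*sqrt(8), min-max scaling, stratified 80/20 row
split, LOO-selected GRNN smoothing, and NSGA-II with population 85,
800 generations, crossover 0.70, mutation 0.01 — and summarize the
outcomes over independent seeds.
"""

from __future__ import annotations

import numpy as np

from .data import (
    DisinfectantKind,
    apply_scaler,
    fit_scaler,
    load_treatment_tables,
    split_train_test,
)
from .evaluation import compare_models
from .models import train_grnn
from .nsga2 import GAConfig, evolve, scenario_for
from .simulate import ReplicateConfig, expand_replicates
from .workflow import train_surrogates

__all__ = [
    "replication_seeds",
    "grnn_test_r2_over_seeds",
    "model_ranking_over_seeds",
    "scenario_ideal_over_seeds",
]


def replication_seeds(base_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds (< 2^31) from one base seed."""
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(base_seed).spawn(n)]


def grnn_test_r2_over_seeds(
    n_seeds: int = 10, base_seed: int = 0, replicates: int = 8, train_fraction: float = 0.8
) -> dict[str, list[float]]:
    """Test-subset R^2 of the GRNN per response, one value per seed."""
    records = load_treatment_tables()
    out: dict[str, list[float]] = {"contamination": [], "germination": []}
    for seed in replication_seeds(base_seed, n_seeds):
        table = expand_replicates(records, ReplicateConfig(replicates, seed))
        train, test = split_train_test(table, train_fraction, seed)
        models, scaler = train_surrogates(train, kinds=("GRNN",), seed=seed)
        report = compare_models(models, train, test, scaler)
        for response in out:
            out[response].append(report.cell("GRNN", response, "test", "R2"))
    return out


def model_ranking_over_seeds(
    n_seeds: int = 10, base_seed: int = 0, replicates: int = 8, train_fraction: float = 0.8
) -> dict:
    """Full three-model comparison per seed: best-model flags and mean
    test R^2 per model kind."""
    records = load_treatment_tables()
    wins: dict[str, int] = {}
    mean_test_r2: dict[str, list[float]] = {}
    grnn_r2: dict[str, list[float]] = {"contamination": [], "germination": []}
    for seed in replication_seeds(base_seed, n_seeds):
        table = expand_replicates(records, ReplicateConfig(replicates, seed))
        train, test = split_train_test(table, train_fraction, seed)
        models, scaler = train_surrogates(train, seed=seed)
        report = compare_models(models, train, test, scaler)
        wins[report.best_model] = wins.get(report.best_model, 0) + 1
        sub = report.table[report.table.subset == "test"]
        for kind, grp in sub.groupby("model"):
            mean_test_r2.setdefault(kind, []).append(float(grp.R2.mean()))
        for response in grnn_r2:
            grnn_r2[response].append(report.cell("GRNN", response, "test", "R2"))
    return {"wins": wins, "mean_test_r2": mean_test_r2, "grnn_test_r2": grnn_r2}


def scenario_ideal_over_seeds(
    disinfectant: str | DisinfectantKind,
    n_seeds: int = 5,
    base_seed: int = 0,
    replicates: int = 8,
    ga: GAConfig | None = None,
) -> list[tuple[float, float]]:
    """Ideal-point (contamination, germination) of the GRNN + NSGA-II run
    for one disinfectant scenario, one pair per seed.

    The GRNN pair is trained on the full expanded dataset each seed.
    """
    kind = DisinfectantKind(disinfectant) if isinstance(disinfectant, str) else disinfectant
    records = load_treatment_tables()
    scenario = scenario_for(kind, records)
    results = []
    for seed in replication_seeds(base_seed, n_seeds):
        table = expand_replicates(records, ReplicateConfig(replicates, seed))
        scaler = fit_scaler(table.X)
        Xs = apply_scaler(scaler, table.X)
        cont = train_grnn(Xs, table.contamination)
        germ = train_grnn(Xs, table.germination)
        cfg = ga if ga is not None else GAConfig()
        cfg = GAConfig(cfg.population, cfg.generations, cfg.crossover_rate,
                       cfg.mutation_rate, cfg.mutation_sd_frac, seed=seed)
        res = evolve(cont, germ, scenario, cfg, scaler=scaler)
        results.append(res.ideal_objectives)
    return results
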