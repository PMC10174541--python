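"""Synthetic replicate expansion and benchmark response surfaces.

Only treatment means and standard errors were published for the
sterilization experiment, so replicate-level data are reconstructed
synthetically: each treatment's replicates are drawn from a normal law
centred on the printed mean with standard deviation SE * sqrt(k)
(k = replicates per treatment, default 8, matching the experiment's
sub-set design), truncated to the feasible [0, 100] percent range.

The module also provides fully synthetic bi-objective benchmark
surfaces with a known optimal input, used for end-to-end
optimum-recovery testing of the surrogate + NSGA-II stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .data import (
    FEATURE_NAMES,
    ObservationTable,
    TreatmentRecord,
    encode_features,
    treatment_label,
)

__all__ = [
    "ReplicateConfig",
    "BenchmarkSurface",
    "expand_replicates",
    "make_benchmark_surface",
    "BENCHMARK_KINDS",
]


@dataclass(frozen=True)
class ReplicateConfig:
    """How printed mean +/- SE rows are expanded into replicates.

    ``replicates_per_treatment`` is the number of synthetic replicates k
    per printed row; the per-replicate noise sd is SE * sqrt(k), i.e. the
    printed value is treated as the standard error of a k-point mean.
    """

    replicates_per_treatment: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_treatment <= 0:
            raise ValueError("replicates_per_treatment must be positive")


def _truncated_normal(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated to [0, 100]; degenerate sd returns the mean."""
    if sd == 0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def expand_replicates(
    records: Sequence[TreatmentRecord], config: ReplicateConfig = ReplicateConfig()
) -> ObservationTable:
    """Expand each treatment record into ``k`` noisy replicate rows.

    Both responses are drawn independently from truncated normals centred
    on the printed means.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    k = config.replicates_per_treatment
    sd_factor = np.sqrt(k)
    X_rows, Y_rows, prov, strata = [], [], [], []
    base_X = encode_features(records)
    for i, r in enumerate(records):
        cont = _truncated_normal(r.contamination_mean, r.contamination_se * sd_factor, k, rng)
        germ = _truncated_normal(r.germination_mean, r.germination_se * sd_factor, k, rng)
        X_rows.append(np.repeat(base_X[i][None, :], k, axis=0))
        Y_rows.append(np.column_stack([cont, germ]))
        prov.extend([treatment_label(r)] * k)
        strata.extend([r.source_table.value] * k)
    return ObservationTable(
        np.vstack(X_rows), np.vstack(Y_rows), np.array(prov, object), np.array(strata, object)
    )


@dataclass(frozen=True)
class BenchmarkSurface:
    """A known bi-objective ground truth over (concentration, time).

    ``contamination`` and ``germination`` map (c, t) arrays to percent
    responses bounded in [0, 100]; ``ideal_input`` is the interior input
    the ideal-point selection should recover; ``bounds`` are the
    ((c_lo, c_hi), (t_lo, t_hi)) search box.
    """

    name: str
    contamination: Callable[[np.ndarray, np.ndarray], np.ndarray]
    germination: Callable[[np.ndarray, np.ndarray], np.ndarray]
    ideal_input: tuple[float, float]
    bounds: tuple[tuple[float, float], tuple[float, float]]
    noise_sd: float


def _surface_sharp() -> BenchmarkSurface:
    # germination: Gaussian bump peaking at (7, 12); contamination: logistic
    # decay in concentration, essentially flat (and near its minimum) by c=7,
    # so the utopia point sits at the germination peak.
    def cont(c, t):
        return 2.0 + 93.0 / (1.0 + np.exp(2.0 * (np.asarray(c, float) - 3.0)))

    def germ(c, t):
        c = np.asarray(c, float)
        t = np.asarray(t, float)
        return 5.0 + 85.0 * np.exp(-((c - 7.0) ** 2 / 8.0 + (t - 12.0) ** 2 / 18.0))

    return BenchmarkSurface("sharp-peak", cont, germ, (7.0, 12.0), ((0.0, 10.0), (5.0, 20.0)), 0.0)


def _surface_broad() -> BenchmarkSurface:
    def cont(c, t):
        c = np.asarray(c, float)
        t = np.asarray(t, float)
        return 1.0 + 90.0 / (1.0 + np.exp(1.2 * (c - 4.0))) + 0.1 * (20.0 - t)

    def germ(c, t):
        c = np.asarray(c, float)
        t = np.asarray(t, float)
        return 8.0 + 80.0 * np.exp(-((c - 8.0) ** 2 / 18.0 + (t - 14.0) ** 2 / 50.0))

    return BenchmarkSurface("broad-peak", cont, germ, (8.0, 14.0), ((0.0, 12.0), (5.0, 25.0)), 0.0)


BENCHMARK_KINDS: dict[str, Callable[[], BenchmarkSurface]] = {
    "sharp-peak": _surface_sharp,
    "broad-peak": _surface_broad,
}


def make_benchmark_surface(
    kind: str = "sharp-peak",
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_shape: tuple[int, int] = (11, 7),
    disinfectant_slot: int = 0,
) -> tuple[ObservationTable, BenchmarkSurface]:
    """Sample a registered benchmark surface on a (concentration, time) grid.

    Returns the noisy sampled observation table (encoded into the 7-slot
    feature layout, with the active concentration in ``disinfectant_slot``)
    and the generating truth.  Deterministic given ``seed``.
    """
    if kind not in BENCHMARK_KINDS:
        raise ValueError(f"unknown benchmark kind {kind!r}; choose from {sorted(BENCHMARK_KINDS)}")
    base = BENCHMARK_KINDS[kind]()
    surface = BenchmarkSurface(
        base.name, base.contamination, base.germination, base.ideal_input, base.bounds, noise_sd
    )
    (c_lo, c_hi), (t_lo, t_hi) = surface.bounds
    cs = np.linspace(c_lo, c_hi, grid_shape[0])
    ts = np.linspace(t_lo, t_hi, grid_shape[1])
    C, T = np.meshgrid(cs, ts, indexing="ij")
    c_flat, t_flat = C.ravel(), T.ravel()
    rng = np.random.default_rng(seed)
    cont = surface.contamination(c_flat, t_flat)
    germ = surface.germination(c_flat, t_flat)
    if noise_sd > 0:
        cont = cont + rng.normal(0.0, noise_sd, cont.shape)
        germ = germ + rng.normal(0.0, noise_sd, germ.shape)
    cont = np.clip(cont, 0.0, 100.0)
    germ = np.clip(germ, 0.0, 100.0)
    X = np.zeros((c_flat.size, len(FEATURE_NAMES)))
    X[:, disinfectant_slot] = c_flat
    X[:, -1] = t_flat
    prov = np.array([f"{kind}@{c:g}x{t:g}" for c, t in zip(c_flat, t_flat)], object)
    strata = np.array([kind] * c_flat.size, object)
    table = ObservationTable(X, np.column_stack([cont, germ]), prov, strata)
    return table, surface
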