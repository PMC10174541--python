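"""NSGA-II over trained surrogates, with ideal-point front selection.

The genetic algorithm is written from scratch: fast non-dominated
sorting, crowding distance, binary tournament selection on (rank,
crowding), two-point crossover, per-gene Gaussian mutation, and
(mu + lambda) elitist environmental selection.  A sterilization
scenario optimizes one disinfectant's concentration and the immersion
time within the experimentally tested bounds, minimizing predicted
contamination while maximizing predicted germination.

From the final non-dominated front a single operating point is reported:
the member minimizing the Euclidean distance
``sqrt((contamination - m)^2 + (germination - n)^2)`` to the utopia
point, where m and n are the minimum observed contamination and the
maximum observed germination of the scenario's data subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .data import DisinfectantKind, ObservationTable, ScalerSpec, TreatmentRecord, apply_scaler

__all__ = [
    "GAConfig",
    "Scenario",
    "ParetoResult",
    "fast_non_dominated_sort",
    "crowding_distance",
    "nsga2",
    "evolve",
    "ideal_point_select",
    "scenario_for",
]


@dataclass(frozen=True)
class GAConfig:
    """NSGA-II settings (defaults follow the sterilization study's run)."""

    population: int = 85
    generations: int = 800
    crossover_rate: float = 0.70
    mutation_rate: float = 0.01
    mutation_sd_frac: float = 0.10  # Gaussian mutation sd as a fraction of the gene range
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.population < 2 or self.generations < 0:
            raise ValueError("population must be >= 2 and generations >= 0")


@dataclass(frozen=True)
class Scenario:
    """One disinfectant's search box plus the observed utopia references.

    Only the disinfectant's concentration slot and the immersion time
    vary; the other five concentration slots are fixed at zero.  ``m``
    and ``n`` are the minimum observed contamination and maximum observed
    germination of this disinfectant's data subset (the utopia point).
    """

    disinfectant: DisinfectantKind
    concentration_bounds: tuple[float, float]
    time_bounds: tuple[float, float]
    m: float
    n: float

    def __post_init__(self) -> None:
        for lo, hi in (self.concentration_bounds, self.time_bounds):
            if lo > hi:
                raise ValueError("scenario bounds are inverted")

    @property
    def gene_bounds(self) -> np.ndarray:
        """(7, 2) box: inactive slots pinned to 0."""
        bounds = np.zeros((7, 2))
        bounds[self.disinfectant.slot] = self.concentration_bounds
        bounds[6] = self.time_bounds
        return bounds

    @property
    def active_mask(self) -> np.ndarray:
        mask = np.zeros(7, dtype=bool)
        mask[self.disinfectant.slot] = True
        mask[6] = True
        return mask


def scenario_for(kind: DisinfectantKind, records: Sequence[TreatmentRecord]) -> Scenario:
    """Build a scenario from a disinfectant's tested ranges and observed extrema."""
    rows = [r for r in records if r.source_table is kind]
    if not rows:
        raise ValueError(f"no records for {kind.value}")
    times = [r.immersion_time for r in rows]
    return Scenario(
        disinfectant=kind,
        concentration_bounds=(0.0, max(r.concentration for r in rows)),
        time_bounds=(min(times), max(times)),
        m=min(r.contamination_mean for r in rows),
        n=max(r.germination_mean for r in rows),
    )


# ---------------------------------------------------------------------------
# core NSGA-II machinery
# ---------------------------------------------------------------------------

def _as_min(objectives: np.ndarray, senses: Sequence[str]) -> np.ndarray:
    F = np.asarray(objectives, dtype=float)
    if F.ndim != 2:
        raise ValueError("objectives must be an n x m array")
    if len(senses) != F.shape[1]:
        raise ValueError("one sense per objective required")
    signs = np.array([1.0 if s == "min" else -1.0 for s in senses])
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite objectives")
    return F * signs


def fast_non_dominated_sort(objectives: np.ndarray, senses: Sequence[str] = ("min", "min")) -> list[np.ndarray]:
    """Partition points into Pareto fronts F1, F2, ... (index arrays)."""
    objectives = np.asarray(objectives, dtype=float)
    if objectives.size == 0:
        return []
    G = _as_min(objectives, senses)
    n = G.shape[0]
    le = np.all(G[:, None, :] <= G[None, :, :], axis=2)
    lt = np.any(G[:, None, :] < G[None, :, :], axis=2)
    dominates = le & lt  # dominates[i, j]: i dominates j
    dom_count = dominates.sum(axis=0)
    fronts: list[np.ndarray] = []
    current = np.flatnonzero(dom_count == 0)
    remaining = dom_count.copy()
    assigned = np.zeros(n, dtype=bool)
    while current.size:
        fronts.append(current)
        assigned[current] = True
        remaining = remaining - dominates[current].sum(axis=0)
        remaining[assigned] = -1
        current = np.flatnonzero(remaining == 0)
    return fronts


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """Crowding distances for one front: boundary points per objective get
    infinity, interior points the sum of normalized neighbour gaps."""
    F = np.asarray(front_objectives, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    n, m = F.shape
    if n == 0:
        raise ValueError("empty front")
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        f = F[order, k]
        span = f[-1] - f[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            gaps = (f[2:] - f[:-2]) / span
            interior = order[1:-1]
            finite = ~np.isinf(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


def _rank_and_crowd(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = fast_non_dominated_sort(G, senses=("min",) * G.shape[1])
    ranks = np.empty(len(G), dtype=int)
    crowd = np.empty(len(G))
    for r, front in enumerate(fronts):
        ranks[front] = r
        crowd[front] = crowding_distance(G[front])
    return ranks, crowd


def _tournament(ranks, crowd, rng) -> int:
    i, j = rng.integers(0, len(ranks), size=2)
    if ranks[i] < ranks[j]:
        return i
    if ranks[j] < ranks[i]:
        return j
    if crowd[i] > crowd[j]:
        return i
    if crowd[j] > crowd[i]:
        return j
    return int(i)


def _two_point_crossover(a: np.ndarray, b: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    d = a.size
    c1, c2 = a.copy(), b.copy()
    lo, hi = sorted(rng.choice(d + 1, size=2, replace=False))
    c1[lo:hi], c2[lo:hi] = b[lo:hi].copy(), a[lo:hi].copy()
    return c1, c2


@dataclass
class NSGA2Result:
    """Raw algorithm output: final population and its Pareto-front subset."""

    population: np.ndarray
    objectives: np.ndarray  # natural scale
    front_idx: np.ndarray
    history: list[float] = field(default_factory=list)

    @property
    def front_X(self) -> np.ndarray:
        return self.population[self.front_idx]

    @property
    def front_F(self) -> np.ndarray:
        return self.objectives[self.front_idx]


def nsga2(
    objective_fn: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    config: GAConfig = GAConfig(),
    senses: Sequence[str] = ("min", "min"),
    active_mask: Optional[np.ndarray] = None,
    track_fn: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
) -> NSGA2Result:
    """Run NSGA-II over a box-bounded decision space.

    ``objective_fn`` maps an (n, d) decision matrix to (n, m) natural-scale
    objectives; ``bounds`` is (d, 2).  Genes outside ``active_mask`` stay
    fixed at their lower bound (used to pin inactive disinfectant slots to
    zero).  ``track_fn`` is recorded per generation (e.g. the running best
    ideal-point distance).  Deterministic given ``config.seed``.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("bounds must be (d, 2) with lo <= hi")
    d = bounds.shape[0]
    mask = np.ones(d, dtype=bool) if active_mask is None else np.asarray(active_mask, bool)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(config.seed)
    pop_n = config.population

    X = lo + rng.uniform(size=(pop_n, d)) * span
    X[:, ~mask] = lo[~mask]
    F = np.atleast_2d(objective_fn(X))
    G = _as_min(F, senses)
    history: list[float] = []

    for _gen in range(config.generations):
        ranks, crowd = _rank_and_crowd(G)
        children = []
        while len(children) < pop_n:
            p1 = X[_tournament(ranks, crowd, rng)]
            p2 = X[_tournament(ranks, crowd, rng)]
            if rng.uniform() < config.crossover_rate:
                c1, c2 = _two_point_crossover(p1, p2, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for c in (c1, c2):
                mut = rng.uniform(size=d) < config.mutation_rate
                if mut.any():
                    c[mut] += rng.normal(0.0, config.mutation_sd_frac, mut.sum()) * span[mut]
                children.append(c)
        C = np.array(children[:pop_n])
        C = np.clip(C, lo, hi)
        C[:, ~mask] = lo[~mask]
        Fc = np.atleast_2d(objective_fn(C))
        Gc = _as_min(Fc, senses)

        # (mu + lambda) elitist truncation by rank, then crowding.  Exact
        # duplicate decision vectors (e.g. un-mutated clones of a parent)
        # are collapsed first — duplicate-blind crowding would otherwise
        # let clones crowd out distinct front members.
        allX = np.vstack([X, C])
        allF = np.vstack([F, Fc])
        allG = np.vstack([G, Gc])
        _, first = np.unique(allX, axis=0, return_index=True)
        uniq = np.sort(first)
        allX, allF, allG = allX[uniq], allF[uniq], allG[uniq]
        fronts = fast_non_dominated_sort(allG, senses=("min",) * allG.shape[1])
        keep: list[int] = []
        for front in fronts:
            if len(keep) + len(front) <= pop_n:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(allG[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(front[order[: pop_n - len(keep)]].tolist())
                break
        while len(keep) < pop_n:  # refill if deduplication left too few
            keep.extend(keep[: pop_n - len(keep)])
        keep_arr = np.asarray(keep)
        X, F, G = allX[keep_arr], allF[keep_arr], allG[keep_arr]
        if track_fn is not None:
            history.append(float(track_fn(X, F)))

    fronts = fast_non_dominated_sort(G, senses=("min",) * G.shape[1])
    front_idx = fronts[0] if fronts else np.array([], dtype=int)
    return NSGA2Result(population=X, objectives=F, front_idx=front_idx, history=history)


# ---------------------------------------------------------------------------
# scenario-level driver
# ---------------------------------------------------------------------------

@dataclass
class ParetoResult:
    """Final front for one disinfectant scenario plus the ideal-point pick."""

    scenario: Scenario
    front_X: np.ndarray  # raw 7-gene inputs
    front_F: np.ndarray  # (contamination %, germination %)
    ideal_x: np.ndarray
    ideal_objectives: tuple[float, float]
    m: float
    n: float
    history: list[float] = field(default_factory=list)

    @property
    def ideal_concentration(self) -> float:
        return float(self.ideal_x[self.scenario.disinfectant.slot])

    @property
    def ideal_time(self) -> float:
        return float(self.ideal_x[6])


def _ideal_distances(F: np.ndarray, m: float, n: float) -> np.ndarray:
    return np.sqrt((F[:, 0] - m) ** 2 + (F[:, 1] - n) ** 2)


def ideal_point_select(front_F: np.ndarray, m: float, n: float) -> int:
    """Index of the front member nearest the utopia point (m, n); ties
    broken by lower contamination."""
    F = np.atleast_2d(np.asarray(front_F, dtype=float))
    if F.size == 0:
        raise ValueError("empty front")
    d = _ideal_distances(F, m, n)
    best = np.flatnonzero(d == d.min())
    if len(best) > 1:
        best = best[np.argsort(F[best, 0], kind="stable")]
    return int(best[0])


def evolve(
    contamination_model,
    germination_model,
    scenario: Scenario,
    config: GAConfig = GAConfig(),
    scaler: Optional[ScalerSpec] = None,
) -> ParetoResult:
    """Run NSGA-II over the surrogate pair for one disinfectant scenario.

    Contamination is minimized and germination maximized; the reported
    solution is the Eq-style ideal-point member of the final front.
    """

    def objective_fn(X_raw: np.ndarray) -> np.ndarray:
        feats = apply_scaler(scaler, X_raw) if scaler is not None else X_raw
        cont = contamination_model.predict(feats)
        germ = germination_model.predict(feats)
        return np.column_stack([cont, germ])

    def track_fn(X: np.ndarray, F: np.ndarray) -> float:
        fronts = fast_non_dominated_sort(F, senses=("min", "max"))
        return float(_ideal_distances(F[fronts[0]], scenario.m, scenario.n).min())

    res = nsga2(
        objective_fn,
        scenario.gene_bounds,
        config=config,
        senses=("min", "max"),
        active_mask=scenario.active_mask,
        track_fn=track_fn,
    )
    front_X, front_F = res.front_X, res.front_F
    idx = ideal_point_select(front_F, scenario.m, scenario.n)
    return ParetoResult(
        scenario=scenario,
        front_X=front_X,
        front_F=front_F,
        ideal_x=front_X[idx],
        ideal_objectives=(float(front_F[idx, 0]), float(front_F[idx, 1])),
        m=scenario.m,
        n=scenario.n,
        history=res.history,
    )
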