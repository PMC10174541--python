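"""Experimental treatment tables and model-ready matrices.

The packaged fixtures hold the published petunia seed-sterilization
experiment: six disinfectants (four chemical sterilants on a percent
scale, two carbon-nanotube materials in mg/L), each tested at several
concentration levels and three immersion times, with mean +/- standard
error of two responses per treatment — contamination rate (%) and seed
germination (%).  This module loads those tables, encodes treatments as
7-dimensional feature vectors (six concentration slots, one per
disinfectant, plus immersion time), min-max scales features, and splits
observation tables into train/test subsets stratified by disinfectant.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DisinfectantKind",
    "TreatmentRecord",
    "ObservationTable",
    "ScalerSpec",
    "load_treatment_tables",
    "records_to_frame",
    "encode_features",
    "observation_table_from_records",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "split_train_test",
    "FEATURE_NAMES",
    "RESPONSE_NAMES",
]


class DisinfectantKind(Enum):
    """The six disinfectants of the sterilization experiment."""

    NaOCl = "NaOCl"
    CaClO2 = "CaClO2"
    HgCl2 = "HgCl2"
    H2O2 = "H2O2"
    NWCNFe = "NWCNFe"
    MWCNT = "MWCNT"

    @property
    def unit(self) -> str:
        """Concentration unit: percent for chemicals, mg/L for nanotubes."""
        return "mg/L" if self in (DisinfectantKind.NWCNFe, DisinfectantKind.MWCNT) else "%"

    @property
    def slot(self) -> int:
        """Column index of this disinfectant in the 7-entry feature vector."""
        return list(DisinfectantKind).index(self)


FEATURE_NAMES = tuple(k.value for k in DisinfectantKind) + ("time_min",)
RESPONSE_NAMES = ("contamination", "germination")

_TABLE_FILES = {
    DisinfectantKind.NaOCl: "naocl.csv",
    DisinfectantKind.CaClO2: "caclo2.csv",
    DisinfectantKind.HgCl2: "hgcl2.csv",
    DisinfectantKind.H2O2: "h2o2.csv",
    DisinfectantKind.NWCNFe: "nwcnfe.csv",
    DisinfectantKind.MWCNT: "mwcnt.csv",
}


@dataclass(frozen=True)
class TreatmentRecord:
    """One printed table row: a treatment and its two mean +/- SE responses.

    ``disinfectant`` is ``None`` for untreated controls (concentration 0);
    ``source_table`` records which disinfectant's table the row came from,
    since each table repeats its own control rows.
    """

    disinfectant: Optional[DisinfectantKind]
    concentration: float
    immersion_time: float
    contamination_mean: float
    contamination_se: float
    germination_mean: float
    germination_se: float
    source_table: DisinfectantKind

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")
        if self.disinfectant is None and self.concentration != 0:
            raise ValueError("control records must have concentration 0")
        for name in ("contamination_mean", "germination_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        for name in ("contamination_se", "germination_se"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class ObservationTable:
    """Replicate-level dataset: features (n x 7), responses (n x 2), provenance.

    Responses are on the raw percent scale (contamination, germination);
    ``provenance`` labels each row with its source treatment.
    """

    X: np.ndarray
    Y: np.ndarray
    provenance: np.ndarray  # string label per row
    strata: np.ndarray  # disinfectant-table label per row, for stratified splits

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=object)
        self.strata = np.asarray(self.strata, dtype=object)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"feature matrix must be n x {len(FEATURE_NAMES)}")
        if self.Y.shape != (self.X.shape[0], 2):
            raise ValueError("response matrix must be n x 2")
        if len(self.provenance) != len(self.X) or len(self.strata) != len(self.X):
            raise ValueError("provenance length mismatch")
        if np.any(self.Y < 0) or np.any(self.Y > 100):
            raise ValueError("responses must lie in [0, 100]")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def contamination(self) -> np.ndarray:
        return self.Y[:, 0]

    @property
    def germination(self) -> np.ndarray:
        return self.Y[:, 1]

    def response(self, name: str) -> np.ndarray:
        return self.Y[:, RESPONSE_NAMES.index(name)]

    def subset(self, idx: np.ndarray) -> "ObservationTable":
        return ObservationTable(self.X[idx], self.Y[idx], self.provenance[idx], self.strata[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df["contamination"] = self.Y[:, 0]
        df["germination"] = self.Y[:, 1]
        df["treatment"] = self.provenance
        df["table"] = self.strata
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservationTable":
        X = df[list(FEATURE_NAMES)].to_numpy(float)
        Y = df[["contamination", "germination"]].to_numpy(float)
        prov = df["treatment"].to_numpy(object) if "treatment" in df else np.array([""] * len(df), object)
        strata = df["table"].to_numpy(object) if "table" in df else prov
        return cls(X, Y, prov, strata)


def _load_one_table(kind: DisinfectantKind, path) -> list[TreatmentRecord]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - corrupt installs only
        raise IOError(f"failed to read treatment table for {kind.value}: {exc}") from exc
    required = {
        "disinfectant", "concentration", "time_min",
        "contamination_mean", "contamination_se", "germination_mean", "germination_se",
    }
    if not required.issubset(df.columns):
        raise IOError(f"treatment table for {kind.value} is missing columns {required - set(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        conc = float(row.concentration)
        records.append(TreatmentRecord(
            disinfectant=None if conc == 0 else kind,
            concentration=conc,
            immersion_time=float(row.time_min),
            contamination_mean=float(row.contamination_mean),
            contamination_se=float(row.contamination_se),
            germination_mean=float(row.germination_mean),
            germination_se=float(row.germination_se),
            source_table=kind,
        ))
    return records


def load_treatment_tables(directory: Optional[Path] = None) -> list[TreatmentRecord]:
    """Load the six packaged treatment tables (90 records, 15 per table).

    ``directory`` may point at user-supplied CSVs with the same file names
    and schema; by default the packaged fixtures are used.
    """
    records: list[TreatmentRecord] = []
    for kind, fname in _TABLE_FILES.items():
        if directory is not None:
            source = Path(directory) / fname
            if not source.exists():
                raise IOError(f"missing treatment table {fname} for {kind.value}")
            records.extend(_load_one_table(kind, source))
        else:
            ref = importlib.resources.files("sterilopt.tables").joinpath(fname)
            if not ref.is_file():
                raise IOError(f"missing packaged treatment table {fname} for {kind.value}")
            with importlib.resources.as_file(ref) as p:
                records.extend(_load_one_table(kind, p))
    return records


def records_to_frame(records: Sequence[TreatmentRecord]) -> pd.DataFrame:
    """Serialize records back to the fixture schema (round-trip safe)."""
    return pd.DataFrame({
        "disinfectant": [r.source_table.value for r in records],
        "concentration": [r.concentration for r in records],
        "time_min": [r.immersion_time for r in records],
        "contamination_mean": [r.contamination_mean for r in records],
        "contamination_se": [r.contamination_se for r in records],
        "germination_mean": [r.germination_mean for r in records],
        "germination_se": [r.germination_se for r in records],
    })


def encode_features(records: Sequence[TreatmentRecord]) -> np.ndarray:
    """Encode records as an n x 7 matrix: one concentration slot per
    disinfectant plus immersion time; controls have all slots zero."""
    X = np.zeros((len(records), len(FEATURE_NAMES)))
    for i, r in enumerate(records):
        if r.disinfectant is not None:
            X[i, r.disinfectant.slot] = r.concentration
        X[i, -1] = r.immersion_time
    if np.any((X[:, :-1] != 0).sum(axis=1) > 1):  # pragma: no cover - guarded by types
        raise ValueError("a record activates more than one disinfectant slot")
    return X


def treatment_label(record: TreatmentRecord) -> str:
    name = record.disinfectant.value if record.disinfectant else "control"
    return f"{record.source_table.value}:{name}@{record.concentration:g}x{record.immersion_time:g}"


def observation_table_from_records(records: Sequence[TreatmentRecord]) -> ObservationTable:
    """One row per record, responses set to the printed means (no replicates)."""
    X = encode_features(records)
    Y = np.column_stack([
        [r.contamination_mean for r in records],
        [r.germination_mean for r in records],
    ])
    prov = np.array([treatment_label(r) for r in records], object)
    strata = np.array([r.source_table.value for r in records], object)
    return ObservationTable(X, Y, prov, strata)


@dataclass(frozen=True)
class ScalerSpec:
    """Per-column min-max affine scaler fitted on training features.

    Non-constant columns map observed min -> 0 and max -> 1; constant
    columns map to 0 by convention (and are not invertible).
    """

    minimum: np.ndarray
    maximum: np.ndarray

    @property
    def span(self) -> np.ndarray:
        return self.maximum - self.minimum


def fit_scaler(X: np.ndarray) -> ScalerSpec:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows to fit a scaler")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    return ScalerSpec(minimum=X.min(axis=0), maximum=X.max(axis=0))


def apply_scaler(spec: ScalerSpec, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    span = spec.span.copy()
    constant = span == 0
    span[constant] = 1.0
    Z = (X - spec.minimum) / span
    Z[:, constant] = 0.0
    return Z


def invert_scaler(spec: ScalerSpec, Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    span = spec.span.copy()
    constant = span == 0
    span[constant] = 1.0
    X = Z * span + spec.minimum
    # constant columns carry no information; restore the training constant
    X[:, constant] = spec.minimum[constant]
    return X


def split_train_test(
    table: ObservationTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[ObservationTable, ObservationTable]:
    """Random row partition, stratified by disinfectant table.

    The train subset holds ``floor(train_fraction * n)`` rows; every
    stratum contributes at least one row to each side.  Reproducible
    given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(table)
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)

    strata = np.asarray(table.strata)
    labels = sorted(set(strata))
    groups = {lab: np.flatnonzero(strata == lab) for lab in labels}
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("every stratum needs at least 2 rows to appear in both subsets")
    if not len(labels) <= n_train <= n - len(labels):
        raise ValueError("train fraction incompatible with stratification at this n")

    # per-stratum proportional allocation: floor, then distribute the
    # remainder by largest fractional part (stable tie-break on label)
    quotas = {lab: train_fraction * len(groups[lab]) for lab in labels}
    base = {lab: min(len(groups[lab]) - 1, max(1, int(np.floor(quotas[lab])))) for lab in labels}
    remainder = n_train - sum(base.values())
    order = sorted(labels, key=lambda lab: (-(quotas[lab] - np.floor(quotas[lab])), lab))
    i = 0
    while remainder != 0 and i < 10 * len(labels):
        lab = order[i % len(labels)]
        if remainder > 0 and base[lab] < len(groups[lab]) - 1:
            base[lab] += 1
            remainder -= 1
        elif remainder < 0 and base[lab] > 1:
            base[lab] -= 1
            remainder += 1
        i += 1
    if remainder != 0:
        raise ValueError("could not satisfy stratified allocation")

    train_idx, test_idx = [], []
    for lab in labels:
        perm = rng.permutation(groups[lab])
        train_idx.extend(perm[: base[lab]])
        test_idx.extend(perm[base[lab]:])
    train_idx = np.sort(np.asarray(train_idx, dtype=int))
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    return table.subset(train_idx), table.subset(test_idx)
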