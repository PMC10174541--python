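"""Model scoring: R^2, RMSE, MBE, and the full model-comparison grid.

Conventions: R^2 uses the observed values about the observed mean in the
denominator; MBE is mean(predicted - observed), so a negative value means
under-prediction.  Both error metrics are on the raw percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data import ObservationTable, RESPONSE_NAMES, ScalerSpec, apply_scaler

__all__ = ["r2", "rmse", "mbe", "MetricsReport", "compare_models", "MODEL_ORDER"]

MODEL_ORDER = ("MLP", "GRNN", "RBF")


def _check(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size == 0 or o.shape != p.shape:
        raise ValueError("observed and predicted must be nonempty and equal length")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(p))):
        raise ValueError("non-finite values in metric inputs")
    return o, p


def r2(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    o, p = _check(observed, predicted)
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values have zero variance")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def rmse(observed, predicted) -> float:
    """Root mean squared error."""
    o, p = _check(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def mbe(observed, predicted) -> float:
    """Mean bias error, predicted - observed."""
    o, p = _check(observed, predicted)
    return float(np.mean(p - o))


@dataclass
class MetricsReport:
    """Per model x response x subset metric grid plus the best-model flag.

    ``best_model`` is the model with the highest test R^2 averaged over
    the two responses.
    """

    table: pd.DataFrame
    best_model: str

    def cell(self, model: str, response: str, subset: str, metric: str) -> float:
        row = self.table[
            (self.table.model == model)
            & (self.table.response == response)
            & (self.table.subset == subset)
        ]
        return float(row[metric].iloc[0])


def compare_models(
    models: Mapping[tuple[str, str], object],
    train: ObservationTable,
    test: ObservationTable,
    scaler: ScalerSpec | None = None,
) -> MetricsReport:
    """Score every (model kind, response) pair on the train and test subsets.

    ``models`` maps (kind, response) -> trained model, with kinds from
    ``MODEL_ORDER`` and responses from ``RESPONSE_NAMES``.  If ``scaler`` is
    given, features are min-max scaled before prediction (models are
    trained on scaled inputs).  All models must have been trained on the
    same split (checked via data fingerprints).
    """
    by_response: dict[str, set] = {}
    for (kind, response), m in models.items():
        by_response.setdefault(response, set()).add(getattr(m, "data_fingerprint", None))
    for response, fps in by_response.items():
        if len(fps) > 1:
            raise ValueError(
                f"models for response {response!r} were trained on different data (split mismatch)"
            )

    kinds = [k for k in MODEL_ORDER if any(key[0] == k for key in models)]
    if not kinds:
        raise ValueError("no trained models supplied")
    rows = []
    for kind in kinds:
        for response in RESPONSE_NAMES:
            if (kind, response) not in models:
                raise ValueError(f"missing trained model for ({kind}, {response})")
            model = models[(kind, response)]
            for subset_name, subset in (("train", train), ("test", test)):
                obs = subset.response(response)
                feats = apply_scaler(scaler, subset.X) if scaler is not None else subset.X
                pred = model.predict(feats)
                rows.append({
                    "model": kind,
                    "response": response,
                    "subset": subset_name,
                    "R2": r2(obs, pred),
                    "RMSE": rmse(obs, pred),
                    "MBE": mbe(obs, pred),
                })
    table = pd.DataFrame(rows)
    test_r2 = (
        table[table.subset == "test"].groupby("model", sort=False)["R2"].mean()
    )
    best = str(test_r2.idxmax())
    return MetricsReport(table=table, best_model=best)
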