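"""Input-importance ranking by leave-one-input-out retraining (VSE / VSR).

For each of the 7 inputs the surrogate is retrained without that column
(same split and seed) and scored on the test subset; the resulting RMSE
is the variable sensitivity error (VSE).  The variable sensitivity ratio
VSR = VSE / RMSE_full compares it with the full model: VSR near 1 marks
an uninformative input, larger values mark more important inputs.
Inputs are ranked by descending VSR (rank 1 = most important), ties
broken by feature order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    FEATURE_NAMES,
    ObservationTable,
    RESPONSE_NAMES,
    apply_scaler,
    fit_scaler,
    split_train_test,
)
from .evaluation import rmse
from .workflow import fit_surrogate

__all__ = ["SensitivityReport", "sensitivity_analysis"]


@dataclass
class SensitivityReport:
    """Per response x input: VSE (percent RMSE), VSR, and integer rank."""

    table: pd.DataFrame
    full_rmse: dict[str, float]

    def rank(self, response: str, feature: str) -> int:
        row = self.table[(self.table.response == response) & (self.table.feature == feature)]
        return int(row["rank"].iloc[0])

    def vsr(self, response: str, feature: str) -> float:
        row = self.table[(self.table.response == response) & (self.table.feature == feature)]
        return float(row["VSR"].iloc[0])


def _fit_and_score(kind: str, train: ObservationTable, test: ObservationTable,
                   cols: np.ndarray, seed: int) -> dict[str, float]:
    """Train one model per response on the given feature columns, test RMSE."""
    scaler = fit_scaler(train.X[:, cols])
    Xtr = apply_scaler(scaler, train.X[:, cols])
    Xte = apply_scaler(scaler, test.X[:, cols])
    out = {}
    for response in RESPONSE_NAMES:
        model = fit_surrogate(kind, Xtr, train.response(response), seed=seed)
        out[response] = rmse(test.response(response), model.predict(Xte))
    return out


def sensitivity_analysis(
    model_kind: str,
    table: ObservationTable,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> SensitivityReport:
    """Rank the 7 inputs of ``table`` by leave-one-input-out VSR.

    The same stratified split and training seed are reused for the full
    model and every reduced model, so VSR differences reflect only the
    removed column.  A retraining failure for some input is recorded as a
    failed row (NaN metrics) rather than silently skipped.
    """
    train, test = split_train_test(table, train_fraction, seed)
    all_cols = np.arange(len(FEATURE_NAMES))
    full = _fit_and_score(model_kind, train, test, all_cols, seed)

    rows = []
    for j, feature in enumerate(FEATURE_NAMES):
        keep = np.delete(all_cols, j)
        try:
            reduced = _fit_and_score(model_kind, train, test, keep, seed)
            for response in RESPONSE_NAMES:
                rows.append({
                    "response": response,
                    "feature": feature,
                    "VSE": reduced[response],
                    "VSR": reduced[response] / full[response],
                    "failed": False,
                })
        except Exception as exc:
            for response in RESPONSE_NAMES:
                rows.append({
                    "response": response,
                    "feature": feature,
                    "VSE": float("nan"),
                    "VSR": float("nan"),
                    "failed": True,
                    "error": str(exc),
                })
    df = pd.DataFrame(rows)

    # descending VSR; ties (and NaNs, ranked last) broken by feature order
    def _rank(group: pd.DataFrame) -> pd.DataFrame:
        g = group.copy()
        keys = [(-v if np.isfinite(v) else np.inf, i) for i, v in enumerate(g["VSR"])]
        order = np.argsort([k[0] for k in keys], kind="stable")
        ranks = np.empty(len(g), dtype=int)
        ranks[order] = np.arange(1, len(g) + 1)
        g["rank"] = ranks
        return g

    df = (
        df.groupby("response", sort=False, group_keys=False)[df.columns]
        .apply(_rank)
        .reset_index(drop=True)
    )
    return SensitivityReport(table=df, full_rmse=full)
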