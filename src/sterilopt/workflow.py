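"""Shared training plumbing: scale features, fit one surrogate per response."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np

from .data import ObservationTable, RESPONSE_NAMES, ScalerSpec, apply_scaler, fit_scaler
from .models import (
    GRNNConfig,
    MLPConfig,
    RBFConfig,
    train_grnn,
    train_mlp,
    train_rbf,
)

__all__ = ["TRAINERS", "default_config", "fit_surrogate", "train_surrogates"]

TRAINERS = {"MLP": train_mlp, "RBF": train_rbf, "GRNN": train_grnn}
_CONFIGS = {"MLP": MLPConfig, "RBF": RBFConfig, "GRNN": GRNNConfig}


def default_config(kind: str, seed: int = 0, n_rows: int | None = None):
    """Default training configuration for a model kind, seeded.

    The RBF center count is capped at the number of available rows when
    ``n_rows`` is given (its nominal hidden layer has 120 centers).
    """
    if kind == "RBF" and n_rows is not None:
        return RBFConfig(n_centers=min(120, n_rows), seed=seed)
    return _CONFIGS[kind](seed=seed)


def fit_surrogate(kind: str, X_scaled: np.ndarray, y: np.ndarray, config=None, seed: int = 0):
    """Train one surrogate of ``kind`` on scaled features."""
    if kind not in TRAINERS:
        raise ValueError(f"unknown model kind {kind!r}")
    if config is None:
        config = default_config(kind, seed=seed, n_rows=len(X_scaled))
    return TRAINERS[kind](X_scaled, y, config)


def train_surrogates(
    train: ObservationTable,
    kinds: Iterable[str] = ("MLP", "GRNN", "RBF"),
    seed: int = 0,
    configs: Optional[Mapping[str, object]] = None,
) -> tuple[dict[tuple[str, str], object], ScalerSpec]:
    """Fit a min-max scaler on the training features and train every
    (kind, response) surrogate on the scaled inputs.

    Returns the model dictionary keyed by (kind, response) and the scaler.
    """
    scaler = fit_scaler(train.X)
    Xs = apply_scaler(scaler, train.X)
    models: dict[tuple[str, str], object] = {}
    for kind in kinds:
        cfg = configs.get(kind) if configs and kind in configs else None
        for response in RESPONSE_NAMES:
            models[(kind, response)] = fit_surrogate(
                kind, Xs, train.response(response), config=cfg, seed=seed
            )
    return models, scaler
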