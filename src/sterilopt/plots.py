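"""Pareto-front plotting."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .nsga2 import ParetoResult


def plot_front(result: ParetoResult, path: str | Path) -> None:
    """Scatter the final front (contamination vs germination) and mark the
    ideal-point selection."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.front_F[:, 0], result.front_F[:, 1], s=14, label="Pareto front")
    ax.scatter(*result.ideal_objectives, color="black", zorder=3, label="ideal point")
    ax.scatter([result.m], [result.n], marker="*", color="tab:red", zorder=3, label="utopia (m, n)")
    ax.set_xlabel("contamination rate (%)")
    ax.set_ylabel("seed germination (%)")
    ax.set_title(f"{result.scenario.disinfectant.value}: NSGA-II front")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
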