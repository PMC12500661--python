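"""Diagnostic plots: weight-sensitivity lines and MC difference histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model_config import ValueTree
from .scoring import PreferenceMatrix
from .sensitivity import perturb_weight
from .aggregation import score_cards
from .uncertainty import MCResult

__all__ = ["plot_weight_sensitivity", "plot_mc_differences"]


def plot_weight_sensitivity(tree: ValueTree, matrix: PreferenceMatrix,
                            out_path: str | Path,
                            targets: Sequence[str] | None = None,
                            deltas: np.ndarray | None = None) -> Path:
    """Total score of each alternative as a function of each target's weight.

    One panel per target; the x axis is the relative perturbation of the
    target's weight, lines are alternatives. Rank robustness shows as
    lines that never cross within the scanned band.
    """
    if targets is None:
        targets = list(tree.ids) + ["benefit", "risk"]
    if deltas is None:
        deltas = np.linspace(-0.5, 0.5, 41)
    ncol = 3
    nrow = -(-len(targets) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False, sharey=True)
    from .sensitivity import SensitivityError
    for ax, target in zip(axes.flat, targets):
        totals = {alt: [] for alt in matrix.alternatives}
        xs = []
        for d in deltas:
            try:
                cards = score_cards(matrix,
                                    perturb_weight(tree, target, float(d)))
            except SensitivityError:
                continue  # delta pushed this target's weight out of range
            xs.append(d * 100)
            for c in cards:
                totals[c.alternative].append(c.total_value)
        for alt, ys in totals.items():
            ax.plot(xs, ys, label=alt)
        ax.set_title(target)
        ax.set_xlabel("weight change (%)")
        ax.set_ylabel("total value")
    for ax in axes.flat[len(targets):]:
        ax.set_visible(False)
    axes.flat[0].legend()
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_mc_differences(result: MCResult, out_path: str | Path) -> Path:
    """Histograms of the benefit, risk and total score differences plus the
    exceedance curve of the total difference."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (name, arr) in zip(
            axes.flat,
            [("benefit difference", result.benefit_diff),
             ("risk difference", result.risk_diff),
             ("total difference", result.total_diff)]):
        ax.hist(arr, bins=60, color="steelblue", edgecolor="none")
        ax.axvline(0.0, color="crimson", lw=1)
        ax.set_title(name)
    ax = axes.flat[3]
    xs = np.sort(result.total_diff)
    ax.plot(xs, 1.0 - np.arange(1, len(xs) + 1) / len(xs))
    ax.axvline(0.0, color="crimson", lw=1)
    ax.set_title(f"P(total diff > x); P(>0) = {result.p_superiority:.2%}")
    ax.set_xlabel("x")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
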