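"""Publication-style figures for screen and panel results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dose import PanelResult
from .screen import ScreenResult

__all__ = ["screen_correlation_plot", "panel_bar_plot"]


def screen_correlation_plot(result: ScreenResult, path: str | Path) -> Path:
    """Fold-space scatter of all strains: inert circle centred at (1, 1),
    the two-fold up/down square, and labelled selective hits."""
    fig, ax = plt.subplots(figsize=(6, 6))
    pts = result.points
    is_hit = result.classes == "selective_hit"
    ax.scatter(
        pts.loc[~is_hit, "ff_fold"], pts.loc[~is_hit, "ren_fold"],
        s=18, c="tab:blue", alpha=0.7, label="strains",
    )
    if is_hit.any():
        ax.scatter(
            pts.loc[is_hit, "ff_fold"], pts.loc[is_hit, "ren_fold"],
            s=40, c="tab:red", label="selective hits",
        )
        for strain, row in pts.loc[is_hit].iterrows():
            ax.annotate(strain, (row["ff_fold"], row["ren_fold"]),
                        textcoords="offset points", xytext=(6, 4), fontsize=8)
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(1 + result.radius * np.cos(theta), 1 + result.radius * np.sin(theta),
            c="grey", lw=1, label=f"inert circle (r={result.radius:.2f})")
    # square marking two-fold change up and down
    ax.plot([0.5, 2, 2, 0.5, 0.5], [0.5, 0.5, 2, 2, 0.5], c="grey", ls="--", lw=0.8)
    ax.axhline(1, c="grey", lw=0.5)
    ax.axvline(1, c="grey", lw=0.5)
    ax.set_xlabel("FF fold change vs wild type")
    ax.set_ylabel("REN fold change vs wild type")
    rho = result.rho
    ax.set_title(f"Screen correlation plot (rho = {rho:.2f})" if rho == rho
                 else "Screen correlation plot")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def panel_bar_plot(result: PanelResult, path: str | Path, per_row: int = 6) -> Path:
    """Grouped FF/REN fold bars per compound across the dose grid."""
    n = len(result.results)
    if n == 0:
        raise ValueError("empty panel result")
    rows = (n + per_row - 1) // per_row
    fig, axes = plt.subplots(rows, per_row, figsize=(2.4 * per_row, 2.2 * rows),
                             squeeze=False, sharey=True)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for ax, r in zip(axes.flat, result.results):
        doses = r.effects.index.to_numpy()
        x = np.arange(len(doses))
        ax.bar(x - 0.2, r.effects["ff_fold"], width=0.4, color="tab:blue", label="FF")
        ax.bar(x + 0.2, r.effects["ren_fold"], width=0.4, color="tab:orange", label="REN")
        ax.axhline(1, c="grey", lw=0.6)
        ax.set_xticks(x)
        ax.set_xticklabels([f"{d:g}" for d in doses], rotation=90, fontsize=6)
        ax.set_title(f"{r.compound_id} [{r.cls}]", fontsize=8)
    axes.flat[0].legend(fontsize=7)
    fig.supylabel("fold vs untreated control")
    fig.supxlabel("dose (M)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
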