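"""Static plots: enrichment curves, score barplots, activation dot matrix."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .gsea import EnrichmentResult, RankedList
from .meta import ActivationMatrix

__all__ = ["plot_enrichment", "plot_score_barplot", "plot_activation_matrix"]


def plot_enrichment(
    result: EnrichmentResult, ranked: RankedList, path: str | Path,
    members: set[str] | None = None,
) -> Path:
    """GSEA-style plot: running-sum curve, member rug, ES marker.

    The x axis is the experiment rank (sorted by decreasing connectivity);
    tick marks show where the set's members fall. ``members`` defaults to
    the leading edge when the full set is not supplied.
    """
    if result.running_sum is None:
        raise ValueError("result carries no running sum; re-run with keep_running_sum")
    running = np.asarray(result.running_sum)
    n = running.size
    positions = ranked.positions_of(
        frozenset(members if members is not None else result.leading_edge)
    )
    fig, (ax, rug) = plt.subplots(
        2, 1, figsize=(6, 4), sharex=True,
        gridspec_kw={"height_ratios": [4, 1], "hspace": 0.05},
    )
    ax.plot(np.arange(1, n + 1), running, color="#2a7e43", lw=1.5)
    ax.axhline(0, color="grey", lw=0.5)
    extremum = int(np.argmax(np.abs(running)))
    ax.plot(extremum + 1, running[extremum], "o", color="#c23b22", ms=5)
    ax.set_ylabel("running enrichment score")
    ax.set_title(
        f"{result.name}   NES={result.nes:.2f}  q={result.qval:.3g}",
        fontsize=10,
    )
    if positions.size:
        rug.vlines(positions + 1, 0, 1, color="black", lw=0.6)
    rug.set_yticks([])
    rug.set_xlabel("experiment rank (by connectivity)")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_score_barplot(
    results: list[EnrichmentResult], path: str | Path, k: int = 10,
    title: str = "",
) -> Path:
    """Horizontal bars of the k most positive and k most negative NES."""
    if not results:
        raise ValueError("no results to plot")
    finite = [r for r in results if np.isfinite(r.nes)]
    finite.sort(key=lambda r: (-r.nes, r.name))
    chosen = finite[:k] + [r for r in finite[-k:] if r not in finite[:k]]
    chosen.sort(key=lambda r: (r.nes, r.name))
    names = [r.name for r in chosen]
    nes = [r.nes for r in chosen]
    colors = ["#c23b22" if v > 0 else "#2b6ca3" for v in nes]
    fig, ax = plt.subplots(figsize=(5, 0.32 * len(chosen) + 1.2))
    ax.barh(np.arange(len(chosen)), nes, color=colors)
    ax.set_yticks(np.arange(len(chosen)), names, fontsize=8)
    ax.axvline(0, color="black", lw=0.7)
    ax.set_xlabel("normalized enrichment score")
    if title:
        ax.set_title(title, fontsize=10)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_activation_matrix(am: ActivationMatrix, path: str | Path) -> Path:
    """Dot matrix: circle area proportional to |activation|, red +, blue -."""
    if not am.drugs:
        raise ValueError("empty activation matrix")
    vals = np.asarray(am.values)
    n_drugs, n_contrasts = vals.shape
    fig, ax = plt.subplots(
        figsize=(0.6 * n_contrasts + 2.5, 0.3 * n_drugs + 1.5)
    )
    for i in range(n_drugs):
        for j in range(n_contrasts):
            v = vals[i, j]
            if v == 0:
                continue
            ax.scatter(
                j, n_drugs - 1 - i, s=250 * abs(v),
                color="#c23b22" if v > 0 else "#2b6ca3",
                alpha=0.85, edgecolors="none",
            )
    ax.set_xticks(range(n_contrasts), am.contrast_names, rotation=45,
                  ha="right", fontsize=8)
    ax.set_yticks(range(n_drugs), list(reversed(am.drugs)), fontsize=8)
    ax.set_xlim(-0.5, n_contrasts - 0.5)
    ax.set_ylim(-0.5, n_drugs - 0.5)
    ax.set_title("relative activation", fontsize=10)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
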