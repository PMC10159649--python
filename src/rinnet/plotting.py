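"""Optional static plots of the ensemble analyses (data files are the contract)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

from .cluster import ClusterAssignment, Dendrogram
from .ensemble import ContactProbabilityMap


def plot_probability_map(cmap: ContactProbabilityMap, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cmap.matrix, vmin=0, vmax=1, cmap="viridis",
                   origin="lower")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    ax.set_title(f"contact probability ({cmap.type_scope})")
    fig.colorbar(im, ax=ax, label="fraction of states")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(dend: Dendrogram, path: str | Path,
                    cutoff: float | None = None) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    _scipy_dendrogram(dend.linkage, ax=ax, color_threshold=cutoff or 0)
    if cutoff is not None:
        ax.axhline(cutoff, ls="--", color="k", lw=0.8)
    ax.set_ylabel("merge height (Å RMSD)")
    ax.set_xlabel("state")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_timeline(assignment: ClusterAssignment, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 1.8))
    ax.imshow([assignment.labels], aspect="auto", cmap="tab20",
              interpolation="nearest")
    ax.set_yticks([])
    ax.set_xlabel("state (time order)")
    ax.set_title(f"cluster assignment (cutoff {assignment.cutoff_used} Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
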