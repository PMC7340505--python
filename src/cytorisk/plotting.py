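"""Plot bundle for a fitted stratification run.

Produces the standard figures: the 2-D embedding colored by cell density,
by cluster and by prognostic direction; Kaplan-Meier curves per prognostic
cluster with censoring ticks; the MEM score heatmap; phenotype-similarity
heatmaps; and the biaxial two-marker gate view.  All functions return the
matplotlib figure and optionally write a PNG.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

DIRECTION_COLORS = {"negative": "#c0392b", "positive": "#2e6da4", "NS": "#b0b0b0"}


def _save(fig, out_dir, name):
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fig.savefig(out / f"{name}.png", dpi=120, bbox_inches="tight")
    return fig


def plot_embedding(results, color: str = "cluster", out_dir=None):
    """Scatter of the first two embedding dimensions.

    ``color``: 'density', 'cluster' or 'direction'.
    """
    coords = results.embedding.coords[:, :2]
    fig, ax = plt.subplots(figsize=(6, 5))
    if color == "density":
        from scipy.stats import gaussian_kde

        idx = np.random.default_rng(0).choice(
            coords.shape[0], size=min(coords.shape[0], 20000), replace=False
        )
        sub = coords[idx]
        dens = gaussian_kde(sub[:: max(1, len(sub) // 2000)].T)(sub.T)
        ax.scatter(sub[:, 0], sub[:, 1], c=dens, s=2, cmap="viridis", lw=0)
    elif color == "cluster":
        labs = results.clusters.labels
        ax.scatter(coords[:, 0], coords[:, 1], c=labs, s=2, cmap="tab20", lw=0)
    elif color == "direction":
        direction = results.survival_table["direction"]
        cell_dir = direction.reindex(results.clusters.labels).to_numpy()
        for d, c in DIRECTION_COLORS.items():
            m = cell_dir == d
            ax.scatter(coords[m, 0], coords[m, 1], c=c, s=2, lw=0, label=d)
        ax.legend(markerscale=6, frameon=False)
    else:
        raise ValueError(f"unknown color mode {color!r}")
    ax.set_xlabel(f"{results.embedding.method} 1")
    ax.set_ylabel(f"{results.embedding.method} 2")
    ax.set_title(f"Embedding colored by {color}")
    return _save(fig, out_dir, f"embedding_{color}")


def plot_km(results, cluster: int, out_dir=None):
    """Kaplan-Meier curves for one cluster's high/low patient split."""
    curves = results.km_curves(cluster)
    row = results.survival_table.loc[int(cluster)]
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, df in curves.items():
        color = "#c0392b" if grp == "high" else "#555555"
        ax.step(df["time"], df["survival"], where="post", label=grp, color=color)
        ct = df.attrs.get("censor_times", [])
        if len(ct):
            s_at = np.interp(ct, df["time"], df["survival"])
            ax.plot(ct, s_at, "|", color=color, ms=8)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_title(
        f"Cluster {cluster}: HR={row['HR']:.2f}, p={row['p']:.3g} ({row['direction']})"
    )
    ax.legend(frameon=False)
    return _save(fig, out_dir, f"km_cluster_{cluster}")


def plot_mem_heatmap(results, out_dir=None):
    """Clusters x markers heatmap of MEM scores on the ±10 scale."""
    mat = pd.DataFrame({c: l.scores for c, l in sorted(results.mem_labels.items())}).T
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * mat.shape[1]), max(3, 0.3 * mat.shape[0])))
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-10, vmax=10, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), [f"c{c}" for c in mat.index], fontsize=7)
    fig.colorbar(im, label="MEM score")
    ax.set_title("Marker enrichment (±10)")
    return _save(fig, out_dir, "mem_heatmap")


def plot_similarity_heatmap(consensus, out_dir=None):
    """Phenotype-similarity (RMSD-derived, 0-100) heatmap."""
    sim = consensus.similarity
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sim.to_numpy(), cmap="magma", vmin=0, vmax=100)
    ax.set_xticks(range(sim.shape[1]), sim.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(sim.shape[0]), sim.index, fontsize=6)
    fig.colorbar(im, label="similarity")
    ax.set_title("MEM phenotype similarity")
    return _save(fig, out_dir, "phenotype_similarity")


def plot_gate(results, gate, out_dir=None):
    """Biaxial view of the two gate markers with the gate rectangles."""
    x = results.pooled.values[:, results.pooled.marker_index(gate.marker_pp)]
    y = results.pooled.values[:, results.pooled.marker_index(gate.marker_np)]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.hexbin(x, y, gridsize=60, cmap="Greys", bins="log")
    ax.axvline(gate.pp_threshold, color="#2e6da4", ls="--", lw=1)
    ax.axhline(gate.np_threshold, color="#c0392b", ls="--", lw=1)
    ax.set_xlabel(gate.marker_pp)
    ax.set_ylabel(gate.marker_np)
    ax.set_title(
        f"NP-like: {gate.marker_np}+ / {gate.marker_pp}-;  PP-like: {gate.marker_pp}+"
    )
    return _save(fig, out_dir, "gate_biaxial")


def run_report_figures(results, out_dir=None):
    """The standard figure bundle for one fitted run."""
    figs = {
        "embedding_cluster": plot_embedding(results, "cluster", out_dir),
        "embedding_direction": plot_embedding(results, "direction", out_dir),
        "mem_heatmap": plot_mem_heatmap(results, out_dir),
    }
    for c in results.prognostic_report.prognostic_clusters():
        figs[f"km_cluster_{c}"] = plot_km(results, c, out_dir)
    plt.close("all")
    return figs
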