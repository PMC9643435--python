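"""Movement-based "directed vs undirected" clustering (DD-clusters).

K-means (k = 2) on the most discriminative long-term movement features,
with the cluster of higher net-displacement centre named "directed" post
hoc, so the naming never depends on k-means initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class DDClusterResult:
    assignments: pd.Series  # per-track "directed"/"undirected"
    centers: np.ndarray  # (2, n_features) in standardized space
    selected_features: list
    composition: pd.DataFrame  # per-phenotype proportions

    def __post_init__(self) -> None:
        sums = self.composition[["undirected", "directed"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


def select_features(coef_report: pd.DataFrame, n: int = 2) -> list[str]:
    """Top-n features by |coefficient| from a coefficient report.

    Ties break by canonical (alphabetical) feature order, which the
    report already encodes.
    """
    if n > len(coef_report):
        raise ValueError(f"n={n} exceeds {len(coef_report)} available features")
    return coef_report["feature"].head(n).tolist()


def kmeans_dd(
    feature_table: pd.DataFrame,
    selected_features: list[str],
    seed: int = 0,
    n_init: int = 10,
) -> DDClusterResult:
    """Two-cluster k-means on standardized selected features.

    The per-phenotype composition table gives (undirected, directed)
    proportions summing to 1.  Requires a ``net_distance`` column to
    orient the cluster naming (higher mean net displacement → directed).
    """
    if len(feature_table) < 2:
        raise ValueError("need at least 2 tracks")
    x = feature_table[selected_features].to_numpy(dtype=float)
    std = x.std(axis=0)
    if np.all(x.std(axis=0) == 0) or np.allclose(x, x[0]):
        raise ValueError("degenerate clustering: all feature vectors identical")
    z = (x - x.mean(axis=0)) / np.where(std == 0, 1, std)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    raw = km.fit_predict(z)
    if "net_distance" in feature_table.columns:
        net = feature_table["net_distance"].to_numpy(dtype=float)
    elif "net_distance" in selected_features:
        net = x[:, selected_features.index("net_distance")]
    else:
        raise ValueError("feature table must contain a net_distance column")
    mean_net = [net[raw == c].mean() for c in (0, 1)]
    directed_cluster = int(np.argmax(mean_net))
    names = np.where(raw == directed_cluster, "directed", "undirected")
    assignments = pd.Series(names, index=feature_table.index, name="dd_cluster")
    composition = composition_table(assignments, feature_table.get("phenotype"))
    return DDClusterResult(
        assignments=assignments,
        centers=km.cluster_centers_,
        selected_features=list(selected_features),
        composition=composition,
    )


def composition_table(assignments: pd.Series, phenotypes: pd.Series | None) -> pd.DataFrame:
    """Per-phenotype (undirected, directed) proportions."""
    if phenotypes is None:
        phenotypes = pd.Series(["all"] * len(assignments), index=assignments.index)
    rows = []
    for ph in sorted(set(phenotypes)):
        sel = assignments[phenotypes == ph]
        if len(sel) == 0:
            warnings.warn(f"phenotype {ph!r} has no tracks; row omitted")
            continue
        undirected = float((sel == "undirected").mean())
        rows.append(
            {
                "phenotype": ph,
                "undirected": undirected,
                "directed": 1.0 - undirected,
                "n_tracks": len(sel),
            }
        )
    return pd.DataFrame(rows)


def composition_report(result: DDClusterResult, out_csv=None, plot_path=None, tracks=None):
    """Composition table export, optionally with a colored-track overlay
    (pale color marks directed tracks)."""
    table = result.composition
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if plot_path is not None and tracks is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for tr, label in zip(tracks, result.assignments):
            color = "#ff9999" if label == "directed" else "#2ca02c"
            alpha = 0.5 if label == "directed" else 0.9
            ax.plot(tr.x, tr.y, color=color, alpha=alpha, linewidth=0.8)
        ax.set_aspect("equal")
        ax.invert_yaxis()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return table
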