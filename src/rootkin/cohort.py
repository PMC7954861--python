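"""Cohort concatenation, line × feature matrices, and clustergrams.

Replicate movies are pooled into one table (track ids namespaced by movie),
per-line feature averages form the line × parameter matrix shown as heat
maps, and z-scored rows feed an agglomerative clustergram of the
experimental lines.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "concatenate_cohort",
    "line_feature_matrix",
    "zscore_matrix",
    "cluster_lines",
    "linkage_to_newick",
]

log = logging.getLogger(__name__)


def concatenate_cohort(movies: dict[str, pd.DataFrame],
                       metadata: dict[str, dict] | None = None) -> pd.DataFrame:
    """Pool per-movie kinematics tables into one cohort table.

    ``movies`` maps movie id → kinematics/track table; ``metadata`` maps
    movie id → {'line': ..., 'treatment': ...}. Track ids are namespaced as
    '<movie>/<track_id>'. Duplicate movie ids are impossible by
    construction of the dict, but schema mismatches are rejected with the
    offending column named.
    """
    if not movies:
        raise ValueError("no movies to concatenate")
    metadata = metadata or {}
    ref_cols = None
    parts = []
    for movie_id, table in movies.items():
        if ref_cols is None:
            ref_cols = set(table.columns)
            ref_name = movie_id
        missing = ref_cols.symmetric_difference(table.columns)
        if missing:
            raise ValueError(
                f"schema mismatch between movies {ref_name!r} and {movie_id!r}: "
                f"columns {sorted(missing)}")
        part = table.copy()
        part.insert(0, "movie_id", movie_id)
        part["track_id"] = [f"{movie_id}/{t}" for t in part["track_id"]]
        meta = metadata.get(movie_id, {})
        part["line"] = meta.get("line", movie_id)
        part["treatment"] = meta.get("treatment", "none")
        parts.append(part)
        log.info("cohort: movie %s contributes %d rows, %d tracks",
                 movie_id, len(part), part["track_id"].nunique())
    return pd.concat(parts, ignore_index=True)


def line_feature_matrix(cohort: pd.DataFrame, parameters: list[str],
                        time_window_h: tuple[float, float] | None = None,
                        weighting: str = "sample", min_samples: int = 10) -> pd.DataFrame:
    """Line × parameter matrix of time-and-cell averages.

    Every cell-frame sample weighs equally by default ('sample'); 'track'
    first averages within tracks. Parameters for which any line has fewer
    than ``min_samples`` finite samples are dropped for all lines.
    """
    df = cohort
    if time_window_h is not None:
        lo, hi = time_window_h
        df = df[(df["t_h"] >= lo) & (df["t_h"] <= hi)]
        if df.empty:
            raise ValueError("empty time window")
    missing = [p for p in parameters if p not in df.columns]
    if missing:
        raise ValueError(f"parameters not in cohort table: {missing}")
    if df["line"].nunique() < 1:
        raise ValueError("no lines in cohort")
    if weighting == "track":
        df = df.groupby(["line", "track_id"])[parameters].mean().reset_index()
    rows = {}
    counts = df.groupby("line")[parameters].count()
    keep_params = [p for p in parameters if counts[p].min() >= min_samples]
    dropped = sorted(set(parameters) - set(keep_params))
    if dropped:
        log.warning("dropping parameters with < %d samples in some line: %s",
                    min_samples, dropped)
    for line, g in df.groupby("line"):
        rows[line] = g[keep_params].mean()
    return pd.DataFrame(rows).T.sort_index()


def zscore_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score over lines; zero-variance columns are dropped."""
    sd = matrix.std(ddof=0)
    zero = sd[sd == 0].index
    if len(zero):
        import warnings

        warnings.warn(f"dropping constant columns before z-scoring: {list(zero)}",
                      stacklevel=2)
    m = matrix.drop(columns=zero)
    return (m - m.mean()) / m.std(ddof=0)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def recurse(node):
        if node.is_leaf():
            return labels[node.id]
        left = recurse(node.get_left())
        right = recurse(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return recurse(tree) + ";"


def cluster_lines(matrix: pd.DataFrame, metric: str = "euclidean",
                  method: str = "average", n_clusters: int | None = None) -> dict:
    """Hierarchical clustergram of lines on a z-scored feature matrix.

    Rows are sorted by label before linkage so that cost ties break
    deterministically by label. Returns the linkage matrix, leaf order,
    cophenetic distances, the Newick form and (optionally) flat cluster
    labels for an ``n_clusters`` cut.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 lines to cluster")
    z = zscore_matrix(matrix).sort_index()
    labels = list(z.index)
    dist = pdist(z.to_numpy(), metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    leaves = hierarchy.leaves_list(Z)
    coph_corr, coph_d = hierarchy.cophenet(Z, dist)
    out = {
        "linkage": Z,
        "labels": labels,
        "leaf_order": [labels[i] for i in leaves],
        "cophenetic": coph_d,
        "cophenetic_correlation": float(coph_corr),
        "newick": linkage_to_newick(Z, labels),
        "zscored": z,
    }
    if n_clusters is not None:
        flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        out["flat_clusters"] = dict(zip(labels, (int(c) for c in flat)))
    return out


def plot_clustergram(result: dict, path=None):
    """Row-dendrogram + z-score heat map for a cluster_lines result."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = result["zscored"].loc[result["leaf_order"]]
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(10, 0.6 * len(z) + 2), width_ratios=[1, 3])
    hierarchy.dendrogram(result["linkage"], labels=result["labels"],
                         orientation="left", ax=ax_d, color_threshold=0)
    im = ax_h.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax_h.set_yticks(range(len(z)), z.index)
    ax_h.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=7)
    fig.colorbar(im, ax=ax_h, label="z-score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
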