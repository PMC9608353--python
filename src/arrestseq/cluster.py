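"""Correlation-distance diameter clustering, Z-scores, and display ordering.

Genes are clustered on their mean-expression profiles over time under a
complete-diameter constraint: every pair of genes in a cluster must have
correlation distance (1 - Pearson r) at most ``max_diameter``. The
construction is a seeded greedy scan with consolidation passes; the diameter
invariant holds unconditionally for every output, while the particular
partition depends on the seed (the procedure is deliberately randomized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def mean_profiles(expr: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Gene x time matrix of expression averaged over replicates per time point."""
    meta = sheet.set_index("sample_id")
    times = sorted(meta.loc[list(expr.columns), "time_h"].unique())
    return pd.DataFrame(
        {t: expr[[c for c in expr.columns if meta.loc[c, "time_h"] == t]]
            .mean(axis=1) for t in times})


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of 1 - Pearson r between gene profiles.

    Raises for genes with zero variance across time (correlation undefined).
    """
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    bad = profiles.index[sd == 0].tolist()
    if bad:
        raise ValueError(f"zero-variance profiles for gene(s): {bad[:10]}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class Clustering:
    """Partition of genes into diameter-constrained clusters."""

    labels: pd.Series          # gene -> cluster id (1-based, by size desc)
    max_diameter: float
    seed: int
    sizes: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.sizes = self.labels.value_counts().sort_index()

    def members(self, cluster_id: int) -> list[str]:
        return self.labels.index[self.labels == cluster_id].tolist()

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.labels.unique())


def _fits(dist: np.ndarray, gene: int, members: list[int], max_d: float) -> bool:
    return bool(np.all(dist[gene, members] <= max_d))


def diameter_cluster(dist: pd.DataFrame, max_diameter: float = 0.2,
                     seed: int = 0, max_passes: int = 100) -> Clustering:
    """Greedy randomized complete-diameter clustering.

    Genes are scanned in a seed-shuffled order; each joins the first existing
    cluster whose *every* member is within ``max_diameter``, else opens a new
    cluster. Consolidation passes then move genes into larger clusters that
    fully accept them until the partition is stable. Cluster ids are assigned
    by decreasing size (1 = largest).
    """
    if not (0.0 < max_diameter < 2.0):
        raise ValueError("max_diameter must lie in (0, 2)")
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    if n == 0:
        raise ValueError("empty distance matrix")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    clusters: list[list[int]] = []
    assignment = np.full(n, -1, dtype=int)
    for g in order:
        for ci, members in enumerate(clusters):
            if _fits(D, g, members, max_diameter):
                members.append(g)
                assignment[g] = ci
                break
        else:
            clusters.append([g])
            assignment[g] = len(clusters) - 1

    # consolidation: move a gene into a strictly-preferable cluster that
    # accepts it entirely; target size >= source size keeps a strictly
    # increasing sum-of-squared-sizes potential, so the loop terminates
    for _ in range(max_passes):
        moved = False
        for g in order:
            src = assignment[g]
            src_size = len(clusters[src])
            best, best_size = -1, src_size - 1
            for ci, members in enumerate(clusters):
                if ci == src or len(members) <= best_size:
                    continue
                if len(members) >= src_size and _fits(D, g, members, max_diameter):
                    best, best_size = ci, len(members)
            if best >= 0:
                clusters[src].remove(g)
                clusters[best].append(g)
                assignment[g] = best
                moved = True
        if not moved:
            break

    clusters = [c for c in clusters if c]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    lab = np.empty(n, dtype=int)
    for cid, members in enumerate(clusters, start=1):
        lab[members] = cid
    labels = pd.Series(lab, index=dist.index)
    return Clustering(labels=labels, max_diameter=max_diameter, seed=seed)


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z-scores across time points (sample sd, n-1 denominator)."""
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    bad = profiles.index[sd == 0].tolist()
    if bad:
        raise ValueError(f"zero-variance profiles for gene(s): {bad[:10]}")
    z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def cluster_centroid_timepoint(mean_z: np.ndarray, literal: bool = False) -> int:
    """Temporal centroid of a cluster-mean Z profile (1-based index).

    The profile is shifted so its minimum is 0. By default the centroid is
    the first time point at which the running sum reaches at least half the
    total (first crossing of half mass). ``literal=True`` selects the last
    time point at which the running sum is still below half the total, an
    alternative reading of the same rule.
    """
    v = np.asarray(mean_z, dtype=float)
    if v.size < 2:
        raise ValueError("profile must have length >= 2")
    shifted = v - v.min()
    total = shifted.sum()
    if total == 0:
        import warnings
        warnings.warn("all-zero shifted profile; centroid defaults to 1")
        return 1
    csum = np.cumsum(shifted)
    if literal:
        below = np.flatnonzero(csum < total / 2.0)
        return int(below[-1]) + 1 if below.size else 1
    return int(np.argmax(csum >= total / 2.0)) + 1


def order_clusters(clustering: Clustering, z: pd.DataFrame,
                   literal_centroid: bool = False) -> tuple[pd.DataFrame, list[str]]:
    """Display order of clusters and genes for the heatmap.

    Clusters sort by (1) time point of peak mean Z, ascending; (2) centroid
    time point, ascending; (3) peak mean Z value -- descending for peaks in
    the first half of the time points, ascending for peaks in the second
    half. Genes within a cluster stay contiguous in their stored order.

    Returns (cluster summary table in display order, flat gene order).
    """
    missing = set(clustering.labels.index) - set(z.index)
    if missing:
        raise ValueError(f"z matrix lacks {len(missing)} clustered genes")
    n_time = z.shape[1]
    half = n_time / 2.0
    rows = []
    for cid in clustering.cluster_ids:
        members = clustering.members(cid)
        mean_z = z.loc[members].mean(axis=0).to_numpy()
        peak_tp = int(np.argmax(mean_z)) + 1
        centroid = cluster_centroid_timepoint(mean_z, literal=literal_centroid)
        peak_val = float(mean_z.max())
        tiebreak = -peak_val if peak_tp <= half else peak_val
        rows.append((cid, len(members), peak_tp, centroid, peak_val, tiebreak))
    summary = pd.DataFrame(rows, columns=["cluster", "size", "peak_timepoint",
                                          "centroid_timepoint", "peak_z",
                                          "_tiebreak"])
    summary = summary.sort_values(
        ["peak_timepoint", "centroid_timepoint", "_tiebreak", "cluster"],
        kind="stable").drop(columns="_tiebreak").reset_index(drop=True)
    summary["order_rank"] = np.arange(1, len(summary) + 1)
    gene_order: list[str] = []
    for cid in summary["cluster"]:
        gene_order.extend(clustering.members(int(cid)))
    return summary, gene_order


def export_heatmap(z: pd.DataFrame, gene_order: list[str], path: str,
                   order_path: str | None = None) -> str:
    """Write a Z-score heatmap image plus the exact row-order TSV.

    The TSV (``<path>.order.tsv`` unless ``order_path`` given) is the
    testable surface; the image is for inspection.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = z.loc[gene_order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5, interpolation="nearest")
    ax.set_xticks(range(z.shape[1]))
    ax.set_xticklabels(z.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("time point")
    ax.set_ylabel(f"{len(gene_order)} genes")
    fig.colorbar(im, ax=ax, label="Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    order_path = order_path or f"{path}.order.tsv"
    pd.DataFrame({"gene_id": gene_order,
                  "row": np.arange(1, len(gene_order) + 1)}).to_csv(
        order_path, sep="\t", index=False)
    return order_path


def validate_diameter(dist: pd.DataFrame, clustering: Clustering) -> float:
    """Maximum within-cluster pairwise distance (must be <= max_diameter)."""
    D = dist.to_numpy()
    pos = {g: i for i, g in enumerate(dist.index)}
    worst = 0.0
    for cid in clustering.cluster_ids:
        idx = [pos[g] for g in clustering.members(cid)]
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            worst = max(worst, float(sub.max()))
    return worst
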