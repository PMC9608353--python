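"""Gene-group enrichment, transcription-dependence classification, KS tests.

Enrichment of a gene group within each cluster uses the exact upper-tail
hypergeometric probability P(X >= k) over a user-defined universe (no normal
approximation). The classification stage intersects pairwise DE results to
split consistently up-regulated genes into transcription-driven and
stability-driven subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tsde import bh_adjust  # noqa: F401  (re-exported convenience)


@dataclass
class GeneSet:
    name: str
    members: list[str]
    note: str = ""

    def __post_init__(self) -> None:
        seen = set()
        unique = []
        for g in self.members:
            if g not in seen:
                seen.add(g)
                unique.append(g)
        self.members = unique

    def __len__(self) -> int:
        return len(self.members)


def filter_to_expressed(group: GeneSet, expressed) -> GeneSet:
    """Restrict a gene set to the expressed universe; error if nothing is left."""
    expressed = set(expressed)
    kept = [g for g in group.members if g in expressed]
    if not kept:
        raise ValueError(f"gene set {group.name!r} has no expressed members")
    return GeneSet(name=group.name, members=kept, note=group.note)


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeom(N population, K marked, n draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(group: GeneSet, clustering, universe) -> pd.DataFrame:
    """Per-cluster over-representation of a gene group.

    ``universe`` is the expressed-gene background; both the group and every
    cluster must be contained in it. Returns one row per cluster with
    N (universe), K (cluster size), n (group size), k (overlap) and the exact
    hypergeometric p.
    """
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    outside = [g for g in group.members if g not in uset]
    if outside:
        raise ValueError(
            f"gene set {group.name!r} has {len(outside)} members outside the "
            f"universe (e.g. {outside[:3]})")
    cluster_genes = set(clustering.labels.index)
    if not cluster_genes <= uset:
        raise ValueError("clustered genes are not contained in the universe")
    N = len(universe)
    n = len(group)
    gset = set(group.members)
    rows = []
    for cid in clustering.cluster_ids:
        members = clustering.members(cid)
        K = len(members)
        k = len(gset.intersection(members))
        rows.append((group.name, cid, N, K, n, k, hypergeom_pvalue(N, K, n, k)))
    return pd.DataFrame(rows, columns=["group", "cluster", "N", "K", "n", "k", "p"])


@dataclass
class ClassifiedSets:
    """Transcription-dependence decomposition of up-regulated genes."""

    transcription_dependent: set[str]
    high_confidence_upregulated: set[str]
    td_upregulated: set[str] = field(init=False)
    ti_upregulated: set[str] = field(init=False)
    fdr: float = 0.05
    overlap_fraction: float = field(init=False, default=float("nan"))
    overlap_p: float = field(init=False, default=float("nan"))

    def __post_init__(self) -> None:
        self.td_upregulated = (self.high_confidence_upregulated
                               & self.transcription_dependent)
        self.ti_upregulated = (self.high_confidence_upregulated
                               - self.transcription_dependent)


def classify_sets(de_soma_auxin_vs_etoh: pd.DataFrame,
                  de_time_by_strain: dict[str, pd.DataFrame],
                  fdr: float = 0.05,
                  required_strains=("soma_TIR1", "germline_TIR1",
                                    "soma_TIR1_AID", "germline_TIR1_AID"),
                  lenient: bool = False) -> ClassifiedSets:
    """Split up-regulated genes by transcription dependence.

    * transcription-dependent: q < fdr and log2FC < 0 in the soma-degron
      auxin-versus-solvent contrast at the late time point;
    * high-confidence up-regulated: positive late-versus-baseline log2FC in
      every strain under solvent, with q < fdr in every strain (default) or
      in at least one strain (``lenient=True``).

    The intersection is the transcription-dependent up-regulated set; the
    difference is the transcription-independent up-regulated set. Also
    reports the overlap fraction and its hypergeometric p over the shared
    gene basis.
    """
    missing = [s for s in required_strains if s not in de_time_by_strain]
    if missing:
        raise ValueError(f"missing per-strain DE tables for: {missing}")
    soma = de_soma_auxin_vs_etoh
    td = set(soma.index[(soma["q"] < fdr) & (soma["log2FC"] < 0)])

    basis = set(soma.index)
    for tab in de_time_by_strain.values():
        basis &= set(tab.index)
    up_all = None
    sig_any = set()
    for strain in required_strains:
        tab = de_time_by_strain[strain]
        up = set(tab.index[tab["log2FC"] > 0])
        sig = set(tab.index[tab["q"] < fdr])
        sig_any |= sig & up
        strain_up = up if lenient else (up & sig)
        up_all = strain_up if up_all is None else (up_all & strain_up)
    high_conf = (up_all & basis) if not lenient else (up_all & sig_any & basis)

    result = ClassifiedSets(transcription_dependent=td & basis,
                            high_confidence_upregulated=high_conf, fdr=fdr)
    if high_conf:
        k = len(result.td_upregulated)
        result.overlap_fraction = k / len(high_conf)
        result.overlap_p = hypergeom_pvalue(len(basis), len(td & basis),
                                            len(high_conf), k)
    return result


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test: (D statistic, p)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def target_profile_summary(group: GeneSet, z: pd.DataFrame,
                           n_boot: int = 1000, ci: float = 0.99,
                           seed: int = 0) -> pd.DataFrame:
    """Mean Z per time point for a gene group with a bootstrap percentile CI.

    Resamples genes with replacement (``n_boot`` times, seeded) and reports
    the ``ci`` percentile interval around the group mean at each time point.
    """
    present = [g for g in group.members if g in z.index]
    if not present:
        raise ValueError(f"gene set {group.name!r} absent from the Z matrix")
    sub = z.loc[present].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = sub.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = sub[idx].mean(axis=1)  # n_boot x time
    lo_q, hi_q = (1 - ci) / 2.0, 1 - (1 - ci) / 2.0
    return pd.DataFrame({
        "timepoint": z.columns,
        "mean_z": sub.mean(axis=0),
        "ci_lo": np.quantile(boot_means, lo_q, axis=0),
        "ci_hi": np.quantile(boot_means, hi_q, axis=0),
        "n_genes": n,
    })
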