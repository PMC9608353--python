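"""Normalization and spike-in-based absolute quantification.

Implements counts-per-million scaling, upper-quartile size factors, a
control-gene SVD factor of unwanted variation, per-sample log-log spike-in
regression, conversion of gene counts to attomoles per microliter and per
worm, and the spike-read-proportion diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import spike_mask


@dataclass
class SpikeFit:
    """Per-sample log10-log10 regression of spike counts on concentration."""

    slope: pd.Series
    intercept: pd.Series
    r_squared: pd.Series
    n_spikes: pd.Series


@dataclass
class UnwantedFactor:
    """Per-sample scores of k unwanted-variation factors (unit norm each)."""

    scores: pd.DataFrame  # samples x k
    k: int
    control_ids: list[str]


def cpm(counts: pd.DataFrame, exclude_spikes: bool = True) -> pd.DataFrame:
    """Counts per million.

    Library size is the column sum over non-spike genes when
    ``exclude_spikes`` is set (the default), so that varying spike-in content
    does not distort gene CPM. Spike rows are still scaled (by the gene-based
    library size) but are not part of the basis.
    """
    mask = spike_mask(counts)
    basis = counts.loc[~mask] if exclude_spikes else counts
    lib = basis.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"all-zero library size for sample(s): {list(zero.index)}")
    return counts.div(lib, axis=1) * 1e6


def log2_mean_centered(cpm_values: pd.DataFrame,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount), centered per gene to mean zero across samples."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logged = np.log2(cpm_values + pseudocount)
    return logged.sub(logged.mean(axis=1), axis=0)


def upper_quartile_factors(counts: pd.DataFrame) -> pd.Series:
    """Upper-quartile size factors, rescaled to geometric mean 1.

    The factor for a sample is the 75th percentile (linear interpolation
    between order statistics) of its nonzero gene counts. Dividing counts by
    the factors equalizes upper quartiles across samples.
    """
    mask = spike_mask(counts)
    genes = counts.loc[~mask]
    uq = {}
    for sample in genes.columns:
        nz = genes[sample].to_numpy()
        nz = nz[nz > 0]
        if nz.size < 4:
            raise ValueError(f"sample {sample!r} has fewer than 4 nonzero genes")
        uq[sample] = float(np.percentile(nz, 75))
    uq = pd.Series(uq)
    return uq / np.exp(np.log(uq).mean())


def unwanted_variation_factor(logcounts: pd.DataFrame, control_ids,
                              k: int = 1) -> UnwantedFactor:
    """Factor(s) of unwanted variation from control genes.

    Centers each control gene's log counts across samples and takes the
    first ``k`` right singular vectors of the centered control submatrix as
    per-sample factor scores. Factors are unit-norm and defined up to sign;
    the sign is fixed so the largest-magnitude score is positive.
    """
    control_ids = [g for g in control_ids if g in logcounts.index]
    n_samples = logcounts.shape[1]
    if k >= n_samples:
        raise ValueError(f"k={k} must be < number of samples ({n_samples})")
    if len(control_ids) < k + 2:
        raise ValueError(f"need at least {k + 2} control genes, got {len(control_ids)}")
    sub = logcounts.loc[control_ids].to_numpy(dtype=float)
    centered = sub - sub.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = vt[:k].T  # samples x k
    for i in range(k):
        if s[i] < 1e-12:  # degenerate direction: no variation to score
            scores[:, i] = 0.0
            continue
        j = np.argmax(np.abs(scores[:, i]))
        if scores[j, i] < 0:
            scores[:, i] = -scores[:, i]
    frame = pd.DataFrame(scores, index=logcounts.columns,
                         columns=[f"W{i + 1}" for i in range(k)])
    return UnwantedFactor(scores=frame, k=k, control_ids=control_ids)


def fit_spike_regression(counts: pd.DataFrame, mix: pd.DataFrame) -> SpikeFit:
    """Per-sample least-squares fit of log10(spike count) on log10(conc).

    Zero-count spikes are excluded (no pseudocount). Requires at least three
    usable spikes per sample.
    """
    spikes = mix.set_index("spike_id")["conc_attomol_per_ul"]
    present = [s for s in spikes.index if s in counts.index]
    if not present:
        raise ValueError("no spike rows found in the count matrix")
    spike_counts = counts.loc[present]
    conc = spikes.loc[present].to_numpy(dtype=float)
    slope, intercept, r2, n_used = {}, {}, {}, {}
    for sample in counts.columns:
        y = spike_counts[sample].to_numpy(dtype=float)
        usable = y > 0
        if usable.sum() < 3:
            raise ValueError(
                f"sample {sample!r} has only {int(usable.sum())} spikes with "
                "nonzero counts (need >= 3)")
        res = stats.linregress(np.log10(conc[usable]), np.log10(y[usable]))
        slope[sample] = res.slope
        intercept[sample] = res.intercept
        r2[sample] = res.rvalue ** 2
        n_used[sample] = int(usable.sum())
    return SpikeFit(slope=pd.Series(slope), intercept=pd.Series(intercept),
                    r_squared=pd.Series(r2), n_spikes=pd.Series(n_used))


def to_attomoles_per_worm(counts: pd.DataFrame, fit: SpikeFit,
                          sheet: pd.DataFrame) -> pd.DataFrame:
    """Convert gene counts to attomoles of transcript per worm.

    Per sample: ``amol/uL = 10**((log10(count) - intercept) / slope)`` for
    positive counts (zero maps to zero), then
    ``amol/worm = amol/uL * spike_volume_ul / worms_per_sample``.
    """
    for col in ("sample_id", "worms_per_sample", "spike_volume_ul"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    meta = sheet.set_index("sample_id")
    mask = spike_mask(counts)
    genes = counts.loc[~mask]
    out = {}
    for sample in genes.columns:
        slope = float(fit.slope[sample])
        if slope == 0:
            raise ValueError(f"zero spike-regression slope for sample {sample!r}")
        y = genes[sample].to_numpy(dtype=float)
        amol_ul = np.zeros_like(y)
        pos = y > 0
        amol_ul[pos] = 10.0 ** ((np.log10(y[pos]) - float(fit.intercept[sample]))
                                / slope)
        vol = float(meta.loc[sample, "spike_volume_ul"])
        worms = float(meta.loc[sample, "worms_per_sample"])
        out[sample] = amol_ul * vol / worms
    return pd.DataFrame(out, index=genes.index)


def spike_read_proportion(counts: pd.DataFrame) -> pd.Series:
    """Per-sample proportion of reads mapping to spike-in rows, in [0, 1]."""
    mask = spike_mask(counts)
    total = counts.sum(axis=0).astype(float)
    spike = counts.loc[mask].sum(axis=0).astype(float)
    prop = (spike / total).where(total > 0, 0.0)
    return prop
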