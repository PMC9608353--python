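"""Synthetic count-data generator with full ground truth.

Generates two dataset shapes that mirror the biology the downstream analysis
assumes:

* a starvation **time series** (12 time points, 4 replicates by default), and
* a **perturbation experiment** with four strains sampled at a 36 h baseline
  and at 132 h under solvent or auxin, where auxin abolishes transcription in
  one tissue compartment of the degron-carrying strains.

Each gene follows linear birth-death dynamics ``da/dt = s(t) - k*a`` with an
archetype-specific transcription-rate profile ``s(t)`` (piecewise exponential
segments) and decay rate ``k = ln2 / halflife``. Germline genes are
transcriptionally silent after hatch but carry long-lived maternal
transcripts, so their *relative* expression rises as the rest of the
transcriptome decays. Total RNA per worm declines deterministically, halving
every 96 h, and the polyadenylated fraction tracks it.

Counts are drawn from a gamma-mixed multinomial at an exact per-library depth,
with spike-in species contributing reads in proportion to amount added and
gene species in proportion to molecules-per-worm times worms-per-sample.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import SPIKE_PREFIX, io

ARCHETYPES = ("early_peak", "monotone_down", "monotone_up_stable", "flat")
COMPARTMENTS = ("soma", "germline", "muscle")

#: default archetype mix
DEFAULT_FRACTIONS: dict[str, float] = {
    "early_peak": 0.30,
    "monotone_down": 0.30,
    "monotone_up_stable": 0.30,
    "flat": 0.10,
}

# --- generator constants (documented defaults; see module docstring) -------
BURST_FACTOR = 8.0          # early transcriptional burst relative to plateau
BURST_END_H = 12.0          # end of the burst phase
DOWN_SHUTOFF_H = 3.0        # when monotone_down genes stop transcribing
FLAT_BASAL_FACTOR = 0.3     # pre-induction basal rate of "flat" genes
FLAT_ONSET_H = 24.0         # induction time of "flat" genes
SOMA_RATE_DECLINE_HALFTIME_H = 120.0  # slow decline of ongoing somatic rates
TOTAL_RNA_HALFTIME_H = 96.0  # total RNA per worm halves every 96 h
RNA0_NG_PER_WORM = 0.005     # total RNA per worm at t=0
RNA_USED_NG = 25.0           # total RNA used per library
SPIKE_VOLUME_UL = 2.0        # spike-in volume added per library
CAPTURE_EFFICIENCY_SD = 0.25  # log-sd of per-sample mRNA capture efficiency
MOLECULES_PER_ATTOMOLE = 602214.0

DEFAULT_TIMEPOINTS_H = (0.0, 2.0, 4.0, 6.0, 12.0, 24.0, 48.0, 72.0,
                        120.0, 192.0, 240.0, 288.0)
AID_STRAINS = ("soma_TIR1", "germline_TIR1", "soma_TIR1_AID", "germline_TIR1_AID")
AID_SHUTDOWN_START_H = 36.0

#: compartments whose transcription is abolished per strain under auxin
_AUXIN_TARGETS: dict[str, tuple[str, ...]] = {
    "soma_TIR1_AID": ("soma", "muscle"),
    "germline_TIR1_AID": ("germline",),
}


class InvalidConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


# ---------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: which (strain, treatment, time) cells, how deep."""

    kind: str  # "timeseries" or "aid"
    timepoints_h: tuple[float, ...]
    n_replicates: int = 4
    strains: tuple[str, ...] = ("N2",)
    library_depth: int = 1_000_000

    def __post_init__(self) -> None:
        if self.kind not in ("timeseries", "aid"):
            raise InvalidConfigError(f"unknown design kind {self.kind!r}")
        if not self.timepoints_h or self.n_replicates < 1 or not self.strains:
            raise InvalidConfigError("empty design")
        if any(t < 0 for t in self.timepoints_h):
            raise InvalidConfigError("negative time point in design")
        if self.library_depth < 1:
            raise InvalidConfigError("library_depth must be positive")


def default_timeseries_design(n_replicates: int = 4,
                              library_depth: int = 1_000_000) -> DesignSpec:
    """12-time-point, 4-replicate starvation time series."""
    return DesignSpec(kind="timeseries", timepoints_h=DEFAULT_TIMEPOINTS_H,
                      n_replicates=n_replicates, library_depth=library_depth)


def default_aid_design(n_replicates: int = 4,
                       library_depth: int = 1_000_000) -> DesignSpec:
    """4 strains x {36 h baseline, 132 h + EtOH, 132 h + auxin} x replicates."""
    return DesignSpec(kind="aid", timepoints_h=(36.0, 132.0),
                      n_replicates=n_replicates, strains=AID_STRAINS,
                      library_depth=library_depth)


def build_sample_table(design: DesignSpec) -> pd.DataFrame:
    """Expand a design into one row per library (no measurements yet)."""
    rows = []
    if design.kind == "timeseries":
        for strain in design.strains:
            for t in design.timepoints_h:
                for rep in range(1, design.n_replicates + 1):
                    rows.append((f"t{t:g}h_r{rep}", strain, "none", t, rep))
    else:
        t0, t1 = min(design.timepoints_h), max(design.timepoints_h)
        conditions = [(t0, "none"), (t1, "ethanol"), (t1, "auxin")]
        for strain in design.strains:
            for t, treat in conditions:
                for rep in range(1, design.n_replicates + 1):
                    rows.append((f"{strain}_{treat}_{t:g}h_r{rep}",
                                 strain, treat, t, rep))
    return pd.DataFrame(rows, columns=["sample_id", "strain", "treatment",
                                       "time_h", "replicate"])


# ---------------------------------------------------------------------------
# gene catalog


def make_gene_catalog(n_genes: int,
                      fractions: Mapping[str, float] | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Draw a gene catalog: archetypes, compartments, kinetic parameters.

    Parameters
    ----------
    n_genes : int
        Number of genes (>= 10).
    fractions : mapping archetype -> proportion, summing to 1
        Archetype mix; defaults to :data:`DEFAULT_FRACTIONS`.
    seed : int
        RNG seed; identical seed+config gives an identical catalog. The first
        draw on ``numpy.random.default_rng(seed)`` is the archetype choice
        (``rng.choice`` over the fraction keys in mapping order).

    Returns
    -------
    pandas.DataFrame
        Columns: gene_id, compartment, archetype, s0, decay_halflife, a0,
        transcription_dependent.
    """
    if n_genes < 10:
        raise InvalidConfigError(f"n_genes must be >= 10, got {n_genes}")
    if fractions is None:
        fractions = DEFAULT_FRACTIONS
    names = list(fractions)
    unknown = set(names) - set(ARCHETYPES)
    if unknown:
        raise InvalidConfigError(f"unknown archetypes: {sorted(unknown)}")
    probs = np.array([fractions[a] for a in names], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise InvalidConfigError(f"archetype fractions sum to {probs.sum()!r}, not 1")

    rng = np.random.default_rng(seed)
    arch = rng.choice(np.array(names), size=n_genes, p=probs)

    # kinetic parameters, drawn per gene in a fixed order
    soma_hl = np.exp(rng.normal(math.log(12.0), 0.10, size=n_genes))
    down_hl = np.exp(rng.normal(math.log(18.0), 0.10, size=n_genes))
    germ_hl = np.exp(rng.normal(math.log(400.0), 0.05, size=n_genes))
    s0_ep = np.exp(rng.normal(math.log(25.0), 0.80, size=n_genes))
    s0_down = np.exp(rng.normal(math.log(60.0), 0.80, size=n_genes))
    s0_flat = np.exp(rng.normal(math.log(30.0), 0.80, size=n_genes))
    a0_germ = np.exp(rng.normal(math.log(350.0), 0.80, size=n_genes))
    germ_vs_muscle = rng.random(n_genes)

    compartment = np.full(n_genes, "soma", dtype=object)
    up = arch == "monotone_up_stable"
    compartment[up & (germ_vs_muscle < 0.8)] = "germline"
    compartment[up & (germ_vs_muscle >= 0.8)] = "muscle"

    halflife = np.where(arch == "monotone_down", down_hl, soma_hl)
    soma_median_hl = float(np.median(halflife[~up])) if (~up).any() else 12.0
    halflife = np.where(up, np.maximum(germ_hl, 5.0 * soma_median_hl), halflife)

    s0 = np.zeros(n_genes)
    s0[arch == "early_peak"] = s0_ep[arch == "early_peak"]
    s0[arch == "monotone_down"] = s0_down[arch == "monotone_down"]
    s0[arch == "flat"] = s0_flat[arch == "flat"]

    k = math.log(2.0) / halflife
    a0 = np.zeros(n_genes)
    a0[arch == "early_peak"] = (0.02 * BURST_FACTOR * s0 / k)[arch == "early_peak"]
    a0[arch == "monotone_down"] = (s0 / k)[arch == "monotone_down"]
    a0[arch == "flat"] = (FLAT_BASAL_FACTOR * s0 / k)[arch == "flat"]
    a0[up] = a0_germ[up]

    # truth label: somatic genes still transcribing beyond the shutdown start
    td = (compartment == "soma") & np.isin(arch, ("early_peak", "flat"))

    catalog = pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
        "compartment": compartment,
        "archetype": arch,
        "s0": s0,
        "decay_halflife": halflife,
        "a0": a0,
        "transcription_dependent": td,
    })
    return catalog


# ---------------------------------------------------------------------------
# abundance dynamics


def _rate_segments(archetype: str, s0: float) -> list[tuple[float, float, float]]:
    """Transcription profile as (start, rate_at_start, decline_rate) segments."""
    lam = math.log(2.0) / SOMA_RATE_DECLINE_HALFTIME_H
    if archetype == "early_peak":
        return [(0.0, BURST_FACTOR * s0, 0.0), (BURST_END_H, s0, lam)]
    if archetype == "monotone_down":
        return [(0.0, s0, 0.0), (DOWN_SHUTOFF_H, 0.0, 0.0)]
    if archetype == "monotone_up_stable":
        return [(0.0, 0.0, 0.0)]
    if archetype == "flat":
        # basal then induced mid-starvation: constant-rate late transcription
        return [(0.0, FLAT_BASAL_FACTOR * s0, 0.0), (FLAT_ONSET_H, s0, 0.0)]
    raise InvalidConfigError(f"unknown archetype {archetype!r}")


def _propagate(a: float, c: float, lam: float, k: float, dt: float) -> float:
    """Exact step of da/dt = c*exp(-lam*(t-t0)) - k*a over dt."""
    if dt == 0.0:
        return a
    ek = math.exp(-k * dt)
    if c == 0.0:
        return a * ek
    if abs(k - lam) < 1e-12:
        return a * ek + c * dt * ek
    return a * ek + c * (math.exp(-lam * dt) - ek) / (k - lam)


def abundance_trajectory(gene, t_grid: Sequence[float],
                         shutdown_time: float | None = None) -> np.ndarray:
    """Molecules per worm over ``t_grid`` for one gene.

    ``gene`` is any mapping with archetype, s0, decay_halflife and a0 (a
    catalog row works). With ``shutdown_time`` set, transcription is zero from
    that time on, so for t > t0 the trajectory is exactly
    ``a(t0) * 2**(-(t - t0)/halflife)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        return np.array([])
    if np.any(t_grid < 0):
        raise ValueError("negative time in t_grid")
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be ascending")
    hl = float(gene["decay_halflife"])
    if hl <= 0:
        raise ValueError("decay_halflife must be > 0")
    k = math.log(2.0) / hl
    segments = _rate_segments(str(gene["archetype"]), float(gene["s0"]))
    if shutdown_time is not None:
        if shutdown_time < 0:
            raise ValueError("negative shutdown_time")
        segments = [(t0, c, lam) for (t0, c, lam) in segments if t0 < shutdown_time]
        segments.append((float(shutdown_time), 0.0, 0.0))

    starts = [s[0] for s in segments]
    out = np.empty(t_grid.size)
    a = float(gene["a0"])
    cur_t = 0.0
    seg_i = 0
    for j, t in enumerate(t_grid):
        while seg_i + 1 < len(segments) and starts[seg_i + 1] <= t:
            nxt = starts[seg_i + 1]
            c0, lam = segments[seg_i][1], segments[seg_i][2]
            c = c0 * math.exp(-lam * (cur_t - starts[seg_i]))
            a = _propagate(a, c, lam, k, nxt - cur_t)
            cur_t = nxt
            seg_i += 1
        c0, lam = segments[seg_i][1], segments[seg_i][2]
        c = c0 * math.exp(-lam * (cur_t - starts[seg_i]))
        a = _propagate(a, c, lam, k, t - cur_t)
        cur_t = t
        out[j] = max(a, 0.0)
    return out


def _shutdown_for(strain: str, treatment: str) -> tuple[float | None, tuple[str, ...]]:
    """(shutdown time, affected compartments) for a sample's condition."""
    if treatment == "auxin" and strain in _AUXIN_TARGETS:
        return AID_SHUTDOWN_START_H, _AUXIN_TARGETS[strain]
    return None, ()


def total_rna_ng_per_worm(t_h: float) -> float:
    """Deterministic total-RNA decline: halves every 96 h."""
    return RNA0_NG_PER_WORM * 0.5 ** (t_h / TOTAL_RNA_HALFTIME_H)


# ---------------------------------------------------------------------------
# spike-in mix


def make_default_spike_mix(n_species: int = 92, total_conc: float = 470.0,
                           span_orders: float = 4.0,
                           volume_ul: float = SPIKE_VOLUME_UL) -> pd.DataFrame:
    """Geometric concentration ladder of spike-in species (attomoles/uL)."""
    if n_species < 2:
        raise InvalidConfigError("need at least 2 spike species")
    r = 10.0 ** (span_orders / (n_species - 1))
    base = total_conc * (r - 1.0) / (r ** n_species - 1.0)
    conc = base * r ** np.arange(n_species)
    return pd.DataFrame({
        "spike_id": [f"{SPIKE_PREFIX}{i:05d}" for i in range(1, n_species + 1)],
        "conc_attomol_per_ul": conc,
        "volume_ul": volume_ul,
    })


# ---------------------------------------------------------------------------
# truth assembly and count sampling


@dataclass
class SimTruth:
    """Ground truth: gene catalog, per-sample scalars, abundance matrix."""

    genes: pd.DataFrame
    samples: pd.DataFrame          # per-sample metadata + per-worm truth
    abundance: pd.DataFrame        # genes x samples, molecules per worm


def build_truth(catalog: pd.DataFrame, design: DesignSpec) -> SimTruth:
    """Evaluate gene dynamics for every library in the design."""
    sheet = build_sample_table(design)
    n_samples = len(sheet)
    if n_samples == 0:
        raise InvalidConfigError("empty design")

    # evaluate each distinct (time, condition) once
    cache: dict[tuple, np.ndarray] = {}
    abund = np.empty((len(catalog), n_samples))
    for j, row in sheet.iterrows():
        shutdown, targets = _shutdown_for(row["strain"], row["treatment"])
        key = (row["time_h"], shutdown, targets)
        if key not in cache:
            col = np.empty(len(catalog))
            for i, gene in enumerate(catalog.itertuples()):
                sd = shutdown if gene.compartment in targets else None
                col[i] = abundance_trajectory(
                    {"archetype": gene.archetype, "s0": gene.s0,
                     "decay_halflife": gene.decay_halflife, "a0": gene.a0},
                    [row["time_h"]], shutdown_time=sd)[0]
            cache[key] = col
        abund[:, j] = cache[key]

    rna_per_worm = sheet["time_h"].map(total_rna_ng_per_worm).to_numpy()
    worms = np.round(RNA_USED_NG / rna_per_worm).astype(int)
    mrna_per_worm = abund.sum(axis=0)

    samples = sheet.copy()
    samples["worms_per_sample"] = worms
    samples["spike_volume_ul"] = SPIKE_VOLUME_UL
    samples["total_rna_ng"] = RNA_USED_NG
    samples["total_rna_ng_per_worm"] = rna_per_worm
    samples["mrna_molecules_per_worm"] = mrna_per_worm
    samples["mrna_total_rna_ratio"] = mrna_per_worm / rna_per_worm

    abundance = pd.DataFrame(abund, index=catalog["gene_id"].to_numpy(),
                             columns=samples["sample_id"].to_numpy())
    abundance.index.name = "gene_id"
    return SimTruth(genes=catalog, samples=samples, abundance=abundance)


def expected_shares(truth: SimTruth, mix: pd.DataFrame) -> pd.DataFrame:
    """Noise-free expected read share per species (genes then spikes)."""
    worms = truth.samples["worms_per_sample"].to_numpy(dtype=float)
    gene_w = truth.abundance.to_numpy() * worms[None, :]
    spike_amt = (mix["conc_attomol_per_ul"] * mix["volume_ul"]
                 * MOLECULES_PER_ATTOMOLE).to_numpy()
    spike_w = np.tile(spike_amt[:, None], (1, len(truth.samples)))
    w = np.vstack([gene_w, spike_w])
    shares = w / w.sum(axis=0, keepdims=True)
    index = np.concatenate([truth.abundance.index.to_numpy(),
                            mix["spike_id"].to_numpy()])
    return pd.DataFrame(shares, index=index, columns=truth.abundance.columns)


def expected_counts(truth: SimTruth, mix: pd.DataFrame,
                    design: DesignSpec) -> pd.DataFrame:
    """Real-valued expected counts at the design's library depth."""
    return expected_shares(truth, mix) * design.library_depth


def sample_counts(truth: SimTruth, design: DesignSpec, mix: pd.DataFrame,
                  overdispersion: float = 0.05,
                  seed: int = 0,
                  capture_sd: float = CAPTURE_EFFICIENCY_SD) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a gamma-mixed multinomial count matrix at exact library depth.

    Each library's counts sum to ``design.library_depth`` exactly. With
    ``overdispersion`` zero the draw is plain multinomial on the expected
    shares; otherwise each species' weight is multiplied by an independent
    Gamma(1/od, od) factor (mean 1, variance od), giving a marginal count
    distribution close to negative binomial.

    ``capture_sd`` injects the single unwanted factor the analysis is meant
    to remove: a per-sample lognormal mRNA capture efficiency that scales
    every gene's weight relative to the spike-ins (spike amounts are pipetted
    independently of capture). Set to 0 for noise-free composition.
    """
    if overdispersion < 0:
        raise InvalidConfigError("overdispersion must be >= 0")
    if capture_sd < 0:
        raise InvalidConfigError("capture_sd must be >= 0")
    shares = expected_shares(truth, mix).to_numpy()
    n_genes = truth.abundance.shape[0]
    n_species, n_samples = shares.shape
    rng = np.random.default_rng(seed)
    counts = np.empty((n_species, n_samples), dtype=np.int64)
    for j in range(n_samples):
        w = shares[:, j].copy()
        if capture_sd > 0:
            w[:n_genes] *= rng.lognormal(0.0, capture_sd)
        if overdispersion > 0:
            w *= rng.gamma(1.0 / overdispersion, overdispersion, size=n_species)
        counts[:, j] = rng.multinomial(design.library_depth, w / w.sum())
    index = np.concatenate([truth.abundance.index.to_numpy(),
                            mix["spike_id"].to_numpy()])
    counts_df = pd.DataFrame(counts, index=index,
                             columns=truth.abundance.columns)
    counts_df.index.name = "gene_id"
    sheet_cols = ["sample_id", "strain", "treatment", "time_h", "replicate",
                  "worms_per_sample", "spike_volume_ul", "total_rna_ng"]
    return counts_df, truth.samples[sheet_cols].copy()


# ---------------------------------------------------------------------------
# convenience wrappers and on-disk dataset


@dataclass
class SimDataset:
    counts: pd.DataFrame
    samples: pd.DataFrame
    spikes: pd.DataFrame
    truth: SimTruth


def simulate_timeseries(n_genes: int = 2000,
                        fractions: Mapping[str, float] | None = None,
                        design: DesignSpec | None = None,
                        mix: pd.DataFrame | None = None,
                        overdispersion: float = 0.05,
                        seed: int = 0) -> SimDataset:
    """Default starvation time-series dataset (counts + truth)."""
    design = design or default_timeseries_design()
    mix = mix if mix is not None else make_default_spike_mix()
    catalog = make_gene_catalog(n_genes, fractions, seed=seed)
    truth = build_truth(catalog, design)
    counts, sheet = sample_counts(truth, design, mix, overdispersion, seed=seed + 1)
    return SimDataset(counts=counts, samples=sheet, spikes=mix, truth=truth)


def simulate_aid(n_genes: int = 2000,
                 fractions: Mapping[str, float] | None = None,
                 design: DesignSpec | None = None,
                 mix: pd.DataFrame | None = None,
                 overdispersion: float = 0.05,
                 seed: int = 0) -> SimDataset:
    """Default 4-strain perturbation dataset (counts + truth)."""
    design = design or default_aid_design()
    mix = mix if mix is not None else make_default_spike_mix()
    catalog = make_gene_catalog(n_genes, fractions, seed=seed)
    truth = build_truth(catalog, design)
    counts, sheet = sample_counts(truth, design, mix, overdispersion, seed=seed + 1)
    return SimDataset(counts=counts, samples=sheet, spikes=mix, truth=truth)


def compartment_gene_sets(catalog: pd.DataFrame) -> dict[str, list[str]]:
    """One gene set per compartment (true tissue annotation)."""
    return {c: catalog.loc[catalog["compartment"] == c, "gene_id"].tolist()
            for c in COMPARTMENTS
            if (catalog["compartment"] == c).any()}


def write_dataset(dataset: SimDataset, directory: str | os.PathLike) -> None:
    """Write counts, sample sheet, spike table, truth tables and a GMT file."""
    directory = str(directory)
    try:
        os.makedirs(directory, exist_ok=True)
        io.write_counts(dataset.counts, os.path.join(directory, "counts.tsv"))
        io.write_sample_sheet(dataset.samples, os.path.join(directory, "samples.tsv"))
        io.write_spikes(dataset.spikes, os.path.join(directory, "spikes.tsv"))
        dataset.truth.genes.to_csv(os.path.join(directory, "truth_genes.tsv"),
                                   sep="\t", index=False)
        dataset.truth.samples.to_csv(os.path.join(directory, "truth_samples.tsv"),
                                     sep="\t", index=False)
        dataset.truth.abundance.to_csv(
            os.path.join(directory, "truth_abundance.tsv"),
            sep="\t", index_label="gene_id")
        io.write_gmt(compartment_gene_sets(dataset.truth.genes),
                     os.path.join(directory, "genesets.gmt"))
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc


def read_dataset(directory: str | os.PathLike) -> SimDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    directory = str(directory)
    counts = io.read_counts(os.path.join(directory, "counts.tsv"))
    samples = io.read_sample_sheet(os.path.join(directory, "samples.tsv"))
    spikes = io.read_spikes(os.path.join(directory, "spikes.tsv"))
    genes = pd.read_csv(os.path.join(directory, "truth_genes.tsv"), sep="\t")
    truth_samples = pd.read_csv(os.path.join(directory, "truth_samples.tsv"), sep="\t")
    abundance = pd.read_csv(os.path.join(directory, "truth_abundance.tsv"),
                            sep="\t", index_col=0)
    truth = SimTruth(genes=genes, samples=truth_samples, abundance=abundance)
    return SimDataset(counts=counts, samples=samples, spikes=spikes, truth=truth)
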