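"""End-to-end workflows with configuration, logging and provenance.

Two workflows are wired here: the starvation time series
(filter -> CPM -> log2-center -> PCA + rate-of-change -> time-course LRT ->
BH -> cluster -> order -> enrich) and the perturbation experiment
(count filter -> upper-quartile + spike-based unwanted factor -> pairwise
LRTs -> classification -> spike regression -> absolute quantification ->
spike-read-proportion). Every stage output is written as TSV and registered
in a manifest with a content hash; the configuration is serialized verbatim
into the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cluster as clustermod
from . import genesets, io, normquant, tsde

log = logging.getLogger("arrestseq")


@dataclass
class RunConfig:
    """Paths and stage parameters for one workflow run."""

    counts: str = "counts.tsv"
    samples: str = "samples.tsv"
    spikes: str = "spikes.tsv"
    gene_sets: str | None = None
    workflow: str = "timeseries"

    filter_threshold: float = 1.0     # CPM > 1 (timeseries) / counts > 10 (aid)
    filter_min_libs: int = 4
    filter_mode: str = "cpm"
    fdr: float = 0.05
    sig_cutoff: float = 1e-30         # clustering input cutoff on q
    max_diameter: float = 0.2
    cluster_seed: int = 1
    pseudocount: float = 1.0
    ruv_k: int = 1
    enrich_alpha: float = 0.01
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Output directory with a manifest and a run log."""

    def __init__(self, outdir: str, config: RunConfig, inputs: dict[str, str]):
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.manifest: dict[str, dict] = {"inputs": {}, "outputs": {}}
        for name, path in inputs.items():
            self.manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}
        config.to_yaml(os.path.join(outdir, "config.yaml"))
        handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
        self._handler = handler

    def write_table(self, name: str, table: pd.DataFrame, index: bool = True,
                    index_label: str | None = "gene_id") -> str:
        path = os.path.join(self.outdir, name)
        if index:
            table.to_csv(path, sep="\t", index_label=index_label)
        else:
            table.to_csv(path, sep="\t", index=False)
        self.register(name)
        return path

    def register(self, name: str) -> None:
        path = os.path.join(self.outdir, name)
        self.manifest["outputs"][name] = {"sha256": _sha256(path)}

    def finish(self) -> None:
        path = os.path.join(self.outdir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        log.removeHandler(self._handler)
        self._handler.close()


def _stage(name: str):
    log.info("stage: %s", name)


def run_timeseries(config: RunConfig, outdir: str) -> str:
    """Execute the time-series workflow; returns the output directory."""
    counts = io.read_counts(config.counts)
    sheet = io.read_sample_sheet(config.samples)
    inputs = {"counts": config.counts, "samples": config.samples}
    run = _Run(outdir, config, inputs)
    try:
        _stage("filter")
        expressed = tsde.filter_expressed(counts, config.filter_threshold,
                                          config.filter_min_libs,
                                          mode=config.filter_mode)
        log.info("filter: %d of %d genes kept", len(expressed), len(counts))
        genes = counts.loc[expressed]

        _stage("normalize")
        cpm = normquant.cpm(counts, exclude_spikes=True).loc[expressed]
        centered = normquant.log2_mean_centered(cpm, config.pseudocount)
        run.write_table("cpm.tsv", cpm)

        _stage("pca")
        scores, var_frac = tsde.pca_scores(centered)
        scores["variance_fraction"] = np.nan
        scores.iloc[:len(var_frac),
                    scores.columns.get_loc("variance_fraction")] = var_frac
        run.write_table("pca_scores.tsv", scores, index_label="sample_id")

        _stage("rate_of_change")
        rates = tsde.rate_of_change(centered, sheet)
        run.write_table("rate_of_change.tsv", rates, index=False)

        _stage("differential_expression")
        meta = sheet.set_index("sample_id")
        groups = meta.loc[list(genes.columns), "time_h"].to_numpy()
        de = tsde.lrt_timecourse(genes, groups)
        n_sig = int((de["q"] < config.fdr).sum())
        log.info("timecourse LRT: %d genes with q < %g", n_sig, config.fdr)
        run.write_table("de_timecourse.tsv", de)

        _stage("cluster")
        sig_genes = de.index[de["q"] < config.sig_cutoff].tolist()
        profiles = clustermod.mean_profiles(cpm, sheet).loc[sig_genes]
        profiles = profiles[profiles.std(axis=1) > 0]
        log.info("clustering input: %d genes at q < %g", len(profiles),
                 config.sig_cutoff)
        dist = clustermod.correlation_distance(profiles)
        clustering = clustermod.diameter_cluster(dist, config.max_diameter,
                                                 seed=config.cluster_seed)
        log.info("clusters: %d", len(clustering.cluster_ids))
        z = clustermod.zscore_profiles(profiles)
        summary, gene_order = clustermod.order_clusters(clustering, z)
        rank = {cid: r for cid, r in zip(summary["cluster"],
                                         summary["order_rank"])}
        out = pd.DataFrame({
            "gene_id": clustering.labels.index,
            "cluster": clustering.labels.to_numpy(),
        })
        out["order_rank"] = out["cluster"].map(rank)
        run.write_table("clusters.tsv", out, index=False)
        run.write_table("cluster_summary.tsv", summary, index=False)
        clustermod.export_heatmap(
            z, gene_order, os.path.join(run.outdir, "heatmap.png"),
            os.path.join(run.outdir, "heatmap_order.tsv"))
        run.register("heatmap_order.tsv")

        if config.gene_sets:
            _stage("enrichment")
            run.manifest["inputs"]["gene_sets"] = {
                "path": config.gene_sets, "sha256": _sha256(config.gene_sets)}
            groups_gmt = io.read_gmt(config.gene_sets)
            tables = []
            for name, members in groups_gmt.items():
                gs = genesets.GeneSet(name, members)
                try:
                    gs = genesets.filter_to_expressed(gs, expressed)
                except ValueError:
                    log.warning("gene set %s empty after filtering; skipped", name)
                    continue
                gs = genesets.GeneSet(
                    gs.name, [g for g in gs.members if g in profiles.index])
                if not gs.members:
                    continue
                tables.append(genesets.hypergeom_enrichment(
                    gs, clustering, list(profiles.index)))
            if tables:
                run.write_table("enrichment.tsv", pd.concat(tables),
                                index=False)
        run.finish()
        return run.outdir
    except Exception as exc:
        log.error("workflow failed: %s", exc)
        raise


def run_aid(config: RunConfig, outdir: str) -> str:
    """Execute the perturbation workflow; returns the output directory."""
    counts = io.read_counts(config.counts)
    sheet = io.read_sample_sheet(config.samples)
    spikes = io.read_spikes(config.spikes)
    for col in ("strain", "treatment"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    inputs = {"counts": config.counts, "samples": config.samples,
              "spikes": config.spikes}
    run = _Run(outdir, config, inputs)
    try:
        _stage("filter")
        mode = config.filter_mode if config.filter_mode else "count"
        expressed = tsde.filter_expressed(counts, config.filter_threshold,
                                          config.filter_min_libs, mode=mode)
        log.info("filter: %d of %d genes kept", len(expressed), len(counts))
        spike_ids = [s for s in spikes["spike_id"] if s in counts.index]
        genes = counts.loc[expressed]

        _stage("normalize")
        uq = normquant.upper_quartile_factors(counts)
        logcounts = np.log2(counts.loc[expressed + spike_ids] + 1.0)
        ruv = normquant.unwanted_variation_factor(logcounts, spike_ids,
                                                  k=config.ruv_k)
        run.write_table("unwanted_factors.tsv", ruv.scores,
                        index_label="sample_id")

        meta = sheet.set_index("sample_id")
        t_late = float(meta["time_h"].max())
        t_base = float(meta["time_h"].min())

        def samples_for(strain, treatment, time_h):
            sel = meta[(meta["strain"] == strain)
                       & (meta["treatment"] == treatment)
                       & (meta["time_h"] == time_h)]
            return [s for s in sel.index if s in genes.columns]

        _stage("pairwise_de")
        strains = list(dict.fromkeys(sheet["strain"]))
        de_auxin: dict[str, pd.DataFrame] = {}
        de_time: dict[str, pd.DataFrame] = {}
        counts_summary = []
        for strain in strains:
            etoh = samples_for(strain, "ethanol", t_late)
            auxin = samples_for(strain, "auxin", t_late)
            base = samples_for(strain, "none", t_base)
            de_auxin[strain] = tsde.lrt_pairwise(
                genes, etoh, auxin, covariates=ruv, size_factors=uq)
            de_time[strain] = tsde.lrt_pairwise(
                genes, base, etoh, covariates=ruv, size_factors=uq)
            n_aux = int((de_auxin[strain]["q"] < config.fdr).sum())
            n_time = int((de_time[strain]["q"] < config.fdr).sum())
            log.info("%s: auxin-vs-EtOH %d DE, %gh-EtOH-vs-%gh %d DE",
                     strain, n_aux, t_late, t_base, n_time)
            counts_summary.append((strain, n_aux, n_time))
            run.write_table(f"de_auxin_vs_etoh_{strain}.tsv", de_auxin[strain])
            run.write_table(f"de_time_{strain}.tsv", de_time[strain])
        run.write_table("de_counts.tsv", pd.DataFrame(
            counts_summary,
            columns=["strain", "n_de_auxin_vs_etoh", "n_de_time"]),
            index=False)

        _stage("classify")
        soma_key = next((s for s in strains if s == "soma_TIR1_AID"), None)
        if soma_key is None:
            raise ValueError("design lacks a soma_TIR1_AID strain")
        classified = genesets.classify_sets(de_auxin[soma_key], de_time,
                                            fdr=config.fdr,
                                            required_strains=tuple(strains))
        io.write_gmt({
            "transcription_dependent": sorted(classified.transcription_dependent),
            "high_confidence_upregulated":
                sorted(classified.high_confidence_upregulated),
            "td_upregulated": sorted(classified.td_upregulated),
            "ti_upregulated": sorted(classified.ti_upregulated),
        }, os.path.join(run.outdir, "classified_sets.gmt"))
        run.register("classified_sets.gmt")
        log.info("classified: %d td, %d high-conf up, overlap %.1f%% (p=%.3g)",
                 len(classified.transcription_dependent),
                 len(classified.high_confidence_upregulated),
                 100 * classified.overlap_fraction, classified.overlap_p)

        _stage("absolute_quantification")
        fit = normquant.fit_spike_regression(counts, spikes)
        run.write_table("spike_fit.tsv", pd.DataFrame({
            "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "n_spikes": fit.n_spikes}),
            index_label="sample_id")
        amol = normquant.to_attomoles_per_worm(counts.loc[expressed + spike_ids],
                                               fit, sheet)
        io.write_matrix(amol, os.path.join(run.outdir, "attomol_per_worm.tsv"),
                        unit="attomol_per_worm")
        run.register("attomol_per_worm.tsv")

        _stage("spike_read_proportion")
        prop = normquant.spike_read_proportion(counts)
        run.write_table("spike_read_proportion.tsv",
                        prop.rename("spike_read_proportion").to_frame(),
                        index_label="sample_id")
        run.finish()
        return run.outdir
    except Exception as exc:
        log.error("workflow failed: %s", exc)
        raise


def plot_gene(gene_id: str, expr: pd.DataFrame, sheet: pd.DataFrame,
              path: str) -> str:
    """Write a per-gene expression-vs-time figure plus its numeric TSV."""
    if gene_id not in expr.index:
        raise KeyError(f"unknown gene id {gene_id!r}")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = sheet.set_index("sample_id")
    times = meta.loc[list(expr.columns), "time_h"]
    table = pd.DataFrame({"time_h": times.to_numpy(),
                          "value": expr.loc[gene_id].to_numpy()},
                         index=expr.columns)
    mean = table.groupby("time_h")["value"].mean()

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(table["time_h"], table["value"], "o", alpha=0.5, label="replicates")
    ax.plot(mean.index, mean.to_numpy(), "-", color="black", label="mean")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("expression")
    ax.set_title(gene_id)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    tsv = f"{path}.tsv"
    mean.rename("mean_value").to_frame().to_csv(tsv, sep="\t",
                                                index_label="time_h")
    return tsv
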