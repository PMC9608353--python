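# arrestseq

Analysis toolkit for starvation-arrest transcriptome time courses, with a
matched synthetic data generator. The package covers the computational core
of a whole-organism starvation study: time-course differential expression on
RNA-seq counts, correlation-diameter clustering of temporal profiles,
hypergeometric gene-group enrichment, spike-in-based absolute quantification
(attomoles of transcript per worm), and the set-logic that separates
transcription-driven from transcript-stability-driven expression changes.

## Modules

| module | what it does |
|---|---|
| `arrestseq.synthgen` | simulates a 12-time-point starvation time series and a 4-strain degron perturbation experiment (36 h baseline; 132 h with solvent or auxin), with birth–death gene dynamics, 92 spike-in species, declining total RNA per worm, and full ground truth |
| `arrestseq.normquant` | CPM, log2 mean-centered CPM, upper-quartile size factors, control-gene SVD unwanted-variation factor, per-sample log–log spike regression, attomoles per µL → per worm, spike-read-proportion diagnostic |
| `arrestseq.tsde` | expression filters (CPM or count mode), negative-binomial GLM + likelihood-ratio tests (time-course and pairwise), BH FDR, PCA, rate-of-change between adjacent time points |
| `arrestseq.cluster` | 1 − Pearson correlation distances, seeded greedy complete-diameter clustering, Z-scores, cluster centroid/peak ordering, heatmap export |
| `arrestseq.genesets` | GMT gene groups, exact hypergeometric cluster enrichment, transcription-dependence classification, KS comparisons, bootstrap profile summaries |
| `arrestseq.pipeline` | the two end-to-end workflows with YAML config, per-stage logging, and a hash manifest |

## CLI

```bash
# generate a synthetic dataset with ground truth
arrestseq simulate --kind timeseries --n-genes 2000 --seed 1 --out data/ts
arrestseq simulate --kind aid --n-genes 2000 --seed 1 --out data/aid

# individual stages
arrestseq normalize --counts data/ts/counts.tsv --log --out norm/
arrestseq de --counts data/ts/counts.tsv --samples data/ts/samples.tsv \
    --mode timecourse --filter cpm:1:4 --out de.tsv
arrestseq cluster --counts data/ts/counts.tsv --samples data/ts/samples.tsv \
    --de-table de.tsv --sig-cutoff 1e-30 --max-diameter 0.2 --seed 1 --out clus/
arrestseq enrich --clusters clus/clusters.tsv --gene-sets data/ts/genesets.gmt \
    --alpha 0.01 --out enrichment.tsv
arrestseq absquant --counts data/aid/counts.tsv --samples data/aid/samples.tsv \
    --spikes data/aid/spikes.tsv --out aq/

# full workflows from one YAML config
arrestseq run-timeseries --config cfg.yaml --out run_ts/
arrestseq run-aid --config cfg.yaml --out run_aid/
```

A minimal config for `run-aid`:

```yaml
counts: data/aid/counts.tsv
samples: data/aid/samples.tsv
spikes: data/aid/spikes.tsv
workflow: aid
filter_threshold: 10
filter_mode: count
fdr: 0.05
```

## File formats

All interchange is TSV. Count matrices have a `gene_id` first column and one
column per sample; spike-in rows use an `ERCC-` id prefix. The sample sheet
records strain, treatment, time (h), replicate, worms per sample, spike-in
volume (µL) and total RNA (ng). Spike concentrations are attomoles/µL. Gene
groups use standard GMT. Normalized matrices carry a `#unit:` header line.

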