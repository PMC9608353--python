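"""arrestseq: analysis toolkit for starvation-arrest transcriptome time courses.

Subpackages/modules:

- :mod:`arrestseq.synthgen` -- synthetic count-data generator with ground truth
- :mod:`arrestseq.normquant` -- normalization and spike-in absolute quantification
- :mod:`arrestseq.tsde` -- filtering, NB-GLM differential expression, PCA, rates
- :mod:`arrestseq.cluster` -- correlation-diameter clustering and ordering
- :mod:`arrestseq.genesets` -- hypergeometric enrichment and set classification
- :mod:`arrestseq.pipeline` -- end-to-end workflows and provenance
"""

__version__ = "0.1.0"

SPIKE_PREFIX = "ERCC-"


def is_spike(gene_id: str) -> bool:
    """True if a row id denotes a spike-in species."""
    return str(gene_id).startswith(SPIKE_PREFIX)
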