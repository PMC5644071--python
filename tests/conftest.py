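"""Shared fixtures: a hand-built human mini-genome and the session-scoped
synthetic comparative dataset plus its full pipeline run."""

from __future__ import annotations

import pytest

from syntelinc.core import (
    GeneModel,
    GenomeBundle,
    GenomicInterval,
    LincRNA,
    RepeatFeature,
)
from syntelinc.pipeline import PipelineParams, run_analysis
from syntelinc.simulate import SimConfig, build_dataset


def make_gene(gene_id, chrom, exon_spans, biotype="protein_coding",
              strand="+", subtype=None):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_spans]
    span = GenomicInterval(chrom, exon_spans[0][0], exon_spans[-1][1], strand)
    return GeneModel(gene_id=gene_id, biotype=biotype, span=span, exons=exons,
                     pseudogene_subtype=subtype)


@pytest.fixture
def mini_human():
    """A 100 kb hand-built human chromosome with known gene layout.

    chr1: coding gene A at [10000, 14000) with exons [10000,11000) and
    [13000,14000); lncRNA gene B at [30000, 31000); pseudogene P at
    [60000, 61000); coding gene C at [80000, 84000) exons [80000,81000),
    [83000,84000); one LINE at [20000,20500) and one simple repeat at
    [21000,21200).
    """
    seq = "ACGT" * 25000
    genes = [
        make_gene("A", "chr1", [(10000, 11000), (13000, 14000)]),
        make_gene("B", "chr1", [(30000, 31000)], biotype="lincRNA"),
        make_gene("P", "chr1", [(60000, 61000)], biotype="pseudogene",
                  subtype="unitary"),
        make_gene("C", "chr1", [(80000, 81000), (83000, 84000)]),
    ]
    repeats = [
        RepeatFeature(GenomicInterval("chr1", 20000, 20500, "+"),
                      "LINE/L1", "L1sim"),
        RepeatFeature(GenomicInterval("chr1", 21000, 21200, "+"),
                      "Simple_repeat", "(CA)n"),
    ]
    return GenomeBundle("human", {"chr1": seq}, genes, repeats)


def make_linc(linc_id, chrom, start, end, strand="+", cdna=None):
    if cdna is None:
        cdna = ("ACGT" * ((end - start) // 4 + 51))[: max(end - start, 201)]
    return LincRNA(linc_id=linc_id,
                   span=GenomicInterval(chrom, start, end, strand), cdna=cdna)


@pytest.fixture(scope="session")
def sim_config():
    """The scaled-down verification conditions: 3 target species at 5%
    divergence, five lincRNAs per scenario."""
    return SimConfig(rng_seed=2017)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    return build_dataset(sim_config)


@pytest.fixture(scope="session")
def pipeline_result(sim_data, sim_config):
    params = PipelineParams(window_bp=sim_config.window_bp,
                            juxtaposition_bp=sim_config.juxtaposition_bp)
    return run_analysis(sim_data.human, sim_data.species, sim_data.lincs,
                        sim_data.orthology, sim_data.cerna, params,
                        rng_seed=2017)
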