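"""Genomic-context classification and coverage profiling of putative orthologs.

A putative ortholog region is classified by the annotation it overlaps
(strand-blind, >=1 bp), with protein-coding taking precedence:

* ``protein_coding`` - overlaps at least one protein-coding gene span;
* ``non_coding``     - otherwise overlaps a non-coding gene (lncRNA or
  short non-coding RNA);
* ``intergenic``     - overlaps neither.

Pseudogene-biotype annotations trigger neither class: they are consumed
only by the pseudogene/paralog analysis on the human side, which keeps
the three classes mutually exclusive.

The exon/intron/intergenic coverage of a region is the fraction of its
length falling in each stratum of the overlapping protein-coding genes
(exon union across genes; intronic = within a coding gene span but not
exonic).  A region is *exonic* iff exon coverage is exactly 100%, and
*intronic* iff intron coverage is exactly 100%; everything else is
*mixed*.  Coverage is computed in integer bp and divided once, so the
three fractions sum to 1 exactly in bp arithmetic.

TE coverage is the fraction covered by transposable-element repeat
annotations (Simple_repeat / Low_complexity / Satellite excluded); a
region counts as TE-derived only when strictly more than ``min_te_bp``
(default 10) bp are TE-covered.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GenomeBundle, GenomicInterval, intersect_bp, merge_intervals

NONCODING_BIOTYPES = ("lincRNA", "other_noncoding")


@dataclass
class CoverageProfile:
    """Exon/intron/intergenic and TE coverage of one putative ortholog."""

    exon_bp: int
    intron_bp: int
    intergenic_bp: int
    te_bp: int
    length: int
    te_derived: bool

    def __post_init__(self) -> None:
        if self.exon_bp + self.intron_bp + self.intergenic_bp != self.length:
            raise ValueError("coverage strata must partition the region")

    @property
    def exon_cov(self) -> float:
        return self.exon_bp / self.length

    @property
    def intron_cov(self) -> float:
        return self.intron_bp / self.length

    @property
    def intergenic_cov(self) -> float:
        return self.intergenic_bp / self.length

    @property
    def te_cov(self) -> float:
        return self.te_bp / self.length

    @property
    def structural_label(self) -> str:
        if self.exon_bp == self.length:
            return "exonic"
        if self.intron_bp == self.length:
            return "intronic"
        return "mixed"


def classify_ortholog(region: GenomicInterval, bundle: GenomeBundle) -> str:
    """Class of a putative ortholog region: protein_coding > non_coding >
    intergenic, by >=1 bp strand-blind span overlap."""
    if bundle.genes_overlapping(region, biotype="protein_coding"):
        return "protein_coding"
    for bt in NONCODING_BIOTYPES:
        if bundle.genes_overlapping(region, biotype=bt):
            return "non_coding"
    return "intergenic"


def coverage_profile(region: GenomicInterval, bundle: GenomeBundle,
                     min_te_bp: int = 10) -> CoverageProfile:
    """Exon/intron/intergenic + TE coverage of a region, in integer bp."""
    coding = bundle.genes_overlapping(region, biotype="protein_coding")
    exon_ivs = [ex for g in coding for ex in g.exons]
    span_ivs = [g.span for g in coding]
    exon_bp = intersect_bp(region, exon_ivs)
    genic_bp = intersect_bp(region, span_ivs)
    intron_bp = genic_bp - exon_bp
    intergenic_bp = len(region) - genic_bp
    te_bp, te_derived = te_coverage_bp(region, bundle, min_te_bp)
    return CoverageProfile(
        exon_bp=exon_bp, intron_bp=intron_bp, intergenic_bp=intergenic_bp,
        te_bp=te_bp, length=len(region), te_derived=te_derived,
    )


def te_coverage_bp(region: GenomicInterval, bundle: GenomeBundle,
                   min_te_bp: int = 10) -> tuple[int, bool]:
    """(TE-covered bp, TE-derived flag) for a region.

    TE-derived requires strictly more than ``min_te_bp`` covered bp.
    """
    te_ivs = [r.span for r in bundle.repeats_overlapping(region) if r.is_te]
    te_bp = intersect_bp(region, te_ivs)
    return te_bp, te_bp > min_te_bp


def te_coverage(region: GenomicInterval, bundle: GenomeBundle,
                min_te_bp: int = 10) -> tuple[float, bool]:
    """(TE coverage fraction, TE-derived flag) for a region."""
    te_bp, te_derived = te_coverage_bp(region, bundle, min_te_bp)
    return te_bp / len(region), te_derived
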