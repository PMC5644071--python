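"""Pseudogenization-origin analysis of lincRNAs with exonic orthologs.

For a lincRNA whose selected putative orthologs are exonic in other
species, the protein-coding genes those regions fall in (*aligned
proteins*) hint at a pseudogenized ancestor.  Two scenarios are typed:

* *unitary* pseudogenization - the coding gene was lost in place in
  human: the aligned proteins have no human ortholog, and the lincRNA
  overlaps or sits next to an annotated human pseudogene;
* *duplicated* pseudogenization - a disabled duplicate: the aligned
  proteins do have a human ortholog (*putative paralog* of the lincRNA)
  that still aligns to the lincRNA at the stringent E-value cutoff.

Only lincRNAs whose exonic orthologs carry no transposable-element
signal are eligible; everything else is left unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .align import KAParams, ScoringScheme, ka_params, local_align
from .core import GenomeBundle, GenomicInterval, LincRNA, OrthologyMap
from .synteny import PutativeOrtholog

log = logging.getLogger(__name__)

DEFAULT_JUXTAPOSITION_BP = 10_000


@dataclass
class OriginCall:
    """Pseudogenization-origin assessment for one lincRNA."""

    linc_id: str
    aligned_proteins: list[tuple[str, str]] = field(default_factory=list)
    human_paralogs: list[str] = field(default_factory=list)
    pseudogene_relation: str = "none"  # overlap / juxtaposed / none
    nearest_pseudogene: Optional[tuple[str, int]] = None
    hypothesis: str = "unclassified"   # unitary_candidate / duplicated_candidate

    def __post_init__(self) -> None:
        if self.pseudogene_relation == "overlap" and self.nearest_pseudogene:
            assert self.nearest_pseudogene[1] == 0


def aligned_proteins(orthologs: dict[str, PutativeOrtholog],
                     bundles: dict[str, GenomeBundle]
                     ) -> list[tuple[str, str]]:
    """Every protein-coding gene overlapped by a protein-coding-classified
    putative ortholog, as (species, gene_id) pairs."""
    out: list[tuple[str, str]] = []
    for sp, po in sorted(orthologs.items()):
        if po.ortholog_class != "protein_coding":
            continue
        bundle = bundles[sp]
        for g in bundle.genes_overlapping(po.region, biotype="protein_coding"):
            out.append((sp, g.gene_id))
    return out


def aligned_protein_orthology_check(proteins: list[tuple[str, str]],
                                    orth: OrthologyMap) -> bool:
    """True iff at least one cross-species pair of aligned proteins is
    connected in the orthology map; False with fewer than 2 species."""
    if len({sp for sp, _ in proteins}) < 2:
        return False
    for i, (sa, ga) in enumerate(proteins):
        for sb, gb in proteins[i + 1:]:
            if sa != sb and orth.are_orthologous(sa, ga, sb, gb):
                return True
    return False


def spliced_sequence(bundle: GenomeBundle, gene_id: str) -> str:
    """Spliced exonic sequence of a gene (forward-strand exon union)."""
    gene = bundle.genes_by_id[gene_id]
    return "".join(bundle.fetch(ex) for ex in gene.exons)


def putative_paralogs(
    linc: LincRNA,
    proteins: list[tuple[str, str]],
    orth: OrthologyMap,
    human: GenomeBundle,
    scheme: ScoringScheme = ScoringScheme(),
    *,
    evalue_cutoff: float = 1e-10,
    human_species: str = "human",
    ka: Optional[KAParams] = None,
) -> list[str]:
    """Human orthologs of the aligned proteins that still align to the
    lincRNA cDNA below the E-value cutoff (spliced vs spliced)."""
    if ka is None:
        ka = ka_params(scheme)
    cand_genes: set[str] = set()
    for sp, gid in proteins:
        for osp, og in orth.orthologs(sp, gid, in_species=human_species):
            if og in human.genes_by_id:
                cand_genes.add(og)
    out = []
    for gid in sorted(cand_genes):
        subject = spliced_sequence(human, gid)
        hits = local_align(linc.cdna, subject, scheme,
                           query_id=linc.linc_id, ka=ka)
        if hits and hits[0].evalue < evalue_cutoff:
            out.append(gid)
    return out


def pseudogene_relation(
    linc: LincRNA,
    human: GenomeBundle,
    juxtaposition_bp: int = DEFAULT_JUXTAPOSITION_BP,
) -> tuple[str, Optional[tuple[str, int]]]:
    """Relation of a lincRNA to annotated human pseudogenes.

    ``overlap`` on >=1 bp shared with a pseudogene span; else
    ``juxtaposed`` when the nearest pseudogene boundary is within
    ``juxtaposition_bp`` (inclusive); else ``none``.  Returns the nearest
    pseudogene (id, distance) when one exists on the chromosome.
    """
    nearest: Optional[tuple[str, int]] = None
    for g in human.genes:
        if g.biotype != "pseudogene" or g.span.chrom != linc.span.chrom:
            continue
        dist = linc.span.distance(g.span)
        if nearest is None or dist < nearest[1] or (
            dist == nearest[1] and g.gene_id < nearest[0]
        ):
            nearest = (g.gene_id, dist)
    if nearest is None:
        return "none", None
    if nearest[1] == 0:
        return "overlap", nearest
    if nearest[1] <= juxtaposition_bp:
        return "juxtaposed", nearest
    return "none", nearest


def origin_hypothesis(
    human_paralogs: list[str],
    relation: str,
    *,
    eligible: bool = True,
    linc_id: str = "",
) -> str:
    """Type the pseudogenization scenario of an eligible lincRNA.

    ``unitary_candidate``: no human paralog and an overlapping or
    juxtaposed human pseudogene.  ``duplicated_candidate``: at least one
    human paralog.  Everything else (and any ineligible call) is
    ``unclassified``.
    """
    if not eligible:
        log.warning("origin_hypothesis: %s is not eligible (needs an exonic, "
                    "TE-free ortholog); returning unclassified", linc_id)
        return "unclassified"
    if human_paralogs:
        return "duplicated_candidate"
    if relation in ("overlap", "juxtaposed"):
        return "unitary_candidate"
    return "unclassified"


def call_origin(
    linc: LincRNA,
    orthologs: dict[str, PutativeOrtholog],
    bundles: dict[str, GenomeBundle],
    orth: OrthologyMap,
    human: GenomeBundle,
    scheme: ScoringScheme = ScoringScheme(),
    *,
    evalue_cutoff: float = 1e-10,
    juxtaposition_bp: int = DEFAULT_JUXTAPOSITION_BP,
    human_species: str = "human",
    ka: Optional[KAParams] = None,
) -> OriginCall:
    """Full origin assessment for one lincRNA given its selected orthologs.

    Eligibility (exonic ortholog in some species, no TE-derived signal in
    any exonic ortholog) gates the hypothesis; aligned proteins and the
    pseudogene relation are reported regardless.
    """
    exonic = [po for po in orthologs.values()
              if po.coverage is not None
              and po.coverage.structural_label == "exonic"]
    eligible = bool(exonic) and not any(po.coverage.te_derived for po in exonic)
    proteins = aligned_proteins(orthologs, bundles)
    paralogs = putative_paralogs(linc, proteins, orth, human, scheme,
                                 evalue_cutoff=evalue_cutoff,
                                 human_species=human_species, ka=ka)
    relation, nearest = pseudogene_relation(linc, human, juxtaposition_bp)
    hyp = origin_hypothesis(paralogs, relation) if eligible else "unclassified"
    return OriginCall(
        linc_id=linc.linc_id,
        aligned_proteins=proteins,
        human_paralogs=paralogs,
        pseudogene_relation=relation,
        nearest_pseudogene=nearest,
        hypothesis=hyp,
    )
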