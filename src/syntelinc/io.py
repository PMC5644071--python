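"""Readers and writers for the standard formats the pipeline touches.

External conventions are converted at this boundary only: GFF3 and
RepeatMasker ``.out`` are 1-based inclusive, BED is 0-based half-open;
internally everything is 0-based half-open (see :mod:`syntelinc.core`).

lincRNA pre-filtering (drop lincRNAs overlapping protein-coding genes)
also lives here because it is the first thing done to freshly loaded
annotation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BIOTYPES,
    CeRNAPairTable,
    GeneModel,
    GenomeBundle,
    GenomicInterval,
    LincRNA,
    OrthologyMap,
    RepeatFeature,
)

log = logging.getLogger(__name__)

_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "lincRNA": "lincRNA",
    "lncRNA": "lincRNA",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "unitary_pseudogene": "pseudogene",
    "miRNA": "other_noncoding",
    "snoRNA": "other_noncoding",
    "snRNA": "other_noncoding",
    "rRNA": "other_noncoding",
    "misc_RNA": "other_noncoding",
    "other_noncoding": "other_noncoding",
}

_PSEUDO_SUBTYPES = {"processed", "duplicated", "unitary", "unknown"}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 genes


def _normalize_biotype(raw: str, gene_id: str) -> str:
    if raw in _BIOTYPE_ALIASES:
        return _BIOTYPE_ALIASES[raw]
    log.warning("gene %s: unparseable biotype %r mapped to other_noncoding",
                gene_id, raw)
    return "other_noncoding"


def read_genes_gff3(path) -> list[GeneModel]:
    """Parse gene models (gene + exon features) from GFF3.

    Genes carry ``biotype`` (and optionally ``pseudogene_subtype``)
    attributes; exon features point at their gene via ``Parent``.
    Isoforms, if present, are collapsed to the per-gene exon union.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.id
        raw_bt = (feat.attributes.get("biotype") or ["other_noncoding"])[0]
        biotype = _normalize_biotype(raw_bt, gene_id)
        subtype = (feat.attributes.get("pseudogene_subtype") or [None])[0]
        if subtype is not None and subtype not in _PSEUDO_SUBTYPES:
            subtype = "unknown"
        span = GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                               feat.strand or ".")
        exons = []
        for child in db.children(feat, featuretype="exon"):
            if child.seqid != feat.seqid:
                raise ValueError(
                    f"gene {gene_id}: exon on {child.seqid} but gene on "
                    f"{feat.seqid}"
                )
            exons.append(GenomicInterval(child.seqid, child.start - 1,
                                         child.end, child.strand or "."))
        if not exons:
            exons = [span]
        genes.append(GeneModel(gene_id=gene_id, biotype=biotype, span=span,
                               exons=exons, pseudogene_subtype=subtype))
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return genes


def write_genes_gff3(path, genes: Iterable[GeneModel],
                     source: str = "syntelinc") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.span.chrom, g.span.start,
                                              g.gene_id)):
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            if g.pseudogene_subtype:
                attrs += f";pseudogene_subtype={g.pseudogene_subtype}"
            fh.write("\t".join([
                g.span.chrom, source, "gene", str(g.span.start + 1),
                str(g.span.end), ".", g.span.strand, ".", attrs,
            ]) + "\n")
            for i, ex in enumerate(g.exons, 1):
                fh.write("\t".join([
                    ex.chrom, source, "exon", str(ex.start + 1), str(ex.end),
                    ".", ex.strand, ".",
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                ]) + "\n")


# ---------------------------------------------------------------------------
# lincRNAs


def read_lincrnas(gff_path, cdna_fasta_path) -> list[LincRNA]:
    """Load lincRNAs from a GFF3 of lincRNA genes plus a spliced-cDNA FASTA."""
    cdnas = read_fasta(cdna_fasta_path)
    lincs = []
    for gene in read_genes_gff3(gff_path):
        if gene.gene_id not in cdnas:
            raise ValueError(f"lincRNA {gene.gene_id} missing from cDNA FASTA")
        lincs.append(LincRNA(linc_id=gene.gene_id, span=gene.span,
                             cdna=cdnas[gene.gene_id]))
    return lincs


def read_lincrnas_bed12(bed_path, cdna_fasta_path) -> list[LincRNA]:
    """Load lincRNAs from BED12 (0-based half-open) plus a cDNA FASTA."""
    cdnas = read_fasta(cdna_fasta_path)
    lincs = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{bed_path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if parts[5] in "+-" else "."
            if name not in cdnas:
                raise ValueError(f"lincRNA {name} missing from cDNA FASTA")
            lincs.append(LincRNA(
                linc_id=name,
                span=GenomicInterval(chrom, start, end, strand),
                cdna=cdnas[name],
            ))
    return lincs


def write_lincrnas_gff3(path, lincs: Iterable[LincRNA],
                        source: str = "syntelinc") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in sorted(lincs, key=lambda l: (l.span.chrom, l.span.start)):
            attrs = f"ID={l.linc_id};biotype=lincRNA"
            fh.write("\t".join([
                l.span.chrom, source, "gene", str(l.span.start + 1),
                str(l.span.end), ".", l.span.strand, ".", attrs,
            ]) + "\n")
            fh.write("\t".join([
                l.span.chrom, source, "exon", str(l.span.start + 1),
                str(l.span.end), ".", l.span.strand, ".",
                f"ID={l.linc_id}.exon1;Parent={l.linc_id}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# repeats


def read_repeats(path) -> list[RepeatFeature]:
    """Read repeat annotations from RepeatMasker ``.out`` or BED6.

    Dispatch is by extension; BED names follow the UCSC convention
    ``repeat_name#repeat_class``.
    """
    path = Path(path)
    if path.suffix == ".out":
        return read_repeatmasker_out(path)
    return read_repeats_bed(path)


def read_repeatmasker_out(path) -> list[RepeatFeature]:
    """Parse RepeatMasker ``.out``: 1-based inclusive query coordinates,
    repeat name in column 10 and class/family in column 11."""
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            if parts[0] in ("SW", "score") or parts[0].startswith("-"):
                continue  # header lines
            try:
                chrom = parts[4]
                start = int(parts[5]) - 1
                end = int(parts[6])
                strand = "+" if parts[8] == "+" else "-"
                name = parts[9]
                rclass = parts[10]
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed RepeatMasker line: {exc}"
                ) from exc
            repeats.append(RepeatFeature(
                span=GenomicInterval(chrom, start, end, strand),
                repeat_class=rclass, repeat_name=name,
            ))
    return repeats


def read_repeats_bed(path) -> list[RepeatFeature]:
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else "repeat#Unknown"
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}"
                                 ) from exc
            if "#" in name:
                rname, rclass = name.split("#", 1)
            else:
                rname, rclass = name, "Unknown"
            repeats.append(RepeatFeature(
                span=GenomicInterval(chrom, start, end, strand),
                repeat_class=rclass, repeat_name=rname,
            ))
    return repeats


def write_repeats_bed(path, repeats: Iterable[RepeatFeature]) -> None:
    with open(path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r.span.chrom, r.span.start)):
            strand = r.span.strand if r.span.strand in "+-" else "+"
            fh.write("\t".join([
                r.span.chrom, str(r.span.start), str(r.span.end),
                f"{r.repeat_name}#{r.repeat_class}", "0", strand,
            ]) + "\n")


# ---------------------------------------------------------------------------
# orthology / ceRNA tables


def read_orthology_tsv(path) -> OrthologyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["species_a", "gene_a", "species_b", "gene_b"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"orthology table needs columns {required}")
    return OrthologyMap(df[required].itertuples(index=False, name=None))


def write_orthology_tsv(path, orth: OrthologyMap) -> None:
    df = pd.DataFrame(orth.edges(),
                      columns=["species_a", "gene_a", "species_b", "gene_b"])
    df.to_csv(path, sep="\t", index=False)


def read_cerna_tsv(path) -> CeRNAPairTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["lnc_id", "gene_id"]:
        raise ValueError("ceRNA table needs columns lnc_id, gene_id")
    return CeRNAPairTable(df[["lnc_id", "gene_id"]]
                          .itertuples(index=False, name=None))


def write_cerna_tsv(path, cerna: CeRNAPairTable) -> None:
    df = pd.DataFrame(list(cerna), columns=["lnc_id", "gene_id"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bundles


def read_genome_bundle(fasta_path, gff_path, repeats_path,
                       species: Optional[str] = None) -> GenomeBundle:
    """Load one species' genome FASTA + gene GFF3 + repeat annotation.

    All coordinates are normalised to internal 0-based half-open; interval
    indices are built on construction.  An annotation naming an unknown
    sequence, or extending past its end, raises with the offending record
    named.
    """
    if species is None:
        species = Path(fasta_path).stem
    sequences = read_fasta(fasta_path)
    genes = read_genes_gff3(gff_path)
    repeats = read_repeats(repeats_path) if repeats_path else []
    return GenomeBundle(species=species, sequences=sequences, genes=genes,
                        repeats=repeats)


# ---------------------------------------------------------------------------
# lincRNA pre-filter


def filter_lincrnas(lincs: list[LincRNA], human: GenomeBundle) -> list[LincRNA]:
    """Drop lincRNAs overlapping (>=1 bp, strand-blind) any protein-coding
    gene span in the human annotation.  Idempotent; preserves input order."""
    kept = []
    for linc in lincs:
        coding = human.genes_overlapping(linc.span, biotype="protein_coding")
        if not coding:
            kept.append(linc)
    return kept


# ---------------------------------------------------------------------------
# ortholog table

ORTHOLOG_TABLE_COLUMNS = [
    "linc_id", "species", "chrom", "start", "end", "evalue", "class",
    "exon_cov", "intron_cov", "intergenic_cov", "te_cov", "structural_label",
]


def write_ortholog_table(results, path) -> None:
    """Write selected putative orthologs as a TSV with a fixed column set
    and deterministic (linc_id, species) row order."""
    rows = []
    for po in results:
        cov = po.coverage
        rows.append({
            "linc_id": po.linc_id,
            "species": po.species,
            "chrom": po.region.chrom,
            "start": po.region.start,
            "end": po.region.end,
            "evalue": f"{po.evalue:.3e}",
            "class": po.ortholog_class,
            "exon_cov": f"{cov.exon_cov:.6f}" if cov else "",
            "intron_cov": f"{cov.intron_cov:.6f}" if cov else "",
            "intergenic_cov": f"{cov.intergenic_cov:.6f}" if cov else "",
            "te_cov": f"{cov.te_cov:.6f}" if cov else "",
            "structural_label": cov.structural_label if cov else "",
        })
    df = pd.DataFrame(rows, columns=ORTHOLOG_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["linc_id", "species"], kind="stable")
    df.to_csv(path, sep="\t", index=False)
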