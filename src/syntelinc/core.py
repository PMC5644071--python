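"""Core domain types for the lincRNA ortholog-search pipeline.

All coordinates are 0-based, half-open ``[start, end)`` on the forward
strand of the named sequence.  Converters to/from 1-based inclusive
conventions (GFF3, RepeatMasker) live at the I/O boundary in
:mod:`syntelinc.io`; nothing else in the package should ever shift a
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

VALID_STRANDS = {"+", "-", "."}

#: Gene biotypes the pipeline distinguishes.
BIOTYPES = {"protein_coding", "lincRNA", "other_noncoding", "pseudogene"}

#: RepeatMasker repeat classes that do NOT count as transposable elements.
#: Everything else (LINE, SINE, LTR, DNA, RC, Retroposon, ...) does.
NON_TE_REPEAT_CLASSES = {"Simple_repeat", "Low_complexity", "Satellite"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind >=1 bp overlap on the same sequence."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> Optional[int]:
        """Boundary-to-boundary gap in bp; 0 when overlapping; None across chroms."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass
class GeneModel:
    """One gene collapsed to its per-gene exon union (isoform-blind)."""

    gene_id: str
    biotype: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    pseudogene_subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have >=1 exon")
        self.exons = merge_intervals(self.exons)
        for ex in self.exons:
            if ex.chrom != self.span.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass(frozen=True)
class RepeatFeature:
    """A RepeatMasker-style repeat annotation."""

    span: GenomicInterval
    repeat_class: str
    repeat_name: str = ""

    def __post_init__(self) -> None:
        if not self.repeat_class:
            raise ValueError("repeat_class must be non-empty")

    @property
    def is_te(self) -> bool:
        base = self.repeat_class.split("/")[0]
        return base not in NON_TE_REPEAT_CLASSES


@dataclass
class LincRNA:
    """A human lincRNA: genomic span plus spliced cDNA sequence (>200 nt)."""

    linc_id: str
    span: GenomicInterval
    cdna: str

    def __post_init__(self) -> None:
        self.cdna = self.cdna.upper()
        if len(self.cdna) < 200:
            raise ValueError(
                f"{self.linc_id}: lincRNA cDNA must be longer than 200 nt "
                f"(got {len(self.cdna)})"
            )
        if set(self.cdna) - set("ACGTN"):
            raise ValueError(f"{self.linc_id}: cDNA has characters outside ACGTN")


class GenomeBundle:
    """One species' sequences, gene models and repeats, interval-indexed.

    Parameters
    ----------
    species
        Species label used in orthology tables and reports.
    sequences
        Mapping sequence name -> DNA string (uppercase ACGTN).
    genes, repeats
        Annotations; every feature must lie within a known sequence.
    """

    def __init__(
        self,
        species: str,
        sequences: dict[str, str],
        genes: Iterable[GeneModel] = (),
        repeats: Iterable[RepeatFeature] = (),
    ) -> None:
        self.species = species
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.genes = list(genes)
        self.repeats = list(repeats)
        self._check_bounds()
        self._gene_index: dict[str, IntervalTree] = {}
        self._repeat_index: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._gene_index.setdefault(g.span.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g
            )
        for r in self.repeats:
            self._repeat_index.setdefault(r.span.chrom, IntervalTree()).addi(
                r.span.start, r.span.end, r
            )
        self.genes_by_id = {g.gene_id: g for g in self.genes}

    def _check_bounds(self) -> None:
        for g in self.genes:
            self._check_one(g.span, g.gene_id)
        for r in self.repeats:
            self._check_one(r.span, r.repeat_name or r.repeat_class)

    def _check_one(self, span: GenomicInterval, label: str) -> None:
        if span.chrom not in self.sequences:
            raise ValueError(
                f"{self.species}: annotation {label!r} references unknown "
                f"sequence {span.chrom!r}"
            )
        if span.end > len(self.sequences[span.chrom]):
            raise ValueError(
                f"{self.species}: annotation {label!r} extends past end of "
                f"{span.chrom} ({span.end} > {len(self.sequences[span.chrom])})"
            )

    # -- queries ---------------------------------------------------------

    def genes_overlapping(
        self, region: GenomicInterval, biotype: Optional[str] = None
    ) -> list[GeneModel]:
        tree = self._gene_index.get(region.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(region.start, region.end)]
        if biotype is not None:
            hits = [g for g in hits if g.biotype == biotype]
        return sorted(hits, key=lambda g: (g.span.start, g.span.end, g.gene_id))

    def repeats_overlapping(self, region: GenomicInterval) -> list[RepeatFeature]:
        tree = self._repeat_index.get(region.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(region.start, region.end)]
        return sorted(hits, key=lambda r: (r.span.start, r.span.end))

    def fetch(self, region: GenomicInterval) -> str:
        """Forward-strand sequence of a region."""
        return self.sequences[region.chrom][region.start : region.end]


class OrthologyMap:
    """Symmetric cross-species gene-gene orthology relation.

    Stores edges between (species, gene_id) nodes; the symmetric closure
    is enforced on insertion.  Also used to look up human paralog edges
    (human orthologs of genes aligned in other species).
    """

    def __init__(self, edges: Iterable[tuple[str, str, str, str]] = ()) -> None:
        self._adj: dict[tuple[str, str], set[tuple[str, str]]] = {}
        for sa, ga, sb, gb in edges:
            self.add(sa, ga, sb, gb)

    def add(self, species_a: str, gene_a: str, species_b: str, gene_b: str) -> None:
        a, b = (species_a, gene_a), (species_b, gene_b)
        if a == b:
            raise ValueError(f"self-orthology edge for {a}")
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def orthologs(self, species: str, gene_id: str, in_species: Optional[str] = None
                  ) -> list[tuple[str, str]]:
        out = sorted(self._adj.get((species, gene_id), ()))
        if in_species is not None:
            out = [(s, g) for s, g in out if s == in_species]
        return out

    def are_orthologous(self, species_a: str, gene_a: str,
                        species_b: str, gene_b: str) -> bool:
        return (species_b, gene_b) in self._adj.get((species_a, gene_a), ())

    def edges(self) -> list[tuple[str, str, str, str]]:
        out = []
        for (sa, ga), nbrs in self._adj.items():
            for sb, gb in nbrs:
                if (sa, ga) < (sb, gb):
                    out.append((sa, ga, sb, gb))
        return sorted(out)

    def __len__(self) -> int:
        return len(self.edges())


class CeRNAPairTable:
    """Set of known (lncRNA id, mRNA gene id) competing-endogenous-RNA pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._pairs: set[tuple[str, str]] = set()
        for lnc, gene in pairs:
            if not lnc or not gene:
                raise ValueError("ceRNA pair ids must be non-empty")
            self._pairs.add((lnc, gene))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(sorted(self._pairs))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and union overlapping/adjacent-overlapping intervals (per chrom).

    Strand information is dropped on merge (merged pieces get '.') only when
    strands disagree; a lone interval keeps its strand.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            strand = prev.strand if prev.strand == iv.strand else "."
            out[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end), strand
            )
        else:
            out.append(iv)
    return out


def intersect_bp(region: GenomicInterval,
                 intervals: Iterable[GenomicInterval]) -> int:
    """Total bp of ``region`` covered by the union of ``intervals``."""
    total = 0
    for iv in merge_intervals(
        [iv for iv in intervals if iv.chrom == region.chrom]
    ):
        total += region.overlap_bp(iv)
    return total
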