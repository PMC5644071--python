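"""Synteny-constrained candidate identification and cross-species selection.

A putative ortholog of a human lincRNA in another species is an
alignment hit (E < 1e-10) that is *flanked* by the orthologs of a pair
of the lincRNA's human neighbour protein-coding genes - one upstream,
one downstream, each within ``window_bp`` (default 750 kb) of the hit.
Candidates anchored by the same neighbour-gene pair in different species
are treated as the same genomic locus; a locus supported by a single
species is discarded, and per species the candidate from the locus with
the widest species support wins (ties by lowest E-value, then by
coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import AlignmentHit, KAParams, ScoringScheme, ka_params, search_windows
from .classify import CoverageProfile
from .core import GeneModel, GenomeBundle, GenomicInterval, LincRNA, OrthologyMap, merge_intervals

DEFAULT_WINDOW_BP = 750_000


@dataclass
class NeighborContext:
    """Human protein-coding neighbour genes of one lincRNA.

    Genes qualify when their span midpoint lies within ``window_bp`` of
    the lincRNA span boundary on the respective side; lists are ordered
    nearest-first.
    """

    linc_id: str
    upstream_genes: list[str]
    downstream_genes: list[str]
    window_bp: int = DEFAULT_WINDOW_BP


@dataclass
class OrthologCandidate:
    """An alignment hit that passed the synteny (flanking-anchor) test."""

    linc_id: str
    species: str
    hit: AlignmentHit
    anchor_pair: tuple[str, str]  # (upstream human gene, downstream human gene)
    species_support: int = 0


@dataclass
class PutativeOrtholog:
    """The selected syntenic match of one lincRNA in one species."""

    linc_id: str
    species: str
    region: GenomicInterval
    evalue: float
    anchor_pair: tuple[str, str]
    species_support: int = 0
    ortholog_class: Optional[str] = None   # intergenic / protein_coding / non_coding
    coverage: Optional[CoverageProfile] = None


def neighbor_context(linc: LincRNA, human: GenomeBundle,
                     window_bp: int = DEFAULT_WINDOW_BP) -> NeighborContext:
    """Protein-coding genes flanking a lincRNA within ``window_bp``.

    Assumes the lincRNA already passed the coding-overlap filter, so every
    coding gene lies strictly up- or downstream by midpoint.
    """
    up: list[tuple[int, str]] = []
    down: list[tuple[int, str]] = []
    probe = GenomicInterval(linc.span.chrom,
                            max(0, linc.span.start - window_bp),
                            linc.span.end + window_bp)
    for g in human.genes_overlapping(probe, biotype="protein_coding"):
        mid = (g.span.start + g.span.end) // 2
        if mid <= linc.span.start:
            dist = linc.span.start - mid
            if dist <= window_bp:
                up.append((dist, g.gene_id))
        elif mid >= linc.span.end:
            dist = mid - linc.span.end
            if dist <= window_bp:
                down.append((dist, g.gene_id))
    up.sort()
    down.sort()
    return NeighborContext(
        linc_id=linc.linc_id,
        upstream_genes=[g for _, g in up],
        downstream_genes=[g for _, g in down],
        window_bp=window_bp,
    )


def syntenic_windows(
    ctx: NeighborContext,
    species: GenomeBundle,
    orth: OrthologyMap,
    window_bp: Optional[int] = None,
    human_species: str = "human",
) -> list[tuple[GenomicInterval, tuple[str, str]]]:
    """Target-genome search windows implied by each anchor pair.

    For every (upstream u, downstream d) neighbour pair whose orthologs
    u', d' land on the same target chromosome within ``2 * window_bp`` of
    each other, the window spans u' and d' extended by ``window_bp`` on
    each side (clipped to the chromosome).  Windows of the same anchor
    pair on the same chromosome are merged when overlapping.
    """
    if window_bp is None:
        window_bp = ctx.window_bp
    out: list[tuple[GenomicInterval, tuple[str, str]]] = []
    for u in ctx.upstream_genes:
        u_orths = [g for s, g in orth.orthologs(human_species, u,
                                                in_species=species.species)]
        if not u_orths:
            continue
        for d in ctx.downstream_genes:
            d_orths = [g for s, g in orth.orthologs(human_species, d,
                                                    in_species=species.species)]
            wins: list[GenomicInterval] = []
            for ug in u_orths:
                gu = species.genes_by_id.get(ug)
                if gu is None:
                    continue
                for dg in d_orths:
                    gd = species.genes_by_id.get(dg)
                    if gd is None or gd.span.chrom != gu.span.chrom:
                        continue
                    gap = gu.span.distance(gd.span)
                    if gap is None or gap > 2 * window_bp:
                        continue
                    lo = min(gu.span.start, gd.span.start)
                    hi = max(gu.span.end, gd.span.end)
                    chrom_len = len(species.sequences[gu.span.chrom])
                    wins.append(GenomicInterval(
                        gu.span.chrom,
                        max(0, lo - window_bp),
                        min(chrom_len, hi + window_bp),
                    ))
            for win in merge_intervals(wins):
                out.append((win, (u, d)))
    out.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))
    return out


def _flanks(hit_iv: GenomicInterval, gene: GeneModel, window_bp: int) -> Optional[str]:
    """'left'/'right' when the gene span lies entirely on one side of the hit
    within window_bp (boundary-to-boundary); None otherwise."""
    span = gene.span
    if span.chrom != hit_iv.chrom:
        return None
    if span.end <= hit_iv.start:
        return "left" if hit_iv.start - span.end <= window_bp else None
    if span.start >= hit_iv.end:
        return "right" if span.start - hit_iv.end <= window_bp else None
    return None  # overlaps the hit: not a flank


def find_candidates(
    linc: LincRNA,
    species: GenomeBundle,
    ctx: NeighborContext,
    orth: OrthologyMap,
    scheme: ScoringScheme = ScoringScheme(),
    *,
    evalue_cutoff: float = 1e-10,
    window_bp: Optional[int] = None,
    human_species: str = "human",
    require_order: bool = False,
    ka: Optional[KAParams] = None,
) -> list[OrthologCandidate]:
    """Alignment hits in syntenic windows that are flanked by an anchor pair.

    A hit qualifies when, for at least one anchor pair, one anchor's
    ortholog lies entirely on each side of the hit within ``window_bp``.
    With ``require_order=True`` the upstream anchor must lie left of the
    hit and the downstream anchor right (human orientation preserved);
    the default makes no order/orientation demand.  Of several qualifying
    pairs the nearest (smallest summed boundary distance) is kept.
    """
    if window_bp is None:
        window_bp = ctx.window_bp
    anchored = syntenic_windows(ctx, species, orth, window_bp, human_species)
    if not anchored:
        return []
    # align once against the merged union of all windows, then test anchors
    merged = merge_intervals([w for w, _ in anchored])
    hits = search_windows(linc, [(species, w) for w in merged], scheme,
                          evalue_cutoff, ka=ka)
    pairs = sorted({ap for _, ap in anchored})
    candidates = []
    for hit in hits:
        best: Optional[tuple[int, tuple[str, str]]] = None
        for u, d in pairs:
            u_genes = [species.genes_by_id[g]
                       for _, g in orth.orthologs(human_species, u,
                                                  in_species=species.species)
                       if g in species.genes_by_id]
            d_genes = [species.genes_by_id[g]
                       for _, g in orth.orthologs(human_species, d,
                                                  in_species=species.species)
                       if g in species.genes_by_id]
            for gu in u_genes:
                su = _flanks(hit.subject_interval, gu, window_bp)
                if su is None:
                    continue
                for gd in d_genes:
                    sd = _flanks(hit.subject_interval, gd, window_bp)
                    if sd is None or sd == su:
                        continue
                    if require_order and su != "left":
                        continue
                    dist = (hit.subject_interval.distance(gu.span)
                            + hit.subject_interval.distance(gd.span))
                    if best is None or dist < best[0]:
                        best = (dist, (u, d))
        if best is not None:
            candidates.append(OrthologCandidate(
                linc_id=linc.linc_id, species=species.species, hit=hit,
                anchor_pair=best[1],
            ))
    return candidates


def select_putative_orthologs(
    candidates: list[OrthologCandidate],
    min_species_support: int = 2,
) -> dict[str, PutativeOrtholog]:
    """Apply the cross-species selection cascade to one lincRNA's candidates.

    1. Candidates sharing an anchor pair form one cross-species locus group.
    2. Groups supported by fewer than ``min_species_support`` species are
       dropped.
    3. Per species, the candidate from the group with the most supporting
       species wins; ties break by lowest E-value, then smallest
       (chrom, start).

    Returns at most one putative ortholog per species.
    """
    groups: dict[tuple[str, str], list[OrthologCandidate]] = {}
    for c in candidates:
        groups.setdefault(c.anchor_pair, []).append(c)
    support = {ap: len({c.species for c in cs}) for ap, cs in groups.items()}
    surviving = [c for c in candidates
                 if support[c.anchor_pair] >= min_species_support]
    for c in surviving:
        c.species_support = support[c.anchor_pair]
    selected: dict[str, PutativeOrtholog] = {}
    by_species: dict[str, list[OrthologCandidate]] = {}
    for c in surviving:
        by_species.setdefault(c.species, []).append(c)
    for sp, cs in by_species.items():
        cs.sort(key=lambda c: (
            -c.species_support, c.hit.evalue,
            c.hit.subject_interval.chrom, c.hit.subject_interval.start,
        ))
        top = cs[0]
        selected[sp] = PutativeOrtholog(
            linc_id=top.linc_id, species=sp,
            region=top.hit.subject_interval,
            evalue=top.hit.evalue,
            anchor_pair=top.anchor_pair,
            species_support=top.species_support,
        )
    return selected
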