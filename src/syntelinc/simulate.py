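"""Synthetic comparative-genome generator with planted ground truth.

Emulates the study design at desk scale: a human chromosome carrying
lincRNAs between protein-coding genes, plus several target-species
chromosomes whose gene order mirrors the human one (so synteny anchors
exist by construction).  Each lincRNA is assigned a scenario that plants
- or deliberately withholds - a diverged copy of its sequence in every
target species:

``intergenic_homolog``   copy between the flank-gene orthologs;
``exonic_homolog``       copy inside an exon of a host coding gene;
``intronic_homolog``     copy inside an intron of a host coding gene;
``noncoding_homolog``    copy inside an annotated lncRNA gene;
``no_homolog``           conserved flanks, no copy anywhere;
``unitary_scenario``     exonic copies in hosts orthologous among the
                         target species but with no human ortholog, and
                         an annotated human pseudogene overlapping or
                         juxtaposed to the lincRNA;
``duplicated_scenario``  exonic copies in hosts orthologous to a human
                         paralog gene that itself carries a diverged
                         copy of the lincRNA sequence.

Transposable-element annotations are planted exactly where recorded
(a perfect RepeatMasker stand-in): real consensus-library insertions in
intergenic background, and annotation-only TE intervals inside
intronic/exonic homologs at configurable densities.  Every emitted file
round-trips through :mod:`syntelinc.io`, and the machine-readable truth
records what the pipeline should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .align import revcomp
from .core import (
    CeRNAPairTable,
    GeneModel,
    GenomeBundle,
    GenomicInterval,
    LincRNA,
    OrthologyMap,
    RepeatFeature,
)

SCENARIOS = (
    "intergenic_homolog",
    "exonic_homolog",
    "intronic_homolog",
    "noncoding_homolog",
    "no_homolog",
    "unitary_scenario",
    "duplicated_scenario",
)

_EXONIC_SCENARIOS = {"exonic_homolog", "unitary_scenario", "duplicated_scenario"}

#: expected (class, structural label) per scenario; None = no selection expected
_EXPECTATIONS = {
    "intergenic_homolog": ("intergenic", "mixed"),
    "exonic_homolog": ("protein_coding", "exonic"),
    "intronic_homolog": ("protein_coding", "intronic"),
    "noncoding_homolog": ("non_coding", "mixed"),
    "no_homolog": (None, None),
    "unitary_scenario": ("protein_coding", "exonic"),
    "duplicated_scenario": ("protein_coding", "exonic"),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one synthetic comparative dataset.

    Defaults mirror the scaled-down verification conditions: three
    target species at 5% per-site divergence, five lincRNAs per
    scenario, compact ~1 Mb chromosomes with correspondingly scaled
    synteny windows (the suggested ``window_bp`` of 50 kb plays the role
    the 750 kb window plays at full genome scale).
    """

    rng_seed: int = 0
    n_species: int = 3
    divergence: Union[float, list[float]] = 0.05
    with_indels: bool = False
    scenario_counts: dict[str, int] = field(
        default_factory=lambda: {s: 5 for s in SCENARIOS})
    linc_length: int = 500
    extra_genes: int = 6
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (150, 350)
    intron_length: tuple[int, int] = (400, 1200)
    gap_pad: tuple[int, int] = (2500, 4000)      # spare-gap padding
    linc_gap_pad: tuple[int, int] = (3000, 4500)  # padding around lincs/plants
    exon_margin: int = 40        # homolog-free exon flank inside host exons
    te_library: Optional[list[tuple[str, str, str]]] = None  # (name, class, seq)
    n_background_te: int = 30
    intronic_te_density: float = 0.32
    exonic_te_density: float = 0.07
    paralog_divergence: float = 0.05
    cerna_fraction: float = 0.6
    n_background_cerna: int = 30
    juxtaposed_distance: int = 1500
    chromosome_length: int = 1_200_000
    window_bp: int = 50_000
    juxtaposition_bp: int = 4_000

    def __post_init__(self) -> None:
        for s in self.scenario_counts:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
            if self.scenario_counts[s] < 0:
                raise ValueError("scenario counts must be >= 0")
        divs = self.divergences
        if any(not (0 <= d < 0.3 + 1e-9) for d in divs):
            raise ValueError("divergence must be in [0, 0.3]")
        homolog_wanted = any(
            self.scenario_counts.get(s, 0) > 0
            for s in SCENARIOS if s != "no_homolog"
        )
        if homolog_wanted and self.n_species < 2:
            raise ValueError("homolog scenarios need at least 2 target species")
        if self.linc_length < 201:
            raise ValueError("linc_length must exceed 200")

    @property
    def divergences(self) -> list[float]:
        if isinstance(self.divergence, (int, float)):
            return [float(self.divergence)] * self.n_species
        if len(self.divergence) != self.n_species:
            raise ValueError("need one divergence per species")
        return [float(d) for d in self.divergence]

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


@dataclass
class PlantedLinc:
    """Ground truth for one lincRNA."""

    linc_id: str
    scenario: str
    human_span: tuple[int, int]
    expected_class: Optional[str]
    expected_label: Optional[str]
    expected_hypothesis: Optional[str]
    planted: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_te_bp: dict[str, int] = field(default_factory=dict)
    pseudogene_id: Optional[str] = None
    pseudogene_relation: str = "none"
    paralog_id: Optional[str] = None
    in_cerna_table: bool = False


@dataclass
class TruthSet:
    """All planted ground truth of one synthetic dataset.

    Serialised as JSON mapping linc_id -> PlantedLinc fields:
    ``scenario``, ``human_span`` [start, end), ``expected_class``,
    ``expected_label``, ``expected_hypothesis`` (nullable),
    ``planted`` {species: [start, end)}, ``planted_te_bp`` {species: bp},
    ``pseudogene_id``/``pseudogene_relation``, ``paralog_id`` and
    ``in_cerna_table``.
    """

    lincs: dict[str, PlantedLinc] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {lid: asdict(pl) for lid, pl in sorted(self.lincs.items())}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        lincs = {}
        for lid, d in payload.items():
            d = dict(d)
            d["human_span"] = tuple(d["human_span"])
            d["planted"] = {sp: tuple(v) for sp, v in d["planted"].items()}
            lincs[lid] = PlantedLinc(**d)
        return cls(lincs=lincs)


@dataclass
class SimulatedData:
    """In-memory synthetic dataset (what the emitted files contain)."""

    human: GenomeBundle
    species: dict[str, GenomeBundle]
    lincs: list[LincRNA]
    orthology: OrthologyMap
    cerna: CeRNAPairTable
    truth: TruthSet
    config: SimConfig


# ---------------------------------------------------------------------------
# sequence helpers


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def mutate_sequence(seq: str, divergence: float,
                    rng: Optional[np.random.Generator] = None,
                    with_indels: bool = False) -> str:
    """Mutate each site to a different base with probability ``divergence``
    (uniform substitution model); optional small indels (rate
    divergence/10, lengths 1-5) behind the ``with_indels`` flag."""
    if not (0 <= divergence < 1):
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(rng)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.zeros(arr.shape, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    hit = rng.random(len(arr)) < divergence
    shift = rng.integers(1, 4, size=len(arr))
    new_code = (code + shift) % 4
    arr[hit] = _BASES[new_code[hit]]
    out = arr.tobytes().decode()
    if with_indels and divergence > 0:
        rate = divergence / 10
        pieces = []
        i = 0
        while i < len(out):
            if rng.random() < rate:
                length = int(rng.integers(1, 6))
                if rng.random() < 0.5:
                    i += length  # deletion
                else:
                    pieces.append(_rand_seq(rng, length))  # insertion
            pieces.append(out[i : i + 1])
            i += 1
        out = "".join(pieces)
    return out


class _Chrom:
    """Append-only chromosome builder tracking the cursor position."""

    def __init__(self, name: str = "chr1") -> None:
        self.name = name
        self.parts: list[str] = []
        self.pos = 0

    def add(self, seq: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    def sequence(self) -> str:
        return "".join(self.parts)


def _default_te_library(rng: np.random.Generator
                        ) -> list[tuple[str, str, str]]:
    return [
        ("simL1", "LINE/L1", _rand_seq(rng, 1500)),
        ("simAlu", "SINE/Alu", _rand_seq(rng, 300)),
        ("simERV", "LTR/ERV1", _rand_seq(rng, 600)),
    ]


def _te_segments(rng: np.random.Generator, start: int, end: int,
                 density: float) -> list[tuple[int, int]]:
    """Non-overlapping sub-intervals of [start, end) totalling exactly
    ``round(density * length)`` bp (annotation-only planted TEs)."""
    length = end - start
    target = int(round(density * length))
    if target <= 0:
        return []
    k = max(1, int(np.ceil(target / 100)))
    per = target // k
    segs = []
    chunk = length // k
    used = 0
    for i in range(k):
        seg_len = per if i < k - 1 else target - used
        lo = start + i * chunk
        hi = start + (i + 1) * chunk if i < k - 1 else end
        if seg_len <= 0 or hi - lo < seg_len:
            continue
        off = int(rng.integers(0, hi - lo - seg_len + 1))
        segs.append((lo + off, lo + off + seg_len))
        used += seg_len
    return segs


# ---------------------------------------------------------------------------
# gene construction


def _random_gene(rng: np.random.Generator, cfg: SimConfig, chrom: _Chrom,
                 gene_id: str, biotype: str = "protein_coding") -> GeneModel:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    for i in range(n_ex):
        if i > 0:
            chrom.add(_rand_seq(rng, int(rng.integers(*cfg.intron_length))))
        s, e = chrom.add(_rand_seq(rng, int(rng.integers(*cfg.exon_length))))
        exons.append(GenomicInterval(chrom.name, s, e, strand))
    span = GenomicInterval(chrom.name, exons[0].start, exons[-1].end, strand)
    return GeneModel(gene_id=gene_id, biotype=biotype, span=span, exons=exons)


def _host_gene_with_copy(rng: np.random.Generator, cfg: SimConfig,
                         chrom: _Chrom, gene_id: str, copy_seq: str,
                         placement: str) -> tuple[GeneModel, tuple[int, int]]:
    """A coding gene whose exon (or intron) contains the planted copy.

    Returns (gene, planted interval).  The copy keeps a homology-free
    margin inside its stratum so alignment creep cannot cross a
    stratum boundary.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    m = cfg.exon_margin
    exons = []
    s, e = chrom.add(_rand_seq(rng, int(rng.integers(*cfg.exon_length))))
    exons.append(GenomicInterval(chrom.name, s, e, strand))
    if placement == "exon":
        chrom.add(_rand_seq(rng, int(rng.integers(*cfg.intron_length))))
        s0, _ = chrom.add(_rand_seq(rng, int(rng.integers(m, 2 * m))))
        ps, pe = chrom.add(copy_seq)
        _, e1 = chrom.add(_rand_seq(rng, int(rng.integers(m, 2 * m))))
        exons.append(GenomicInterval(chrom.name, s0, e1, strand))
    elif placement == "intron":
        chrom.add(_rand_seq(rng, int(rng.integers(2 * m, 3 * m))))
        ps, pe = chrom.add(copy_seq)
        chrom.add(_rand_seq(rng, int(rng.integers(2 * m, 3 * m))))
    else:
        raise ValueError(placement)
    chrom.add(_rand_seq(rng, int(rng.integers(*cfg.intron_length))))
    s, e = chrom.add(_rand_seq(rng, int(rng.integers(*cfg.exon_length))))
    exons.append(GenomicInterval(chrom.name, s, e, strand))
    span = GenomicInterval(chrom.name, exons[0].start, exons[-1].end, strand)
    gene = GeneModel(gene_id=gene_id, biotype="protein_coding", span=span,
                     exons=exons)
    return gene, (ps, pe)


# ---------------------------------------------------------------------------
# dataset builder


def build_dataset(cfg: SimConfig) -> SimulatedData:
    """Build the full synthetic dataset in memory (deterministic in the
    config, including its seed)."""
    rng = np.random.default_rng(cfg.rng_seed)
    te_library = cfg.te_library or _default_te_library(rng)

    plan: list[tuple[str, str]] = []
    j = 0
    for scen in SCENARIOS:
        for _ in range(cfg.scenario_counts.get(scen, 0)):
            plan.append((f"LINC{j:04d}", scen))
            j += 1
    linc_seqs = {lid: _rand_seq(rng, cfg.linc_length) for lid, _ in plan}
    n_genes = len(plan) + cfg.extra_genes + 1

    truth = TruthSet()
    for lid, scen in plan:
        exp_class, exp_label = _EXPECTATIONS[scen]
        hyp = {"unitary_scenario": "unitary_candidate",
               "duplicated_scenario": "duplicated_candidate"}.get(scen)
        truth.lincs[lid] = PlantedLinc(
            linc_id=lid, scenario=scen, human_span=(0, 0),
            expected_class=exp_class, expected_label=exp_label,
            expected_hypothesis=hyp,
        )

    orth_edges: list[tuple[str, str, str, str]] = []
    all_species = ["human"] + cfg.species_names
    divs = dict(zip(cfg.species_names, cfg.divergences))

    # slot gene ids per species (same order everywhere: synteny by design)
    def slot_gene(sp: str, slot: int) -> str:
        return f"HG{slot:03d}" if sp == "human" else f"{sp}_G{slot:03d}"

    for slot in range(n_genes):
        for a in range(len(all_species)):
            for b in range(a + 1, len(all_species)):
                orth_edges.append((all_species[a], slot_gene(all_species[a], slot),
                                   all_species[b], slot_gene(all_species[b], slot)))
    # host-gene orthology (among target species; duplicated also to human paralog)
    for lid, scen in plan:
        if scen in ("exonic_homolog", "intronic_homolog", "unitary_scenario",
                    "duplicated_scenario"):
            hosts = [(sp, f"{sp}_HOST_{lid}") for sp in cfg.species_names]
            for a in range(len(hosts)):
                for b in range(a + 1, len(hosts)):
                    orth_edges.append(hosts[a] + hosts[b])
            if scen == "duplicated_scenario":
                for sp, hid in hosts:
                    orth_edges.append((sp, hid, "human", f"PAR_{lid}"))

    bundles: dict[str, GenomeBundle] = {}
    lincs: list[LincRNA] = []

    for sp in all_species:
        chrom = _Chrom("chr1")
        genes: list[GeneModel] = []
        repeats: list[RepeatFeature] = []
        for slot in range(n_genes):
            if slot >= 1:
                gidx = slot - 1
                if gidx < len(plan):
                    lid, scen = plan[gidx]
                    _build_linc_gap(rng, cfg, chrom, sp, lid, scen,
                                    linc_seqs[lid], divs, genes, repeats,
                                    lincs, truth)
                else:
                    _build_spare_gap(rng, cfg, chrom, te_library, repeats)
            else:
                chrom.add(_rand_seq(rng, int(rng.integers(*cfg.gap_pad))))
            genes.append(_random_gene(rng, cfg, chrom, slot_gene(sp, slot)))
        if sp == "human":
            # paralog genes of duplicated-scenario lincRNAs
            for lid, scen in plan:
                if scen != "duplicated_scenario":
                    continue
                chrom.add(_rand_seq(rng, int(rng.integers(*cfg.gap_pad))))
                copy = mutate_sequence(linc_seqs[lid], cfg.paralog_divergence,
                                       rng, cfg.with_indels)
                gene, _ = _host_gene_with_copy(rng, cfg, chrom,
                                               f"PAR_{lid}", copy, "exon")
                genes.append(gene)
                truth.lincs[lid].paralog_id = gene.gene_id
        tail = cfg.chromosome_length - chrom.pos
        if tail < 0:
            raise ValueError(
                f"{sp}: layout needs {chrom.pos} bp but chromosome_length is "
                f"{cfg.chromosome_length}; increase chromosome_length"
            )
        if tail:
            chrom.add(_rand_seq(rng, tail))
        bundles[sp] = GenomeBundle(
            species=sp, sequences={chrom.name: chrom.sequence()},
            genes=genes, repeats=repeats,
        )

    # ceRNA table: a fraction of planted (linc, paralog) pairs + background
    cerna_pairs: set[tuple[str, str]] = set()
    for lid, scen in plan:
        if scen == "duplicated_scenario" and rng.random() < cfg.cerna_fraction:
            cerna_pairs.add((lid, f"PAR_{lid}"))
            truth.lincs[lid].in_cerna_table = True
    human_coding = sorted(g.gene_id for g in bundles["human"].genes
                          if g.is_coding)
    n_planted = sum(1 for l in truth.lincs.values() if l.in_cerna_table)
    n_possible = sum(len(human_coding) - (1 if tr.paralog_id else 0)
                     for tr in truth.lincs.values())
    target = min(cfg.n_background_cerna, max(0, n_possible - n_planted))
    linc_ids = [lid for lid, _ in plan]
    while linc_ids and human_coding and len(cerna_pairs) < target + n_planted:
        lid = linc_ids[int(rng.integers(len(linc_ids)))]
        gid = human_coding[int(rng.integers(len(human_coding)))]
        if gid == truth.lincs[lid].paralog_id:
            continue
        cerna_pairs.add((lid, gid))

    return SimulatedData(
        human=bundles["human"],
        species={sp: bundles[sp] for sp in cfg.species_names},
        lincs=lincs,
        orthology=OrthologyMap(orth_edges),
        cerna=CeRNAPairTable(cerna_pairs),
        truth=truth,
        config=cfg,
    )


def _build_linc_gap(rng, cfg: SimConfig, chrom: _Chrom, sp: str, lid: str,
                    scen: str, linc_seq: str, divs: dict[str, float],
                    genes: list, repeats: list, lincs: list,
                    truth: TruthSet) -> None:
    """Contents of the inter-gene gap assigned to one lincRNA, for one
    species (human gets the lincRNA itself; targets get the plant)."""
    tr = truth.lincs[lid]
    chrom.add(_rand_seq(rng, int(rng.integers(*cfg.linc_gap_pad))))
    if sp == "human":
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = linc_seq if strand == "+" else revcomp(linc_seq)
        ls, le = chrom.add(genomic)
        lincs.append(LincRNA(
            linc_id=lid, span=GenomicInterval(chrom.name, ls, le, strand),
            cdna=linc_seq))
        tr.human_span = (ls, le)
        if scen == "unitary_scenario":
            overlap = int(lid[4:]) % 2 == 0  # alternate overlap / juxtaposed
            pg_id = f"PG_{lid}"
            if overlap:
                span = GenomicInterval(chrom.name, ls + len(linc_seq) // 2,
                                       le + 400, strand)
                tr.pseudogene_relation = "overlap"
            else:
                span = GenomicInterval(chrom.name, le + cfg.juxtaposed_distance,
                                       le + cfg.juxtaposed_distance + 400,
                                       strand)
                tr.pseudogene_relation = "juxtaposed"
            genes.append(GeneModel(gene_id=pg_id, biotype="pseudogene",
                                   span=span, exons=[span],
                                   pseudogene_subtype="unitary"))
            tr.pseudogene_id = pg_id
    else:
        div = divs[sp]
        if scen == "no_homolog":
            chrom.add(_rand_seq(rng, len(linc_seq)))
        else:
            copy = mutate_sequence(linc_seq, div, rng, cfg.with_indels)
            if rng.random() < 0.5:
                copy = revcomp(copy)
            if scen == "intergenic_homolog":
                ps, pe = chrom.add(copy)
            elif scen == "noncoding_homolog":
                s0, _ = chrom.add(_rand_seq(rng, 120))
                ps, pe = chrom.add(copy)
                _, e1 = chrom.add(_rand_seq(rng, 120))
                span = GenomicInterval(chrom.name, s0, e1, "+")
                genes.append(GeneModel(gene_id=f"{sp}_NC_{lid}",
                                       biotype="lincRNA", span=span,
                                       exons=[span]))
            elif scen == "intronic_homolog":
                gene, (ps, pe) = _host_gene_with_copy(
                    rng, cfg, chrom, f"{sp}_HOST_{lid}", copy, "intron")
                genes.append(gene)
                segs = _te_segments(rng, ps, pe, cfg.intronic_te_density)
                for i, (a, b) in enumerate(segs):
                    repeats.append(RepeatFeature(
                        span=GenomicInterval(chrom.name, a, b, "+"),
                        repeat_class="LINE/L1",
                        repeat_name=f"anc_te_{lid}_{i}"))
                tr.planted_te_bp[sp] = sum(b - a for a, b in segs)
            else:  # exonic_homolog, unitary_scenario, duplicated_scenario
                gene, (ps, pe) = _host_gene_with_copy(
                    rng, cfg, chrom, f"{sp}_HOST_{lid}", copy, "exon")
                genes.append(gene)
                if scen == "exonic_homolog" and cfg.exonic_te_density > 0:
                    segs = _te_segments(rng, ps, pe, cfg.exonic_te_density)
                    for i, (a, b) in enumerate(segs):
                        repeats.append(RepeatFeature(
                            span=GenomicInterval(chrom.name, a, b, "+"),
                            repeat_class="SINE/Alu",
                            repeat_name=f"anc_te_{lid}_{i}"))
                    tr.planted_te_bp[sp] = sum(b - a for a, b in segs)
            tr.planted[sp] = (ps, pe)
    chrom.add(_rand_seq(rng, int(rng.integers(*cfg.linc_gap_pad))))


def _build_spare_gap(rng, cfg: SimConfig, chrom: _Chrom,
                     te_library: list[tuple[str, str, str]],
                     repeats: list) -> None:
    """A lincRNA-free inter-gene gap with background TE insertions and the
    occasional simple repeat."""
    chrom.add(_rand_seq(rng, int(rng.integers(*cfg.gap_pad))))
    n_te = int(rng.integers(0, 3))
    for _ in range(n_te):
        name, rclass, consensus = te_library[int(rng.integers(len(te_library)))]
        frag_len = int(rng.integers(len(consensus) // 2, len(consensus) + 1))
        frag = mutate_sequence(consensus[:frag_len], 0.1, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        s, e = chrom.add(frag if strand == "+" else revcomp(frag))
        repeats.append(RepeatFeature(
            span=GenomicInterval(chrom.name, s, e, strand),
            repeat_class=rclass, repeat_name=name))
        chrom.add(_rand_seq(rng, int(rng.integers(200, 600))))
    if rng.random() < 0.3:
        s, e = chrom.add("CA" * int(rng.integers(20, 50)))
        repeats.append(RepeatFeature(
            span=GenomicInterval(chrom.name, s, e, "+"),
            repeat_class="Simple_repeat", repeat_name="(CA)n"))
    chrom.add(_rand_seq(rng, int(rng.integers(*cfg.gap_pad))))


# ---------------------------------------------------------------------------
# file emission


def generate_comparative_dataset(cfg: SimConfig, outdir
                                 ) -> tuple[dict, TruthSet]:
    """Build a dataset and write it as the file formats the pipeline reads.

    Emits per-species FASTA + gene GFF3 + repeat BED, the human lincRNA
    GFF3 + cDNA FASTA, the orthology and ceRNA TSVs, the truth JSON and a
    ready-to-run pipeline config YAML (parameters scaled to the compact
    chromosomes).  Returns (manifest of paths, TruthSet).
    """
    from . import io as sio  # local import keeps module load light
    import yaml

    data = build_dataset(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"species": {}, "human": {}}
    for sp, bundle in [("human", data.human)] + sorted(data.species.items()):
        fa = outdir / f"{sp}.fa"
        gff = outdir / f"{sp}.genes.gff3"
        bed = outdir / f"{sp}.repeats.bed"
        sio.write_fasta(fa, bundle.sequences)
        sio.write_genes_gff3(gff, bundle.genes)
        sio.write_repeats_bed(bed, bundle.repeats)
        entry = {"fasta": str(fa), "genes": str(gff), "repeats": str(bed)}
        if sp == "human":
            manifest["human"] = entry
        else:
            manifest["species"][sp] = entry

    linc_gff = outdir / "lincrnas.gff3"
    linc_fa = outdir / "lincrnas.fa"
    sio.write_lincrnas_gff3(linc_gff, data.lincs)
    sio.write_fasta(linc_fa, {l.linc_id: l.cdna for l in data.lincs})
    manifest["lincrnas"] = {"gff": str(linc_gff), "cdna": str(linc_fa)}

    orth_path = outdir / "orthology.tsv"
    cerna_path = outdir / "cerna.tsv"
    truth_path = outdir / "truth.json"
    sio.write_orthology_tsv(orth_path, data.orthology)
    sio.write_cerna_tsv(cerna_path, data.cerna)
    data.truth.to_json(truth_path)
    manifest["orthology"] = str(orth_path)
    manifest["cerna"] = str(cerna_path)
    manifest["truth"] = str(truth_path)

    config = {
        "human": manifest["human"],
        "species": manifest["species"],
        "lincrnas": manifest["lincrnas"],
        "orthology": str(orth_path),
        "cerna": str(cerna_path),
        "output_dir": str(outdir / "results"),
        "parameters": {
            "window_bp": cfg.window_bp,
            "juxtaposition_bp": cfg.juxtaposition_bp,
        },
        "rng_seed": int(cfg.rng_seed),
    }
    cfg_path = outdir / "pipeline_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    manifest["pipeline_config"] = str(cfg_path)
    return manifest, data.truth
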