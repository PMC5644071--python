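"""Neighbour context, syntenic windows, flanking test and the selection
cascade."""

import numpy as np
import pytest

from syntelinc.align import AlignmentHit
from syntelinc.core import GenomeBundle, GenomicInterval, OrthologyMap
from syntelinc.synteny import (
    OrthologCandidate,
    neighbor_context,
    select_putative_orthologs,
    syntenic_windows,
)

from conftest import make_gene, make_linc
from oracles import selection_oracle


def bundle_from_genes(species, genes, length=2_000_000):
    return GenomeBundle(species, {"chr1": "A" * length}, genes)


class TestNeighborContext:
    def test_both_flanks_captured(self):
        genes = [make_gene("u", "chr1", [(88_000, 90_000)]),
                 make_gene("d", "chr1", [(110_000, 112_000)])]
        human = bundle_from_genes("human", genes)
        linc = make_linc("l", "chr1", 100_000, 101_000)
        ctx = neighbor_context(linc, human, window_bp=750_000)
        assert ctx.upstream_genes == ["u"]
        assert ctx.downstream_genes == ["d"]

    def test_gene_just_past_window_excluded(self):
        # midpoint at 751 kb upstream of the linc start
        genes = [make_gene("far", "chr1", [(248_000, 250_000)]),
                 make_gene("near", "chr1", [(249_500, 250_500)])]
        human = bundle_from_genes("human", genes)
        linc = make_linc("l", "chr1", 1_000_000, 1_001_000)
        ctx = neighbor_context(linc, human, window_bp=750_000)
        assert ctx.upstream_genes == ["near"]

    def test_matches_brute_force_distance_scan(self):
        rng = np.random.default_rng(10)
        genes = []
        for i in range(60):
            s = int(rng.integers(0, 1_900_000))
            genes.append(make_gene(f"g{i}", "chr1", [(s, s + 1000)]))
        human = bundle_from_genes("human", genes)
        linc = make_linc("l", "chr1", 950_000, 951_000)
        w = 200_000
        ctx = neighbor_context(linc, human, window_bp=w)
        exp_up, exp_down = [], []
        for g in genes:
            mid = (g.span.start + g.span.end) // 2
            if mid <= 950_000 and 950_000 - mid <= w:
                exp_up.append((950_000 - mid, g.gene_id))
            elif mid >= 951_000 and mid - 951_000 <= w:
                exp_down.append((mid - 951_000, g.gene_id))
        assert ctx.upstream_genes == [g for _, g in sorted(exp_up)]
        assert ctx.downstream_genes == [g for _, g in sorted(exp_down)]

    def test_window_enlargement_never_drops_genes(self):
        rng = np.random.default_rng(11)
        genes = []
        for i in range(40):
            s = int(rng.integers(0, 1_500_000))
            genes.append(make_gene(f"g{i}", "chr1", [(s, s + 800)]))
        human = bundle_from_genes("human", genes)
        linc = make_linc("l", "chr1", 800_000, 801_000)
        small = neighbor_context(linc, human, window_bp=100_000)
        big = neighbor_context(linc, human, window_bp=400_000)
        assert set(small.upstream_genes) <= set(big.upstream_genes)
        assert set(small.downstream_genes) <= set(big.downstream_genes)


class TestSyntenicWindows:
    def _setup(self):
        human = bundle_from_genes("human", [
            make_gene("u", "chr1", [(90_000, 92_000)]),
            make_gene("d", "chr1", [(110_000, 112_000)]),
        ])
        linc = make_linc("l", "chr1", 100_000, 101_000)
        ctx = neighbor_context(linc, human, window_bp=50_000)
        return linc, ctx

    def test_adjacent_orthologs_one_window(self):
        _, ctx = self._setup()
        target = bundle_from_genes("sp1", [
            make_gene("u1", "chr1", [(500_000, 502_000)]),
            make_gene("d1", "chr1", [(520_000, 522_000)]),
        ])
        orth = OrthologyMap([("human", "u", "sp1", "u1"),
                             ("human", "d", "sp1", "d1")])
        wins = syntenic_windows(ctx, target, orth, window_bp=50_000)
        assert len(wins) == 1
        win, pair = wins[0]
        assert pair == ("u", "d")
        assert win.start == 450_000 and win.end == 572_000

    def test_orthologs_on_different_chromosomes_yield_nothing(self):
        _, ctx = self._setup()
        target = GenomeBundle("sp1", {"chr1": "A" * 600_000,
                                      "chr2": "A" * 600_000}, [
            make_gene("u1", "chr1", [(500_000, 502_000)]),
            make_gene("d1", "chr2", [(520_000, 522_000)]),
        ])
        orth = OrthologyMap([("human", "u", "sp1", "u1"),
                             ("human", "d", "sp1", "d1")])
        assert syntenic_windows(ctx, target, orth, window_bp=50_000) == []

    def test_multi_anchor_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        human_genes, target_genes, edges = [], [], []
        for i in range(6):
            hs = 50_000 + i * 30_000
            human_genes.append(make_gene(f"h{i}", "chr1", [(hs, hs + 2000)]))
            ts = int(rng.integers(0, 900_000))
            target_genes.append(make_gene(f"t{i}", "chr1", [(ts, ts + 2000)]))
            edges.append(("human", f"h{i}", "sp1", f"t{i}"))
        human = bundle_from_genes("human", human_genes)
        target = bundle_from_genes("sp1", target_genes, length=1_000_000)
        orth = OrthologyMap(edges)
        linc = make_linc("l", "chr1", 140_500, 141_500)
        w = 60_000
        ctx = neighbor_context(linc, human, window_bp=w)
        wins = syntenic_windows(ctx, target, orth, window_bp=w)
        # brute force over all (u, d) anchor combinations
        expected = set()
        tg = {g.gene_id: g.span for g in target_genes}
        for u in ctx.upstream_genes:
            for d in ctx.downstream_genes:
                su, sd = tg[f"t{u[1:]}"], tg[f"t{d[1:]}"]
                gap = max(0, max(su.start, sd.start) - min(su.end, sd.end))
                if gap > 2 * w:
                    continue
                lo = max(0, min(su.start, sd.start) - w)
                hi = min(1_000_000, max(su.end, sd.end) + w)
                expected.add((lo, hi, u, d))
        got = {(win.start, win.end, p[0], p[1]) for win, p in wins}
        assert got == expected


def _cand(species, anchor, evalue, start=1000, chrom="chr1", linc="L"):
    hit = AlignmentHit(
        query_id=linc,
        subject_interval=GenomicInterval(chrom, start, start + 500),
        query_start=0, query_end=500, raw_score=400, evalue=evalue,
        strand="+",
    )
    return OrthologCandidate(linc_id=linc, species=species, hit=hit,
                             anchor_pair=anchor)


class TestSelection:
    def test_single_species_locus_discarded(self):
        ap1, ap2 = ("u1", "d1"), ("u2", "d2")
        cands = [_cand("sp1", ap1, 1e-30), _cand("sp2", ap1, 1e-25),
                 _cand("sp3", ap1, 1e-20), _cand("sp4", ap2, 1e-50)]
        sel = select_putative_orthologs(cands)
        assert set(sel) == {"sp1", "sp2", "sp3"}
        assert all(po.anchor_pair == ap1 for po in sel.values())

    def test_single_species_only_empty(self):
        sel = select_putative_orthologs([_cand("sp1", ("u", "d"), 1e-40)])
        assert sel == {}

    def test_tie_broken_by_lowest_evalue(self):
        apA, apB = ("uA", "dA"), ("uB", "dB")
        cands = [_cand("sp1", apA, 1e-20), _cand("sp2", apA, 1e-22),
                 _cand("sp1", apB, 1e-12, start=9000),
                 _cand("sp2", apB, 1e-13, start=9000)]
        sel = select_putative_orthologs(cands)
        assert sel["sp1"].anchor_pair == apA
        assert sel["sp2"].anchor_pair == apA

    def test_at_most_one_per_species_and_min_support_holds(self):
        rng = np.random.default_rng(3)
        pairs = [("u1", "d1"), ("u2", "d2"), ("u3", "d3")]
        cands = []
        for _ in range(40):
            sp = f"sp{int(rng.integers(1, 5))}"
            ap = pairs[int(rng.integers(3))]
            cands.append(_cand(sp, ap, 10.0 ** -int(rng.integers(11, 40)),
                               start=int(rng.integers(0, 100_000))))
        sel = select_putative_orthologs(cands)
        support = {}
        for c in cands:
            support.setdefault(c.anchor_pair, set()).add(c.species)
        for sp, po in sel.items():
            assert po.species == sp
            assert len(support[po.anchor_pair]) >= 2

    def test_matches_rule_oracle_on_random_cases(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            pairs = [("u1", "d1"), ("u2", "d2"), ("u3", "d3")]
            cands = []
            raw = []
            for _ in range(int(rng.integers(1, 12))):
                sp = f"sp{int(rng.integers(1, 5))}"
                ap = pairs[int(rng.integers(3))]
                ev = 10.0 ** -int(rng.integers(11, 40))
                start = int(rng.integers(0, 50_000))
                cands.append(_cand(sp, ap, ev, start=start))
                raw.append((sp, ap, ev, "chr1", start))
            sel = select_putative_orthologs(cands)
            exp = selection_oracle(raw)
            assert set(sel) == set(exp)
            for sp, po in sel.items():
                assert (po.anchor_pair, po.evalue,
                        po.region.chrom, po.region.start) == exp[sp]
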