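"""Synthetic-data generator: mutation model, determinism, parsability and
synteny-by-construction guarantees."""

import filecmp

import numpy as np
import pytest

from syntelinc.core import GenomicInterval
from syntelinc.io import read_genome_bundle, read_lincrnas
from syntelinc.simulate import (
    SCENARIOS,
    SimConfig,
    TruthSet,
    build_dataset,
    generate_comparative_dataset,
    mutate_sequence,
)


class TestMutateSequence:
    def test_zero_divergence_identity(self):
        seq = "ACGT" * 100
        assert mutate_sequence(seq, 0.0, np.random.default_rng(0)) == seq

    def test_divergence_one_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", 1.0)

    def test_observed_mismatch_fraction_concentrates(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
        out = mutate_sequence(seq, 0.1, rng)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert abs(frac - 0.10) < 0.01

    def test_indels_change_length(self):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        out = mutate_sequence(seq, 0.2, rng, with_indels=True)
        assert len(out) != len(seq)


class TestConfigValidation:
    def test_homolog_scenarios_need_two_species(self):
        with pytest.raises(ValueError, match="2 target species"):
            SimConfig(n_species=1,
                      scenario_counts={"exonic_homolog": 1})

    def test_divergence_range_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(divergence=0.5)

    def test_layout_must_fit_chromosome(self):
        cfg = SimConfig(chromosome_length=50_000)
        with pytest.raises(ValueError, match="chromosome_length"):
            build_dataset(cfg)


@pytest.fixture(scope="module")
def small_cfg():
    return SimConfig(rng_seed=11,
                     scenario_counts={s: 1 for s in SCENARIOS},
                     n_species=2, chromosome_length=400_000)


@pytest.fixture(scope="module")
def small_data(small_cfg):
    return build_dataset(small_cfg)


class TestDatasetStructure:
    def test_truth_covers_every_scenario(self, small_data):
        scens = {t.scenario for t in small_data.truth.lincs.values()}
        assert scens == set(SCENARIOS)

    def test_planted_coordinates_contain_diverged_copies(self, small_data,
                                                         small_cfg):
        lincs = {l.linc_id: l for l in small_data.lincs}
        for tr in small_data.truth.lincs.values():
            for sp, (s, e) in tr.planted.items():
                assert e - s == small_cfg.linc_length
                planted = small_data.species[sp].fetch(
                    GenomicInterval("chr1", s, e))
                cdna = lincs[tr.linc_id].cdna
                # identity to the cdna (either strand) well above background
                ident = max(
                    sum(a == b for a, b in zip(planted, cdna)),
                    sum(a == b for a, b in zip(
                        planted, cdna.translate(
                            str.maketrans("ACGT", "TGCA"))[::-1])),
                ) / small_cfg.linc_length
                assert ident > 0.85

    def test_flank_orthologs_within_window_by_construction(self, small_data,
                                                           small_cfg):
        """Every planted homolog has the orthologs of its human flanking
        genes within the scaled synteny window on each side."""
        human = small_data.human
        orth = small_data.orthology
        coding = [g for g in human.genes if g.is_coding]
        for tr in small_data.truth.lincs.values():
            if not tr.planted:
                continue
            hs, he = tr.human_span
            up = max((g for g in coding if g.span.end <= hs),
                     key=lambda g: g.span.end)
            down = min((g for g in coding if g.span.start >= he),
                       key=lambda g: g.span.start)
            for sp, (s, e) in tr.planted.items():
                bundle = small_data.species[sp]
                for anchor, side in ((up, "left"), (down, "right")):
                    orths = [g for _, g in orth.orthologs(
                        "human", anchor.gene_id, in_species=sp)]
                    spans = [bundle.genes_by_id[g].span for g in orths
                             if g in bundle.genes_by_id]
                    assert any(
                        sp_.distance(GenomicInterval("chr1", s, e))
                        <= small_cfg.window_bp for sp_ in spans
                    )

    def test_pseudogene_truth_consistent(self, small_data):
        human = small_data.human
        for tr in small_data.truth.lincs.values():
            if tr.scenario != "unitary_scenario":
                continue
            pg = human.genes_by_id[tr.pseudogene_id]
            linc_iv = GenomicInterval("chr1", *tr.human_span)
            dist = linc_iv.distance(pg.span)
            if tr.pseudogene_relation == "overlap":
                assert dist == 0
            else:
                assert 0 < dist <= small_data.config.juxtaposition_bp

    def test_cerna_table_contains_recorded_pairs(self, small_data):
        for tr in small_data.truth.lincs.values():
            if tr.in_cerna_table:
                assert (tr.linc_id, tr.paralog_id) in small_data.cerna


class TestEmission:
    def test_same_seed_byte_identical_bundle(self, small_cfg, tmp_path):
        m1, _ = generate_comparative_dataset(small_cfg, tmp_path / "a")
        m2, _ = generate_comparative_dataset(small_cfg, tmp_path / "b")
        files1 = sorted(p.name for p in (tmp_path / "a").iterdir()
                        if p.is_file())
        for name in files1:
            if name == "pipeline_config.yaml":
                continue  # embeds absolute paths
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_emitted_files_parse_losslessly(self, small_cfg, small_data,
                                            tmp_path):
        manifest, truth = generate_comparative_dataset(small_cfg, tmp_path)
        sp = "sp1"
        entry = manifest["species"][sp]
        bundle = read_genome_bundle(entry["fasta"], entry["genes"],
                                    entry["repeats"], species=sp)
        orig = small_data.species[sp]
        assert bundle.sequences == orig.sequences
        assert {(g.gene_id, g.biotype, g.span.start, g.span.end)
                for g in bundle.genes} == \
               {(g.gene_id, g.biotype, g.span.start, g.span.end)
                for g in orig.genes}
        assert {(r.span.start, r.span.end, r.repeat_class)
                for r in bundle.repeats} == \
               {(r.span.start, r.span.end, r.repeat_class)
                for r in orig.repeats}
        lincs = read_lincrnas(manifest["lincrnas"]["gff"],
                              manifest["lincrnas"]["cdna"])
        assert {(l.linc_id, l.span.start, l.span.end, l.cdna)
                for l in lincs} == \
               {(l.linc_id, l.span.start, l.span.end, l.cdna)
                for l in small_data.lincs}
        back = TruthSet.from_json(manifest["truth"])
        assert back == truth
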