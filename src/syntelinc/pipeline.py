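"""End-to-end orchestration: filter -> synteny search -> selection ->
classification -> pseudogene/paralog typing -> ceRNA bootstrap ->
optional shuffle null.

Parameter defaults follow the study settings: word size 7, reward +1,
penalty -1, E < 1e-10, +/-750 kb synteny windows, >10 bp TE rule,
B = 10,000 bootstrap replicates, 5000 dinucleotide shuffles.  Synthetic
datasets ship a config with the window scaled to their compact
chromosomes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import ScoringScheme, ka_params
from .classify import classify_ortholog, coverage_profile
from .core import CeRNAPairTable, GenomeBundle, LincRNA, OrthologyMap, merge_intervals
from .io import (
    filter_lincrnas,
    read_cerna_tsv,
    read_genome_bundle,
    read_lincrnas,
    read_orthology_tsv,
    write_ortholog_table,
)
from .pseudogene import OriginCall, call_origin
from .resample import BootstrapResult, ShuffleNull, cerna_bootstrap_p, shuffle_null_distribution
from .synteny import (
    OrthologCandidate,
    PutativeOrtholog,
    find_candidates,
    neighbor_context,
    select_putative_orthologs,
    syntenic_windows,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All tunable parameters, defaulting to the study's stated values."""

    word_size: int = 7
    reward: int = 1
    penalty: int = -1
    gap_open: int = 2
    gap_extend: int = 1
    evalue_cutoff: float = 1e-10
    window_bp: int = 750_000
    min_te_bp: int = 10
    juxtaposition_bp: int = 10_000
    min_species_support: int = 2
    require_order: bool = False
    B: int = 10_000
    n_shuffles: int = 5000
    shuffle_max_lincs: int = 0  # 0 disables the shuffle-null stage

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            match_reward=self.reward, mismatch_penalty=self.penalty,
            gap_open=self.gap_open, gap_extend=self.gap_extend,
            word_size=self.word_size,
        )


@dataclass
class PipelineConfig:
    """File-level configuration (paths per species + parameters + seed)."""

    human_fasta: str
    human_genes: str
    human_repeats: str
    species_inputs: dict[str, dict[str, str]]  # sp -> {fasta, genes, repeats}
    lincrna_gff: str
    lincrna_cdna: str
    orthology: str
    cerna: Optional[str] = None
    output_dir: Optional[str] = None
    params: PipelineParams = field(default_factory=PipelineParams)
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.get("parameters", {}))
        return cls(
            human_fasta=raw["human"]["fasta"],
            human_genes=raw["human"]["genes"],
            human_repeats=raw["human"].get("repeats", ""),
            species_inputs=raw["species"],
            lincrna_gff=raw["lincrnas"]["gff"],
            lincrna_cdna=raw["lincrnas"]["cdna"],
            orthology=raw["orthology"],
            cerna=raw.get("cerna"),
            output_dir=raw.get("output_dir"),
            params=params,
            rng_seed=int(raw.get("rng_seed", 0)),
        )


@dataclass
class PipelineResult:
    """All stage outputs of one run."""

    filtered_lincs: list[LincRNA]
    n_input_lincs: int
    candidates: dict[str, list[OrthologCandidate]]
    selected: dict[str, dict[str, PutativeOrtholog]]
    origin_calls: dict[str, OriginCall]
    observed_pairs: list[tuple[str, str]]
    bootstrap: Optional[BootstrapResult]
    shuffle_nulls: dict[str, ShuffleNull]
    summary: dict
    manifest: dict

    def all_selected(self) -> list[PutativeOrtholog]:
        out = []
        for per_species in self.selected.values():
            out.extend(per_species.values())
        out.sort(key=lambda po: (po.linc_id, po.species))
        return out


def run_analysis(
    human: GenomeBundle,
    species: dict[str, GenomeBundle],
    lincs: list[LincRNA],
    orth: OrthologyMap,
    cerna: Optional[CeRNAPairTable] = None,
    params: PipelineParams = PipelineParams(),
    rng_seed: int = 0,
    output_dir: Optional[str] = None,
) -> PipelineResult:
    """Run every stage on loaded data; optionally write report files."""
    scheme = params.scheme()
    ka = ka_params(scheme)
    seed_seq = np.random.SeedSequence(rng_seed)
    boot_seed, shuffle_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                               for s in seed_seq.spawn(2)]

    filtered = filter_lincrnas(lincs, human)
    log.info("lincRNA filter: %d in, %d retained", len(lincs), len(filtered))

    candidates: dict[str, list[OrthologCandidate]] = {}
    selected: dict[str, dict[str, PutativeOrtholog]] = {}
    contexts = {}
    for linc in filtered:
        ctx = neighbor_context(linc, human, params.window_bp)
        contexts[linc.linc_id] = ctx
        linc_cands: list[OrthologCandidate] = []
        for sp in sorted(species):
            linc_cands.extend(find_candidates(
                linc, species[sp], ctx, orth, scheme,
                evalue_cutoff=params.evalue_cutoff,
                window_bp=params.window_bp,
                require_order=params.require_order, ka=ka,
            ))
        candidates[linc.linc_id] = linc_cands
        sel = select_putative_orthologs(linc_cands, params.min_species_support)
        if sel:
            selected[linc.linc_id] = sel
    log.info("selection: %d lincRNAs with putative orthologs",
             len(selected))

    for per_species in selected.values():
        for sp, po in per_species.items():
            bundle = species[sp]
            po.ortholog_class = classify_ortholog(po.region, bundle)
            po.coverage = coverage_profile(po.region, bundle, params.min_te_bp)

    lincs_by_id = {l.linc_id: l for l in filtered}
    origin_calls: dict[str, OriginCall] = {}
    for lid in sorted(selected):
        origin_calls[lid] = call_origin(
            lincs_by_id[lid], selected[lid], species, orth, human, scheme,
            evalue_cutoff=params.evalue_cutoff,
            juxtaposition_bp=params.juxtaposition_bp, ka=ka,
        )

    observed_pairs = sorted(
        (lid, g) for lid, call in origin_calls.items()
        for g in call.human_paralogs
    )
    bootstrap = None
    if cerna is not None and observed_pairs:
        coding = sorted(g.gene_id for g in human.genes if g.is_coding)
        universe = [(l.linc_id, g) for l in filtered for g in coding]
        bootstrap = cerna_bootstrap_p(observed_pairs, cerna, universe,
                                      B=params.B, rng=boot_seed)
        log.info("ceRNA bootstrap: N_obv=%d of %d pairs, p=%.4g",
                 bootstrap.n_obv, bootstrap.n_pairs, bootstrap.p_value)

    shuffle_nulls: dict[str, ShuffleNull] = {}
    if params.shuffle_max_lincs > 0 and params.n_shuffles > 0:
        # mirror the original design: shuffle lincRNAs that do have
        # protein-coding orthologs, most significant first
        ranked = sorted(
            (lid for lid, per in selected.items()
             if any(po.ortholog_class == "protein_coding"
                    for po in per.values())),
        )[: params.shuffle_max_lincs]
        srng = np.random.default_rng(shuffle_seed)
        for lid in ranked:
            windows = []
            ctx = contexts[lid]
            for sp in sorted(species):
                wins = syntenic_windows(ctx, species[sp], orth,
                                        params.window_bp)
                for win in merge_intervals([w for w, _ in wins]):
                    windows.append((species[sp], win))
            shuffle_nulls[lid] = shuffle_null_distribution(
                lincs_by_id[lid], windows, scheme,
                n_shuffles=params.n_shuffles,
                rng=srng, evalue_threshold=params.evalue_cutoff, ka=ka,
            )

    summary = _summarize(lincs, filtered, candidates, selected, origin_calls,
                         bootstrap, shuffle_nulls, species)
    manifest = {
        "tool": "syntelinc",
        "version": __version__,
        "rng_seed": rng_seed,
        "parameters": asdict(params),
        "n_species": len(species),
        "species": sorted(species),
    }

    result = PipelineResult(
        filtered_lincs=filtered,
        n_input_lincs=len(lincs),
        candidates=candidates,
        selected=selected,
        origin_calls=origin_calls,
        observed_pairs=observed_pairs,
        bootstrap=bootstrap,
        shuffle_nulls=shuffle_nulls,
        summary=summary,
        manifest=manifest,
    )
    if output_dir is not None:
        write_report(result, output_dir)
    return result


def _summarize(lincs, filtered, candidates, selected, origin_calls,
               bootstrap, shuffle_nulls, species) -> dict:
    per_species_class: dict[str, dict[str, int]] = {
        sp: {"intergenic": 0, "protein_coding": 0, "non_coding": 0}
        for sp in species
    }
    label_counts = {"exonic": 0, "intronic": 0, "mixed": 0}
    for per in selected.values():
        for sp, po in per.items():
            per_species_class[sp][po.ortholog_class] += 1
            if po.ortholog_class == "protein_coding":
                label_counts[po.coverage.structural_label] += 1
    hyp_counts: dict[str, int] = {}
    for call in origin_calls.values():
        hyp_counts[call.hypothesis] = hyp_counts.get(call.hypothesis, 0) + 1
    return {
        "n_input_lincs": len(lincs),
        "n_filtered_lincs": len(filtered),
        "n_candidates": sum(len(c) for c in candidates.values()),
        "n_lincs_with_orthologs": len(selected),
        "n_selected_orthologs": sum(len(per) for per in selected.values()),
        "class_counts_per_species": per_species_class,
        "coding_ortholog_labels": label_counts,
        "hypothesis_counts": hyp_counts,
        "bootstrap_p": bootstrap.p_value if bootstrap else None,
        "bootstrap_n_obv": bootstrap.n_obv if bootstrap else None,
        "shuffle_hits_below_cutoff": {
            lid: sn.n_below_threshold for lid, sn in shuffle_nulls.items()
        },
    }


def write_report(result: PipelineResult, output_dir) -> dict:
    """Write the TSV/JSON report bundle; returns the path manifest."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["orthologs"] = str(outdir / "orthologs.tsv")
    write_ortholog_table(result.all_selected(), paths["orthologs"])

    rows = []
    for lid in sorted(result.candidates):
        sel = result.selected.get(lid, {})
        for c in result.candidates[lid]:
            po = sel.get(c.species)
            is_sel = (po is not None
                      and po.region == c.hit.subject_interval)
            rows.append({
                "linc_id": lid, "species": c.species,
                "chrom": c.hit.subject_interval.chrom,
                "start": c.hit.subject_interval.start,
                "end": c.hit.subject_interval.end,
                "evalue": f"{c.hit.evalue:.3e}",
                "anchor_u": c.anchor_pair[0], "anchor_d": c.anchor_pair[1],
                "species_support": c.species_support,
                "selected": int(is_sel),
            })
    pd.DataFrame(rows, columns=[
        "linc_id", "species", "chrom", "start", "end", "evalue",
        "anchor_u", "anchor_d", "species_support", "selected",
    ]).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    paths["candidates"] = str(outdir / "candidates.tsv")

    rows = []
    for lid in sorted(result.origin_calls):
        call = result.origin_calls[lid]
        rows.append({
            "linc_id": lid,
            "relation": call.pseudogene_relation,
            "nearest_pseudogene": call.nearest_pseudogene[0]
            if call.nearest_pseudogene else "",
            "distance": call.nearest_pseudogene[1]
            if call.nearest_pseudogene else "",
            "aligned_proteins": ";".join(
                f"{sp}:{g}" for sp, g in call.aligned_proteins),
            "paralogs": ";".join(call.human_paralogs),
            "hypothesis": call.hypothesis,
        })
    pd.DataFrame(rows, columns=[
        "linc_id", "relation", "nearest_pseudogene", "distance",
        "aligned_proteins", "paralogs", "hypothesis",
    ]).to_csv(outdir / "origin_calls.tsv", sep="\t", index=False)
    paths["origin_calls"] = str(outdir / "origin_calls.tsv")

    if result.bootstrap is not None:
        with open(outdir / "bootstrap.json", "w") as fh:
            b = result.bootstrap
            json.dump({
                "N_obv": b.n_obv, "n_pairs": b.n_pairs, "B": b.B,
                "p_value": b.p_value, "add_one": b.add_one,
                "rng_seed": b.rng_seed,
            }, fh, indent=1)
        paths["bootstrap"] = str(outdir / "bootstrap.json")

    if result.shuffle_nulls:
        rows = [{
            "linc_id": lid,
            "n_shuffles": sn.n_shuffles,
            "n_below_threshold": sn.n_below_threshold,
            "min_best_evalue": min(sn.best_evalues),
        } for lid, sn in sorted(result.shuffle_nulls.items())]
        pd.DataFrame(rows).to_csv(outdir / "shuffle_null.tsv", sep="\t",
                                  index=False)
        paths["shuffle_null"] = str(outdir / "shuffle_null.tsv")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
    paths["summary"] = str(outdir / "summary.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = str(outdir / "manifest.json")
    return paths


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Load all inputs named in the config and run the analysis."""
    human = read_genome_bundle(cfg.human_fasta, cfg.human_genes,
                               cfg.human_repeats or None, species="human")
    species = {}
    for sp, entry in sorted(cfg.species_inputs.items()):
        species[sp] = read_genome_bundle(
            entry["fasta"], entry["genes"], entry.get("repeats"), species=sp)
    lincs = read_lincrnas(cfg.lincrna_gff, cfg.lincrna_cdna)
    orth = read_orthology_tsv(cfg.orthology)
    cerna = read_cerna_tsv(cfg.cerna) if cfg.cerna else None
    return run_analysis(human, species, lincs, orth, cerna, cfg.params,
                        cfg.rng_seed, cfg.output_dir)
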