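# syntelinc

Synteny-constrained homology search and origin classification for human
long intergenic non-coding RNAs (lincRNAs).

## The problem

Human lincRNAs (>200 nt, located between protein-coding genes) can arise
by three routes: de novo from intergenic sequence (often via transposable
elements), by duplication of other long non-coding RNAs, or by
**pseudogenization** of a protein-coding gene — the route this package is
built to detect. Because lincRNA sequences diverge quickly, a naive
similarity search is unreliable; the method here constrains every match
by **synteny**: a region in another species only counts as a *putative
ortholog* of a lincRNA if it is flanked by the orthologs of the
lincRNA's own neighbouring protein-coding genes (one upstream, one
downstream, each within ±750 kb by default).

The pipeline, for each lincRNA and each target species:

1. **Aligns** the spliced cDNA to the syntenic windows with a
   blastn-like seed-and-extend local aligner (word size 7, match +1,
   mismatch −1), keeping hits with Karlin–Altschul E-value
   `E = K·m·n·e^(−λS) < 10⁻¹⁰`.
2. **Selects** at most one putative ortholog per species: candidate loci
   (keyed by their flanking anchor pair) seen in only one species are
   discarded; per species the locus with the widest cross-species
   support wins, ties broken by lowest E-value.
3. **Classifies** each ortholog by overlapping annotation
   (protein-coding > non-coding > intergenic) and computes its
   exon/intron/intergenic coverage — a region is an *exonic ortholog*
   iff exon coverage = 100%, an *intronic ortholog* iff intron
   coverage = 100% — plus its transposable-element coverage (TE-derived
   iff > 10 bp of RepeatMasker-annotated TE).
4. **Types the pseudogenization scenario** of lincRNAs with TE-free
   exonic orthologs: *unitary* (the aligned proteins have no human
   ortholog and the lincRNA overlaps/neighbours an annotated human
   pseudogene) vs *duplicated* (a human *putative paralog* of the
   aligned proteins still aligns to the lincRNA at E < 10⁻¹⁰).
5. **Tests enrichment** of known ceRNA (competing endogenous RNA) pairs
   among the lincRNA–paralog pairs with a bootstrap:
   `P = (1/B) Σ_k I(N_k > N_obv)` over B = 10,000 resamples, and guards
   all homology calls with a dinucleotide-preserving shuffle null
   (Altschul–Erickson Eulerian-walk shuffle, 5000 shuffles at full
   scale).

Because the full Ensembl-scale inputs are not required, the package
ships a **synthetic comparative-genome generator** (`syntelinc.simulate`)
that plants homologs in exonic/intronic/intergenic/non-coding contexts,
TE insertions, and unitary/duplicated pseudogene scenarios across
multiple species with machine-readable ground truth, so every stage is
verifiable end to end.

## Worked example

```bash
syntelinc simulate --seed 3 --n-species 2 --lincs-per-scenario 1 \
    --outdir sim
syntelinc run sim/pipeline_config.yaml
```

The second command prints the run summary (numbers from this exact
invocation):

```json
{
 "bootstrap_n_obv": 0,
 "bootstrap_p": 0.281,
 "class_counts_per_species": {
  "sp1": {"intergenic": 1, "non_coding": 1, "protein_coding": 4},
  "sp2": {"intergenic": 1, "non_coding": 1, "protein_coding": 4}
 },
 "coding_ortholog_labels": {"exonic": 6, "intronic": 2, "mixed": 0},
 "hypothesis_counts": {
  "duplicated_candidate": 1, "unclassified": 4, "unitary_candidate": 1
 },
 "n_candidates": 12,
 "n_filtered_lincs": 7,
 "n_input_lincs": 7,
 "n_lincs_with_orthologs": 6,
 "n_selected_orthologs": 12,
 "shuffle_hits_below_cutoff": {}
}
```

Reading it: of 7 simulated lincRNAs (one per scenario), the one with no
planted homolog is correctly never selected; the other six each get one
putative ortholog per species at the planted locus. Orthologs landing in
host-gene exons are labelled exonic, the intron plant intronic. The
lincRNA whose aligned proteins have a human paralog is typed
`duplicated_candidate`; the one overlapping a human pseudogene with no
paralog is `unitary_candidate`. The single observed lincRNA–paralog
pair happens not to be in this small simulated ceRNA table (N_obv = 0),
so the bootstrap enrichment p-value is unremarkable (0.281) — at larger
simulated scales, where several planted pairs are annotated, the same
test returns p ≈ 0. Full per-ortholog detail is written to
`sim/results/orthologs.tsv`, `candidates.tsv` and `origin_calls.tsv`.

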