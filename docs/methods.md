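# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `syntelinc`.

## Coordinates and annotation model

All internal coordinates are 0-based half-open; GFF3 and RepeatMasker
`.out` (1-based inclusive) and BED (0-based half-open) are converted at
the I/O boundary only. Genes are isoform-collapsed: a gene is its
per-gene exon union, its span the min-start/max-end of the exons.
Overlap everywhere in the pipeline (filtering, classification,
pseudogene relation) is strand-blind, because transcription from either
strand of a conserved region is evidence of the same underlying
sequence relationship. The lincRNA pre-filter removes any lincRNA whose
span shares ≥1 bp with a protein-coding gene *span* (not exons only):
with spans, an intronic lincRNA is excluded from the analysis rather
than risking self-matches against its host gene's locus.

## Local alignment and significance

The aligner is a blastn-style seed-and-extend search parameterised for
short, diverged matches: exact 7-mer seeds on both strands, ungapped
X-drop extension (X = 20), then a banded affine-gap (Gotoh) extension
(band of 31 diagonals centred on the seed diagonal) for ungapped
segments scoring ≥ 25. Scoring defaults to match +1 / mismatch −1; gap
costs are open 2 / extend 1 (a gap of length g costs 2 + g), chosen to
approximate common blastn behaviour for ±1 scoring; both are
configurable. `N` never matches; other IUPAC ambiguity codes are
rejected at parse time. Overlapping hits are merged keeping the maximum
score. The test suite verifies the search recovers the exact
Smith–Waterman optimum (independent DP implementation) on random pairs
with planted shared blocks.

Significance uses ungapped Karlin–Altschul statistics,
`E = K·m·n·e^(−λS)` with m the query length and n the searched window
length. λ is the unique positive root of
`Σ_ij p_i p_j e^{λ s_ij} = 1`, solved by bracketed root-finding to
10⁻⁹ residual (for +1/−1 at uniform frequencies the closed form is
λ = ln 3). K is estimated by simulation: all diagonals of a random
pair comparison are i.i.d. score walks, so maximal Karlin excursions
are counted across simulated walks and fitted to the exceedance model;
finite-length diagonals bias K slightly low, and agreement within a
factor of 2 is the documented contract. Two deliberate approximations:
the ungapped (λ, K) pair is reused for gapped scores, and the
finite-size edge correction to the search space is omitted (windows are
much longer than queries). Both are harmless here because every
downstream decision thresholds at E < 10⁻¹⁰ — at these window sizes
that requires raw scores near 40 while random best scores hover near
15, so order-unity errors in K cannot flip a call. The suite's
calibration check (1000 random length-500 pairs, zero hits below
10⁻¹⁰) and the shuffle null confirm this margin empirically.

## Synteny constraint and selection

Neighbour context: protein-coding genes whose span midpoint lies within
`window_bp` (default 750,000 bp) of the lincRNA's span boundary, per
side, ordered nearest first; all qualifying genes are considered, not
just the closest. For each (upstream u, downstream d) pair whose
orthologs land on one target chromosome within `2·window_bp` of each
other, the search window spans the two orthologs extended by
`window_bp` each side. A hit becomes a candidate when at least one
anchor pair *flanks* it — one anchor ortholog entirely on each side,
each within `window_bp` boundary-to-boundary. Preserving the human
left/right order of the anchors is not required by default (a strict
mode exists) since inversions should not disqualify otherwise-conserved
loci.

Selection applies the cascade: candidates sharing an anchor pair across
species form one locus group; groups supported by a single species are
dropped (`min_species_support` = 2); per species the candidate from the
most-supported group wins; ties break by lowest E-value, then smallest
(chrom, start) for determinism. The anchor pair is the only
species-independent key available to identify "the same locus" across
genomes, which is why groups are keyed by it.

## Classification and coverage

Class precedence is protein_coding > non_coding > intergenic on ≥1 bp
overlap. Pseudogene-biotype annotations trigger neither protein-coding
nor non-coding classification — they are consumed only by the
origin-typing stage on the human side — keeping the three classes
mutually exclusive. Coverage is computed in integer bp (exon union
across all overlapping coding genes; intronic = genic minus exonic) and
divided by the region length once, so the ternary partition is exact by
construction; *exonic*/*intronic* labels require exactly 100% coverage.
TE coverage counts repeat classes other than Simple_repeat,
Low_complexity and Satellite; a region is TE-derived only when strictly
more than 10 bp are TE-covered. When several introns contribute, the
aggregate intronic TE figure is bp-weighted.

## Pseudogenization typing

Eligible lincRNAs are those with at least one exonic ortholog and no
TE-derived signal in any exonic ortholog. *Aligned proteins* are the
coding genes overlapped by protein-coding orthologs. *Putative
paralogs* are human orthologs of aligned proteins whose spliced exonic
sequence aligns to the lincRNA cDNA below the E-value cutoff
(spliced-vs-spliced nucleotide comparison: the lincRNA cDNA is itself
spliced, and a nucleotide test matches the ceRNA framing downstream).
The pseudogene relation is overlap (≥1 bp), juxtaposed (nearest
boundary ≤ `juxtaposition_bp`, default 10,000 bp — "juxtaposed" has no
standard definition, so the radius is configurable and the synthetic
configs scale it down with their genomes), else none. Hypotheses:
paralogs present → duplicated_candidate; no paralogs but an
overlapping/juxtaposed pseudogene → unitary_candidate; otherwise
unclassified. The three outcomes are exhaustive and mutually exclusive
over eligible lincRNAs.

## Resampling statistics

The dinucleotide-preserving shuffle is the Altschul–Erickson
Eulerian-walk construction: a uniform random last-edge arborescence
toward the final base (rejection-sampled) plus uniform permutation of
the remaining edge multiset yields a uniform sample over all sequences
with identical dinucleotide counts (hence identical mononucleotide
counts and first/last base). Uniformity is verified against exhaustive
enumeration. Sequences containing N are split at N runs and each
segment shuffled independently — a documented deviation needed because
the Eulerian construction is defined on the ACGT alphabet. The shuffle
null realigns each shuffle to the lincRNA's syntenic windows and
records the best E-value (+∞ when no hit).

The ceRNA bootstrap draws `n = |observed pairs|` pairs uniformly *with
replacement* (standard bootstrap; sampling without replacement is the
other defensible reading) from the universe of all (lincRNA,
protein-coding gene) pairs constructible from the loaded annotation,
and reports `P = (1/B)·#{k: N_k > N_obv}` with the strict inequality.
Because the strict estimator can return exactly 0, a conservative
add-one estimator `(1+#exceed)/(1+B)` is available behind a flag. The
null-count distribution is binomial when the universe is homogeneous,
which the tests exploit as a closed-form oracle.

## Synthetic data: what it emulates, and what it does not

The generator lays out a human chromosome of spaced multi-exon coding
genes with lincRNAs in inter-gene gaps, and target-species chromosomes
with the same gene order (so synteny anchors exist by construction);
per-slot orthology edges connect all species. Scenario plants are
described in the module docstring; planted copies are mutated at the
per-species divergence under a uniform (Jukes–Cantor-like) substitution
model, optionally with small indels. Homolog copies keep homology-free
margins (~40 bp) inside their annotation stratum so that alignment
creep beyond the planted sequence cannot cross a stratum boundary.

Default study conditions (chosen once): 3 target species at 5%
divergence, five lincRNAs per scenario, 500 bp lincRNAs, ~1.2 Mb
chromosomes. The synteny window is scaled to 50 kb and the juxtaposition
radius to 4 kb to match the compact gene spacing — these play the roles
the 750 kb / 10 kb values play at full genome scale. Planted TE
densities inside intronic (0.32) and exonic (0.07) homologs mirror the
TE-coverage levels characteristic of real intronic/exonic conserved
regions; pseudogene-scenario hosts carry no TEs so the origin-typing
eligibility rule is exercised. TE annotations are written exactly where
planted (a perfect RepeatMasker stand-in, since running RepeatMasker is
out of scope); background insertions are real mutated consensus copies.

What the simulation does **not** model — and hence what passing tests do
not establish about real data: realistic TE/indel evolutionary dynamics,
rate heterogeneity, rearrangements breaking synteny, assembly gaps,
incomplete or erroneous annotation, and isoform complexity. Recovery
rates measured here are upper bounds for annotation-limited real inputs.

## Numerical and degenerate-input choices

Root-finding brackets λ in (0, c/match_reward·2^k]; E-values are exact
floats of `K·m·n·e^{−λS}`. Alignment reporting floor is raw score 15
(far below any decision threshold) to bound hit-list sizes. Empty
sequences or windows yield empty hit lists; a lincRNA with no neighbour
genes simply can never gain candidates; `n_shuffles = 0` and an empty
bootstrap universe are errors. Selection ties are broken
lexicographically so reruns are byte-identical; every stochastic stage
takes an explicit seed and the pipeline derives per-stage seeds from
one master seed.

## Problem sizes used in verification

The shipped tests and the acceptance script run the 3-species / 5%
divergence / 5-per-scenario dataset, 200-replicate shuffle nulls on two
lincRNAs, B = 10,000 bootstraps, and K-estimation at a few thousand
simulated pairs — sizes chosen so the full suite completes comfortably
on a single CPU while leaving every statistical check well-powered.
The full-scale parameters (750 kb windows, 5000 shuffles) remain the
defaults of the public API.

## Known limitations

* Gapped E-values reuse ungapped (λ, K); do not compare E-values
  digit-for-digit with NCBI BLAST (decisions are threshold-based).
* Anchor-pair grouping treats loci with different nearest anchors as
  different loci; a hit exactly between two alternative anchor pairs in
  different species could fail to group. Not observed under the study
  conditions.
* The paralog test is nucleotide spliced-vs-spliced; a protein-level
  test might differ for ancient duplications.
* `dust`-style low-complexity masking is not implemented; the synthetic
  genomes are not low-complexity-rich, real genomes are.
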