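"""Resampling procedures: the dinucleotide-preserving shuffle null for
homology calls and the bootstrap enrichment test for ceRNA pairs.

The shuffle null guards against composition artefacts: each lincRNA
cDNA is shuffled preserving its exact dinucleotide counts (Eulerian-walk
construction) and re-aligned to its syntenic windows; a real homolog
keeps its significant hit while shuffles should yield none below the
cutoff.

The ceRNA test asks whether known competing-endogenous-RNA pairs are
enriched among the identified lincRNA-paralog pairs: ``B`` bootstrap
replicates draw the same number of (lincRNA, coding gene) pairs with
replacement from a universe and the p-value is the fraction of
replicates with strictly more known pairs than observed,
``P = (1/B) * #{k : N_k > N_obv}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .align import KAParams, ScoringScheme, ka_params, local_align
from .core import CeRNAPairTable, GenomeBundle, GenomicInterval, LincRNA

RngLike = Union[int, np.random.Generator, None]


def _as_rng(rng: RngLike) -> tuple[np.random.Generator, Optional[int]]:
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng)), int(rng)
    return np.random.default_rng(rng), None


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle


def dinuc_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def dinuc_shuffle(seq: str, rng: RngLike = None) -> str:
    """Uniform random sequence with the same dinucleotide counts as ``seq``.

    Altschul-Erickson Eulerian-walk construction: the sequence is an
    Eulerian path in the multigraph of adjacent base pairs; a uniform
    random last-edge arborescence towards the final base (rejection
    sampled) plus uniform permutation of the remaining edges yields a
    uniform random Eulerian path, hence a uniform valid shuffle.
    Preserves mononucleotide counts and the first/last base.  Sequences
    containing N are rejected; see :func:`dinuc_shuffle_masked`.
    """
    rng, _ = _as_rng(rng)
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("need length >= 2 to shuffle dinucleotides")
    if set(seq) - set("ACGT"):
        raise ValueError("dinuc_shuffle requires an N-free ACGT sequence; "
                         "split at N runs first (dinuc_shuffle_masked)")
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, final = seq[0], seq[-1]
    non_terminal = [v for v in edges if v != final]

    last_edge: dict[str, str] = {}
    if non_terminal:
        while True:
            last_edge = {
                v: edges[v][int(rng.integers(len(edges[v])))]
                for v in non_terminal
            }
            if all(_reaches(v, final, last_edge) for v in non_terminal):
                break

    out_lists: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        tail: list[str] = []
        if v in last_edge:
            rest.remove(last_edge[v])
            tail = [last_edge[v]]
        perm = [rest[i] for i in rng.permutation(len(rest))] if rest else []
        out_lists[v] = perm + tail

    out = [first]
    idx = {v: 0 for v in out_lists}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = out_lists[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _reaches(v: str, final: str, last_edge: dict[str, str]) -> bool:
    seen = set()
    while v != final:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


def dinuc_shuffle_masked(seq: str, rng: RngLike = None) -> str:
    """Dinucleotide shuffle tolerating Ns: maximal N-free segments are
    shuffled independently and re-concatenated around the N runs."""
    rng, _ = _as_rng(rng)
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            out.append(seq[i:j])
            i = j
        else:
            j = i
            while j < n and seq[j] != "N":
                j += 1
            segment = seq[i:j]
            out.append(dinuc_shuffle(segment, rng) if len(segment) >= 2
                       else segment)
            i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# shuffle null for homology calls


@dataclass
class ShuffleNull:
    """Null distribution of best alignment E-values over shuffled cDNAs."""

    linc_id: str
    n_shuffles: int
    best_evalues: list[float]
    evalue_threshold: float = 1e-10
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.best_evalues) != self.n_shuffles:
            raise ValueError("need one best E-value per shuffle")

    @property
    def exceedance(self) -> float:
        """Fraction of shuffles whose best E-value beats the threshold."""
        return sum(e < self.evalue_threshold for e in self.best_evalues) \
            / self.n_shuffles

    @property
    def n_below_threshold(self) -> int:
        return sum(e < self.evalue_threshold for e in self.best_evalues)


def best_window_evalue(
    seq: str,
    windows: Sequence[tuple[GenomeBundle, GenomicInterval]],
    scheme: ScoringScheme = ScoringScheme(),
    *,
    query_id: str = "query",
    ka: Optional[KAParams] = None,
) -> float:
    """Minimum E-value of ``seq`` against the windows; +inf with no hit."""
    if ka is None:
        ka = ka_params(scheme)
    best = math.inf
    for bundle, win in windows:
        hits = local_align(seq, bundle.fetch(win), scheme, query_id=query_id,
                           chrom=win.chrom, offset=win.start, ka=ka,
                           search_space_n=len(win))
        if hits:
            best = min(best, hits[0].evalue)
    return best


def shuffle_null_distribution(
    linc: LincRNA,
    windows: Sequence[tuple[GenomeBundle, GenomicInterval]],
    scheme: ScoringScheme = ScoringScheme(),
    n_shuffles: int = 5000,
    rng: RngLike = None,
    *,
    evalue_threshold: float = 1e-10,
    ka: Optional[KAParams] = None,
) -> ShuffleNull:
    """Align dinucleotide-preserving shuffles of a lincRNA cDNA to its
    syntenic windows, recording each shuffle's best E-value.

    With no windows every best E-value is +inf.  Fixing the seed makes
    the result fully reproducible.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng, seed = _as_rng(rng)
    if ka is None:
        ka = ka_params(scheme)
    best_evalues = []
    for _ in range(n_shuffles):
        shuffled = dinuc_shuffle_masked(linc.cdna, rng)
        best_evalues.append(best_window_evalue(
            shuffled, windows, scheme, query_id=linc.linc_id, ka=ka))
    return ShuffleNull(
        linc_id=linc.linc_id, n_shuffles=n_shuffles,
        best_evalues=best_evalues, evalue_threshold=evalue_threshold,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# ceRNA bootstrap


@dataclass
class BootstrapResult:
    """Bootstrap enrichment test of observed pairs against a known set."""

    n_obv: int
    n_pairs: int
    B: int
    null_counts: list[int]
    p_value: float
    add_one: bool = False
    rng_seed: Optional[int] = None


def cerna_bootstrap_p(
    observed_pairs: Iterable[tuple[str, str]],
    cerna: CeRNAPairTable,
    universe: Sequence[tuple[str, str]],
    B: int = 10_000,
    rng: RngLike = None,
    *,
    add_one: bool = False,
) -> BootstrapResult:
    """Bootstrap p-value for enrichment of known ceRNA pairs.

    ``N_obv`` counts observed pairs present in the known table; each of
    ``B`` replicates draws ``n = len(observed_pairs)`` pairs uniformly
    with replacement from ``universe`` and counts known pairs the same
    way.  The p-value uses the strict indicator ``N_k > N_obv``; with
    ``add_one=True`` the conservative ``(1 + #exceed) / (1 + B)``
    estimator is reported instead (the strict version can return
    exactly 0).
    """
    observed = list(observed_pairs)
    if not observed:
        raise ValueError("need at least one observed pair")
    if not len(universe):
        raise ValueError("universe must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng, seed = _as_rng(rng)
    n = len(observed)
    n_obv = sum(1 for p in observed if p in cerna)
    is_cerna = np.fromiter((p in cerna for p in universe), dtype=bool,
                           count=len(universe))
    idx = rng.integers(0, len(universe), size=(B, n))
    null_counts = is_cerna[idx].sum(axis=1).astype(int)
    n_exceed = int((null_counts > n_obv).sum())
    p = (1 + n_exceed) / (1 + B) if add_one else n_exceed / B
    return BootstrapResult(
        n_obv=n_obv, n_pairs=n, B=B, null_counts=null_counts.tolist(),
        p_value=p, add_one=add_one, rng_seed=seed,
    )
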