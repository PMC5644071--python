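"""Aligner unit tests: Karlin-Altschul statistics, seed-and-extend
correctness against an independent DP, and E-value behaviour."""

import math

import numpy as np
import pytest

from syntelinc.align import (
    KAParams,
    ScoringScheme,
    estimate_ka_K,
    ka_params,
    local_align,
    revcomp,
    search_windows,
    solve_ka_lambda,
)
from syntelinc.core import GenomeBundle, GenomicInterval, LincRNA

from oracles import sw_best_score


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestKarlinAltschul:
    def test_lambda_plus1_minus1_uniform_is_ln3(self):
        lam = solve_ka_lambda(ScoringScheme(1, -1))
        assert abs(lam - math.log(3)) < 1e-9

    def test_lambda_scale_invariance(self):
        lam2 = solve_ka_lambda(ScoringScheme(2, -2))
        assert abs(lam2 - math.log(3) / 2) < 1e-9

    def test_positive_expected_score_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            solve_ka_lambda(ScoringScheme(1, -1), freqs=(1.0, 0.0, 0.0, 0.0))

    def test_k_positive_and_stable_across_lengths(self):
        k200 = estimate_ka_K(ScoringScheme(), n_pairs=2000, length=200,
                             rng=np.random.default_rng(1))
        k400 = estimate_ka_K(ScoringScheme(), n_pairs=800, length=400,
                             rng=np.random.default_rng(2))
        assert k200 > 0 and k400 > 0
        assert abs(k200 - k400) / k200 < 0.20

    def test_k_fit_reproduces_exceedance_counts(self):
        lam = math.log(3)
        k, scores, tails = estimate_ka_K(
            ScoringScheme(), n_pairs=2000, length=200, lam=lam,
            rng=np.random.default_rng(3), return_counts=True)
        mn = 200.0 * 200.0 * 2000
        for s, obs in zip(scores, tails):
            fitted = k * mn * math.exp(-lam * s)
            # Poisson-scale agreement with slack for finite-length bias
            assert abs(obs - fitted) < 4 * math.sqrt(fitted) + 0.25 * fitted

    def test_evalue_monotonic_in_score_and_search_space(self):
        ka = KAParams(lam=math.log(3), K=0.3)
        e = [ka.evalue(s, 500, 10_000) for s in range(10, 60)]
        assert all(a > b for a, b in zip(e, e[1:]))
        n = [ka.evalue(40, 500, nn) for nn in (1_000, 10_000, 100_000)]
        assert n[0] < n[1] < n[2]


class TestLocalAlign:
    def test_identity_hit_scores_full_length(self):
        rng = np.random.default_rng(0)
        s = rand_seq(rng, 100)
        hits = local_align(s, s)
        assert hits[0].raw_score == 100
        assert hits[0].strand == "+"
        assert (hits[0].subject_interval.start,
                hits[0].subject_interval.end) == (0, 100)
        assert (hits[0].query_start, hits[0].query_end) == (0, 100)

    def test_reverse_complement_hits_minus_strand(self):
        rng = np.random.default_rng(1)
        s = rand_seq(rng, 120)
        hits = local_align(s, revcomp(s))
        assert hits[0].raw_score == 120
        assert hits[0].strand == "-"

    def test_empty_sequences_yield_no_hits(self):
        assert local_align("", "ACGTACGT") == []
        assert local_align("ACGTACGT", "") == []

    def test_symmetry_of_best_score(self):
        rng = np.random.default_rng(2)
        block = rand_seq(rng, 40)
        a = rand_seq(rng, 100) + block + rand_seq(rng, 60)
        b = rand_seq(rng, 30) + block + rand_seq(rng, 150)
        best_ab = max(h.raw_score for h in local_align(a, b))
        best_ba = max(h.raw_score for h in local_align(b, a))
        assert best_ab == best_ba

    def test_n_never_matches(self):
        core = "ACGTACGTACGTACGTACGT"
        hits = local_align(core + "N" * 10 + core,
                           core + "N" * 10 + core)
        # N-N columns score as mismatches, so the best hit cannot reach
        # the full 50 that exact self-identity would give
        assert hits[0].raw_score < 50

    def test_matches_smith_waterman_on_planted_blocks(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            bl = int(rng.integers(30, 50))
            block = rand_seq(rng, bl)
            lq, ls = int(rng.integers(60, 300)), int(rng.integers(60, 300))
            q, s = rand_seq(rng, lq), rand_seq(rng, ls)
            qp = int(rng.integers(0, lq - bl + 1))
            sp = int(rng.integers(0, ls - bl + 1))
            q = q[:qp] + block + q[qp + bl:]
            s = s[:sp] + block + s[sp + bl:]
            got = max((h.raw_score for h in local_align(q, s)), default=0)
            assert got == sw_best_score(q, s)


class TestSearchWindows:
    def _bundle_with_plant(self, rng, plant, at=50_000, total=120_000):
        seq = rand_seq(rng, at) + plant + rand_seq(rng, total - at - len(plant))
        return GenomeBundle("sp", {"chr1": seq})

    def test_no_shared_word_empty(self):
        linc = LincRNA("l", GenomicInterval("chr1", 0, 300), "A" * 300)
        bundle = GenomeBundle("sp", {"chr1": "CG" * 5000})
        win = GenomicInterval("chr1", 0, 10_000)
        assert search_windows(linc, [(bundle, win)]) == []

    def test_planted_diverged_homolog_single_hit_covering_plant(self):
        rng = np.random.default_rng(11)
        plant = rand_seq(rng, 300)
        mutated = list(plant)
        for i in rng.choice(300, size=30, replace=False):  # 90% identity
            mutated[i] = "ACGT"[(("ACGT".index(mutated[i])) + 1) % 4]
        bundle = self._bundle_with_plant(rng, "".join(mutated))
        linc = LincRNA("l", GenomicInterval("chr1", 0, 300), plant)
        win = GenomicInterval("chr1", 0, 120_000)
        hits = search_windows(linc, [(bundle, win)])
        assert len(hits) == 1
        ov = hits[0].subject_interval.overlap_bp(
            GenomicInterval("chr1", 50_000, 50_300))
        assert ov >= 0.8 * 300

    def test_infinite_cutoff_is_superset(self):
        rng = np.random.default_rng(12)
        plant = rand_seq(rng, 250)
        bundle = self._bundle_with_plant(rng, plant)
        linc = LincRNA("l", GenomicInterval("chr1", 0, 250), plant)
        win = GenomicInterval("chr1", 0, 120_000)
        strict = search_windows(linc, [(bundle, win)], evalue_cutoff=1e-10)
        loose = search_windows(linc, [(bundle, win)],
                               evalue_cutoff=math.inf)
        strict_keys = {(h.subject_interval.start, h.subject_interval.end)
                       for h in strict}
        loose_keys = {(h.subject_interval.start, h.subject_interval.end)
                      for h in loose}
        assert strict_keys <= loose_keys
        assert len(strict) == 1


class TestCalibration:
    def test_no_significant_hits_between_random_pairs(self):
        """Random length-500 pairs never reach E < 1e-10 (mirrors the
        shuffle-control expectation qualitatively)."""
        rng = np.random.default_rng(99)
        scheme = ScoringScheme()
        ka = ka_params(scheme)
        n_sig = 0
        for _ in range(1000):
            q, s = rand_seq(rng, 500), rand_seq(rng, 500)
            hits = local_align(q, s, scheme, ka=ka)
            if hits and hits[0].evalue < 1e-10:
                n_sig += 1
        assert n_sig == 0
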