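import numpy as np
import pytest
from scipy import stats

from fpdenovo.footprints import Footprint
from fpdenovo.io_formats import GenomicInterval
from fpdenovo.discovery import (
    DiscoveryParams,
    PoolSequence,
    em_zoops,
    iterative_discovery,
    knee_filter,
    motif_evalue,
    seed_kmers,
    subtract_sites,
)
from fpdenovo.motif_model import motif_distance, uniform_background
from tests.conftest import onehot_motif, strong_motif


def implant_pool(rng, n=200, length=50, kmer="TATAAT"):
    seqs, offsets = [], []
    w = len(kmer)
    for _ in range(n):
        s = "".join(rng.choice(list("ACGT"), length))
        off = int(rng.integers(0, length - w + 1))
        seqs.append(s[:off] + kmer + s[off + w :])
        offsets.append(off)
    return seqs, offsets


class TestSeedKmers:
    def test_implanted_kmer_ranks_first(self, rng):
        seqs, _ = implant_pool(rng, n=100)
        top = seed_kmers(seqs, 6, 3)
        # class representative is the lexicographically smaller of kmer/RC
        assert top[0] in ("ATTATA", "TATAAT")

    def test_random_pool_no_extreme_seed(self, rng):
        # no planted signal: top z-scores stay moderate; assert via counts
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(150)]
        top = seed_kmers(seqs, 6, 1)
        assert len(top) == 1  # well-defined output even without signal

    def test_sequences_shorter_than_w(self):
        assert seed_kmers(["ACG", "TT"], 6, 3) == []


class TestEmZoops:
    def test_recovers_implanted_motif(self, rng):
        seqs, offsets = implant_pool(rng, n=200)
        motif, sites = em_zoops(seqs, "TATAAT", 6)
        assert motif.consensus == "TATAAT"
        exact = sum(1 for i, j, s in sites if j == offsets[i] and s == "+")
        assert exact >= 0.95 * len(offsets)

    def test_no_signal_rejected_as_insignificant(self, rng):
        # EM on pure background can still assign windows (overfitting); the
        # description-length e-value must reject the resulting motif
        from fpdenovo.discovery import overfit_corrected_evalue
        from fpdenovo.motif_model import background_from_sequences

        seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(150)]
        motif, sites = em_zoops(seqs, "TATAAT", 6)
        bg = background_from_sequences(seqs)
        e = overfit_corrected_evalue(motif, sites, seqs, bg, 3)
        assert e > 0.05

    def test_signal_accepted_as_significant(self, rng):
        from fpdenovo.discovery import overfit_corrected_evalue
        from fpdenovo.motif_model import background_from_sequences

        seqs, _ = implant_pool(rng, n=150)
        motif, sites = em_zoops(seqs, "TATAAT", 6)
        bg = background_from_sequences(seqs)
        e = overfit_corrected_evalue(motif, sites, seqs, bg, 3)
        assert e < 1e-10

    def test_single_sequence_degenerate(self):
        motif, sites = em_zoops(["TATAAT"], "TATAAT", 6)
        assert motif.nsites == 1
        assert motif.consensus == "TATAAT"
        assert sites == [(0, 0, "+")]

    def test_width_larger_than_sequences(self):
        with pytest.raises(ValueError):
            em_zoops(["ACGT"], "ACGTACGTACGT", 12)

    def test_deterministic(self, rng):
        seqs, _ = implant_pool(rng, n=50)
        m1, s1 = em_zoops(seqs, "TATAAT", 6)
        m2, s2 = em_zoops(seqs, "TATAAT", 6)
        assert np.array_equal(m1.counts, m2.counts) and s1 == s2


class TestMotifEvalue:
    BG = uniform_background()

    def test_zero_sites_returns_tests(self):
        m = onehot_motif("ACGTACGTAC")
        assert motif_evalue(m, 0, 100, self.BG, 30, 50.0) == 30.0

    def test_strong_motif_tiny_evalue(self):
        m = onehot_motif("ACGTACGTAC", nsites=100)  # 10 bp, IC ~ 20 bits
        e = motif_evalue(m, 100, 100, self.BG, 30, 50.0)
        assert e < 1e-50

    def test_expected_count_not_significant(self):
        # site_count at the null expectation gives p around 1/2
        m = onehot_motif("ACGTAC", nsites=100)
        probs = (m.counts + self.BG[:, None]) / (m.nsites + 1)
        ic = float((probs * np.log2(probs / self.BG[:, None])).sum())
        p0 = min(1.0, 2 * (50 - 6 + 1) * 2 ** (-ic))
        assert p0 < 1.0, "fixture requires a non-saturated null probability"
        n = 400
        k = int(n * p0)
        e = motif_evalue(m, k, n, self.BG, 1, 50.0)
        assert 0.2 < e < 0.8

    def test_site_count_exceeds_pool(self):
        with pytest.raises(ValueError):
            motif_evalue(onehot_motif("ACGT"), 5, 4, self.BG, 1, 50.0)

    def test_matches_binomial_tail_oracle(self):
        m = onehot_motif("ACGTACGTAC", nsites=40)
        probs = (m.counts + self.BG[:, None]) / (m.nsites + 1)
        ic = float((probs * np.log2(probs / self.BG[:, None])).sum())
        p0 = min(1.0, 2 * (30 - 10 + 1) * 2 ** (-ic))
        expected = stats.binom.sf(4, 50, p0) * 7
        assert motif_evalue(m, 5, 50, self.BG, 7, 30.0) == pytest.approx(expected)


class TestKneeFilter:
    def test_bimodal_example(self):
        e = [1e-50, 1e-48, 1e-45, 1e-3, 0.5, 2, 10]
        assert knee_filter(e, 0.05) == [0, 1, 2]

    def test_all_insignificant(self):
        assert knee_filter([10.0] * 5, 0.05) == []

    def test_single_value_fallback(self):
        assert knee_filter([1e-10], 0.05) == [0]
        assert knee_filter([0.5], 0.05) == []

    def test_order_independence(self):
        e = [0.5, 1e-50, 10, 1e-48, 2, 1e-45, 1e-3]
        sig = knee_filter(e, 0.05)
        assert sorted(e[i] for i in sig) == [1e-50, 1e-48, 1e-45]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            knee_filter([], 0.05)


class TestSubtractSites:
    def _pool(self):
        return [PoolSequence("c", 100, 130, "A" * 30)]

    def test_two_fragments(self):
        out = subtract_sites(self._pool(), [(0, 10, 16)], 8)
        assert [(p.start, p.end) for p in out] == [(100, 110), (116, 130)]
        assert [len(p.seq) for p in out] == [10, 14]

    def test_site_spanning_whole_sequence(self):
        assert subtract_sites(self._pool(), [(0, 0, 30)], 8) == []

    def test_min_fragment_size(self):
        out = subtract_sites(self._pool(), [(0, 10, 16)], 12)
        assert [(p.start, p.end) for p in out] == [(116, 130)]

    def test_untouched_pass_through(self):
        pool = self._pool() + [PoolSequence("c", 200, 220, "C" * 20)]
        out = subtract_sites(pool, [(0, 0, 30)], 8)
        assert out == [pool[1]]

    def test_out_of_bounds_site(self):
        with pytest.raises(ValueError):
            subtract_sites(self._pool(), [(0, 25, 35)], 8)


def _fixture_run(rng_seed=1, n_sites=120, motif_seeds=(0, 2), genome_kb=40):
    from fpdenovo.synthetic import implant_motifs, make_fp_track, make_genome
    from fpdenovo.footprints import (
        FootprintParams,
        call_footprints,
        filter_by_size,
        merge_footprints,
    )

    truths = [strong_motif(f"t{i}", 10, s) for i, s in enumerate(motif_seeds)]
    genome = make_genome(genome_kb * 1000, 0.5, rng_seed)
    genome, truth = implant_motifs(
        genome, truths, counts=[n_sites // len(truths)] * len(truths),
        rng_seed=rng_seed + 1,
    )
    track = make_fp_track({c: len(s) for c, s in genome.items()}, truth.sites)
    fps = filter_by_size(
        merge_footprints(
            call_footprints(track, FootprintParams()), track, 6, 0.5
        ),
        8,
    )
    return truths, genome, fps


class TestIterativeDiscovery:
    def test_empty_footprints_error(self):
        with pytest.raises(ValueError):
            iterative_discovery([], {}, DiscoveryParams())

    def test_recovers_implanted_motifs(self):
        truths, genome, fps = _fixture_run()
        params = DiscoveryParams(
            motif_width_range=(9, 11), seeds_per_iteration=2, max_iterations=6,
            rng_seed=3,
        )
        result = iterative_discovery(fps, genome, params)
        for t in truths:
            assert min(motif_distance(c, t) for c in result.consensus) < 0.4

    def test_pool_strictly_shrinks_on_significant_iterations(self):
        truths, genome, fps = _fixture_run()
        params = DiscoveryParams(
            motif_width_range=(9, 11), seeds_per_iteration=2, max_iterations=6,
            rng_seed=3,
        )
        result = iterative_discovery(fps, genome, params)
        bps = result.pool_bps
        assert all(b <= a for a, b in zip(bps, bps[1:]))
        for rec in result.iterations:
            if any(rec.significant):
                # strict progress in total bp whenever something was subtracted
                assert bps[rec.index + 1] < bps[rec.index]

    def test_subtracted_sites_never_reappear(self):
        truths, genome, fps = _fixture_run()
        params = DiscoveryParams(
            motif_width_range=(10, 10), seeds_per_iteration=1, max_iterations=4,
            rng_seed=3,
        )
        result = iterative_discovery(fps, genome, params)
        # pool coordinates of later iterations must avoid earlier site spans
        claimed = [
            (iv.chrom, iv.start, iv.end)
            for sites in result.sites.values()
            for iv, _ in sites
        ]
        assert claimed, "fixture produced no significant sites"
        # all claimed spans are unique genomic spans
        assert len(claimed) == len(set(claimed))

    def test_bit_reproducible(self):
        truths, genome, fps = _fixture_run()
        params = DiscoveryParams(
            motif_width_range=(9, 11), seeds_per_iteration=2, max_iterations=4,
            rng_seed=9,
        )
        r1 = iterative_discovery(fps, genome, params)
        r2 = iterative_discovery(fps, genome, params)
        assert len(r1.consensus) == len(r2.consensus)
        for a, b in zip(r1.consensus, r2.consensus):
            assert a.name == b.name and np.array_equal(a.counts, b.counts)

    def test_pure_background_terminates_by_stagnation(self):
        from fpdenovo.synthetic import make_genome

        genome = make_genome(20_000, 0.5, 11)
        rng = np.random.default_rng(4)
        fps = []
        pos = 50
        while pos < 19_000 and len(fps) < 150:
            width = int(rng.integers(15, 25))
            fps.append(
                Footprint(GenomicInterval("chr1", pos, pos + width), 1.0, 1.0, 0)
            )
            pos += width + int(rng.integers(30, 80))
        params = DiscoveryParams(
            motif_width_range=(8, 10), seeds_per_iteration=1, max_iterations=10,
            stagnation_limit=2, rng_seed=5,
        )
        result = iterative_discovery(fps, genome, params)
        assert result.consensus == []
        assert len(result.iterations) < params.max_iterations

    def test_n_sequences_excluded_from_pool(self):
        genome = {"chr1": "ACGT" * 10 + "NNNN" + "ACGT" * 10}
        fps = [
            Footprint(GenomicInterval("chr1", 0, 20), 1.0, 1.0, 0),
            Footprint(GenomicInterval("chr1", 38, 46), 1.0, 1.0, 0),  # spans N
        ]
        from fpdenovo.discovery import build_pool

        pool = build_pool(fps, genome)
        assert len(pool) == 1 and pool[0].start == 0
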