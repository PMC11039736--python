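import math

import numpy as np
import pytest
from scipy import stats

from fpdenovo.io_formats import Feature, GenomicInterval, ScoreTrack
from fpdenovo.motif_model import Motif, MotifHit
from fpdenovo.downstream import (
    aggregate_profile,
    annotate_hits,
    benjamini_hochberg,
    binding_site_overlap,
    compare_to_database,
    genome_scan,
    gsea,
    region_enrichment,
    tf_class_enrichment,
)
from tests.conftest import onehot_motif, random_motif, strong_motif


def make_hit(chrom, start, end, strand="+", name="m"):
    return MotifHit(name, GenomicInterval(chrom, start, end), strand, 10.0)


# exact hypergeometric tail by explicit summation (independent oracle)
def hypergeom_tail_oracle(k, M, K, n):
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(M - K, n - i) / math.comb(M, n)
    return total


class TestGenomeScan:
    def test_planted_positions_recovered(self, rng):
        motif = onehot_motif("TATAATCGGC")
        genome = list("".join(rng.choice(list("GC"), 5000)))
        positions = sorted(rng.choice(np.arange(100, 4800, 20), 10, replace=False))
        for p in positions:
            genome[p : p + 10] = "TATAATCGGC"
        hits = genome_scan(motif, {"c": "".join(genome)}, 1e-4)
        assert sorted(h.interval.start for h in hits) == [int(p) for p in positions]

    def test_empty_genome(self):
        assert genome_scan(onehot_motif("TATAAT"), {}) == []

    def test_reverse_complement_genome_mirrors_hits(self, rng):
        from fpdenovo.io_formats import reverse_complement

        motif = strong_motif("m", 8, 3)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        fwd = genome_scan(motif, {"c": seq}, 1e-3)
        rev = genome_scan(motif, {"c": reverse_complement(seq)}, 1e-3)
        L = len(seq)
        mirrored = sorted((L - h.interval.end, L - h.interval.start) for h in fwd)
        assert mirrored == sorted((h.interval.start, h.interval.end) for h in rev)


class TestRegionEnrichment:
    def test_fold_80(self):
        genome_bp = 100_000
        regions = [GenomicInterval("c", 0, 1000)]  # 1% of genome
        hits = [make_hit("c", i * 10, i * 10 + 5) for i in range(8)]
        hits += [make_hit("c", 50_000 + i * 10, 50_000 + i * 10 + 5) for i in range(2)]
        enr = region_enrichment(hits, regions, genome_bp)
        assert enr.fold == pytest.approx(80.0)
        assert enr.hits_in_regions == 8 and enr.hits_total == 10

    def test_uniform_hits_fold_one(self):
        genome_bp = 100_000
        regions = [GenomicInterval("c", 0, 1000)]
        hits = [make_hit("c", 500, 505)] + [
            make_hit("c", 1000 + i * 990, 1000 + i * 990 + 5) for i in range(99)
        ]
        enr = region_enrichment(hits, regions, genome_bp)
        assert enr.fold == pytest.approx(1.0)
        expected_p = stats.binom.sf(0, 100, 0.01)
        assert enr.p_value == pytest.approx(expected_p)  # ~0.634

    def test_zero_hits_in_regions(self):
        enr = region_enrichment(
            [make_hit("c", 5000, 5006)], [GenomicInterval("c", 0, 100)], 10_000
        )
        assert enr.fold == 0.0 and enr.p_value == 1.0

    def test_no_hits_flagged(self):
        enr = region_enrichment([], [GenomicInterval("c", 0, 100)], 10_000)
        assert enr.undefined and enr.fold == 0.0 and enr.p_value == 1.0

    def test_uniform_simulation_fold_near_one(self, rng):
        genome_bp = 50_000
        regions = [GenomicInterval("c", 10_000, 20_000)]  # 20%
        folds = []
        for _ in range(10):
            starts = rng.integers(0, genome_bp - 6, size=400)
            hits = [make_hit("c", int(s), int(s) + 6) for s in starts]
            folds.append(region_enrichment(hits, regions, genome_bp).fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)


class TestAnnotateHits:
    FEATURES = [
        Feature(GenomicInterval("c", 1500, 2000, "+"), "gene_a"),
        Feature(GenomicInterval("c", 5000, 6000, "+"), "gene_b"),
    ]

    def test_nearest_anchor(self):
        hit = make_hit("c", 995, 1005)  # midpoint 1000
        (rec,) = annotate_hits([hit], self.FEATURES, 2000)
        assert rec.feature_name == "gene_a" and rec.distance == 500

    def test_out_of_range_unannotated(self):
        hit = make_hit("c", 95, 105)
        assert annotate_hits([hit], self.FEATURES, 1000) == []

    def test_tie_breaks_lexicographically(self):
        features = [
            Feature(GenomicInterval("c", 1500, 1600, "+"), "zeta"),
            Feature(GenomicInterval("c", 400, 500, "-"), "alpha"),  # anchor at 500
        ]
        hit = make_hit("c", 995, 1005)  # 500 from both anchors
        (rec,) = annotate_hits([hit], features, 2000)
        assert rec.feature_name == "alpha"

    def test_overlap_distance_zero(self):
        hit = make_hit("c", 1600, 1610)
        (rec,) = annotate_hits([hit], self.FEATURES, 2000)
        assert rec.distance == 0


class TestGsea:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {"S": [f"g{i}" for i in range(10)]}
        genes = {"g0", "g1", "g2", "g50", "g51"}
        ((name, k, fold, p, q),) = gsea(genes, gene_set, universe)
        assert k == 3
        expected = hypergeom_tail_oracle(3, 100, 10, 5)
        assert expected == pytest.approx(0.00664, abs=5e-5)
        assert p == pytest.approx(expected)

    def test_zero_overlap(self):
        universe = {f"g{i}" for i in range(50)}
        result = gsea({"g40"}, {"S": ["g0", "g1"]}, universe)
        assert result[0][3] == 1.0

    def test_query_equals_set_is_most_enriched(self):
        universe = {f"g{i}" for i in range(60)}
        sets = {"full": [f"g{i}" for i in range(5)], "half": ["g0", "g1", "g40", "g41", "g42"]}
        genes = {f"g{i}" for i in range(5)}
        result = {r[0]: r for r in gsea(genes, sets, universe)}
        assert result["full"][3] < result["half"][3]

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            gsea(set(), {}, set())

    def test_genes_outside_universe(self):
        with pytest.raises(ValueError):
            gsea({"x"}, {}, {"y"})

    def test_exactness_small_instances(self, rng):
        for _ in range(10):
            M = int(rng.integers(10, 50))
            K = int(rng.integers(1, M))
            n = int(rng.integers(1, M))
            universe = {f"g{i}" for i in range(M)}
            gene_set = {"S": [f"g{i}" for i in range(K)]}
            genes = set(rng.choice(sorted(universe), n, replace=False))
            ((_, k, _, p, _),) = gsea(genes, gene_set, universe)
            assert p == pytest.approx(hypergeom_tail_oracle(k, M, K, n), abs=1e-12)


class TestBenjaminiHochberg:
    def test_matches_manual(self):
        p = [0.01, 0.04, 0.03, 0.5]
        q = benjamini_hochberg(p)
        assert q[0] == pytest.approx(0.04)
        assert q[3] == pytest.approx(0.5)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(20)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert all(np.diff(q[order]) >= -1e-12)


class TestCompareToDatabase:
    def test_exact_match_rediscovered(self, rng):
        db = [random_motif(8, rng) for _ in range(3)]
        matches, matrix = compare_to_database([db[1]], db)
        assert matches[0].rediscovered
        assert matches[0].distance == pytest.approx(0.0)
        assert matrix.shape == (1, 3)

    def test_novel_label(self):
        consensus = onehot_motif("AAAAAA", name="q")
        db = [onehot_motif("ACGTAC", name="d")]
        matches, _ = compare_to_database([consensus], db)
        assert not matches[0].rediscovered

    def test_boundary_distance_is_novel(self, rng):
        from fpdenovo.motif_model import motif_distance

        q, d = random_motif(8, rng), random_motif(8, rng)
        dist = motif_distance(q, d)
        matches, _ = compare_to_database([q], [d], threshold=dist)
        assert not matches[0].rediscovered  # strict <

    def test_database_order_invariance(self, rng):
        db = [random_motif(7, rng) for _ in range(5)]
        q = [random_motif(7, rng)]
        m1, _ = compare_to_database(q, db)
        m2, _ = compare_to_database(q, list(reversed(db)))
        assert m1[0].distance == pytest.approx(m2[0].distance)
        assert m1[0].rediscovered == m2[0].rediscovered

    def test_empty_database(self):
        with pytest.raises(ValueError):
            compare_to_database([onehot_motif("ACGT")], [])


class TestBindingSiteOverlap:
    def test_identical_sets(self):
        hits = [make_hit("c", i * 20, i * 20 + 6) for i in range(10)]
        assert binding_site_overlap(hits, hits) == 1.0

    def test_disjoint_sets(self):
        a = [make_hit("c", i * 20, i * 20 + 6) for i in range(10)]
        b = [make_hit("c", i * 20 + 10, i * 20 + 16) for i in range(10)]
        assert binding_site_overlap(a, b) == 0.0

    def test_half_overlap(self):
        a = [make_hit("c", i * 30, i * 30 + 6) for i in range(10)]
        b = [make_hit("c", i * 30 + 3, i * 30 + 9) for i in range(5)]
        b += [make_hit("c", 10_000 + i * 30, 10_000 + i * 30 + 6) for i in range(15)]
        # a is the smaller set (10 vs 20); 5 of a's hits overlap b
        assert binding_site_overlap(a, b) == pytest.approx(0.5)

    def test_empty_set(self):
        assert binding_site_overlap([], [make_hit("c", 0, 5)]) == 0.0


class TestTfClassEnrichment:
    def _db(self, rng, n=40, n_classes=4):
        db = []
        for i in range(n):
            m = random_motif(8, rng)
            m.name = f"db{i}"
            m.metadata["class"] = f"class{i % n_classes}"
            db.append(m)
        return db

    def test_fold_arithmetic(self):
        # N=20, n=10, DN=200, dn=20 -> fold 5.0
        assert (10 / 20) / (20 / 200) == pytest.approx(5.0)

    def test_enrichment_of_correlated_class(self, rng):
        db = self._db(rng)
        target_hits = [make_hit("c", i * 50, i * 50 + 8) for i in range(30)]
        db_hits = {}
        for m in db:
            if m.metadata["class"] == "class0":
                db_hits[m.name] = [
                    make_hit("c", h.interval.start, h.interval.end)
                    for h in target_hits
                ]
            else:
                db_hits[m.name] = [make_hit("c", 100_000 + i * 50, 100_000 + i * 50 + 8)
                                   for i in range(30)]
        rows = tf_class_enrichment(target_hits, db, db_hits, percentile=50)
        by_class = {r.tf_class: r for r in rows}
        assert by_class["class0"].fold > 1.0
        assert by_class["class0"].p_value < 0.01
        assert by_class["class0"].n <= by_class["class0"].N <= by_class["class0"].DN
        assert by_class["class0"].n <= by_class["class0"].dn

    def test_hypergeometric_matches_oracle(self, rng):
        db = self._db(rng, n=30, n_classes=3)
        target_hits = [make_hit("c", i * 50, i * 50 + 8) for i in range(10)]
        db_hits = {
            m.name: [make_hit("c", int(p) * 50, int(p) * 50 + 8)
                     for p in rng.integers(0, 40, 10)]
            for m in db
        }
        rows = tf_class_enrichment(target_hits, db, db_hits, percentile=80)
        for r in rows:
            if r.n > 0:
                assert r.p_value == pytest.approx(
                    hypergeom_tail_oracle(r.n, r.DN, r.dn, r.N), abs=1e-12
                )
            else:
                assert r.p_value == 1.0 and r.fold == 0.0

    def test_unclassed_db_empty_result(self, rng):
        db = [random_motif(8, rng)]
        assert tf_class_enrichment([], db, {}, 95) == []


class TestAggregateProfile:
    def test_constant_track_flat_profile(self):
        track = ScoreTrack({"c": np.full(1000, 2.5)})
        hits = [make_hit("c", 200, 210), make_hit("c", 500, 510)]
        profile, n = aggregate_profile(track, hits, 60)
        assert n == 2 and len(profile) == 120
        assert np.allclose(profile, 2.5)

    def test_depletion_shape(self):
        vec = np.ones(2000)
        hits = []
        for start in range(100, 1900, 200):
            mid = start + 5
            vec[mid - 5 : mid + 5] = 0.2
            hits.append(make_hit("c", start, start + 10))
        profile, n = aggregate_profile(ScoreTrack({"c": vec}), hits, 60)
        center = profile[55:65].mean()
        flank = np.concatenate([profile[:20], profile[-20:]]).mean()
        assert np.argmin(profile) in range(55, 65)
        assert center / flank == pytest.approx(0.2, rel=0.01)

    def test_single_hit_equals_window(self, rng):
        vec = rng.random(500)
        track = ScoreTrack({"c": vec})
        hit = make_hit("c", 200, 210)
        profile, n = aggregate_profile(track, [hit], 30)
        mid = hit.interval.midpoint
        assert n == 1
        assert np.array_equal(profile, vec[mid - 30 : mid + 30])

    def test_minus_strand_reversed(self, rng):
        vec = rng.random(500)
        track = ScoreTrack({"c": vec})
        plus, _ = aggregate_profile(track, [make_hit("c", 200, 210, "+")], 30)
        minus, _ = aggregate_profile(track, [make_hit("c", 200, 210, "-")], 30)
        assert np.array_equal(minus, plus[::-1])

    def test_no_inbounds_hits_error(self):
        track = ScoreTrack({"c": np.zeros(50)})
        with pytest.raises(ValueError):
            aggregate_profile(track, [make_hit("c", 0, 10)], 60)
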