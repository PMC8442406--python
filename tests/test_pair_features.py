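import numpy as np
import pytest
from scipy import stats

from conftest import make_hit
from oracles import features_by_enumeration, random_hit_set
from phagelink.genome_similarity import IdentityMatrix
from phagelink.hmm_hits import build_occurrence_index
from phagelink.pair_features import (
    FEATURE_COLUMNS,
    build_feature_table,
    classify_orientation,
    co_occurrence,
    min_pair_distance,
    pair_features,
)


def index_of(*hits):
    return build_occurrence_index(list(hits))


class TestCoOccurrence:
    def test_partial_overlap(self):
        index = index_of(
            *(make_hit("A", g, 1, 9) for g in ("g1", "g2", "g3")),
            *(make_hit("B", g, 1, 9) for g in ("g2", "g3", "g4")),
        )
        assert co_occurrence(index, "A", "B") == 0.5

    def test_identical_sets(self):
        index = index_of(make_hit("A", "g1", 1, 9), make_hit("B", "g1", 20, 29))
        assert co_occurrence(index, "A", "B") == 1.0

    def test_disjoint_sets(self):
        index = index_of(make_hit("A", "g1", 1, 9), make_hit("B", "g2", 1, 9))
        assert co_occurrence(index, "A", "B") == 0.0

    def test_unknown_group_rejected(self):
        index = index_of(make_hit("A", "g1", 1, 9))
        with pytest.raises(ValueError, match="B"):
            co_occurrence(index, "A", "B")


class TestMinPairDistance:
    def test_simple_gap(self):
        d, _, _ = min_pair_distance(
            [make_hit("A", "g", 100, 400)], [make_hit("B", "g", 501, 800)]
        )
        assert d == 100

    def test_overlap_is_zero(self):
        d, _, _ = min_pair_distance(
            [make_hit("A", "g", 100, 400)], [make_hit("B", "g", 350, 600)]
        )
        assert d == 0

    def test_adjacent_is_zero(self):
        d, _, _ = min_pair_distance(
            [make_hit("A", "g", 1, 3)], [make_hit("B", "g", 4, 6)]
        )
        assert d == 0

    def test_argmin_over_cross_pairs(self):
        # both cross pairs have gap 99; tie goes to the smallest (start_a, start_b)
        hits_a = [make_hit("A", "g", 100, 400), make_hit("A", "g", 900, 1200)]
        hits_b = [make_hit("B", "g", 500, 800)]
        d, ha, hb = min_pair_distance(hits_a, hits_b)
        assert d == 99
        assert (ha.interval.start, hb.interval.start) == (100, 500)

    def test_argmin_unique_minimum(self):
        hits_a = [make_hit("A", "g", 100, 400), make_hit("A", "g", 950, 1200)]
        hits_b = [make_hit("B", "g", 500, 800)]
        d, ha, hb = min_pair_distance(hits_a, hits_b)
        assert d == 99
        assert (ha.interval.start, hb.interval.start) == (100, 500)


class TestClassifyOrientation:
    def test_same_strand_co(self):
        assert classify_orientation(
            make_hit("A", "g", 100, 400, "+"), make_hit("B", "g", 500, 800, "+")
        ) == "co"

    def test_three_prime_facing_convergent(self):
        assert classify_orientation(
            make_hit("A", "g", 100, 400, "+"), make_hit("B", "g", 500, 800, "-")
        ) == "convergent"

    def test_five_prime_facing_divergent(self):
        assert classify_orientation(
            make_hit("A", "g", 100, 400, "-"), make_hit("B", "g", 500, 800, "+")
        ) == "divergent"


class TestPairFeatures:
    def test_single_common_genome_one_hot_and_imputed(self):
        index = index_of(
            make_hit("A", "g1", 100, 400, "+"), make_hit("B", "g1", 500, 800, "+")
        )
        pf = pair_features(index, IdentityMatrix("ANI"), IdentityMatrix("AAI"), "A", "B")
        assert pf.avg_distance == 99
        assert (pf.f_co, pf.f_conv, pf.f_div) == (1.0, 0.0, 0.0)
        assert pf.mean_ani == 100.0 and pf.mean_aai == 100.0

    def test_distance_mean_over_genomes(self):
        index = index_of(
            make_hit("A", "g1", 1, 100), make_hit("B", "g1", 201, 300),
            make_hit("A", "g2", 1, 100), make_hit("B", "g2", 401, 500),
        )
        pf = pair_features(index, None, None, "A", "B")
        assert pf.avg_distance == 200.0  # (100 + 300) / 2

    def test_ani_mean_over_unordered_genome_pairs(self):
        index = index_of(
            *(make_hit("A", g, 1, 9) for g in ("g1", "g2", "g3")),
            *(make_hit("B", g, 20, 29) for g in ("g1", "g2", "g3")),
        )
        ani = IdentityMatrix("ANI")
        ani.set("g1", "g2", 95)
        ani.set("g1", "g3", 90)
        ani.set("g2", "g3", 85)
        pf = pair_features(index, ani, None, "A", "B")
        assert pf.mean_ani == pytest.approx(90.0)

    def test_exchange_symmetry(self):
        rng = np.random.default_rng(5)
        hits = random_hit_set(rng)
        index = build_occurrence_index(hits)
        for a, b in (("P0", "P1"), ("P2", "P3")):
            if not index.co_occurring_genomes(a, b):
                continue
            assert pair_features(index, None, None, a, b) == pair_features(
                index, None, None, b, a
            )

    def test_orientation_fractions_partition_unity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            hits = random_hit_set(rng)
            index = build_occurrence_index(hits)
            for a in index.pvogs:
                for b in index.pvogs:
                    if a < b and index.co_occurring_genomes(a, b):
                        pf = pair_features(index, None, None, a, b)
                        assert pf.f_co + pf.f_conv + pf.f_div == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            hits = random_hit_set(rng)
            index = build_occurrence_index(hits)
            for a in index.pvogs:
                for b in index.pvogs:
                    if a >= b or not index.co_occurring_genomes(a, b):
                        continue
                    pf = pair_features(index, None, None, a, b)
                    expected = features_by_enumeration(hits, a, b)
                    assert pf.avg_distance == expected["avg_distance"]
                    assert pf.f_co == expected["f_co"]
                    assert pf.f_conv == expected["f_conv"]
                    assert pf.f_div == expected["f_div"]


class TestBuildFeatureTable:
    def test_non_co_occurring_pairs_dropped(self):
        index = index_of(
            make_hit("A", "g1", 1, 9), make_hit("B", "g1", 20, 29),
            make_hit("C", "g2", 1, 9),
        )
        table = build_feature_table(
            index, None, None, [("A", "B"), ("A", "C"), ("B", "C")]
        )
        assert len(table) == 1 and tuple(table.iloc[0][:2]) == ("A", "B")

    def test_empty_pair_list(self):
        index = index_of(make_hit("A", "g1", 1, 9))
        assert len(build_feature_table(index, None, None, [])) == 0

    def test_column_order_fixed(self):
        index = index_of(make_hit("A", "g1", 1, 9), make_hit("B", "g1", 20, 29))
        table = build_feature_table(index, None, None, [("B", "A")])
        assert list(table.columns) == ["pvog_a", "pvog_b", *FEATURE_COLUMNS]


def test_planted_cooccurrence_signal_dominates(small_prepared):
    """Interacting pairs' co-occurrence stochastically dominates the
    non-interacting distribution in the planted-signal scenario."""
    table = small_prepared.feature_table.set_index(["pvog_a", "pvog_b"])
    positives = set(small_prepared.positives)
    mask = np.array([pair in positives for pair in table.index])
    pos = table.loc[mask, "co_occurrence"]
    neg = table.loc[~mask, "co_occurrence"]
    stat, p = stats.mannwhitneyu(pos, neg, alternative="greater")
    assert p < 1e-6
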