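"""Single-gene GSEA: stratification, ranking metrics, the weighted KS
enrichment score against exhaustive oracles, and the permutation machinery."""

import itertools
import math

import numpy as np
import pytest

from lncannot import sg_gsea
from lncannot.core_io import ExpressionMatrix, GeneSetCollection, MatrixKind
from lncannot.sg_gsea import (
    PhenotypeSplit,
    RankedList,
    enrichment_score,
    gsea_collection,
    normalize_and_test,
    permutation_null,
    rank_genes,
    stratify_by_target,
)


def es_oracle(scores, hit_flags, p_exp=1.0):
    """Plain-loop running sum: P_hit steps by |r|^p / N_R on members,
    P_miss by 1/(N - N_H) otherwise; ES is the first extremum of |sum|."""
    n = len(scores)
    n_h = sum(hit_flags)
    n_r = sum(abs(s) ** p_exp for s, h in zip(scores, hit_flags) if h)
    running, total = [], 0.0
    for s, h in zip(scores, hit_flags):
        if h:
            total += (abs(s) ** p_exp / n_r) if n_r > 0 else 1.0 / n_h
        else:
            total -= 1.0 / (n - n_h)
        running.append(total)
    best = max(range(n), key=lambda i: (abs(running[i]), -i))
    return running[best], running


def _one_gene_matrix(values, sample_ids=None):
    n = len(values)
    samples = sample_ids or [f"S{j:04d}" for j in range(n)]
    return ExpressionMatrix(
        ["T"], samples, np.array([values], dtype=float), MatrixKind.LOG_NORMALIZED
    )


class TestStratify:
    def test_even_split_of_four(self):
        m = _one_gene_matrix([4.0, 3.0, 2.0, 1.0], ["a", "b", "c", "d"])
        split = stratify_by_target(m, "T", 0.5)
        assert split.high == ["a", "b"]
        assert split.low == ["c", "d"]

    def test_constant_target_splits_by_sample_id(self):
        m = _one_gene_matrix([5.0] * 6, ["f", "e", "d", "c", "b", "a"])
        split = stratify_by_target(m, "T", 1 / 3)
        assert split.high == ["a", "b"]
        assert split.low == ["e", "f"]

    def test_sizes_use_ceil(self):
        m = _one_gene_matrix(list(range(25)))
        split = stratify_by_target(m, "T", 0.10)
        assert len(split.high) == len(split.low) == math.ceil(0.10 * 25)

    def test_overlapping_groups_rejected(self):
        m = _one_gene_matrix([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="overlap"):
            stratify_by_target(m, "T", 0.5)  # ceil(2.5)=3, 6 > 5

    @pytest.mark.parametrize("q", [0.0, 0.6, 1.0])
    def test_quantile_out_of_range_rejected(self, q):
        m = _one_gene_matrix(list(range(20)))
        with pytest.raises(ValueError):
            stratify_by_target(m, "T", q)


def _two_group_matrix(rows):
    genes = list(rows)
    values = np.array([rows[g] for g in genes], dtype=float)
    samples = [f"H{j}" for j in range(3)] + [f"L{j}" for j in range(3)]
    return (
        ExpressionMatrix(genes, samples, values, MatrixKind.LOG_NORMALIZED),
        PhenotypeSplit(high=samples[:3], low=samples[3:], fraction=0.5),
    )


class TestRankGenes:
    def test_signal2noise_matches_hand_computation(self):
        m, split = _two_group_matrix({"G": [4.0, 5.0, 6.0, 1.0, 2.0, 3.0]})
        ranked = rank_genes(m, split, metric="signal2noise")
        # mu_h=5, mu_l=2, sd=1 both; floors: max(1, .2*5, .2)=1, max(1, .2*2, .2)=1
        assert ranked.scores[0] == pytest.approx((5 - 2) / (1 + 1))

    def test_sd_floor_engages_for_tight_groups(self):
        m, split = _two_group_matrix({"G": [10.0, 10.0, 10.0, 1.0, 1.0, 1.0]})
        ranked = rank_genes(m, split, metric="signal2noise")
        # sd=0 floored to .2*|mu|: 2.0 and 0.2
        assert ranked.scores[0] == pytest.approx((10 - 1) / (2.0 + 0.2))

    def test_equal_group_means_score_zero(self):
        m, split = _two_group_matrix({"G": [1.0, 2.0, 3.0, 3.0, 2.0, 1.0]})
        ranked = rank_genes(m, split, metric="log2_ratio")
        assert ranked.scores[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("metric", ["signal2noise", "log2_ratio", "t_stat"])
    def test_swapped_groups_negate_the_metric(self, metric):
        vals = [4.0, 6.0, 5.0, 1.0, 3.0, 2.0]
        m, split = _two_group_matrix({"G": vals})
        swapped = PhenotypeSplit(high=split.low, low=split.high, fraction=0.5)
        r1 = rank_genes(m, split, metric=metric)
        r2 = rank_genes(m, swapped, metric=metric)
        assert r1.scores[0] == pytest.approx(-r2.scores[0])

    def test_target_exclusion(self):
        m, split = _two_group_matrix(
            {"T": [9.0, 9.0, 9.0, 0.0, 0.0, 0.0], "G": [1.0, 2.0, 3.0, 3.0, 2.0, 1.0]}
        )
        ranked = rank_genes(m, split, exclude=("T",))
        assert ranked.gene_ids == ["G"]

    def test_small_group_rejected_for_variance_metrics(self):
        m = _one_gene_matrix([1.0, 2.0, 3.0, 4.0])
        split = PhenotypeSplit(high=["S0000"], low=["S0003"], fraction=0.25)
        with pytest.raises(ValueError, match="2 samples"):
            rank_genes(m, split, metric="signal2noise")


def _ranked(scores, ids=None):
    ids = ids or [f"g{i}" for i in range(len(scores))]
    return RankedList(gene_ids=ids, scores=np.array(scores, dtype=float))


class TestEnrichmentScore:
    def test_singleton_top_gene_scores_one(self):
        ranked = _ranked([3.0, 2.0, 1.0, 0.5, -1.0])
        es, _, lead = enrichment_score(ranked, {"g0"})
        assert es == pytest.approx(1.0)
        assert lead == ["g0"]

    def test_singleton_bottom_gene_scores_minus_one(self):
        ranked = _ranked([3.0, 2.0, 1.0, 0.5, -1.0])
        es, _, lead = enrichment_score(ranked, {"g4"})
        assert es == pytest.approx(-1.0)
        assert lead == ["g4"]

    def test_equal_weights_match_classic_ks_by_hand(self):
        # 10 genes all |r|=1, set {g1, g2, g5}: hit step 1/3, miss step 1/7
        ranked = _ranked([1.0] * 10)
        es, running, _ = enrichment_score(ranked, {"g1", "g2", "g5"})
        expected = [
            -1 / 7, -1 / 7 + 1 / 3, -1 / 7 + 2 / 3, -2 / 7 + 2 / 3,
            -3 / 7 + 2 / 3, -3 / 7 + 1.0, -4 / 7 + 1, -5 / 7 + 1,
            -6 / 7 + 1, 0.0,
        ]
        np.testing.assert_allclose(running, expected, atol=1e-12)
        assert es == pytest.approx(-3 / 7 + 1.0)

    def test_matches_loop_oracle_on_grid(self, rng):
        for n in (5, 8, 12):
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            for size in (1, 2, 3, 4):
                for members in itertools.islice(
                    itertools.combinations(range(n), size), 12
                ):
                    flags = [i in members for i in range(n)]
                    ranked = _ranked(scores)
                    gene_set = {f"g{i}" for i in members}
                    es, running, _ = enrichment_score(ranked, gene_set)
                    es_exp, running_exp = es_oracle(scores, flags)
                    np.testing.assert_allclose(running, running_exp, atol=1e-12)
                    assert es == pytest.approx(es_exp, abs=1e-12)

    def test_reversing_equal_weight_list_negates_es(self):
        ranked = _ranked([1.0] * 8)
        rev = _ranked([1.0] * 8, ids=ranked.gene_ids[::-1])
        gene_set = {"g1", "g4"}
        es_fwd, _, _ = enrichment_score(ranked, gene_set)
        es_rev, _, _ = enrichment_score(rev, gene_set)
        assert es_fwd == pytest.approx(-es_rev)

    def test_invariant_to_score_changes_off_the_set(self):
        scores = [5.0, 4.0, 3.0, 2.0, 1.0, 0.5]
        perturbed = [9.0, 4.0, 3.5, 2.0, 0.7, 0.6]  # order kept, |r| of set kept
        gene_set = {"g1", "g3"}
        es1, _, _ = enrichment_score(_ranked(scores), gene_set)
        es2, _, _ = enrichment_score(_ranked(perturbed), gene_set)
        assert es1 == pytest.approx(es2)

    def test_es_bounded_by_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            size = int(rng.integers(1, n))
            members = rng.choice(n, size, replace=False)
            es, _, _ = enrichment_score(
                _ranked(scores), {f"g{i}" for i in members}
            )
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_empty_and_full_sets_rejected(self):
        ranked = _ranked([2.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"absent"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"g0", "g1", "g2"})


class TestPermutationNull:
    def test_reproducible_from_seed(self):
        ranked = _ranked(np.linspace(2, -2, 30))
        a = permutation_null(ranked, 5, B=50, seed=9)
        b = permutation_null(ranked, 5, B=50, seed=9)
        np.testing.assert_array_equal(a, b)
        c = permutation_null(ranked, 5, B=50, seed=10)
        assert not np.array_equal(a, c)

    def test_matches_exhaustive_subset_null(self, rng):
        n, size = 5, 2
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        ranked = _ranked(scores)
        exact = sorted(
            es_oracle(scores, [i in m for i in range(n)])[0]
            for m in itertools.combinations(range(n), size)
        )
        sample = np.sort(permutation_null(ranked, size, B=10_000, seed=3))
        # KS distance between the empirical sample and the exact 10-point
        # null, counting tied exact values' mass fully
        grid = np.array(exact)
        exact_cdf = np.searchsorted(grid, grid, side="right") / len(grid)
        emp_cdf = np.searchsorted(sample, grid, side="right") / len(sample)
        assert np.max(np.abs(emp_cdf - exact_cdf)) < 0.05

    def test_symmetric_equal_weight_null_has_mean_near_zero(self):
        ranked = _ranked([1.0] * 40)
        null = permutation_null(ranked, 8, B=4000, seed=5)
        assert abs(null.mean()) < 0.02

    def test_bad_set_size_rejected(self):
        ranked = _ranked([1.0, 0.5, 0.0])
        with pytest.raises(ValueError):
            permutation_null(ranked, 3, B=10, seed=0)


class TestNormalizeAndTest:
    def test_toy_null_hand_enumeration(self):
        nes, p = normalize_and_test(0.4, np.array([0.2, 0.4, -0.3]))
        assert nes == pytest.approx(4 / 3)
        assert p == pytest.approx(2 / 3)

    def test_es_at_null_mean_gives_unit_nes(self):
        null = np.array([0.1, 0.2, 0.3, -0.4])
        nes, _ = normalize_and_test(0.2, null)
        assert nes == pytest.approx(1.0)

    def test_extreme_es_gets_smoothed_minimum_p(self):
        null = np.concatenate([np.linspace(0.01, 0.5, 999), [-0.2]])
        _, p = normalize_and_test(0.99, null)
        assert p == pytest.approx(1 / 1000)

    def test_sign_preserved(self):
        null = np.array([0.3, -0.2, -0.4])
        nes, _ = normalize_and_test(-0.35, null)
        assert nes < 0

    def test_no_same_sign_null_raises(self):
        with pytest.raises(ValueError):
            normalize_and_test(0.5, np.array([-0.1, -0.2]))


class TestGseaCollection:
    def test_recovers_planted_structure(self, small_synth):
        cfg, _, logged, truth = small_synth
        res = gsea_collection(
            logged, cfg.target_gene_id, truth.collection, B=300, seed=11
        )
        by_name = {r.set_name: r for r in res}
        assert min(res, key=lambda r: r.nes).set_name == "NEG_SET"
        assert by_name["NEG_SET"].es < 0
        assert by_name["POS_SET"].nes > 0
        assert by_name["NEG_SET"].q_fdr < 0.05
        # leading edge is inside the set and the ranked universe
        lead = set(by_name["NEG_SET"].leading_edge)
        assert lead <= set(truth.collection.sets["NEG_SET"])

    def test_duplicate_set_under_two_names_identical_es_nes(self, small_synth):
        cfg, _, logged, truth = small_synth
        genes = truth.collection.sets["NEG_SET"]
        coll = GeneSetCollection(
            "dup", {"A_NAME": list(genes), "Z_NAME": list(genes)}
        )
        res = {r.set_name: r for r in gsea_collection(
            logged, cfg.target_gene_id, coll, B=200, seed=4
        )}
        assert res["A_NAME"].es == res["Z_NAME"].es
        assert res["A_NAME"].nes == res["Z_NAME"].nes
        assert res["A_NAME"].p_nominal == res["Z_NAME"].p_nominal

    def test_deterministic_given_seed(self, small_synth):
        cfg, _, logged, truth = small_synth
        r1 = gsea_collection(logged, cfg.target_gene_id, truth.collection,
                             B=100, seed=2)
        r2 = gsea_collection(logged, cfg.target_gene_id, truth.collection,
                             B=100, seed=2)
        assert [(a.set_name, a.nes, a.p_fwer, a.q_fdr) for a in r1] == [
            (b.set_name, b.nes, b.p_fwer, b.q_fdr) for b in r2
        ]

    def test_size_filter_can_empty_collection(self, small_synth):
        cfg, _, logged, truth = small_synth
        with pytest.raises(ValueError, match="no gene set"):
            gsea_collection(logged, cfg.target_gene_id, truth.collection,
                            B=10, seed=0, min_size=400, max_size=500)
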