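"""Enrichment scores, permutation nulls, miRES, FDR, scan and ssGSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immumirna import (
    CohortConfig,
    PlantedPair,
    RankedGeneList,
    ScanConfig,
    bh_fdr,
    enrichment_score,
    filter_zero_fraction,
    generate_cohort,
    immu_mirna_scan,
    log2p1,
    mires,
    permutation_test,
    records_to_frame,
    rpm_normalize,
    ssgsea,
)

from helpers import exhaustive_null_p, make_expr, naive_es


def ranked_list(rs, mirna="mir1"):
    rs = np.asarray(rs, dtype=float)
    order = np.argsort(-rs, kind="stable")
    return RankedGeneList(mirna, [f"g{i}" for i in order], rs[order])


def prep(counts):
    return log2p1(rpm_normalize(filter_zero_fraction(counts)))


class TestEnrichmentScore:
    def test_single_member_at_top_unweighted(self, rng):
        ranked = ranked_list(np.arange(10, 0, -1))
        assert enrichment_score(ranked, {ranked.gene_ids[0]}, 0.0) == pytest.approx(1.0)

    def test_single_member_at_bottom_unweighted(self):
        ranked = ranked_list(np.arange(10, 0, -1))
        assert enrichment_score(ranked, {ranked.gene_ids[-1]}, 0.0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("weight_exponent", [0.0, 0.5, 1.0, 2.0])
    def test_matches_naive_running_sum(self, rng, weight_exponent):
        for _ in range(10):
            rs = rng.normal(size=12)
            ranked = ranked_list(rs)
            gene_set = set(rng.choice(ranked.gene_ids, size=3, replace=False))
            expected = naive_es(ranked.gene_ids, ranked.rs, gene_set, weight_exponent)
            assert enrichment_score(ranked, gene_set, weight_exponent) == pytest.approx(
                expected, abs=1e-12
            )

    def test_unweighted_equals_ks_statistic_against_hit_ecdf(self, rng):
        # classic two-sided KS distance between the hit-position ECDF and the
        # miss-position ECDF, computed independently position by position
        for _ in range(50):
            n = int(rng.integers(8, 30))
            k = int(rng.integers(1, n // 2))
            ranked = ranked_list(rng.normal(size=n))
            gene_set = set(rng.choice(ranked.gene_ids, size=k, replace=False))
            hits = np.array([g in gene_set for g in ranked.gene_ids])
            cdf_in = np.cumsum(hits) / k
            cdf_out = np.cumsum(~hits) / (n - k)
            diffs = cdf_in - cdf_out
            expected = (
                diffs.max() if diffs.max() >= -diffs.min() - 1e-12 else diffs.min()
            )
            assert enrichment_score(ranked, gene_set, 0.0) == pytest.approx(
                expected, abs=1e-12
            )

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(ranked_list([1.0, 2.0]), {"absent"})

    def test_all_zero_weights_fall_back_unweighted(self):
        ranked = RankedGeneList("m", ["g0", "g1", "g2", "g3"], np.array([5.0, 1.0, 0.0, 0.0]))
        with pytest.warns(UserWarning, match="zero"):
            es = enrichment_score(ranked, {"g2", "g3"}, 1.0)
        assert es == pytest.approx(
            naive_es(ranked.gene_ids, ranked.rs, {"g2", "g3"}, 0.0)
        )


class TestPermutationTest:
    def test_pseudocount_lower_bound(self, rng):
        ranked = ranked_list(rng.normal(size=30))
        top = set(ranked.gene_ids[:3])
        p = permutation_test(ranked, top, n_perm=200, seed=0)
        assert p >= 1 / 201

    def test_matches_exhaustive_enumeration(self, rng):
        ranked = ranked_list([3.0, 1.5, 0.2, -1.0, -2.5])
        gene_set = set(ranked.gene_ids[:2])
        exact_p, _ = exhaustive_null_p(ranked.gene_ids, ranked.rs, gene_set)
        estimate = permutation_test(ranked, gene_set, n_perm=5000, seed=11)
        assert estimate == pytest.approx(exact_p, abs=0.03)

    def test_deterministic_given_seed(self, rng):
        ranked = ranked_list(rng.normal(size=40))
        gene_set = set(rng.choice(ranked.gene_ids, size=5, replace=False))
        p1 = permutation_test(ranked, gene_set, n_perm=300, seed=42)
        p2 = permutation_test(ranked, gene_set, n_perm=300, seed=42)
        assert p1 == p2

    def test_set_as_large_as_universe_rejected(self):
        ranked = ranked_list([1.0, -1.0])
        with pytest.raises(ValueError, match="universe"):
            permutation_test(ranked, set(ranked.gene_ids), n_perm=100, seed=0)

    def test_null_pvalues_near_uniform(self):
        # random observed sets → p should be uniform up to the permutation grid
        rng = np.random.default_rng(77)
        ranked = ranked_list(rng.normal(size=60))
        pvals = np.array(
            [
                permutation_test(
                    ranked,
                    set(rng.choice(ranked.gene_ids, size=6, replace=False)),
                    n_perm=199,
                    seed=int(rng.integers(2**31)),
                )
                for _ in range(500)
            ]
        )
        counts, _ = np.histogram(pvals, bins=np.linspace(0, 1, 6))
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=4)


class TestMires:
    def test_range_endpoints(self):
        assert mires(0.8, 1e-300) == pytest.approx(1.0)
        assert mires(-0.8, 1e-300) == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "es,p,expected", [(0.5, 0.0025, 0.995), (0.5, 0.5, 0.0), (-0.5, 0.5, 0.0)]
    )
    def test_known_values(self, es, p, expected):
        assert mires(es, p) == pytest.approx(expected)

    def test_monotone_in_p_and_bounded(self, rng):
        ps = np.sort(rng.uniform(1e-6, 1, 50))
        pos = [mires(0.3, p) for p in ps]
        neg = [mires(-0.3, p) for p in ps]
        assert all(np.diff(pos) < 0)
        assert all(np.diff(neg) > 0)
        assert all(abs(v) <= 1 for v in pos + neg)

    def test_zero_es_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mires(0.0, 0.5)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bounds_and_order(self, rng):
        p = rng.uniform(1e-6, 1, 30)
        q = bh_fdr(p)
        assert np.all(q >= p)
        assert np.all(q <= 1)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0


def small_cohort(seed=0, planted=()):
    config = CohortConfig(
        n_samples=60,
        n_mirna=6,
        n_genes=200,
        n_pathways=3,
        genes_per_pathway=15,
        planted=planted,
    )
    return generate_cohort(config, seed)


class TestScan:
    def test_deterministic_including_record_order(self):
        cohort = small_cohort(3)
        mirna, mrna = prep(cohort.mirna_counts), prep(cohort.mrna_counts)
        config = ScanConfig(seed=9, n_perm=150, n_perm_refine=300)
        r1 = immu_mirna_scan(mirna, mrna, cohort.purity, cohort.gene_sets, config)
        r2 = immu_mirna_scan(mirna, mrna, cohort.purity, cohort.gene_sets, config)
        assert records_to_frame(r1).equals(records_to_frame(r2))

    def test_empty_gene_sets_vacuous(self):
        cohort = small_cohort(4)
        from immumirna import GeneSetCollection

        out = immu_mirna_scan(
            prep(cohort.mirna_counts),
            prep(cohort.mrna_counts),
            cohort.purity,
            GeneSetCollection({}),
            ScanConfig(seed=1, n_perm=100),
        )
        assert out == []

    def test_planted_pair_ranks_first(self):
        planted = (PlantedPair("mir_001", "pathway_1", "up", 0.9),)
        cohort = small_cohort(5, planted)
        records = immu_mirna_scan(
            prep(cohort.mirna_counts),
            prep(cohort.mrna_counts),
            cohort.purity,
            cohort.gene_sets,
            ScanConfig(seed=2, n_perm=500, n_perm_refine=2000),
        )
        frame = records_to_frame(records).sort_values("p")
        top = frame.iloc[0]
        assert (top.mirna_id, top.pathway) == ("mir_001", "pathway_1")
        assert top.mires > 0.9

    def test_frame_invariants(self):
        cohort = small_cohort(6)
        frame = records_to_frame(
            immu_mirna_scan(
                prep(cohort.mirna_counts),
                prep(cohort.mrna_counts),
                cohort.purity,
                cohort.gene_sets,
                ScanConfig(seed=3, n_perm=150),
            )
        )
        assert len(frame) == 6 * 3
        assert ((frame.es >= -1) & (frame.es <= 1)).all()
        assert ((frame.p > 0) & (frame.p <= 1)).all()
        # 1 − 2p carries the ES sign only while p < 1/2; beyond that the
        # combined score crosses zero by construction
        small_p = frame.p < 0.5
        assert (np.sign(frame.mires[small_p]) == np.sign(frame.es[small_p])).all()
        assert (frame.fdr >= frame.p - 1e-12).all()
        assert ((frame.fdr > 0) & (frame.fdr <= 1)).all()


class TestSsgsea:
    def test_hand_computed_toy(self):
        # one sample, five genes, two-gene set; alpha=1 for easy arithmetic
        expr = make_expr([[5.0], [4.0], [3.0], [2.0], [1.0]],
                         features=["a", "b", "c", "d", "e"])
        from immumirna import GeneSetCollection

        sets = GeneSetCollection({"S": frozenset({"a", "c"})})
        # ranks down the list: 5,4,3,2,1 → weights with alpha=1
        # in-set cum weights: a(5), c(3) → P_in = [5/8,5/8,8/8,1,1]
        # out cum counts: b,d,e → P_out = [0,1/3,1/3,2/3,1]
        expected = (5 / 8 - 0) + (5 / 8 - 1 / 3) + (1 - 1 / 3) + (1 - 2 / 3) + 0.0
        table = ssgsea(expr, sets, alpha=1.0)
        assert table.loc["S"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_top_genes_dominate_random_sets(self, rng):
        values = rng.normal(size=(100, 1))
        expr = make_expr(values)
        order = np.argsort(-values[:, 0])
        top = frozenset(expr.feature_ids[i] for i in order[:10])
        from immumirna import GeneSetCollection

        top_score = ssgsea(expr, GeneSetCollection({"top": top}), 0.25).iloc[0, 0]
        for _ in range(100):
            random_set = frozenset(rng.choice(expr.feature_ids, 10, replace=False))
            score = ssgsea(expr, GeneSetCollection({"r": random_set}), 0.25).iloc[0, 0]
            assert score < top_score

    def test_identical_samples_identical_scores(self, rng):
        col = rng.normal(size=20)
        expr = make_expr(np.column_stack([col, col]))
        from immumirna import GeneSetCollection

        sets = GeneSetCollection({"S": frozenset(expr.feature_ids[:5])})
        table = ssgsea(expr, sets)
        assert table.iloc[0, 0] == table.iloc[0, 1]

    def test_missing_set_scores_zero_with_warning(self, rng):
        expr = make_expr(rng.normal(size=(10, 2)))
        from immumirna import GeneSetCollection

        sets = GeneSetCollection({"absent": frozenset({"nope"})})
        with pytest.warns(UserWarning, match="absent"):
            table = ssgsea(expr, sets)
        assert (table.to_numpy() == 0).all()

    def test_rescale_bounds(self, rng):
        expr = make_expr(rng.normal(size=(30, 6)))
        from immumirna import GeneSetCollection

        sets = GeneSetCollection({"S": frozenset(expr.feature_ids[:8])})
        table = ssgsea(expr, sets, rescale=True)
        assert table.to_numpy().min() == pytest.approx(0.0)
        assert table.to_numpy().max() == pytest.approx(1.0)
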