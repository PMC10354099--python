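import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmescreen.enrichment import (
    RankedProfile,
    bh_fdr,
    gsea_collection,
    gsea_es,
    gsea_significance,
    hypergeom_enrichment,
    rank_profile,
    ssgsea_matrix,
    ssgsea_score,
)
from tmescreen.types import ExpressionMatrix, GeneSetCollection

from conftest import gsea_oracle, ssgsea_oracle


class TestRankProfile:
    def test_descending_order(self, tiny_matrix):
        prof = rank_profile(tiny_matrix, "s1")
        assert prof.genes == ["A", "C", "B"]

    def test_ties_broken_by_gene_id(self, tiny_matrix):
        prof = rank_profile(tiny_matrix, "s2")  # B=2, C=2, A=1
        assert prof.genes == ["B", "C", "A"]

    def test_unknown_sample(self, tiny_matrix):
        with pytest.raises(KeyError):
            rank_profile(tiny_matrix, "nope")

    def test_constant_profile_warns_and_is_lexicographic(self, caplog):
        m = ExpressionMatrix(
            gene_ids=["B", "A"], sample_ids=["s"], values=np.array([[1.0], [1.0]])
        )
        with caplog.at_level("WARNING"):
            prof = rank_profile(m, "s")
        assert prof.genes == ["A", "B"]
        assert any("degenerate" in r.message for r in caplog.records)


class TestSsgseaScore:
    def test_unweighted_worked_example(self, four_gene_profile):
        assert ssgsea_score(four_gene_profile, ["g1", "g2"], alpha=0) == pytest.approx(2.0)

    def test_reversal_antisymmetry_at_alpha_zero(self, four_gene_profile):
        assert ssgsea_score(four_gene_profile, ["g3", "g4"], alpha=0) == pytest.approx(-2.0)

    def test_weighted_worked_example(self, four_gene_profile):
        # weights 4/7 and 3/7 for the two set genes at the top
        assert ssgsea_score(four_gene_profile, ["g1", "g2"], alpha=1) == pytest.approx(29 / 14)

    def test_absent_set_errors(self, four_gene_profile):
        with pytest.raises(ValueError, match="absent"):
            ssgsea_score(four_gene_profile, ["zz"])

    def test_full_universe_errors(self, four_gene_profile):
        with pytest.raises(ValueError, match="universe"):
            ssgsea_score(four_gene_profile, ["g1", "g2", "g3", "g4"])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle_on_random_universes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        scores = rng.normal(size=n)
        genes = [f"g{i}" for i in range(n)]
        order = np.argsort(-scores)
        prof = RankedProfile(genes=[genes[i] for i in order], scores=scores[order])
        k = int(rng.integers(1, n))
        members = list(rng.choice(genes, size=k, replace=False))
        in_set = np.array([g in set(members) for g in prof.genes])
        assert ssgsea_score(prof, members, alpha=0) == pytest.approx(
            ssgsea_oracle(in_set), abs=1e-12
        )


class TestSsgseaMatrix:
    def test_identical_samples_identical_rows(self):
        m = ExpressionMatrix(
            gene_ids=["a", "b", "c", "d"],
            sample_ids=["s1", "s2"],
            values=np.array([[4.0, 4.0], [3.0, 3.0], [2.0, 2.0], [1.0, 1.0]]),
        )
        coll = GeneSetCollection(sets={"top": ["a", "b"]})
        tab = ssgsea_matrix(m, coll)
        assert tab.loc["s1", "top"] == tab.loc["s2", "top"]

    def test_single_cell_equals_rank_score(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(10, 1))
        genes = [f"g{i}" for i in range(10)]
        m = ExpressionMatrix(gene_ids=genes, sample_ids=["s"], values=values)
        coll = GeneSetCollection(sets={"set": genes[:3]})
        tab = ssgsea_matrix(m, coll, alpha=0.25)
        # equivalent manual path: ranks as scores, same weighting
        prof = rank_profile(m, "s")
        rank_prof = RankedProfile(
            genes=prof.genes, scores=np.arange(len(genes), 0, -1, dtype=float)
        )
        assert tab.loc["s", "set"] == pytest.approx(
            ssgsea_score(rank_prof, genes[:3], alpha=0.25)
        )

    def test_min_max_normalization(self):
        m = ExpressionMatrix(
            gene_ids=["a", "b", "c"],
            sample_ids=["s1", "s2"],
            values=np.array([[3.0, 1.0], [2.0, 2.0], [1.0, 3.0]]),
        )
        coll = GeneSetCollection(sets={"set": ["a"]})
        tab = ssgsea_matrix(m, coll, normalize=True)
        assert sorted(tab["set"]) == [0.0, 1.0]

    def test_absent_set_recorded_missing_not_abort(self, caplog):
        m = ExpressionMatrix(
            gene_ids=["a", "b"], sample_ids=["s"], values=np.array([[1.0], [2.0]])
        )
        coll = GeneSetCollection(sets={"ok": ["a"], "gone": ["zz"]})
        with caplog.at_level("WARNING"):
            tab = ssgsea_matrix(m, coll)
        assert np.isnan(tab.loc["s", "gone"])
        assert np.isfinite(tab.loc["s", "ok"])


class TestGseaEs:
    def test_set_at_top(self, four_gene_profile):
        es, running = gsea_es(four_gene_profile, ["g1", "g2"], p_exponent=0)
        assert es == pytest.approx(1.0)
        assert np.argmax(running) == 1  # peak after the second hit

    def test_interleaved_set_matches_oracle(self, four_gene_profile):
        # the canonical signed max-deviation for {g2, g4}: running sum
        # (-1/2, 0, -1/2, 0) peaks in magnitude at -1/2
        in_set = np.array([False, True, False, True])
        assert gsea_oracle(in_set) == pytest.approx(-0.5)
        es, _ = gsea_es(four_gene_profile, ["g2", "g4"], p_exponent=0)
        assert es == pytest.approx(-0.5)

    def test_set_at_bottom(self, four_gene_profile):
        es, _ = gsea_es(four_gene_profile, ["g3", "g4"], p_exponent=0)
        assert es == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_bounded_and_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 21))
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        prof = RankedProfile(genes=genes, scores=scores)
        k = int(rng.integers(1, n))
        members = sorted(rng.choice(genes, size=k, replace=False))
        es, _ = gsea_es(prof, members, p_exponent=1)
        in_set = np.array([g in set(members) for g in genes])
        assert abs(es) <= 1.0 + 1e-12
        assert es == pytest.approx(gsea_oracle(in_set, np.abs(scores)), abs=1e-12)

    def test_out_of_set_relabeling_leaves_es_unchanged(self, four_gene_profile):
        es1, _ = gsea_es(four_gene_profile, ["g1", "g3"], p_exponent=0)
        relabeled = RankedProfile(
            genes=["g1", "g4", "g3", "g2"], scores=four_gene_profile.scores
        )
        es2, _ = gsea_es(relabeled, ["g1", "g3"], p_exponent=0)
        assert es1 == es2


class TestGseaSignificance:
    @staticmethod
    def _two_class_matrix(seed=0, n_genes=12, shift_genes=(), shift=2.0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n_genes)]
        values = rng.normal(size=(n_genes, 6))
        for g in shift_genes:
            values[genes.index(g), :3] += shift
        m = ExpressionMatrix(gene_ids=genes, sample_ids=[f"s{i}" for i in range(6)], values=values)
        return m, ["pos"] * 3 + ["neg"] * 3

    def test_plus_one_estimator_floor(self):
        # a strongly planted 5-gene set in a 40-gene universe: no random
        # same-size draw can tie the observed ES, so p hits the +1 floor
        m, labels = self._two_class_matrix(
            n_genes=40, shift_genes=tuple(f"g{i:02d}" for i in range(5)), shift=10.0
        )
        res = gsea_significance(
            m, labels, [f"g{i:02d}" for i in range(5)], "pos", n_perm=99, seed=1
        )
        assert res.p_nominal == pytest.approx(1 / 100)
        assert res.nes is not None and res.nes > 1

    def test_degenerate_all_identical_permutations(self):
        # constant expression + phenotype permutation: every relabeling
        # reproduces the observed ES, so p = 1 and NES = 1
        genes = [f"g{i}" for i in range(6)]
        m = ExpressionMatrix(
            gene_ids=genes,
            sample_ids=[f"s{i}" for i in range(6)],
            values=np.tile(np.arange(6.0)[:, None], (1, 6)),
        )
        res = gsea_significance(
            m, ["a"] * 3 + ["b"] * 3, genes[:2], "a", n_perm=50, mode="phenotype", seed=0
        )
        assert res.p_nominal == pytest.approx(1.0)
        assert res.nes == pytest.approx(1.0)

    def test_monte_carlo_matches_exact_enumeration(self):
        # 5-gene universe, 2-gene set: C(5,2)=10 equally likely gene-set draws
        m, labels = self._two_class_matrix(n_genes=5, shift_genes=("g00",), shift=3.0)
        from tmescreen.enrichment import rank_by_metric, signal_to_noise

        metric = signal_to_noise(m, labels, "pos")
        ranked = rank_by_metric(m, metric)
        weights = np.abs(ranked.scores)
        obs_in = np.array([g in {"g00", "g01"} for g in ranked.genes])
        obs = gsea_oracle(obs_in, weights)
        exact = []
        for combo in itertools.combinations(range(5), 2):
            in_set = np.zeros(5, dtype=bool)
            in_set[list(combo)] = True
            exact.append(gsea_oracle(in_set, weights))
        exact = np.array(exact)
        same_sign = exact * np.sign(obs) >= 0
        # exact tail probability under uniform gene-set draws
        p_exact = np.sum(same_sign & (np.abs(exact) >= abs(obs))) / len(exact)

        n_perm = 2000
        res = gsea_significance(m, labels, ["g00", "g01"], "pos", n_perm=n_perm, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p_nominal - p_exact) <= 3 * se + 1 / n_perm

    def test_phenotype_mode_falls_back_with_tiny_classes(self, caplog):
        m, _ = self._two_class_matrix()
        labels = ["pos", "pos", "neg", "neg", "neg", "neg"]  # 2 < 3 per class
        with caplog.at_level("WARNING"):
            res = gsea_significance(
                m, labels, ["g00", "g01"], "pos", n_perm=20, mode="phenotype", seed=0
            )
        assert any("falling back" in r.message for r in caplog.records)
        assert 0 < res.p_nominal <= 1

    def test_phenotype_mode_runs_with_enough_samples(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(10)]
        m = ExpressionMatrix(
            gene_ids=genes,
            sample_ids=[f"s{i}" for i in range(8)],
            values=rng.normal(size=(10, 8)),
        )
        res = gsea_significance(
            m, ["a"] * 4 + ["b"] * 4, genes[:3], "a", n_perm=50, mode="phenotype", seed=2
        )
        assert 0 < res.p_nominal <= 1

    def test_collection_is_seed_reproducible(self):
        m, labels = self._two_class_matrix(shift_genes=("g00", "g01"))
        coll = GeneSetCollection(sets={"a": ["g00", "g01"], "b": ["g05", "g06", "g07"]})
        r1 = gsea_collection(m, labels, coll, "pos", n_perm=100, seed=9)
        r2 = gsea_collection(m, labels, coll, "pos", n_perm=100, seed=9)
        assert r1.equals(r2)


class TestHypergeom:
    def test_full_overlap_worked_example(self):
        universe = [f"u{i}" for i in range(10)]
        assert hypergeom_enrichment(universe[:5], universe[:5], universe) == pytest.approx(
            1 / 252
        )

    def test_empty_set_intersection_gives_one(self):
        universe = ["a", "b", "c"]
        assert hypergeom_enrichment(["a"], ["zz"], universe) == 1.0

    def test_hits_equal_universe_forces_overlap(self):
        universe = ["a", "b", "c", "d"]
        assert hypergeom_enrichment(universe, ["a", "b"], universe) == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrichment([], ["a"], [])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_enumeration_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        universe = [f"u{i}" for i in range(n)]
        hits = list(rng.choice(universe, size=int(rng.integers(1, n)), replace=False))
        members = list(rng.choice(universe, size=int(rng.integers(1, n)), replace=False))
        observed = len(set(hits) & set(members))
        # enumerate all draws of |hits| from the universe
        count = 0
        total = 0
        for combo in itertools.combinations(universe, len(hits)):
            total += 1
            if len(set(combo) & set(members)) >= observed:
                count += 1
        assert hypergeom_enrichment(hits, members, universe) == pytest.approx(
            count / total, abs=1e-12
        )


class TestBhFdr:
    def test_single_p_passthrough(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=8)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_oracle(self, ps):
        # independent implementation of the step-up contract:
        # q_i = min over p_j >= p_i of (m * p_j / rank_j), clipped to 1
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order]
        q_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(20))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p - 1e-12)
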