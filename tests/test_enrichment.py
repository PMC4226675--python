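"""Ranking, the running-sum enrichment statistic, and its permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arnfkb.containers import GeneSet, StratificationLabels
from arnfkb.enrichment import (
    RankedList,
    derive_repressed_targets,
    enrichment_score,
    permutation_test,
    rank_by_t,
)
from arnfkb.scoring import stratify_extremes, summed_zscore, zscore_vs_reference
from arnfkb.simulate import SimulationConfig, generate_cohort

from conftest import make_matrix
from _oracles import brute_es, brute_running_sum, brute_t


def _labels(mapping):
    return StratificationLabels(pd.Series(mapping), rule="test")


def _ranked(pairs):
    metric = pd.Series({g: v for g, v in pairs})
    ordered = metric.loc[[g for g, _ in pairs]]
    return RankedList(genes=[g for g, _ in pairs], metric=ordered, group_sizes=(2, 2))


class TestRankByT:
    def test_equal_groups_give_zero_t(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0], [5.0, 6.0, 7.0, 8.0]],
            index=["SAME", "DIFF"],
            columns=["a", "b", "c", "d"],
        )
        m = make_matrix(values)
        ranked = rank_by_t(m, _labels({"a": "high", "b": "high", "c": "low", "d": "low"}))
        assert ranked.metric["SAME"] == pytest.approx(0.0)
        assert ranked.metric["DIFF"] < 0

    def test_swapping_labels_negates_and_reverses(self, small_matrix):
        samples = list(small_matrix.samples)
        fwd = {s: ("high" if i < 5 else "low") for i, s in enumerate(samples)}
        rev = {s: ("low" if v == "high" else "high") for s, v in fwd.items()}
        r1 = rank_by_t(small_matrix, _labels(fwd))
        r2 = rank_by_t(small_matrix, _labels(rev))
        assert np.allclose(r1.metric.sort_index(), -r2.metric.sort_index(), atol=1e-10)
        assert r1.genes == r2.genes[::-1]

    def test_matches_textbook_formula(self, small_matrix):
        samples = list(small_matrix.samples)
        labels = _labels({s: ("high" if i < 5 else "low") for i, s in enumerate(samples)})
        ranked = rank_by_t(small_matrix, labels)
        expected = brute_t(small_matrix.values.to_numpy(), [0, 1, 2, 3, 4], [5, 6, 7, 8, 9])
        got = ranked.metric.reindex(small_matrix.genes)
        assert np.allclose(got.to_numpy(), expected, atol=1e-10)

    def test_small_group_rejected(self, small_matrix):
        labels = _labels({s: "low" for s in small_matrix.samples} | {"T0": "high"})
        with pytest.raises(ValueError):
            rank_by_t(small_matrix, labels)


class TestEnrichmentScore:
    def test_singleton_ranked_first(self):
        ranked = _ranked([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        res = enrichment_score(ranked, GeneSet("s", ("A",)))
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge.genes == ("A",)

    def test_singleton_ranked_last_weight_zero(self):
        ranked = _ranked([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        res = enrichment_score(ranked, GeneSet("s", ("C",)), weight=0.0)
        assert res.es == pytest.approx(-1.0)
        assert res.leading_edge.genes == ("C",)

    def test_hand_enumerated_running_sum(self):
        """(A:3, B:2, C:1, D:1) with set {A, C}: running sum .75, .25, .5, 0."""
        ranked = _ranked([("A", 3.0), ("B", 2.0), ("C", 1.0), ("D", 1.0)])
        res = enrichment_score(ranked, GeneSet("s", ("A", "C")), weight=1.0)
        assert np.allclose(res.running_sum, [0.75, 0.25, 0.5, 0.0], atol=1e-12)
        assert res.es == pytest.approx(0.75)
        assert res.leading_edge.genes == ("A",)

    def test_empty_or_full_overlap_rejected(self):
        ranked = _ranked([("A", 3.0), ("B", 2.0)])
        with pytest.raises(ValueError):
            enrichment_score(ranked, GeneSet("s", ("X",)))
        with pytest.raises(ValueError):
            enrichment_score(ranked, GeneSet("s", ("A", "B")))

    def test_min_overlap_enforced(self):
        ranked = _ranked([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        with pytest.raises(ValueError):
            enrichment_score(ranked, GeneSet("s", ("A",)), min_overlap=5)

    def test_matches_brute_force_on_random_instances(self):
        """200 random (list <= 50, set <= 10) instances agree with the loop oracle."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            genes = [f"G{i:03d}" for i in range(n)]
            metric = np.sort(rng.normal(0, 2, n))[::-1]
            k = int(rng.integers(1, min(10, n - 1) + 1))
            members = list(rng.choice(genes, size=k, replace=False))
            weight = float(rng.choice([0.0, 1.0, 1.5]))
            ranked = _ranked(list(zip(genes, metric)))
            res = enrichment_score(ranked, GeneSet("s", tuple(members)), weight=weight)
            assert np.allclose(
                res.running_sum, brute_running_sum(metric, genes, members, weight), atol=1e-12
            )
            assert res.es == pytest.approx(brute_es(metric, genes, members, weight), abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_bounds_and_final_zero(self, data):
        n = data.draw(st.integers(4, 40))
        metric = np.sort(
            np.array(data.draw(st.lists(st.floats(-5, 5), min_size=n, max_size=n)))
        )[::-1]
        k = data.draw(st.integers(1, n - 1))
        genes = [f"G{i:03d}" for i in range(n)]
        members = genes[:k]
        res = enrichment_score(_ranked(list(zip(genes, metric))), GeneSet("s", tuple(members)))
        assert -1.0 <= res.es <= 1.0
        assert abs(res.running_sum[-1]) < 1e-9


class TestPermutationTest:
    def test_p_and_nes_match_independent_null_replay(self, small_matrix):
        """p and NES follow the add-one / same-sign formulas on oracle-recomputed nulls.

        The permutation stream is replayed with the same generator seed, but
        every null ES is recomputed with the brute-force t and running-sum
        oracles; the add-one estimator and same-sign NES computed from those
        oracle nulls must match the implementation exactly.
        """
        samples = list(small_matrix.samples)
        labels = _labels({s: ("high" if i < 5 else "low") for i, s in enumerate(samples)})
        gene_set = GeneSet("s", tuple(small_matrix.genes[:4]))
        n_perm, seed = 40, 17
        res = permutation_test(small_matrix, labels, gene_set,
                               n_permutations=n_perm, seed=seed, min_overlap=1)

        values = small_matrix.values.to_numpy()
        pool = np.arange(10)
        rng = np.random.default_rng(seed)
        null = []
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            t = brute_t(values, perm[:5], perm[5:])
            order = sorted(range(len(t)), key=lambda i: -t[i])
            genes = [small_matrix.genes[i] for i in order]
            null.append(brute_es([t[i] for i in order], genes, gene_set.genes))
        null = np.array(null)
        same = null > 0 if res.es >= 0 else null < 0
        m = int(same.sum())
        expected_p = (1 + int((np.abs(null[same]) >= abs(res.es)).sum())) / (1 + m)
        expected_nes = res.es / np.abs(null[same]).mean()
        assert res.p_nominal == pytest.approx(expected_p, abs=1e-12)
        assert res.nes == pytest.approx(expected_nes, rel=1e-9)

    def test_strong_signal_hits_estimator_floor(self, default_cohort):
        """A planted signal stronger than every null lands on p = 1/(1+m)."""
        z = zscore_vs_reference(default_cohort.expression)
        labels = stratify_extremes(summed_zscore(z, default_cohort.ar_set), 1 / 3)
        res = permutation_test(
            default_cohort.expression, labels, default_cohort.nfkb_set,
            n_permutations=99, seed=5,
        )
        assert res.es < 0
        assert res.p_nominal <= 0.05
        # p = (1+0)/(1+m) for some integer m <= 99
        m = 1 / res.p_nominal - 1
        assert m == pytest.approx(round(m), abs=1e-9) and m <= 99

    def test_deterministic_given_seed(self, default_cohort):
        z = zscore_vs_reference(default_cohort.expression)
        labels = stratify_extremes(summed_zscore(z, default_cohort.ar_set), 1 / 3)
        a = permutation_test(default_cohort.expression, labels, default_cohort.nfkb_set,
                             n_permutations=50, seed=3)
        b = permutation_test(default_cohort.expression, labels, default_cohort.nfkb_set,
                             n_permutations=50, seed=3)
        assert a.es == b.es and a.p_nominal == b.p_nominal and a.nes == b.nes

    def test_null_pvalues_calibrated(self):
        """Null cohorts (beta=0): rejection at 0.05 within binomial tolerance."""
        rejections = 0
        n_rep = 100
        for seed in range(n_rep):
            cohort = generate_cohort(
                SimulationConfig(effect_size_beta=0.0, anticorrelation_rho=0.0,
                                 hazard_gamma=0.0, seed=2000 + seed)
            )
            z = zscore_vs_reference(cohort.expression)
            labels = stratify_extremes(summed_zscore(z, cohort.ar_set), 1 / 3)
            res = permutation_test(cohort.expression, labels, cohort.nfkb_set,
                                   n_permutations=99, seed=seed)
            rejections += res.p_nominal <= 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_planted_repression_detected(self):
        """Default cohorts: NF-kB set depleted in high-AR tumors (es<0, p<=0.05)."""
        hits = 0
        for seed in range(25):
            cohort = generate_cohort(SimulationConfig(seed=3000 + seed))
            z = zscore_vs_reference(cohort.expression)
            labels = stratify_extremes(summed_zscore(z, cohort.ar_set), 1 / 3)
            res = permutation_test(cohort.expression, labels, cohort.nfkb_set,
                                   n_permutations=99, seed=seed)
            hits += (res.es < 0) and (res.p_nominal <= 0.05)
        assert hits >= 23

    def test_signal_strength_monotone_in_beta(self):
        """Mean |ES| and the rejection rate grow with the planted effect size.

        |NES| is deliberately not used here: once the enrichment saturates
        (|ES| -> 1) the phenotype-permutation null also inflates, because the
        planted signature genes stay mutually correlated under label
        shuffles, so |NES| can dip at large effect sizes while the
        enrichment itself keeps strengthening.
        """
        mean_es, rejections = [], []
        for beta in (0.0, 0.5, 1.0):
            vals, rej = [], 0
            for seed in range(15):
                cohort = generate_cohort(SimulationConfig(effect_size_beta=beta, seed=4000 + seed))
                z = zscore_vs_reference(cohort.expression)
                labels = stratify_extremes(summed_zscore(z, cohort.ar_set), 1 / 3)
                res = permutation_test(cohort.expression, labels, cohort.nfkb_set,
                                       n_permutations=49, seed=seed)
                vals.append(abs(res.es))
                rej += res.p_nominal <= 0.05
            mean_es.append(np.mean(vals))
            rejections.append(rej)
        assert mean_es[0] <= mean_es[1] <= mean_es[2]
        assert rejections[0] <= rejections[1] <= rejections[2]


class TestDeriveRepressedTargets:
    def test_singleton_negative_case(self):
        ranked = _ranked([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        res = enrichment_score(ranked, GeneSet("s", ("C",)), weight=0.0)
        derived = derive_repressed_targets(res, name="rep")
        assert derived.genes == ("C",)

    def test_positive_enrichment_rejected(self):
        ranked = _ranked([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        res = enrichment_score(ranked, GeneSet("s", ("A",)))
        with pytest.raises(ValueError, match="opposite contrast"):
            derive_repressed_targets(res)

    def test_leading_edge_precision_vs_truth(self):
        """Derived set is dominated by true NF-kB program genes (25 seeds)."""
        good = 0
        for seed in range(25):
            cohort = generate_cohort(SimulationConfig(seed=5000 + seed))
            z = zscore_vs_reference(cohort.expression)
            labels = stratify_extremes(summed_zscore(z, cohort.ar_set), 1 / 3)
            ranked = rank_by_t(cohort.expression, labels)
            res = enrichment_score(ranked, cohort.nfkb_set, min_overlap=5)
            if res.es >= 0:
                continue
            derived = derive_repressed_targets(res)
            truth = set(cohort.truth["nfkb_genes"])
            precision = len(set(derived.genes) & truth) / len(derived.genes)
            good += precision >= 0.8
        assert good >= 20
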