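"""Retrieval ladder, medoid section generation, ROUGE/BERTScore, baselines."""

import numpy as np
import pytest

from conftest import StubTokenEncoder, make_trial
from ecclust.cluster import ClusteringSolution, ClusterParams, compute_medoids, compute_prevalence
from ecclust.embedding import HashTokenEncoder
from ecclust.generation import (
    ShuffleEchoGenerator,
    bert_score,
    generate_section,
    mean_rouge_f1,
    random_reference_baseline,
    retrieve_similar_criteria,
    rouge_score,
    select_evaluation_trials,
    silhouette_quality_correlation,
)
from ecclust.ingest import CriterionRecord, criteria_from_trials
from oracles import rouge_oracle


def crit(cid, trial, n_copies=1):
    return [
        CriterionRecord(
            criterion_id=f"{cid}_{k}", trial_id=trial, text=f"rule {cid} {k}",
            kind="inclusion", phases=frozenset({1}),
            condition_codes=frozenset({"C04.100"}),
            intervention_codes=frozenset({"D02.455"}),
        )
        for k in range(n_copies)
    ]


def trial_with(tid, conds, ints, phases=(1,), n_criteria=5):
    text = "Inclusion Criteria:\n" + "\n".join(
        f"- rule {tid} number {i}" for i in range(n_criteria)
    )
    return make_trial(
        tid, phases=phases, condition_codes=conds, intervention_codes=ints,
        eligibility_text=text,
    )


class TestRetrieval:
    def _registry(self):
        # target shares deep codes with group A, only shallow codes with group B
        target = trial_with("TGT", ("C04.111.222.333",), ("D02.455.426",))
        group_a = [
            trial_with(f"A{i}", ("C04.111.222.333",), ("D02.455.426",), n_criteria=10)
            for i in range(3)
        ]
        group_b = [
            trial_with(f"B{i}", ("C04.111.888.777",), ("D02.888.777",), n_criteria=10)
            for i in range(5)
        ]
        trials = [target] + group_a + group_b
        return target, trials, criteria_from_trials(trials)

    def test_fine_granularity_used_when_it_reaches_threshold(self):
        target, trials, criteria = self._registry()
        result = retrieve_similar_criteria(target, trials, criteria, thresholds=(30, 10))
        assert result.granularity == (4, 3)
        assert len(result.criterion_indices) == 30  # group A only

    def test_ladder_relaxes_to_broadest_when_needed(self):
        target, trials, criteria = self._registry()
        # group A alone (30) misses the relax threshold; (2, 1) adds group B
        result = retrieve_similar_criteria(target, trials, criteria, thresholds=(60, 40))
        assert result.granularity == (2, 1)
        assert len(result.criterion_indices) == 80

    def test_rejection_when_floor_unreachable(self):
        target, trials, criteria = self._registry()
        assert retrieve_similar_criteria(target, trials, criteria, (500, 400)) is None

    def test_target_own_criteria_always_excluded(self):
        target, trials, criteria = self._registry()
        result = retrieve_similar_criteria(target, trials, criteria, thresholds=(30, 10))
        assert all(criteria[i].trial_id != "TGT" for i in result.criterion_indices)

    def test_ladder_counts_are_monotone(self):
        target, trials, criteria = self._registry()
        counts = []
        from ecclust.generation import RETRIEVAL_LADDER, _matches

        for cond_level, int_level in RETRIEVAL_LADDER:
            matched = [
                t for t in trials
                if t.trial_id != "TGT" and _matches(target, t, cond_level, int_level)
            ]
            counts.append(sum(1 for c in criteria if c.trial_id in {t.trial_id for t in matched}))
        assert counts[0] <= counts[1] <= counts[2]


class TestSelectEvaluationTrials:
    def _trials(self):
        trials = [
            trial_with(f"T{i}", (f"C04.1{i % 2}1.222.333",), ("D02.455.426",), n_criteria=8)
            for i in range(6)
        ]
        return trials, criteria_from_trials(trials)

    def test_selection_is_deterministic_and_capped_by_pool(self):
        trials, criteria = self._trials()
        a = select_evaluation_trials(trials, criteria, "C04", n=50,
                                     thresholds=(10, 5), seed=3)
        b = select_evaluation_trials(trials, criteria, "C04", n=50,
                                     thresholds=(10, 5), seed=3)
        assert a == b
        assert set(a) <= {t.trial_id for t in trials}
        assert len(a) == 6  # whole acceptable pool returned with a warning

    def test_subset_selection_from_acceptable_pool(self):
        trials, criteria = self._trials()
        chosen = select_evaluation_trials(trials, criteria, "C04", n=2,
                                          thresholds=(10, 5), seed=4)
        assert len(chosen) == 2

    def test_condition_root_filter_applies(self):
        trials, criteria = self._trials()
        assert select_evaluation_trials(trials, criteria, "C14", n=3,
                                        thresholds=(10, 5), seed=0) == []


def equal_prevalence_solution(n_clusters, per=2):
    assignments = np.repeat(np.arange(n_clusters), per)
    coords = np.random.default_rng(0).normal(size=(len(assignments), 2))
    return ClusteringSolution(
        assignments=assignments, coords_2d=coords, theta=ClusterParams(),
        medoid_index=compute_medoids(coords, assignments),
        prevalence=compute_prevalence(assignments), objective_value=0.0,
    )


class TestGenerateSection:
    def test_section_reaches_target_count_with_enough_clusters(self):
        solution = equal_prevalence_solution(30)
        texts = [f"criterion {i}" for i in range(60)]
        section = generate_section(solution, texts, target_count=30, seed=0)
        assert len(section.texts) == 30

    def test_clusters_exhaust_below_target(self):
        solution = equal_prevalence_solution(5)
        texts = [f"criterion {i}" for i in range(10)]
        section = generate_section(solution, texts, target_count=10, seed=0)
        assert len(section.texts) == 5
        assert len(set(section.source_clusters)) == 5  # each cluster once

    def test_equal_prevalences_fill_in_cluster_id_order_first_pass(self):
        solution = equal_prevalence_solution(6)
        texts = [f"criterion {i}" for i in range(12)]
        section = generate_section(solution, texts, target_count=4, seed=9)
        # inclusion probability is 1 for every candidate, so the first pass
        # takes clusters in prevalence-tie order = ascending cluster id
        assert section.source_clusters == [0, 1, 2, 3]

    def test_deterministic_given_seed_and_length_invariant(self):
        rng = np.random.default_rng(5)
        assignments = np.concatenate([np.full(k + 1, k) for k in range(8)])
        coords = rng.normal(size=(len(assignments), 2))
        solution = ClusteringSolution(
            assignments=assignments, coords_2d=coords, theta=ClusterParams(),
            medoid_index=compute_medoids(coords, assignments),
            prevalence=compute_prevalence(assignments), objective_value=0.0,
        )
        texts = [f"criterion {i}" for i in range(len(assignments))]
        for seed in (0, 1, 2, 3):
            a = generate_section(solution, texts, target_count=5, seed=seed)
            b = generate_section(solution, texts, target_count=5, seed=seed)
            assert a.texts == b.texts
            assert len(a.texts) == 5

    def test_no_clusters_rejected(self):
        solution = equal_prevalence_solution(2)
        solution.medoid_index = {}
        solution.prevalence = {}
        with pytest.raises(ValueError):
            generate_section(solution, ["a"], 3, seed=0)


class TestRouge:
    def test_identical_texts_score_one_on_all_variants(self):
        text = "patients must sign informed consent before screening"
        for variant in ("1", "2", "L"):
            assert rouge_score(text, text, variant) == (1.0, 1.0, 1.0)

    def test_hand_computed_three_token_example(self):
        p, r, f = rouge_score("a b c", "a c d", "1")
        assert (p, r, f) == pytest.approx((2 / 3, 2 / 3, 2 / 3))
        p, r, f = rouge_score("a b c", "a c d", "L")
        assert (p, r, f) == pytest.approx((2 / 3, 2 / 3, 2 / 3))
        assert rouge_score("a b c", "a c d", "2") == (0.0, 0.0, 0.0)

    def test_disjoint_vocabularies_score_zero(self):
        for variant in ("1", "2", "L"):
            assert rouge_score("alpha beta", "gamma delta", variant)[2] == 0.0

    def test_empty_either_side_scores_zero(self):
        assert rouge_score("", "words here", "1") == (0.0, 0.0, 0.0)
        assert rouge_score("words here", "", "L") == (0.0, 0.0, 0.0)

    def test_f1_symmetric_under_swap(self):
        a = "age over 18 with signed consent"
        b = "signed consent and stable disease required"
        for variant in ("1", "2", "L"):
            assert rouge_score(a, b, variant)[2] == pytest.approx(
                rouge_score(b, a, variant)[2]
            )

    def test_matches_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        vocab = [f"word{i}" for i in range(30)]
        for _ in range(50):
            cand = " ".join(rng.choice(vocab, size=rng.integers(1, 25)))
            ref = " ".join(rng.choice(vocab, size=rng.integers(1, 25)))
            for variant in ("1", "2", "L"):
                ours = rouge_score(cand, ref, variant)
                oracle = rouge_oracle(cand, ref, variant)
                assert ours == pytest.approx(oracle, abs=1e-6)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            rouge_score("a", "a", "3")


class TestBertScore:
    def test_identical_sequences_score_one(self):
        enc = HashTokenEncoder(dim=64, seed=0)
        text = "stable cardiac function required"
        p, r, f = bert_score(text, text, enc)
        assert (p, r, f) == pytest.approx((1.0, 1.0, 1.0))

    def test_orthogonal_single_tokens_score_zero(self):
        enc = StubTokenEncoder({
            "a": ([[1.0, 0.0]], [True]),
            "b": ([[0.0, 1.0]], [True]),
        })
        assert bert_score("a", "b", enc) == (0.0, 0.0, 0.0)

    def test_hand_computed_greedy_matching(self):
        s = 1 / np.sqrt(2)
        enc = StubTokenEncoder({
            "cand": ([[1.0, 0.0], [0.0, 1.0]], [True, True]),
            "ref": ([[1.0, 0.0], [s, s]], [True, True]),
        })
        p, r, f = bert_score("cand", "ref", enc)
        expected = (1 + s) / 2
        assert p == pytest.approx(expected)
        assert r == pytest.approx(expected)
        assert f == pytest.approx(expected, abs=1e-3)  # ~0.854

    def test_empty_side_scores_zero(self):
        enc = HashTokenEncoder(dim=16, seed=0)
        assert bert_score("", "words", enc) == (0.0, 0.0, 0.0)


class TestBaselineAndCorrelation:
    def test_degenerate_pool_equals_method_score(self):
        sections = ["age over 18 signed consent"]
        pool = ["age over 18 signed consent"]
        baseline = random_reference_baseline(sections, pool, mean_rouge_f1, seed=0)
        assert baseline["mean"] == pytest.approx(mean_rouge_f1(sections[0], pool[0]))

    def test_baseline_deterministic_given_seed(self):
        sections = [f"section {i} words" for i in range(5)]
        pool = [f"pool entry {i}" for i in range(9)]
        a = random_reference_baseline(sections, pool, mean_rouge_f1, seed=7)
        b = random_reference_baseline(sections, pool, mean_rouge_f1, seed=7)
        assert a == b

    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert silhouette_quality_correlation(x, x)["r"] == pytest.approx(1.0)
        assert silhouette_quality_correlation(x, [-v for v in x])["r"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        result = silhouette_quality_correlation([1, 2, 3], [1, 2, 4])
        assert result["r"] == pytest.approx(9 / np.sqrt(84), abs=1e-9)

    def test_zero_variance_flagged(self):
        result = silhouette_quality_correlation([1, 1, 1], [1, 2, 3])
        assert result["zero_variance"]

    def test_echo_generator_is_seedable_smoke(self):
        trial = trial_with("T1", ("C04.100",), ("D02.455",))
        gen = ShuffleEchoGenerator(seed=0)
        out = gen.generate(trial)
        assert sorted(out.splitlines()) == sorted(
            ln for ln in trial.eligibility_text.splitlines() if ln.strip()
        )
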