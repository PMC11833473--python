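"""Composite labels, AMI against the enumeration oracle, ceiling, review sheet."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_trial
from ecclust.alignment import (
    adjusted_mutual_information,
    build_composite_labels,
    ceiling_ami,
    export_expert_review,
    normalized_alignment,
    score_expert_review,
)
from ecclust.cluster import ClusteringSolution, ClusterParams, compute_medoids, compute_prevalence
from ecclust.ingest import CriterionRecord, criteria_from_trials
from oracles import ami_oracle, partitions


def crit(cid, trial, phases, conds, ints):
    return CriterionRecord(
        criterion_id=cid,
        trial_id=trial,
        text=f"rule {cid}",
        kind="inclusion",
        phases=frozenset(phases),
        condition_codes=frozenset(conds),
        intervention_codes=frozenset(ints),
    )


def solution_from(assignments, coords=None, seed=0):
    assignments = np.asarray(assignments)
    if coords is None:
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(len(assignments), 2))
    return ClusteringSolution(
        assignments=assignments,
        coords_2d=np.asarray(coords, float),
        theta=ClusterParams(),
        medoid_index=compute_medoids(coords, assignments),
        prevalence=compute_prevalence(assignments),
        objective_value=0.0,
        seed=seed,
    )


class TestCompositeLabels:
    def test_paper_style_duplication_two_phases_two_conditions(self):
        c = crit("c1", "T1", {1, 2}, {"C04.111.222.333", "C14.222.333.444"},
                 {"D02.455.426"})
        labeled = build_composite_labels([c], granularity=(4, 3))
        assert len(labeled) == 4
        assert set(labeled.labels) == {
            "P1-D02.455.426-C04.111.222.333",
            "P1-D02.455.426-C14.222.333.444",
            "P2-D02.455.426-C04.111.222.333",
            "P2-D02.455.426-C14.222.333.444",
        }

    def test_single_slot_values_give_one_duplicate(self):
        c = crit("c1", "T1", {3}, {"C04.557"}, {"D02.455"})
        assert len(build_composite_labels([c], (4, 3))) == 1

    def test_truncation_deduplicates_and_halves_the_product(self):
        c = crit("c1", "T1", {1}, {"C04.557.337", "C04.557.470"}, {"D02.455"})
        fine = build_composite_labels([c], (4, 3))
        coarse = build_composite_labels([c], (2, 1))
        assert len(fine) == 2
        assert len(coarse) == 1  # both conditions truncate to C04.557 -> C04

    def test_criterion_missing_a_slot_is_excluded_and_counted(self):
        good = crit("c1", "T1", {1}, {"C04.557"}, {"D02.455"})
        bad = crit("c2", "T1", {1}, set(), {"D02.455"})
        labeled = build_composite_labels([good, bad], (4, 3))
        assert labeled.n_excluded == 1
        assert list(labeled.criterion_index) == [0]

    @given(
        n_phases=st.integers(1, 3),
        n_conds=st.integers(1, 3),
        n_ints=st.integers(1, 3),
    )
    def test_duplication_count_is_product_of_set_sizes(self, n_phases, n_conds, n_ints):
        conds = {f"C{k:02d}.100.200.300" for k in range(1, n_conds + 1)}
        ints = {f"D{k:02d}.400.500" for k in range(1, n_ints + 1)}
        c = crit("c1", "T1", set(range(1, n_phases + 1)), conds, ints)
        labeled = build_composite_labels([c], (4, 3))
        assert len(labeled) == n_phases * n_conds * n_ints

    def test_coarsening_never_increases_distinct_labels(self, synthetic_corpus):
        criteria = synthetic_corpus["criteria"][:400]
        counts = [
            len(set(build_composite_labels(criteria, g).labels))
            for g in ((4, 3), (3, 2), (2, 1))
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestAdjustedMutualInformation:
    def test_identical_partitions_score_one(self):
        assert adjusted_mutual_information(list("AABB"), list("AABB")) == pytest.approx(1.0)

    def test_invariant_to_label_renaming_and_symmetric(self):
        u = ["A", "A", "B", "B", "C"]
        v = ["x", "x", "y", "y", "z"]
        assert adjusted_mutual_information(u, v) == pytest.approx(1.0)
        w = ["x", "y", "x", "y", "x"]
        assert adjusted_mutual_information(u, w) == pytest.approx(
            adjusted_mutual_information(w, u)
        )

    def test_crossed_partition_matches_enumeration_oracle(self):
        u, v = list("AABB"), list("XYXY")
        assert adjusted_mutual_information(u, v) == pytest.approx(
            ami_oracle(u, v), abs=1e-9
        )

    def test_matches_oracle_on_all_partition_pairs_up_to_five_items(self):
        for n in (2, 3, 4, 5):
            parts = list(partitions(n))
            for u, v in itertools.product(parts, repeat=2):
                assert adjusted_mutual_information(u, v) == pytest.approx(
                    ami_oracle(u, v), abs=1e-9
                ), (u, v)

    def test_matches_oracle_on_sampled_partition_pairs_of_six_to_eight(self):
        rng = np.random.default_rng(0)
        for n in (6, 7, 8):
            parts = list(partitions(n))
            for _ in range(40):
                u = parts[int(rng.integers(len(parts)))]
                v = parts[int(rng.integers(len(parts)))]
                assert adjusted_mutual_information(u, v) == pytest.approx(
                    ami_oracle(u, v), abs=1e-9
                ), (u, v)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            adjusted_mutual_information([1, 2], [1])
        with pytest.raises(ValueError):
            adjusted_mutual_information([], [])


class TestCeilingAmi:
    def test_one_criterion_per_trial_reaches_one(self):
        criteria = [
            crit(f"c{i}", f"T{i}", {i % 2 + 1}, {f"C{i:02d}.100"}, {"D02.455"})
            for i in range(6)
        ]
        labeled = build_composite_labels(criteria, (4, 3))
        assert ceiling_ami(labeled) == pytest.approx(1.0)

    def test_two_trials_two_criteria_matches_oracle_construction(self):
        criteria = [
            crit("c1", "T1", {1}, {"C04.100"}, {"D02.455"}),
            crit("c2", "T1", {1}, {"C04.100"}, {"D02.455"}),
            crit("c3", "T2", {2}, {"C14.200"}, {"D27.505"}),
            crit("c4", "T2", {2}, {"C14.200"}, {"D27.505"}),
        ]
        labeled = build_composite_labels(criteria, (4, 3))
        expected = ami_oracle(["L1", "s1", "L2", "s2"], ["L1", "L1", "L2", "L2"])
        assert ceiling_ami(labeled) == pytest.approx(expected, abs=1e-9)

    def test_ceiling_never_exceeds_one(self, synthetic_corpus):
        labeled = build_composite_labels(synthetic_corpus["criteria"][:300], (2, 1))
        assert ceiling_ami(labeled) <= 1.0


class TestNormalizedAlignment:
    def _single_criterion_setup(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        roots = ["C01", "C04", "C14", "C20"]
        criteria = [
            crit(
                f"c{i}", f"T{i}", {int(rng.integers(1, 5))},
                {f"{rng.choice(roots)}.{int(rng.integers(100, 999)):03d}"},
                {f"D{int(rng.integers(1, 30)):02d}.{int(rng.integers(100, 999)):03d}"},
            )
            for i in range(n)
        ]
        return build_composite_labels(criteria, (2, 1))

    def test_idealized_assignment_scores_one(self):
        labeled = self._single_criterion_setup(120, seed=1)
        # one criterion per trial: the ideal assignment is the label partition
        label_ids = {lab: k for k, lab in enumerate(dict.fromkeys(labeled.labels))}
        assignments = np.array([label_ids[lab] for lab in labeled.labels])
        result = normalized_alignment(assignments, labeled)
        assert result["normalized_ami"] == pytest.approx(1.0)

    def test_random_assignments_center_on_zero(self):
        labeled = self._single_criterion_setup(500, seed=2)
        rng = np.random.default_rng(3)
        assignments = rng.integers(0, 25, size=500)
        result = normalized_alignment(assignments, labeled)
        assert abs(result["normalized_ami"]) < 0.05

    def test_planted_structure_beats_collapsed_structure(self, synthetic_corpus):
        criteria = synthetic_corpus["criteria"]
        truth = synthetic_corpus["truth"]
        labeled = build_composite_labels(criteria, (2, 1))
        planted = truth.template_labels(criteria)
        rng = np.random.default_rng(4)
        shuffled = planted.copy()
        rng.shuffle(shuffled)  # same cluster sizes, no association
        score_planted = normalized_alignment(planted, labeled)["normalized_ami"]
        score_shuffled = normalized_alignment(shuffled, labeled)["normalized_ami"]
        assert score_planted > score_shuffled

    def test_noise_handling_modes_differ_only_with_noise(self):
        labeled = self._single_criterion_setup(80, seed=5)
        rng = np.random.default_rng(6)
        assignments = rng.integers(0, 5, size=80)
        pooled = normalized_alignment(assignments, labeled, "pool")
        excluded = normalized_alignment(assignments, labeled, "exclude")
        assert pooled["ami"] == pytest.approx(excluded["ami"])
        with pytest.raises(ValueError):
            normalized_alignment(assignments, labeled, "drop")


class TestExpertReview:
    def _big_solution(self, n_clusters=50, per=20):
        assignments = np.repeat(np.arange(n_clusters), per)
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(len(assignments), 2)) + 10 * np.stack(
            [assignments % 10, assignments // 10], axis=1
        )
        criteria = [
            crit(f"c{i}", f"T{i // per}", {1}, {"C04.100"}, {"D02.455"})
            for i in range(len(assignments))
        ]
        return solution_from(assignments, coords), criteria

    def test_fifty_by_twenty_sheet_has_thousand_rows(self, tmp_path):
        solution, criteria = self._big_solution()
        sheet = export_expert_review(solution, criteria, path=tmp_path / "sheet.csv")
        assert len(sheet) == 1000
        assert list(sheet.columns) == ["criterion_id", "cluster_id", "text", "verdict"]
        assert (sheet["verdict"] == "").all()

    def test_single_cluster_single_row_is_the_medoid(self):
        assignments = np.array([0, 0, 0])
        coords = np.array([(0.0, 0.0), (1.0, 0.0), (5.0, 0.0)])
        solution = solution_from(assignments, coords)
        criteria = [crit(f"c{i}", "T1", {1}, {"C04.100"}, {"D02.455"}) for i in range(3)]
        sheet = export_expert_review(solution, criteria, n_clusters=1, n_per_cluster=1)
        assert len(sheet) == 1
        assert sheet.iloc[0]["criterion_id"] == "c1"  # the collinear medoid

    def test_too_few_eligible_clusters_is_an_error(self):
        solution, criteria = self._big_solution(n_clusters=49)
        with pytest.raises(ValueError, match="49"):
            export_expert_review(solution, criteria, n_clusters=50)

    def test_rows_are_nearest_to_medoid_in_order(self):
        solution, criteria = self._big_solution(n_clusters=2, per=30)
        sheet = export_expert_review(solution, criteria, n_clusters=2, n_per_cluster=5)
        for cid in (0, 1):
            rows = sheet[sheet["cluster_id"] == cid]
            medoid_pt = solution.coords_2d[solution.medoid_index[cid]]
            picked = [int(r[1:]) for r in rows["criterion_id"]]
            dists = np.linalg.norm(solution.coords_2d - medoid_pt, axis=1)
            members = np.flatnonzero(solution.assignments == cid)
            best = members[np.argsort(dists[members], kind="stable")][:5]
            assert sorted(picked) == sorted(int(criteria[i].criterion_id[1:]) for i in best)


class TestScoreExpertReview:
    def test_all_correct_scores_one(self):
        sheet = pd.DataFrame({"verdict": ["correct"] * 5})
        assert score_expert_review(sheet) == 1.0

    def test_fraction_rule_on_thousand_rows(self):
        verdicts = ["correct"] * 843 + ["not correct"] * 100 + ["unclear"] * 57
        assert score_expert_review(pd.DataFrame({"verdict": verdicts})) == pytest.approx(0.843)

    def test_unclear_counts_in_denominator(self):
        sheet = pd.DataFrame(
            {"verdict": ["correct", "not correct", "unclear", "unclear"]}
        )
        assert score_expert_review(sheet) == 0.25

    def test_invalid_verdict_reports_row(self):
        sheet = pd.DataFrame({"verdict": ["correct", "maybe"]})
        with pytest.raises(ValueError, match="row 1"):
            score_expert_review(sheet)
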