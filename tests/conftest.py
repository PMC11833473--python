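"""Shared fixtures: tiny hand-built registries and one clustered synthetic corpus."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

import ecclust
from ecclust.cluster import ClusterParams, cluster_pipeline
from ecclust.ingest import TrialRecord, criteria_from_trials

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_trial(
    trial_id="NCT001",
    study_type="interventional",
    status="completed",
    phases=(2,),
    start_date=dt.date(2010, 5, 1),
    condition_codes=("C04.557.337",),
    intervention_codes=("D02.455.426",),
    eligibility_text="Inclusion Criteria:\n- Age >= 18 years\n- Signed consent",
    enrollment=100,
    duration_days=365.0,
) -> TrialRecord:
    return TrialRecord(
        trial_id=trial_id,
        study_type=study_type,
        status=status,
        phases=frozenset(phases),
        start_date=start_date,
        condition_codes=frozenset(condition_codes),
        intervention_codes=frozenset(intervention_codes),
        eligibility_text=eligibility_text,
        enrollment=enrollment,
        duration_days=duration_days,
    )


@pytest.fixture(scope="session")
def synthetic_corpus():
    """A 60-trial synthetic registry with criteria, embeddings and ground truth."""
    trials, truth = ecclust.generate_registry(
        n_trials=60, n_templates=6, criteria_per_trial=(6, 14), seed=11
    )
    criteria = criteria_from_trials(trials)
    X = ecclust.synthetic_embed(criteria, truth, separation=30, dim=32, seed=11)
    return {"trials": trials, "truth": truth, "criteria": criteria, "X": X}


@pytest.fixture(scope="session")
def clustered_corpus(synthetic_corpus):
    """The synthetic corpus plus a fixed-theta clustering solution."""
    solution = cluster_pipeline(
        synthetic_corpus["X"],
        ClusterParams(min_cluster_size=15, min_samples=5, perplexity=25),
        seed=11,
    )
    return {**synthetic_corpus, "solution": solution}


class StubTokenEncoder:
    """Token encoder returning pre-set vectors/masks keyed by exact text."""

    max_length = 64

    def __init__(self, table):
        self.table = table

    def token_vectors(self, text):
        vectors, mask = self.table[text]
        return np.asarray(vectors, dtype=float), np.asarray(mask, dtype=bool)
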