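"""Eligibility-section generation from cluster medoids, with text metrics.

For a target trial, criteria are retrieved from all other trials sharing at
least one phase, condition and intervention, with condition/intervention
matching first attempted at fine MeSH granularity (condition level 4,
intervention level 3) and relaxed to (3, 2) then (2, 1) whenever fewer than a
threshold of criteria are found; a target whose broadest retrieval still
falls below the acceptance floor is rejected.  The retrieved criteria are
clustered, and a draft eligibility section is assembled from cluster-medoid
criteria: candidates are visited in descending cluster prevalence and
included with probability proportional to prevalence (normalized by the
maximum), looping until a per-condition target length is reached or all
clusters are used, each cluster contributing at most once.

Drafts are scored against the target's real section with self-implemented
ROUGE-1/2/L and a greedy-matching embedding score (BERTScore-style, pluggable
token embedder, no idf weighting or baseline rescaling), against random
reference sections as a baseline, and correlated with cluster quality.
"""

from __future__ import annotations

import abc
import dataclasses
import logging
import re
from collections import Counter
from typing import Sequence

import numpy as np
from scipy import stats

from .cluster import ClusteringSolution
from .embedding import TokenEncoder
from .ingest import CriterionRecord, TrialRecord, truncate_mesh_code

__all__ = [
    "RetrievalResult",
    "GeneratedSection",
    "RETRIEVAL_LADDER",
    "DEFAULT_THRESHOLDS",
    "TARGET_SECTION_LENGTHS",
    "retrieve_similar_criteria",
    "select_evaluation_trials",
    "generate_section",
    "rouge_score",
    "bert_score",
    "random_reference_baseline",
    "silhouette_quality_correlation",
    "TextGenerator",
    "ShuffleEchoGenerator",
]

logger = logging.getLogger(__name__)

#: (condition level, intervention level), tried finest-first.
RETRIEVAL_LADDER = ((4, 3), (3, 2), (2, 1))

#: (relaxation threshold, acceptance floor) in retrieved-criterion counts.
DEFAULT_THRESHOLDS = (5000, 2500)

#: Target generated-section length per condition root (mean criteria per
#: trial for that condition); arbitrary roots fall back to an empirical mean.
TARGET_SECTION_LENGTHS = {"C01": 21, "C04": 30, "C14": 21, "C20": 24}

_TOKEN_RE = re.compile(r"[0-9a-z]+")


@dataclasses.dataclass
class RetrievalResult:
    target_trial_id: str
    granularity: tuple[int, int]
    criterion_indices: list[int]  # indices into the registry criterion list


@dataclasses.dataclass
class GeneratedSection:
    target_trial_id: str
    texts: list[str]
    source_clusters: list[int]
    target_count: int

    def as_text(self) -> str:
        return "\n".join(self.texts)


def _matches(
    target: TrialRecord, other: TrialRecord, cond_level: int, int_level: int
) -> bool:
    if not (target.phases & other.phases):
        return False
    t_cond = {truncate_mesh_code(c, cond_level) for c in target.condition_codes}
    o_cond = {truncate_mesh_code(c, cond_level) for c in other.condition_codes}
    if not (t_cond & o_cond):
        return False
    t_int = {truncate_mesh_code(c, int_level) for c in target.intervention_codes}
    o_int = {truncate_mesh_code(c, int_level) for c in other.intervention_codes}
    return bool(t_int & o_int)


def retrieve_similar_criteria(
    target: TrialRecord,
    trials: Sequence[TrialRecord],
    criteria: Sequence[CriterionRecord],
    thresholds: tuple[int, int] = DEFAULT_THRESHOLDS,
) -> RetrievalResult | None:
    """Criteria from trials sharing phase/condition/intervention with the target.

    Matching starts at granularity (4, 3); whenever fewer than
    ``thresholds[0]`` criteria are retrieved the ladder relaxes to (3, 2) then
    (2, 1).  The first rung reaching the relaxation threshold is used; failing
    that, the broadest rung is accepted if it reaches the floor
    ``thresholds[1]``, otherwise the target is rejected (returns None).
    """
    relax, accept = thresholds
    rows_by_trial: dict[str, list[int]] = {}
    for i, crit in enumerate(criteria):
        rows_by_trial.setdefault(crit.trial_id, []).append(i)
    last: RetrievalResult | None = None
    for cond_level, int_level in RETRIEVAL_LADDER:
        matched = [
            t for t in trials
            if t.trial_id != target.trial_id and _matches(target, t, cond_level, int_level)
        ]
        indices = [i for t in matched for i in rows_by_trial.get(t.trial_id, [])]
        last = RetrievalResult(
            target_trial_id=target.trial_id,
            granularity=(cond_level, int_level),
            criterion_indices=indices,
        )
        if len(indices) >= relax:
            return last
    if last is not None and len(last.criterion_indices) >= accept:
        return last
    return None


def select_evaluation_trials(
    trials: Sequence[TrialRecord],
    criteria: Sequence[CriterionRecord],
    condition_root: str,
    n: int = 100,
    thresholds: tuple[int, int] = DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> list[str]:
    """Sample up to ``n`` evaluation trials matching a condition root.

    Candidates (trials with at least one condition code under the root) are
    visited in seeded random order; a candidate whose retrieval is rejected is
    skipped.  Returns fewer than ``n`` ids (with a logged warning) when the
    acceptable pool is exhausted.
    """
    candidates = [
        t for t in trials
        if any(truncate_mesh_code(c, 1) == condition_root for c in t.condition_codes)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    chosen: list[str] = []
    for idx in order:
        if len(chosen) >= n:
            break
        target = candidates[idx]
        if retrieve_similar_criteria(target, trials, criteria, thresholds) is not None:
            chosen.append(target.trial_id)
    if len(chosen) < n:
        logger.warning(
            "select_evaluation_trials(%s): only %d acceptable trials (asked %d)",
            condition_root, len(chosen), n,
        )
    return chosen


def generate_section(
    solution: ClusteringSolution,
    criterion_texts: Sequence[str],
    target_count: int,
    seed: int = 0,
    target_trial_id: str = "",
) -> GeneratedSection:
    """Assemble a draft section from cluster-medoid criteria.

    Candidates are the medoid criterion of every cluster, ordered by
    descending prevalence (ties to the lower cluster id).  Repeated passes
    visit the not-yet-included candidates, including each with probability
    ``prevalence / max_prevalence`` (so the most prevalent cluster always
    enters on the first pass), until ``target_count`` criteria are included or
    every cluster has contributed.  Each cluster contributes at most once.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if not solution.medoid_index:
        raise ValueError("solution has no clusters to generate from")
    order = sorted(solution.prevalence, key=lambda c: (-solution.prevalence[c], c))
    max_prev = solution.prevalence[order[0]]
    rng = np.random.default_rng(seed)
    included: list[int] = []
    remaining = list(order)
    while remaining and len(included) < target_count:
        progressed = []
        for cid in remaining:
            if len(included) >= target_count:
                progressed.append(cid)
                continue
            if rng.random() < solution.prevalence[cid] / max_prev:
                included.append(cid)
            else:
                progressed.append(cid)
        remaining = progressed
        if len(remaining) == len(order) and not included:
            # degenerate safeguard; cannot occur since max-prevalence always enters
            break
    if len(included) < target_count:
        logger.warning(
            "generate_section: clusters exhausted at %d < target %d",
            len(included), target_count,
        )
    texts = [str(criterion_texts[solution.medoid_index[c]]) for c in included]
    return GeneratedSection(
        target_trial_id=target_trial_id,
        texts=texts,
        source_clusters=included,
        target_count=target_count,
    )


# ---------------------------------------------------------------------------
# ROUGE
# ---------------------------------------------------------------------------


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def rouge_score(
    candidate: str, reference: str, variant: str = "1"
) -> tuple[float, float, float]:
    """ROUGE precision, recall and F1 for variant "1", "2" or "L".

    Tokens are lowercased alphanumeric words.  ROUGE-N uses clipped n-gram
    overlap counts; ROUGE-L uses the longest common subsequence over the whole
    token sequence (document level).  Empty candidate or reference scores all
    zeros.
    """
    variant = str(variant).upper()
    cand, ref = _tokens(candidate), _tokens(reference)
    if not cand or not ref:
        return (0.0, 0.0, 0.0)
    if variant == "L":
        overlap = _lcs_length(cand, ref)
        denom_p, denom_r = len(cand), len(ref)
    elif variant in ("1", "2"):
        n = int(variant)
        c_counts, r_counts = _ngrams(cand, n), _ngrams(ref, n)
        overlap = sum((c_counts & r_counts).values())
        denom_p = max(sum(c_counts.values()), 0)
        denom_r = max(sum(r_counts.values()), 0)
        if denom_p == 0 or denom_r == 0:
            return (0.0, 0.0, 0.0)
    else:
        raise ValueError(f"unknown ROUGE variant: {variant!r}")
    p = overlap / denom_p if denom_p else 0.0
    r = overlap / denom_r if denom_r else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return (p, r, f1)


def mean_rouge_f1(candidate: str, reference: str) -> float:
    """Average of the ROUGE-1, ROUGE-2 and ROUGE-L F1 scores."""
    return float(np.mean([rouge_score(candidate, reference, v)[2] for v in ("1", "2", "L")]))


# ---------------------------------------------------------------------------
# BERTScore-style greedy matching
# ---------------------------------------------------------------------------


def bert_score(
    candidate: str, reference: str, encoder: TokenEncoder
) -> tuple[float, float, float]:
    """Greedy cosine-similarity matching between token embeddings.

    Recall = mean over reference tokens of the maximum similarity to any
    candidate token; precision symmetrically; F = harmonic mean.  No idf
    weighting, no baseline rescaling.  Empty token lists score zeros.
    """
    c_vecs, c_mask = encoder.token_vectors(candidate)
    r_vecs, r_mask = encoder.token_vectors(reference)
    c_vecs, r_vecs = c_vecs[c_mask], r_vecs[r_mask]
    if len(c_vecs) == 0 or len(r_vecs) == 0:
        return (0.0, 0.0, 0.0)

    def _unit(m: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return m / norms

    sim = _unit(np.asarray(c_vecs, dtype=float)) @ _unit(np.asarray(r_vecs, dtype=float)).T
    p = float(sim.max(axis=1).mean())
    r = float(sim.max(axis=0).mean())
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return (p, r, f)


# ---------------------------------------------------------------------------
# Baselines and correlation
# ---------------------------------------------------------------------------


def random_reference_baseline(
    sections: Sequence[str],
    reference_pool: Sequence[str],
    metric,
    seed: int = 0,
) -> dict:
    """Score each generated section against a seeded random reference section.

    ``metric(candidate, reference) -> float``.  Returns per-section scores and
    their mean +- SEM.
    """
    if not reference_pool:
        raise ValueError("reference pool is empty")
    rng = np.random.default_rng(seed)
    picks = rng.integers(len(reference_pool), size=len(sections))
    scores = [metric(sec, reference_pool[int(k)]) for sec, k in zip(sections, picks)]
    arr = np.asarray(scores, dtype=float)
    return {
        "scores": [float(s) for s in arr],
        "mean": float(arr.mean()) if len(arr) else 0.0,
        "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
    }


def silhouette_quality_correlation(
    silhouettes: Sequence[float], scores: Sequence[float]
) -> dict:
    """Pearson correlation between per-trial cluster quality and generation score."""
    x = np.asarray(silhouettes, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired lists with n >= 3")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        return {"r": float("nan"), "p": float("nan"), "zero_variance": True}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "zero_variance": False}


# ---------------------------------------------------------------------------
# Generative comparator interface (stubbed)
# ---------------------------------------------------------------------------


class TextGenerator(abc.ABC):
    """Interface for an external section generator used as a comparator."""

    @abc.abstractmethod
    def generate(self, trial: TrialRecord) -> str:
        """Produce an eligibility section draft for the trial."""


class ShuffleEchoGenerator(TextGenerator):
    """Smoke-test stub: echoes the trial's own section with shuffled lines.

    Stands in for an external generative comparator in end-to-end smoke tests
    only; it sees the reference, so its scores are upper-bound-like and carry
    no scientific meaning.
    """

    def __init__(self, seed: int = 0):
        self._rng = np.random.default_rng(seed)

    def generate(self, trial: TrialRecord) -> str:
        lines = [ln for ln in trial.eligibility_text.splitlines() if ln.strip()]
        self._rng.shuffle(lines)
        return "\n".join(lines)
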