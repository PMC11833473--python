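"""Alignment between criterion clusters and trial-level protocol labels.

Cluster assignments are compared against composite "phase-intervention-
condition" labels built from trial metadata at a chosen MeSH granularity.
Because a criterion's trial can carry several phases, conditions and
interventions, each criterion is duplicated once per unique label combination
before scoring.  Agreement is measured with adjusted mutual information
(AMI), which corrects raw mutual information for chance alignment.

Labels live at the trial level while clusters live at the criterion level, so
an AMI of 1 is unreachable whenever trials have more than one criterion.  The
attainable ceiling is modeled as the assignment in which exactly one
designated criterion per trial lands in the cluster matching its trial label
and every other criterion is a singleton; reported alignment is normalized by
the AMI of that idealized assignment.

A 50-cluster x 20-criterion review sheet (criteria nearest each cluster
medoid) can be exported for human verdicting and scored as the fraction of
"correct" verdicts.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score

from .cluster import NOISE, ClusteringSolution
from .ingest import CriterionRecord, truncate_mesh_code

__all__ = [
    "GRANULARITIES",
    "LabeledCriterionSet",
    "build_composite_labels",
    "adjusted_mutual_information",
    "ceiling_ami",
    "normalized_alignment",
    "export_expert_review",
    "score_expert_review",
    "VERDICTS",
]

logger = logging.getLogger(__name__)

#: (condition level, intervention level) granularity pairs, finest first.
GRANULARITIES = ((4, 3), (3, 2), (2, 1))

VERDICTS = ("correct", "not correct", "unclear")


@dataclasses.dataclass
class LabeledCriterionSet:
    """Duplicated criteria with composite labels.

    Parallel arrays: ``criterion_index[r]`` points into the original criterion
    list, ``labels[r]`` is the composite "P-I-C" string, ``trial_ids[r]`` the
    parent trial.  ``n_excluded`` counts criteria lacking a phase, condition
    or intervention, which cannot be labeled.
    """

    criterion_index: np.ndarray
    labels: list[str]
    trial_ids: list[str]
    granularity: tuple[int, int]
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.labels)


def build_composite_labels(
    criteria: Sequence[CriterionRecord],
    granularity: tuple[int, int] = (4, 3),
) -> LabeledCriterionSet:
    """Duplicate each criterion once per unique phase x intervention x condition label.

    ``granularity`` is (condition level, intervention level); codes are
    truncated then deduplicated, so the duplication count per criterion is
    ``|phases| * |truncated interventions| * |truncated conditions|``.
    Criteria lacking any slot are excluded (counted, logged).
    """
    cond_level, int_level = granularity
    index: list[int] = []
    labels: list[str] = []
    trial_ids: list[str] = []
    excluded = 0
    for i, crit in enumerate(criteria):
        if not (crit.phases and crit.condition_codes and crit.intervention_codes):
            excluded += 1
            continue
        conds = sorted({truncate_mesh_code(c, cond_level) for c in crit.condition_codes})
        ints = sorted({truncate_mesh_code(c, int_level) for c in crit.intervention_codes})
        for phase in sorted(crit.phases):
            for iv in ints:
                for cd in conds:
                    index.append(i)
                    labels.append(f"P{phase}-{iv}-{cd}")
                    trial_ids.append(crit.trial_id)
    if excluded:
        logger.warning("build_composite_labels: excluded %d unlabelable criteria", excluded)
    return LabeledCriterionSet(
        criterion_index=np.array(index, dtype=int),
        labels=labels,
        trial_ids=trial_ids,
        granularity=granularity,
        n_excluded=excluded,
    )


def adjusted_mutual_information(u: Sequence, v: Sequence) -> float:
    """AMI with the hypergeometric (permutation-model) chance correction.

    AMI = (MI - E[MI]) / (mean(H(u), H(v)) - E[MI]); symmetric, invariant to
    label renaming, 1.0 for identical partitions, ~0 for random alignment.
    """
    if len(u) != len(v):
        raise ValueError(f"labeling lengths differ: {len(u)} vs {len(v)}")
    if len(u) == 0:
        raise ValueError("labelings must be nonempty")
    u_codes = pd.factorize(np.asarray(u, dtype=object))[0]
    v_codes = pd.factorize(np.asarray(v, dtype=object))[0]
    return float(adjusted_mutual_info_score(u_codes, v_codes, average_method="arithmetic"))


def ceiling_ami(labeled: LabeledCriterionSet) -> float:
    """AMI of the idealized best assignment against the composite labels.

    For every trial one designated criterion (first by original index) is
    placed in the cluster identified with its label — for a multi-label trial,
    each duplicated row of the designated criterion joins the cluster of that
    row's own label, the per-duplicate reading of "assigned to the correct
    cluster".  Every other criterion becomes its own singleton cluster (its
    duplicated rows share that singleton), mirroring the duplication applied
    to the true labels.
    """
    if len(labeled) == 0:
        raise ValueError("empty labeled set")
    designated: dict[str, int] = {}
    for row, trial in enumerate(labeled.trial_ids):
        idx = int(labeled.criterion_index[row])
        if trial not in designated or idx < designated[trial]:
            designated[trial] = idx
    ideal = [
        f"L:{labeled.labels[row]}"
        if int(labeled.criterion_index[row]) == designated[trial]
        else f"S:{int(labeled.criterion_index[row])}"
        for row, trial in enumerate(labeled.trial_ids)
    ]
    return adjusted_mutual_information(ideal, labeled.labels)


def normalized_alignment(
    solution: ClusteringSolution | np.ndarray,
    labeled: LabeledCriterionSet,
    noise_handling: str = "pool",
) -> dict:
    """Cluster-label AMI normalized by the per-condition ceiling AMI.

    ``noise_handling="pool"`` keeps unassigned criteria as one shared noise
    category; ``"exclude"`` drops their duplicated rows before scoring.
    Returns a dict with raw AMI, ceiling AMI and their ratio.
    """
    assignments = (
        solution.assignments if isinstance(solution, ClusteringSolution) else np.asarray(solution)
    )
    if noise_handling not in ("pool", "exclude"):
        raise ValueError(f"unknown noise_handling: {noise_handling!r}")
    dup_clusters = assignments[labeled.criterion_index]
    labels = np.array(labeled.labels, dtype=object)
    if noise_handling == "exclude":
        keep = dup_clusters != NOISE
        if keep.sum() == 0:
            raise ValueError("all criteria are noise; nothing to score")
        dup_clusters, labels = dup_clusters[keep], labels[keep]
    ceiling = ceiling_ami(labeled)
    if ceiling <= 0:
        raise ValueError("degenerate label structure: ceiling AMI is 0")
    ami = adjusted_mutual_information(dup_clusters, labels)
    return {
        "ami": ami,
        "ceiling_ami": ceiling,
        "normalized_ami": ami / ceiling,
        "noise_handling": noise_handling,
        "granularity": labeled.granularity,
        "n_duplicates": int(len(labels)),
    }


# ---------------------------------------------------------------------------
# Expert review sheet
# ---------------------------------------------------------------------------


def export_expert_review(
    solution: ClusteringSolution,
    criteria: Sequence[CriterionRecord],
    n_clusters: int = 50,
    n_per_cluster: int = 20,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Sheet of the ``n_per_cluster`` criteria nearest each large cluster's medoid.

    Clusters are ranked by member count (ties to the lower id); within a
    cluster, criteria are ranked by Euclidean distance to the medoid point in
    the 2-D plane (ties to the lower index).  The verdict column is left blank
    for the human reviewer and constrained to "correct" / "not correct" /
    "unclear".  Raises when fewer than ``n_clusters`` clusters have
    ``n_per_cluster`` members.
    """
    sizes = {
        cid: int(np.sum(solution.assignments == cid)) for cid in solution.cluster_ids
    }
    eligible = [cid for cid in sizes if sizes[cid] >= n_per_cluster]
    if len(eligible) < n_clusters:
        raise ValueError(
            f"need {n_clusters} clusters with >= {n_per_cluster} members, "
            f"only {len(eligible)} eligible"
        )
    ranked = sorted(eligible, key=lambda c: (-sizes[c], c))[:n_clusters]
    rows = []
    for cid in ranked:
        members = np.flatnonzero(solution.assignments == cid)
        medoid_pt = solution.coords_2d[solution.medoid_index[cid]]
        dists = np.linalg.norm(solution.coords_2d[members] - medoid_pt, axis=1)
        order = members[np.lexsort((members, dists))][:n_per_cluster]
        for idx in order:
            rows.append(
                {
                    "criterion_id": criteria[idx].criterion_id,
                    "cluster_id": int(cid),
                    "text": criteria[idx].text,
                    "verdict": "",
                }
            )
    sheet = pd.DataFrame(rows, columns=["criterion_id", "cluster_id", "text", "verdict"])
    if path is not None:
        sheet.to_csv(path, index=False, encoding="utf-8")
    return sheet


def score_expert_review(sheet: pd.DataFrame | str | Path) -> float:
    """Accuracy of a filled review sheet: #"correct" / #rows.

    "unclear" counts in the denominator.  An invalid verdict raises with the
    offending row number.
    """
    if not isinstance(sheet, pd.DataFrame):
        sheet = pd.read_csv(sheet, dtype=str, keep_default_na=False)
    verdicts = [str(v).strip() for v in sheet["verdict"]]
    for row, verdict in enumerate(verdicts):
        if verdict not in VERDICTS:
            raise ValueError(f"invalid verdict {verdict!r} at row {row}")
    if not verdicts:
        raise ValueError("empty review sheet")
    return sum(v == "correct" for v in verdicts) / len(verdicts)
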