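"""Trial-level outcome classification from cluster-frequency features.

Measures how much protocol information survives the compression from raw
criterion embeddings to cluster ids.  Each trial is featurized three ways:
per-cluster criterion counts (length = number of clusters), the mean of its
criterion embeddings (length = embedding dimension), or a seeded uniform
random vector of the same dimension (chance floor).  Continuous outcomes
(study duration, enrollment count, operational rate = enrollment / duration)
are median-split into balanced binary labels; the phase task is multi-class
over the trial's lowest listed phase.

Classifiers are penalized linear models — logistic regression with L1, L2 or
elastic-net penalty, standing in for Lasso / Ridge / Elastic Net in a
classification setting — tuned by validation macro F1 over a seeded search,
then refit on train + validation and scored on a held-out 20% test split.
Feature modes are compared on identical splits with paired t-tests and a
Bonferroni-corrected significance threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.preprocessing import StandardScaler

from .cluster import NOISE, ClusteringSolution
from .ingest import CriterionRecord, TrialRecord

__all__ = [
    "FEATURE_MODES",
    "OUTCOME_TASKS",
    "split_trials",
    "featurize_trials",
    "binarize_outcome",
    "fit_penalized_classifier",
    "macro_f1",
    "paired_comparison",
    "run_feature_mode_comparison",
]

FEATURE_MODES = ("cluster_counts", "mean_embedding", "uniform_random")
OUTCOME_TASKS = ("phase", "study_duration", "enrollment_count", "operational_rate")


def split_trials(
    trial_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Disjoint, exhaustive train/validation/test split at the trial level.

    Validation and test sizes are the rounded fractions; the remainder goes to
    train.  Deterministic given the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = list(trial_ids)
    n = len(ids)
    if n < 3:
        raise ValueError(f"need >= 3 trials to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    shuffled = [ids[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def featurize_trials(
    trials: Sequence[TrialRecord],
    criteria: Sequence[CriterionRecord],
    mode: str,
    solution: ClusteringSolution | None = None,
    embeddings: np.ndarray | None = None,
    dim: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Feature matrix, one row per trial, in the requested mode.

    ``cluster_counts``: entry c = number of the trial's criteria in cluster c
    (noise ignored; trials with no criteria get a zero vector).
    ``mean_embedding``: arithmetic mean of the trial's criterion embedding
    rows (a trial with no criteria is an error).  ``uniform_random``: seeded
    uniform[0, 1) vector of length ``dim``.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode: {mode!r}")
    rows_of: dict[str, list[int]] = {t.trial_id: [] for t in trials}
    for i, crit in enumerate(criteria):
        if crit.trial_id in rows_of:
            rows_of[crit.trial_id].append(i)

    if mode == "cluster_counts":
        if solution is None:
            raise ValueError("cluster_counts mode needs a ClusteringSolution")
        n_clusters = solution.n_clusters
        out = np.zeros((len(trials), n_clusters))
        for r, trial in enumerate(trials):
            for i in rows_of[trial.trial_id]:
                c = int(solution.assignments[i])
                if c != NOISE:
                    out[r, c] += 1
        return out
    if mode == "mean_embedding":
        if embeddings is None:
            raise ValueError("mean_embedding mode needs the embedding matrix")
        out = np.zeros((len(trials), embeddings.shape[1]))
        for r, trial in enumerate(trials):
            idx = rows_of[trial.trial_id]
            if not idx:
                raise ValueError(f"trial {trial.trial_id} has no criteria to average")
            out[r] = embeddings[idx].mean(axis=0)
        if not np.isfinite(out).all():
            raise ValueError("mean_embedding features contain NaN/Inf")
        return out
    # uniform_random
    if dim is None:
        dim = embeddings.shape[1] if embeddings is not None else (
            solution.n_clusters if solution is not None else 0
        )
    if not dim:
        raise ValueError("uniform_random mode needs a dimension")
    rng = np.random.default_rng(seed)
    return rng.uniform(size=(len(trials), dim))


def binarize_outcome(
    values: Sequence[float], trial_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Median-split into binary labels with an as-even-as-possible class balance.

    Values above the median get 1, below get 0; values tied with the median
    are assigned alternately in trial-id order, starting with whichever class
    is smaller, so the split stays as close to 50/50 as the ties allow.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 trials to binarize")
    if np.all(values == values[0]):
        raise ValueError("all outcome values identical; no median split exists")
    med = float(np.median(values))
    labels = np.full(len(values), -1, dtype=int)
    labels[values > med] = 1
    labels[values < med] = 0
    tie_rows = np.flatnonzero(values == med)
    if len(tie_rows):
        if trial_ids is not None:
            tie_rows = tie_rows[np.argsort(np.asarray(trial_ids, dtype=object)[tie_rows])]
        n0, n1 = int(np.sum(labels == 0)), int(np.sum(labels == 1))
        for row in tie_rows:
            labels[row] = 0 if n0 <= n1 else 1
            if labels[row] == 0:
                n0 += 1
            else:
                n1 += 1
    return labels


def phase_labels(trials: Sequence[TrialRecord]) -> np.ndarray:
    """Multi-class phase label: the trial's lowest listed phase."""
    return np.array([min(t.phases) if t.phases else 0 for t in trials])


@dataclasses.dataclass
class FittedClassifier:
    model: LogisticRegression
    scaler: StandardScaler
    settings: dict
    validation_f1: float
    search_log: list

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.scaler.transform(X))


def _make_classifier(penalty: str, C: float, l1_ratio: float, seed: int) -> LogisticRegression:
    # lasso = pure L1 (l1_ratio 1), ridge = pure L2 (l1_ratio 0), elastic net between
    ratio = {"l1": 1.0, "l2": 0.0}.get(penalty, float(l1_ratio))
    return LogisticRegression(
        C=C, l1_ratio=ratio, max_iter=3000, random_state=seed, solver="saga", tol=1e-3
    )


def fit_penalized_classifier(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    search_space: Mapping | None = None,
    n_trials: int = 20,
    seed: int = 0,
) -> FittedClassifier:
    """Search penalized linear classifiers by validation macro F1, refit on both splits.

    The search space covers the penalty family {l1, l2, elasticnet}, the
    inverse regularization strength C (log-uniform 1e-3..1e3) and, for
    elastic net, the L1 ratio.  A fully enumerable discrete space (grid of
    "choice" entries with at most ``n_trials`` points) is evaluated
    exhaustively; otherwise candidates are drawn by seeded random search.
    """
    if len(set(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    if search_space is None:
        candidates = []
        for _ in range(n_trials):
            penalty = ("l1", "l2", "elasticnet")[int(rng.integers(3))]
            C = float(10 ** rng.uniform(-3, 3))
            l1_ratio = float(rng.uniform(0, 1))
            candidates.append({"penalty": penalty, "C": C, "l1_ratio": l1_ratio})
    else:
        names = list(search_space)
        if all(isinstance(v, (list, tuple)) for v in search_space.values()):
            import itertools

            grid = [
                dict(zip(names, combo))
                for combo in itertools.product(*(search_space[n] for n in names))
            ]
            candidates = grid if len(grid) <= n_trials else [
                grid[int(i)] for i in rng.integers(len(grid), size=n_trials)
            ]
        else:
            raise ValueError("search_space must map names to option lists")

    scaler = StandardScaler().fit(X_train)
    best = None
    log = []
    for settings in candidates:
        model = _make_classifier(
            settings.get("penalty", "l2"),
            settings.get("C", 1.0),
            settings.get("l1_ratio", 0.5),
            seed,
        )
        model.fit(scaler.transform(X_train), y_train)
        score = macro_f1(y_val, model.predict(scaler.transform(X_val)))
        log.append({"settings": settings, "validation_f1": score})
        if best is None or score > best[0]:
            best = (score, settings)
    val_f1, settings = best
    # winner refit on train + validation
    X_full = np.vstack([X_train, X_val])
    y_full = np.concatenate([y_train, y_val])
    scaler_full = StandardScaler().fit(X_full)
    final = _make_classifier(
        settings.get("penalty", "l2"),
        settings.get("C", 1.0),
        settings.get("l1_ratio", 0.5),
        seed,
    )
    final.fit(scaler_full.transform(X_full), y_full)
    return FittedClassifier(
        model=final, scaler=scaler_full, settings=settings,
        validation_f1=val_f1, search_log=log,
    )


def macro_f1(y_true: Sequence, y_pred: Sequence) -> float:
    """Unweighted mean of per-class F1 over classes present in truth or prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    return float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))


@dataclasses.dataclass
class PairedComparison:
    t_statistic: float
    p_value: float
    significant_raw: bool
    significant_bonferroni: bool
    n_comparisons: int
    zero_variance: bool = False


def paired_comparison(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> PairedComparison:
    """Two-sided paired t-test with Bonferroni threshold alpha / n_comparisons."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired score lists with n >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return PairedComparison(
            t_statistic=0.0, p_value=1.0, significant_raw=False,
            significant_bonferroni=False, n_comparisons=n_comparisons,
            zero_variance=True,
        )
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(
        t_statistic=float(t),
        p_value=float(p),
        significant_raw=bool(p < alpha),
        significant_bonferroni=bool(p < alpha / n_comparisons),
        n_comparisons=n_comparisons,
    )


def run_feature_mode_comparison(
    trials: Sequence[TrialRecord],
    criteria: Sequence[CriterionRecord],
    solution: ClusteringSolution,
    embeddings: np.ndarray,
    task: str = "study_duration",
    n_repeats: int = 4,
    n_search_trials: int = 12,
    seed: int = 0,
) -> dict:
    """Test macro F1 for the three feature modes on identical repeated splits.

    Each repeat draws one 70/10/20 trial split shared by all feature modes
    (the pairing precondition of the t-tests) and fits a tuned penalized
    classifier per mode.  Returns per-mode score lists and pairwise paired
    comparisons.
    """
    if task == "phase":
        y_all = phase_labels(trials)
    else:
        values = {
            "study_duration": [t.duration_days for t in trials],
            "enrollment_count": [float(t.enrollment) for t in trials],
            "operational_rate": [
                t.enrollment / t.duration_days if t.duration_days > 0 else 0.0
                for t in trials
            ],
        }[task]
        y_all = binarize_outcome(values, [t.trial_id for t in trials])
    trial_ids = [t.trial_id for t in trials]
    pos = {tid: i for i, tid in enumerate(trial_ids)}

    features = {
        "cluster_counts": featurize_trials(trials, criteria, "cluster_counts", solution=solution),
        "mean_embedding": featurize_trials(trials, criteria, "mean_embedding", embeddings=embeddings),
        "uniform_random": featurize_trials(
            trials, criteria, "uniform_random", embeddings=embeddings, seed=seed + 17
        ),
    }
    scores: dict[str, list[float]] = {m: [] for m in FEATURE_MODES}
    for rep in range(n_repeats):
        train, val, test = split_trials(trial_ids, seed=seed + rep)
        rows = {part: [pos[t] for t in part_ids] for part, part_ids in
                zip(("train", "val", "test"), (train, val, test))}
        for mode in FEATURE_MODES:
            X = features[mode]
            clf = fit_penalized_classifier(
                X[rows["train"]], y_all[rows["train"]],
                X[rows["val"]], y_all[rows["val"]],
                n_trials=n_search_trials, seed=seed + rep,
            )
            scores[mode].append(macro_f1(y_all[rows["test"]], clf.predict(X[rows["test"]])))
    comparisons = {}
    pairs = [
        ("cluster_counts", "uniform_random"),
        ("mean_embedding", "uniform_random"),
        ("mean_embedding", "cluster_counts"),
    ]
    for a, b in pairs:
        comparisons[f"{a}_vs_{b}"] = dataclasses.asdict(
            paired_comparison(scores[a], scores[b], n_comparisons=len(pairs))
        )
    return {
        "task": task,
        "seed": seed,
        "scores": scores,
        "mean_f1": {m: float(np.mean(s)) for m, s in scores.items()},
        "comparisons": comparisons,
    }
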