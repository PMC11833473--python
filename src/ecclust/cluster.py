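"""Two-stage density clustering of criterion embeddings in a 2-D plane.

The pipeline reduces embeddings to two dimensions with t-SNE, clusters the
plane with HDBSCAN (noise allowed, label -1), then attempts to split every
sufficiently large primary cluster with a second HDBSCAN run restricted to
its members.  A secondary split is accepted only if it "converges": the
sub-run must not raise, must produce at least two sub-clusters, and must not
mark more than half of the members as noise — otherwise the primary cluster
is kept intact.  Points that are noise in the first stage stay noise.

Cluster quality is scored with a composite objective

    O(C | theta) = silhouette(assigned points) + N_assigned / N_total,

bounded in [-1, 2]: the silhouette term rewards separation, the coverage term
penalizes leaving points unassigned.  Hyperparameters are tuned by maximizing
this objective, by default with 100 trials of seeded random search (a
Tree-structured Parzen Estimator sampler is used instead when `optuna` is
importable; a purely discrete space small enough to enumerate is searched
exhaustively).  All distances — clustering, silhouette, medoids — live in the
reduced 2-D space, the space the clusterer saw.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterParams",
    "ClusteringSolution",
    "DEFAULT_SEARCH_SPACE",
    "reduce_to_plane",
    "cluster_two_stage",
    "assigned_silhouette",
    "clustering_objective",
    "search_hyperparameters",
    "compute_medoids",
    "compute_prevalence",
    "cluster_pipeline",
]

logger = logging.getLogger(__name__)

NOISE = -1

#: Default hyperparameter search ranges ("int", lo, hi), ("float", lo, hi) or
#: ("choice", options); overridable wherever a space argument is accepted.
DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "min_cluster_size": ("int", 10, 500),
    "min_samples": ("int", 5, 100),
    "cluster_selection_epsilon": ("float", 0.0, 1.0),
    "perplexity": ("int", 10, 100),
}


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Hyperparameter set theta for the reduction + clustering procedure."""

    min_cluster_size: int = 15
    min_samples: int = 5
    cluster_selection_epsilon: float = 0.0
    perplexity: float = 30.0
    secondary: bool = True

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ClusteringSolution:
    """A clustering of criteria: assignments, plane coordinates, and summaries.

    ``assignments[i] == -1`` marks an unassigned (noise) criterion.  Medoids
    and prevalences are computed over assigned criteria only, so prevalences
    sum to 1 whenever at least one criterion is assigned.
    """

    assignments: np.ndarray
    coords_2d: np.ndarray
    theta: ClusterParams
    medoid_index: dict[int, int]
    prevalence: dict[int, float]
    objective_value: float
    seed: int = 0

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.medoid_index)

    @property
    def n_clusters(self) -> int:
        return len(self.medoid_index)

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.assignments != NOISE))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignments": self.assignments.tolist(),
            "coords_2d": self.coords_2d.tolist(),
            "theta": self.theta.as_dict(),
            "medoid_index": {str(k): v for k, v in self.medoid_index.items()},
            "prevalence": {str(k): v for k, v in self.prevalence.items()},
            "objective_value": self.objective_value,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusteringSolution":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            assignments=np.array(payload["assignments"], dtype=int),
            coords_2d=np.array(payload["coords_2d"], dtype=float),
            theta=ClusterParams(**payload["theta"]),
            medoid_index={int(k): int(v) for k, v in payload["medoid_index"].items()},
            prevalence={int(k): float(v) for k, v in payload["prevalence"].items()},
            objective_value=float(payload["objective_value"]),
            seed=int(payload["seed"]),
        )


# ---------------------------------------------------------------------------
# Reduction
# ---------------------------------------------------------------------------


def reduce_to_plane(X: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """t-SNE reduction of an embedding matrix to 2-D, deterministic per seed."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 rows for 2-D reduction, got {n}")
    if perplexity >= n / 3:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n} (requires perplexity < n/3)"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return np.asarray(tsne.fit_transform(X), dtype=float)


# ---------------------------------------------------------------------------
# Two-stage clustering
# ---------------------------------------------------------------------------


def _hdbscan_labels(coords: np.ndarray, theta: ClusterParams) -> np.ndarray:
    n = len(coords)
    model = HDBSCAN(
        min_cluster_size=max(2, min(theta.min_cluster_size, n)),
        min_samples=max(1, min(theta.min_samples, n - 1)) if n > 1 else 1,
        cluster_selection_epsilon=float(theta.cluster_selection_epsilon),
        copy=True,
    )
    return model.fit(coords).labels_


def cluster_two_stage(coords: np.ndarray, theta: ClusterParams) -> np.ndarray:
    """Primary HDBSCAN followed by per-cluster secondary splitting.

    Secondary clustering is attempted only for primary clusters with at least
    ``2 * min_cluster_size`` members; a sub-run that raises, yields fewer than
    two sub-clusters, or marks more than 50% of the members noise is rejected
    and the primary cluster kept intact.  In an accepted sub-run, sub-noise
    points become global noise.  Final labels are renumbered 0..K-1; primary
    noise is never revisited.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        return np.zeros(0, dtype=int)
    if not np.isfinite(coords).all():
        raise ValueError("coords must be finite")
    primary = _hdbscan_labels(coords, theta)
    if not theta.secondary:
        return _renumber(primary)
    final = np.array(primary)
    next_id = (primary.max() if primary.max() >= 0 else 0) + 1
    for cid in sorted(set(primary[primary != NOISE])):
        members = np.flatnonzero(primary == cid)
        if len(members) < 2 * theta.min_cluster_size:
            continue
        try:
            sub = _hdbscan_labels(coords[members], theta)
        except Exception:  # sub-run failed outright: keep primary intact
            continue
        sub_clusters = set(sub[sub != NOISE])
        noise_frac = float(np.mean(sub == NOISE))
        if len(sub_clusters) < 2 or noise_frac > 0.5:
            continue  # did not converge: keep primary intact
        for scid in sorted(sub_clusters):
            final[members[sub == scid]] = next_id
            next_id += 1
        final[members[sub == NOISE]] = NOISE
    return _renumber(final)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids to contiguous 0..K-1, keeping -1 as noise."""
    out = np.full(len(labels), NOISE, dtype=int)
    for new, old in enumerate(sorted(set(labels[labels != NOISE]))):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def assigned_silhouette(assignments: np.ndarray, coords: np.ndarray) -> float:
    """Silhouette over assigned points only; sentinel -1 when degenerate."""
    assignments = np.asarray(assignments)
    coords = np.asarray(coords, dtype=float)
    mask = assignments != NOISE
    labels = assignments[mask]
    if len(set(labels)) < 2 or len(labels) - 1 < len(set(labels)):
        return -1.0
    return float(silhouette_score(coords[mask], labels, metric="euclidean"))


def clustering_objective(assignments: np.ndarray, coords: np.ndarray) -> float:
    """Composite objective: silhouette over assigned points + assigned fraction.

    The silhouette term uses Euclidean distance in the 2-D plane over assigned
    points only; when those span fewer than two clusters (or are otherwise
    degenerate) it takes the sentinel value -1, so the objective stays in
    [-1, 2] with all-noise scoring exactly -1.
    """
    assignments = np.asarray(assignments)
    coords = np.asarray(coords, dtype=float)
    if len(assignments) != len(coords):
        raise ValueError("assignments and coords lengths differ")
    n = len(assignments)
    if n == 0:
        return -1.0
    coverage = float(np.sum(assignments != NOISE)) / n
    return assigned_silhouette(assignments, coords) + coverage


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------


def _sample_theta(space: Mapping[str, tuple], rng: np.random.Generator) -> dict:
    values = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "int":
            values[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "float":
            values[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "choice":
            options = spec[1]
            values[name] = options[int(rng.integers(len(options)))]
        else:
            raise ValueError(f"unknown space spec {spec!r} for {name!r}")
    return values


def _grid(space: Mapping[str, tuple]) -> list[dict] | None:
    """Full grid when every dimension is a 'choice'; None otherwise."""
    if not all(spec[0] == "choice" for spec in space.values()):
        return None
    names = list(space)
    combos = itertools.product(*(space[n][1] for n in names))
    return [dict(zip(names, c)) for c in combos]


def search_hyperparameters(
    X: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    space: Mapping[str, tuple] | None = None,
    n_trials: int = 100,
    seed: int = 0,
    secondary: bool = True,
) -> tuple[ClusterParams, ClusteringSolution, list[dict]]:
    """Tune theta by maximizing the composite clustering objective.

    Either precomputed 2-D ``coords`` (perplexity then fixed) or the raw
    embedding matrix ``X`` (t-SNE re-run per distinct sampled perplexity,
    cached) must be given.  A fully discrete space with at most ``n_trials``
    combinations is enumerated exhaustively; otherwise candidates are drawn by
    TPE when `optuna` is importable, else by seeded random search.  Returns
    the best parameters, the corresponding solution, and the full trial log.
    """
    if (X is None) == (coords is None):
        raise ValueError("provide exactly one of X or coords")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = dict(space if space is not None else DEFAULT_SEARCH_SPACE)
    if coords is not None:
        space.pop("perplexity", None)

    plane_cache: dict[float, np.ndarray] = {}

    def plane_for(values: dict) -> np.ndarray:
        if coords is not None:
            return coords
        perp = float(values.get("perplexity", 30.0))
        if perp not in plane_cache:
            plane_cache[perp] = reduce_to_plane(X, perplexity=perp, seed=seed)
        return plane_cache[perp]

    def evaluate(values: dict) -> tuple[float, ClusterParams, np.ndarray, np.ndarray]:
        theta = ClusterParams(secondary=secondary, **values)
        pts = plane_for(values)
        assignments = cluster_two_stage(pts, theta)
        return clustering_objective(assignments, pts), theta, assignments, pts

    grid = _grid(space)
    if grid is not None and len(grid) <= n_trials:
        candidates = grid
    else:
        candidates = _candidate_list(space, n_trials, seed)

    log: list[dict] = []
    best: tuple[float, ClusterParams, np.ndarray, np.ndarray] | None = None
    failures: list[str] = []
    for values in candidates:
        try:
            score, theta, assignments, pts = evaluate(values)
        except Exception as exc:
            failures.append(f"{values}: {exc}")
            log.append({"theta": values, "objective": None, "error": str(exc)})
            continue
        log.append({"theta": values, "objective": score})
        if best is None or score > best[0]:
            best = (score, theta, assignments, pts)
    if best is None:
        raise RuntimeError(
            "all hyperparameter trials failed:\n" + "\n".join(failures)
        )
    score, theta, assignments, pts = best
    solution = ClusteringSolution(
        assignments=assignments,
        coords_2d=pts,
        theta=theta,
        medoid_index=compute_medoids(pts, assignments),
        prevalence=compute_prevalence(assignments),
        objective_value=score,
        seed=seed,
    )
    return theta, solution, log


def _candidate_list(
    space: Mapping[str, tuple], n_trials: int, seed: int
) -> list[dict]:
    """Candidate thetas: TPE via optuna when importable, else random search."""
    try:
        import optuna
    except ImportError:
        rng = np.random.default_rng(seed)
        return [_sample_theta(space, rng) for _ in range(n_trials)]

    optuna.logging.set_verbosity(optuna.logging.WARNING)
    sampler = optuna.samplers.TPESampler(seed=seed)
    study = optuna.create_study(direction="maximize", sampler=sampler)
    picked: list[dict] = []

    def objective(trial: "optuna.Trial") -> float:
        values = {}
        for name, spec in space.items():
            if spec[0] == "int":
                values[name] = trial.suggest_int(name, spec[1], spec[2])
            elif spec[0] == "float":
                values[name] = trial.suggest_float(name, spec[1], spec[2])
            else:
                values[name] = trial.suggest_categorical(name, list(spec[1]))
        picked.append(values)
        return 0.0  # scored later by the shared evaluation loop

    study.optimize(objective, n_trials=n_trials)
    return picked


# ---------------------------------------------------------------------------
# Medoids and prevalence
# ---------------------------------------------------------------------------


def compute_medoids(
    coords: np.ndarray, assignments: np.ndarray
) -> dict[int, int]:
    """Per-cluster medoid: member minimizing total Euclidean distance to members.

    Distances are taken in the 2-D plane; ties break to the lowest index.
    """
    coords = np.asarray(coords, dtype=float)
    assignments = np.asarray(assignments)
    medoids: dict[int, int] = {}
    for cid in sorted(set(assignments[assignments != NOISE])):
        members = np.flatnonzero(assignments == cid)
        pts = coords[members]
        dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1).sum(axis=1)
        medoids[int(cid)] = int(members[int(np.argmin(dists))])
    return medoids


def compute_prevalence(assignments: np.ndarray) -> dict[int, float]:
    """Fraction of *assigned* criteria per cluster; empty map when all noise."""
    assignments = np.asarray(assignments)
    assigned = assignments[assignments != NOISE]
    if len(assigned) == 0:
        return {}
    ids, counts = np.unique(assigned, return_counts=True)
    total = counts.sum()
    return {int(c): float(k) / total for c, k in zip(ids, counts)}


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------


def cluster_pipeline(
    X: np.ndarray,
    theta: ClusterParams | None = None,
    seed: int = 0,
) -> ClusteringSolution:
    """Reduce to the plane and cluster with a fixed theta (no search)."""
    theta = theta or ClusterParams()
    coords = reduce_to_plane(X, perplexity=theta.perplexity, seed=seed)
    assignments = cluster_two_stage(coords, theta)
    return ClusteringSolution(
        assignments=assignments,
        coords_2d=coords,
        theta=theta,
        medoid_index=compute_medoids(coords, assignments),
        prevalence=compute_prevalence(assignments),
        objective_value=clustering_objective(assignments, coords),
        seed=seed,
    )
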