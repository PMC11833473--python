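"""Config-driven orchestration of the ingest / cluster / evaluate stages.

Each stage reads the artifacts of its upstream stage from the output
directory and writes its own, stamped with the configuration hash and seed so
every number in a report is reproducible from (config, seed) alone.  Stages:

    synth     generate a synthetic registry (registry.csv + ground_truth.json)
    ingest    parse + filter a registry, emit the criterion table
    cluster   embed criteria, tune and run the two-stage clustering
    align     composite-label alignment at the configured granularities
    classify  feature-mode comparison on trial outcomes
    generate  per-trial section generation and scoring
    report    merge all stage reports into one JSON

Re-running a stage refuses to overwrite existing artifacts unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import alignment as _alignment
from . import classification as _classification
from . import cluster as _cluster
from . import embedding as _embedding
from . import generation as _generation
from . import ingest as _ingest
from . import synthetic as _synthetic

__all__ = ["PipelineConfig", "run_experiment", "export_scatter", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("synth", "ingest", "cluster", "align", "classify", "generate")


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of the pipeline; serializable, hashable for provenance."""

    output_dir: str = "ecclust_out"
    registry_path: str | None = None  # None => use the synth stage's output
    condition_roots: tuple[str, ...] = ("C01", "C04", "C14", "C20")
    embedder: str = "synthetic"  # "synthetic" (needs ground truth) or "hash"
    pooling: str = "mean_non_pad"
    embedding_dim: int = 64
    separation: float = 30.0
    search_trials: int = 100
    search_space: dict | None = None
    perplexity: float = 30.0
    granularities: tuple[tuple[int, int], ...] = _alignment.GRANULARITIES
    split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    target_section_lengths: dict | None = None
    retrieval_thresholds: tuple[int, int] = _generation.DEFAULT_THRESHOLDS
    classification_task: str = "study_duration"
    n_eval_trials: int = 10
    # synthetic registry condition parameters
    n_trials: int = 200
    n_templates: int = 20
    criteria_per_trial: tuple[int, int] = (10, 40)
    effect_size: float = 1.0
    lexical_noise: float = 0.1
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.granularities = tuple(tuple(g) for g in cfg.granularities)
        cfg.split_fractions = tuple(cfg.split_fractions)
        cfg.criteria_per_trial = tuple(cfg.criteria_per_trial)
        cfg.retrieval_thresholds = tuple(cfg.retrieval_thresholds)
        cfg.condition_roots = tuple(cfg.condition_roots)
        return cfg


def _out(config: PipelineConfig) -> Path:
    path = Path(config.output_dir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _stamp(config: PipelineConfig, payload: dict) -> dict:
    payload["provenance"] = {"config_hash": config.config_hash(), "seed": config.seed}
    return payload


def _write_json(path: Path, payload: dict, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True / --force to overwrite")
    path.write_text(json.dumps(payload, indent=1, default=str), encoding="utf-8")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}; run the '{stage}' stage first"
        )
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_synth(config: PipelineConfig, force: bool) -> dict:
    out = _out(config)
    trials, truth = _synthetic.generate_registry(
        n_trials=config.n_trials,
        n_templates=config.n_templates,
        criteria_per_trial=config.criteria_per_trial,
        effect_size=config.effect_size,
        lexical_noise=config.lexical_noise,
        seed=config.seed,
    )
    reg = out / "registry.csv"
    if reg.exists() and not force:
        raise FileExistsError(f"{reg} exists; pass force=True / --force to overwrite")
    _synthetic.write_registry(trials, reg)
    _synthetic.write_ground_truth(truth, out / "ground_truth.json")
    report = _stamp(config, {"n_trials": len(trials), "registry": str(reg)})
    _write_json(out / "synth_report.json", report, force=True)
    return report


def _stage_ingest(config: PipelineConfig, force: bool) -> dict:
    out = _out(config)
    source = Path(config.registry_path) if config.registry_path else out / "registry.csv"
    _require(source, "synth")
    problems: list[str] = []
    trials = _ingest.parse_registry(source, problems)
    kept = _ingest.filter_trials(trials)
    n_rows = _ingest.emit_criterion_table(kept, out / "criteria.csv")
    _synthetic.write_registry(kept, out / "filtered_registry.csv")
    report = _stamp(
        config,
        {
            "n_input_trials": len(trials),
            "n_kept_trials": len(kept),
            "n_criteria": n_rows,
            "problems": problems,
        },
    )
    _write_json(out / "ingest_report.json", report, force=True)
    return report


def _load_corpus(config: PipelineConfig):
    out = _out(config)
    trials = _ingest.parse_registry(_require(out / "filtered_registry.csv", "ingest"))
    criteria = _ingest.read_criterion_table(_require(out / "criteria.csv", "ingest"))
    return trials, criteria


def _embed(config: PipelineConfig, criteria) -> np.ndarray:
    out = _out(config)
    truth_path = out / "ground_truth.json"
    if config.embedder == "synthetic":
        if not truth_path.exists():
            raise FileNotFoundError(
                "embedder 'synthetic' needs ground_truth.json; run 'synth' or use 'hash'"
            )
        truth = _synthetic.read_ground_truth(truth_path)
        return _synthetic.synthetic_embed(
            criteria, truth, separation=config.separation,
            dim=config.embedding_dim, seed=config.seed,
        )
    if config.embedder == "hash":
        return _embedding.fallback_hash_embedder(
            [c.text for c in criteria], dim=config.embedding_dim, seed=config.seed
        )
    encoder = _embedding.get_encoder(config.embedder, dim=config.embedding_dim, seed=config.seed)
    return _embedding.embed_texts([c.text for c in criteria], encoder, config.pooling)


def _stage_cluster(config: PipelineConfig, force: bool) -> dict:
    out = _out(config)
    trials, criteria = _load_corpus(config)
    X = _embed(config, criteria)
    _embedding.save_embeddings(
        out / "embeddings", X, [c.criterion_id for c in criteria],
        model=config.embedder, pooling=config.pooling,
    )
    coords = _cluster.reduce_to_plane(X, perplexity=config.perplexity, seed=config.seed)
    space = config.search_space or {
        k: v for k, v in _cluster.DEFAULT_SEARCH_SPACE.items() if k != "perplexity"
    }
    theta, solution, log = _cluster.search_hyperparameters(
        coords=coords, space=space, n_trials=config.search_trials, seed=config.seed
    )
    sol_path = out / "solution.json"
    if sol_path.exists() and not force:
        raise FileExistsError(f"{sol_path} exists; pass force=True / --force to overwrite")
    solution.to_json(sol_path)
    export_scatter(solution, criteria, out / "scatter.json")
    report = _stamp(
        config,
        {
            "n_criteria": len(criteria),
            "n_clusters": solution.n_clusters,
            "n_assigned": solution.n_assigned,
            "objective": solution.objective_value,
            "theta": theta.as_dict(),
            "n_search_trials": len(log),
        },
    )
    _write_json(out / "cluster_report.json", report, force=True)
    return report


def _stage_align(config: PipelineConfig, force: bool) -> dict:
    out = _out(config)
    _trials, criteria = _load_corpus(config)
    solution = _cluster.ClusteringSolution.from_json(_require(out / "solution.json", "cluster"))
    results = {}
    for gran in config.granularities:
        labeled = _alignment.build_composite_labels(criteria, tuple(gran))
        key = f"granularity_{gran[0]}_{gran[1]}"
        try:
            results[key] = _alignment.normalized_alignment(solution, labeled)
        except ValueError:
            # ceiling not positive: labels nearly unique per trial at this
            # scale, so normalization is undefined; report raw AMI only
            dup = solution.assignments[labeled.criterion_index]
            results[key] = {
                "ami": _alignment.adjusted_mutual_information(dup, labeled.labels),
                "ceiling_ami": _alignment.ceiling_ami(labeled),
                "normalized_ami": None,
                "degenerate_ceiling": True,
                "granularity": tuple(gran),
                "n_duplicates": len(labeled),
            }
    report = _stamp(config, {"alignment": results})
    _write_json(out / "align_report.json", report, force)
    return report


def _stage_classify(config: PipelineConfig, force: bool) -> dict:
    out = _out(config)
    trials, criteria = _load_corpus(config)
    solution = _cluster.ClusteringSolution.from_json(_require(out / "solution.json", "cluster"))
    X, _sidecar = _embedding.load_embeddings(out / "embeddings")
    result = _classification.run_feature_mode_comparison(
        trials, criteria, solution, X,
        task=config.classification_task, seed=config.seed,
    )
    report = _stamp(config, {"classification": result})
    _write_json(out / "classify_report.json", report, force)
    return report


def _stage_generate(config: PipelineConfig, force: bool) -> dict:
    out = _out(config)
    trials, criteria = _load_corpus(config)
    X, _sidecar = _embedding.load_embeddings(out / "embeddings")
    encoder = _embedding.HashTokenEncoder(dim=config.embedding_dim, seed=config.seed)
    targets_per_root = config.target_section_lengths or _generation.TARGET_SECTION_LENGTHS
    trial_by_id = {t.trial_id: t for t in trials}
    all_sections = {t.trial_id: t.eligibility_text for t in trials}
    results = {}
    sections_out = {}
    for root in config.condition_roots:
        chosen = _generation.select_evaluation_trials(
            trials, criteria, root, n=config.n_eval_trials,
            thresholds=config.retrieval_thresholds, seed=config.seed,
        )
        per_trial = []
        for tid in chosen:
            target = trial_by_id[tid]
            retrieval = _generation.retrieve_similar_criteria(
                target, trials, criteria, config.retrieval_thresholds
            )
            idx = retrieval.criterion_indices
            # keep t-SNE feasible (perplexity < n/3) and the density floor
            # proportionate on small retrieved sets
            perp = min(config.perplexity, max(2.0, (len(idx) - 1) / 3.5))
            theta = _cluster.ClusterParams(
                min_cluster_size=max(3, min(15, len(idx) // 12)),
                min_samples=max(2, min(5, len(idx) // 30)),
                perplexity=perp,
            )
            sub_solution = _cluster.cluster_pipeline(X[idx], theta=theta, seed=config.seed)
            if not sub_solution.medoid_index:
                logger.warning("generate: no clusters for target %s; skipped", tid)
                continue
            count = targets_per_root.get(root) or max(
                1, round(np.mean([len(_ingest.criteria_from_trial(t)) for t in trials]))
            )
            section = _generation.generate_section(
                sub_solution, [criteria[i].text for i in idx], count,
                seed=config.seed, target_trial_id=tid,
            )
            reference = all_sections[tid]
            sil = _cluster.assigned_silhouette(
                sub_solution.assignments, sub_solution.coords_2d
            )
            per_trial.append(
                {
                    "trial_id": tid,
                    "granularity": retrieval.granularity,
                    "n_retrieved": len(idx),
                    "section_length": len(section.texts),
                    "rouge_f1": _generation.mean_rouge_f1(section.as_text(), reference),
                    "bert_f1": _generation.bert_score(section.as_text(), reference, encoder)[2],
                    "silhouette": sil,
                }
            )
            sections_out[tid] = {
                "texts": section.texts,
                "source_clusters": section.source_clusters,
            }
        if not per_trial:
            continue
        gen_sections = [
            "\n".join(sections_out[row["trial_id"]]["texts"]) for row in per_trial
        ]
        pool = list(all_sections.values())
        baseline = _generation.random_reference_baseline(
            gen_sections, pool, _generation.mean_rouge_f1, seed=config.seed
        )
        results[root] = {
            "per_trial": per_trial,
            "mean_rouge_f1": float(np.mean([r["rouge_f1"] for r in per_trial])),
            "mean_bert_f1": float(np.mean([r["bert_f1"] for r in per_trial])),
            "random_baseline_rouge_f1": baseline["mean"],
        }
    report = _stamp(config, {"generation": results})
    _write_json(out / "generated_sections.json", _stamp(config, dict(sections_out)), force)
    _write_json(out / "generate_report.json", report, force)
    return report


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "ingest": _stage_ingest,
    "cluster": _stage_cluster,
    "align": _stage_align,
    "classify": _stage_classify,
    "generate": _stage_generate,
}


def run_experiment(name: str, config: PipelineConfig, force: bool = False) -> dict:
    """Run one named stage, or "all" for every stage in dependency order.

    "report" merges the per-stage reports into ``report.json``.
    """
    if name == "all":
        results = {}
        for stage in STAGES:
            if stage == "synth" and config.registry_path:
                continue
            results[stage] = _STAGE_FUNCS[stage](config, force=True)
        results["report"] = run_experiment("report", config, force=True)
        return results
    if name == "report":
        out = _out(config)
        merged = {}
        for stage in STAGES:
            path = out / f"{stage}_report.json"
            if path.exists():
                merged[stage] = json.loads(path.read_text(encoding="utf-8"))
        report = _stamp(config, merged)
        _write_json(out / "report.json", report, force)
        return report
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; options: {STAGES + ('report', 'all')}")
    return _STAGE_FUNCS[name](config, force)


def export_scatter(
    solution: _cluster.ClusteringSolution,
    criteria: Sequence[_ingest.CriterionRecord],
    path: str | Path | None = None,
    snippet_chars: int = 80,
) -> list[dict]:
    """One JSON point record per criterion for an external 2-D viewer.

    Unassigned criteria carry the reserved cluster id -1.
    """
    if len(criteria) != len(solution.assignments):
        raise ValueError("criteria and solution sizes differ")
    points = [
        {
            "criterion_id": crit.criterion_id,
            "x": float(solution.coords_2d[i, 0]),
            "y": float(solution.coords_2d[i, 1]),
            "cluster_id": int(solution.assignments[i]),
            "text": crit.text[:snippet_chars],
        }
        for i, crit in enumerate(criteria)
    ]
    if path is not None:
        Path(path).write_text(json.dumps(points), encoding="utf-8")
    return points
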