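"""Synthetic trial registries with planted criterion-template structure.

Real eligibility sections are lists of recurring rule archetypes ("age >= 18",
"signed informed consent", "no prior chemotherapy" ...) whose usage depends on
the trial's phase, condition and intervention.  The generator emulates that:
a small bank of latent criterion templates, each with an affinity profile over
(phase, condition root, intervention root), emits perturbed copies of its base
text into trials whose context matches.  Continuous trial outcomes (duration,
enrollment) depend on the trial's template mixture through a planted linear
effect, so downstream classification has a recoverable signal.

Everything is reproducible from a single seed, fanned out to per-component
seeds via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import CriterionRecord, TrialRecord

__all__ = [
    "TemplateSpec",
    "SyntheticGroundTruth",
    "make_mesh_vocabulary",
    "generate_registry",
    "synthetic_embed",
    "write_registry",
    "write_ground_truth",
    "read_ground_truth",
]


# Word pool for template base texts; deliberately clinical-flavoured but
# synthetic (no attempt at medical validity).
_WORD_POOL = (
    "age years adult signed informed consent prior therapy chemotherapy "
    "radiotherapy surgery biopsy metastatic disease stable cardiac hepatic "
    "renal function creatinine clearance bilirubin platelet count hemoglobin "
    "neutrophil pregnancy lactation contraception willing comply protocol "
    "visits history allergy hypersensitivity study drug active infection "
    "hepatitis immunodeficiency vaccine immunosuppressive corticosteroid "
    "treatment within days weeks months screening baseline performance "
    "status score measurable lesion imaging documented diagnosis confirmed "
    "severe uncontrolled hypertension diabetes psychiatric disorder abuse "
    "alcohol substance enrollment concurrent trial investigational agent "
    "dose washout period life expectancy tumor progression relapse remission "
    "transplant dialysis oxygen ventricular ejection fraction interval"
).split()

_SUFFIXES = ("", "s", "al", "ic")


@dataclasses.dataclass(frozen=True)
class TemplateSpec:
    """One latent criterion template: base text, kind, and usage affinity."""

    template_id: int
    base_text: str
    kind: str  # "inclusion" or "exclusion"
    affinity: dict  # (phase, condition root, intervention root) -> weight >= 0


@dataclasses.dataclass
class SyntheticGroundTruth:
    """Planted structure of a synthetic registry.

    ``template_of`` maps every synthetic criterion_id to its template_id
    (-1 for idiosyncratic background criteria) and ``variant_of`` to its
    sub-template variant.  Outcome parameters record the planted linear
    effects on log-duration and log-enrollment: the template mixture
    (coefficient ``effect_size``), the finer variant mixture (half that
    coefficient), and the mean latent severity of the trial's background
    criteria (equal coefficient, opposite sign for enrollment).  The variant
    and background layers
    emulate residual signal present in raw embeddings but lost to
    template-level cluster assignments.
    """

    templates: list[TemplateSpec]
    template_of: dict[str, int]
    variant_of: dict[str, int]
    background_latent: dict[str, float]
    n_variants: int
    duration_beta: list[float]
    enrollment_beta: list[float]
    duration_sub_beta: list[list[float]]
    enrollment_sub_beta: list[list[float]]
    effect_size: float
    seed: int

    def template_labels(self, criteria: Sequence[CriterionRecord]) -> np.ndarray:
        """Planted template id per criterion, aligned to ``criteria`` order."""
        try:
            return np.array([self.template_of[c.criterion_id] for c in criteria])
        except KeyError as exc:
            raise KeyError(f"unknown criterion_id: {exc.args[0]!r}") from exc

    def variant_labels(self, criteria: Sequence[CriterionRecord]) -> np.ndarray:
        """Planted sub-template variant per criterion."""
        try:
            return np.array([self.variant_of[c.criterion_id] for c in criteria])
        except KeyError as exc:
            raise KeyError(f"unknown criterion_id: {exc.args[0]!r}") from exc


def make_mesh_vocabulary(
    n_roots: int, depth: int, branching: int, seed: int = 0
) -> list[str]:
    """Generate a prefix-closed set of MeSH-like tree numbers.

    Roots are ``C01, C02, ...``; every node above the maximum depth has
    ``branching`` numeric children, so the vocabulary contains
    ``n_roots * (branching**depth - 1) / (branching - 1)`` codes (geometric
    series; every truncation of a member is itself a member).
    """
    if min(n_roots, depth, branching) < 1:
        raise ValueError("n_roots, depth and branching must all be >= 1")
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    frontier = [f"C{r + 1:02d}" for r in range(n_roots)]
    codes.extend(frontier)
    for _ in range(depth - 1):
        nxt: list[str] = []
        for parent in frontier:
            children = rng.choice(np.arange(100, 999), size=branching, replace=False)
            nxt.extend(f"{parent}.{int(c):03d}" for c in children)
        codes.extend(nxt)
        frontier = nxt
    return codes


def _make_templates(
    n_templates: int,
    phases: Sequence[int],
    cond_roots: Sequence[str],
    int_roots: Sequence[str],
    rng: np.random.Generator,
) -> list[TemplateSpec]:
    templates = []
    for tid in range(n_templates):
        n_words = int(rng.integers(6, 12))
        words = list(rng.choice(_WORD_POOL, size=n_words, replace=True))
        # two distinctive anchor tokens per template keep templates lexically
        # separable even under word-level noise
        words.insert(0, f"{rng.choice(_WORD_POOL)}{tid:02d}")
        words.append(f"{rng.choice(_WORD_POOL)}{tid:02d}x")
        kind = "inclusion" if tid % 2 == 0 else "exclusion"
        # affinity = outer product of sparse per-axis preferences
        phase_w = rng.dirichlet(np.full(len(phases), 0.8))
        cond_w = rng.dirichlet(np.full(len(cond_roots), 0.8))
        int_w = rng.dirichlet(np.full(len(int_roots), 0.8))
        affinity = {
            (p, cr, ir): float(phase_w[i] * cond_w[j] * int_w[k])
            for i, p in enumerate(phases)
            for j, cr in enumerate(cond_roots)
            for k, ir in enumerate(int_roots)
        }
        templates.append(
            TemplateSpec(
                template_id=tid,
                base_text=" ".join(words).capitalize(),
                kind=kind,
                affinity=affinity,
            )
        )
    return templates


def _perturb(words: list[str], noise: float, rng: np.random.Generator) -> list[str]:
    """Word-level paraphrase noise: synonym suffix, drop, or adjacent swap."""
    out = list(words)
    i = 0
    while i < len(out):
        if len(out) > 2 and rng.random() < noise:
            op = rng.integers(3)
            if op == 0:  # synonym-like variant
                out[i] = out[i] + str(rng.choice(_SUFFIXES))
            elif op == 1 and len(out) > 3:  # drop
                del out[i]
                continue
            elif op == 2 and i + 1 < len(out):  # swap
                out[i], out[i + 1] = out[i + 1], out[i]
                i += 1
        i += 1
    return out


def generate_registry(
    n_trials: int = 200,
    n_templates: int = 20,
    criteria_per_trial: tuple[int, int] = (10, 40),
    effect_size: float = 1.0,
    lexical_noise: float = 0.1,
    seed: int = 0,
    n_variants: int = 3,
    background_fraction: float = 0.2,
) -> tuple[list[TrialRecord], SyntheticGroundTruth]:
    """Generate a synthetic registry with planted template and outcome structure.

    Parameters
    ----------
    n_trials, n_templates
        Number of trials and of latent criterion templates.
    criteria_per_trial
        Inclusive (min, max) range for the number of criteria per trial.
    effect_size
        Coefficient scaling how strongly the trial's template mixture shifts
        log-duration and log-enrollment; 0 removes all outcome signal.  The
        finer variant mixture contributes with half this coefficient.
    lexical_noise
        Per-word perturbation probability applied to template base texts.
    n_variants
        Sub-template variants per template; a criterion of variant v > 0
        carries a variant token in its text (variant 0 is the base text).
    background_fraction
        Probability that a criterion slot is an idiosyncratic one-off rule
        instead of a template instance.  Background criteria have unique
        texts, no template, and a latent severity scalar that shifts the
        trial's outcomes — residual information that never forms a cluster.
    """
    lo, hi = criteria_per_trial
    if hi < lo:
        raise ValueError(f"criteria_per_trial range has max < min: {criteria_per_trial}")
    if n_trials < 1 or n_templates < 2:
        raise ValueError("need n_trials >= 1 and n_templates >= 2")
    if not 0.0 <= lexical_noise <= 1.0:
        raise ValueError("lexical_noise must be a probability")

    ss = np.random.SeedSequence(seed)
    rng_struct, rng_trials, rng_outcome = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    phases = (1, 2, 3, 4)
    cond_roots = ("C01", "C04", "C14", "C20")
    int_roots = ("D02", "D27")
    # condition leaves at depth 4 and intervention leaves at depth 3, per root
    cond_vocab = {}
    for i, r in enumerate(cond_roots):
        sub = make_mesh_vocabulary(1, 4, 2, seed=1000 + i)
        cond_vocab[r] = [c.replace("C01", r, 1) for c in sub if c.count(".") == 3]
    int_vocab = {}
    for i, r in enumerate(int_roots):
        sub = make_mesh_vocabulary(1, 3, 2, seed=2000 + i)
        int_vocab[r] = [c.replace("C01", r, 1) for c in sub if c.count(".") == 2]

    templates = _make_templates(n_templates, phases, cond_roots, int_roots, rng_struct)
    duration_beta = rng_struct.normal(size=n_templates)
    enrollment_beta = rng_struct.normal(size=n_templates)
    duration_sub_beta = rng_struct.normal(size=(n_templates, n_variants))
    enrollment_sub_beta = rng_struct.normal(size=(n_templates, n_variants))

    trials: list[TrialRecord] = []
    template_of: dict[str, int] = {}
    variant_of: dict[str, int] = {}
    background_latent: dict[str, float] = {}
    window_days = (_dt.date(2024, 6, 1) - _dt.date(2000, 1, 1)).days
    for t in range(n_trials):
        trial_id = f"SYN{t:05d}"
        trial_phases = tuple(
            sorted(rng_trials.choice(phases, size=int(rng_trials.integers(1, 3)), replace=False))
        )
        cr = str(rng_trials.choice(cond_roots))
        ir = str(rng_trials.choice(int_roots))
        conds = frozenset(
            str(c)
            for c in rng_trials.choice(
                cond_vocab[cr], size=int(rng_trials.integers(1, 3)), replace=False
            )
        )
        ints = frozenset(
            str(c)
            for c in rng_trials.choice(
                int_vocab[ir], size=int(rng_trials.integers(1, 3)), replace=False
            )
        )
        # template mixture from affinity to this trial's context
        weights = np.array(
            [
                sum(tpl.affinity[(p, cr, ir)] for p in trial_phases)
                for tpl in templates
            ]
        )
        weights = weights + 1e-6
        weights = weights / weights.sum()
        n_crit = int(rng_trials.integers(lo, hi + 1))
        is_background = rng_trials.random(n_crit) < background_fraction
        chosen = rng_trials.choice(n_templates, size=n_crit, p=weights)
        variants = rng_trials.integers(n_variants, size=n_crit)
        latents = rng_trials.normal(size=n_crit)  # used only for background slots
        tmpl_slots = ~is_background
        n_tmpl = int(tmpl_slots.sum())
        mixture = (
            np.bincount(chosen[tmpl_slots], minlength=n_templates) / n_tmpl
            if n_tmpl else np.zeros(n_templates)
        )
        sub_counts = np.zeros((n_templates, n_variants))
        for tid, vid in zip(chosen[tmpl_slots], variants[tmpl_slots]):
            sub_counts[tid, vid] += 1
        sub_mixture = sub_counts / n_tmpl if n_tmpl else sub_counts
        mean_latent = float(latents[is_background].mean()) if is_background.any() else 0.0

        # per-slot rendering info: (kind, text, template_id, variant, latent)
        slots = []
        for i in range(n_crit):
            if is_background[i]:
                n_words = int(rng_trials.integers(5, 10))
                words = list(rng_trials.choice(_WORD_POOL, size=n_words)) + [
                    f"uniq{t}x{i}"
                ]
                kind = "inclusion" if rng_trials.random() < 0.5 else "exclusion"
                slots.append((kind, " ".join(words), -1, -1, float(latents[i])))
            else:
                tpl = templates[chosen[i]]
                vid = int(variants[i])
                words = tpl.base_text.split()
                if vid > 0:
                    words = words + [f"typ{tpl.template_id}v{vid}"]
                line = " ".join(_perturb(words, lexical_noise, rng_trials))
                slots.append((tpl.kind, line, tpl.template_id, vid, 0.0))

        # render eligibility text: inclusion bullets first, then exclusion,
        # preserving a deterministic order so tokenization round-trips
        ordered = sorted(range(n_crit), key=lambda i: (slots[i][0] != "inclusion", i))
        inc_lines, exc_lines = [], []
        for rank, i in enumerate(ordered):
            kind, line, tid, vid, latent = slots[i]
            (inc_lines if kind == "inclusion" else exc_lines).append(f"- {line}")
            cid = f"{trial_id}_EC{rank}"
            template_of[cid] = int(tid)
            variant_of[cid] = int(vid)
            if tid == -1:
                background_latent[cid] = latent
        parts = []
        if inc_lines:
            parts.append("Inclusion Criteria:")
            parts.extend(inc_lines)
        if exc_lines:
            parts.append("Exclusion Criteria:")
            parts.extend(exc_lines)
        eligibility = "\n".join(parts)

        z_d, z_e = rng_outcome.normal(size=2)
        log_dur = (
            6.5
            + effect_size * float(duration_beta @ mixture)
            + 0.5 * effect_size * float((duration_sub_beta * sub_mixture).sum())
            + effect_size * mean_latent
            + 0.35 * z_d
        )
        duration = float(np.exp(log_dur))
        log_enr = (
            4.5
            + effect_size * float(enrollment_beta @ mixture)
            + 0.5 * effect_size * float((enrollment_sub_beta * sub_mixture).sum())
            - effect_size * mean_latent
            + 0.35 * z_e
        )
        enrollment = int(rng_outcome.poisson(np.exp(log_enr)))

        start = _dt.date(2000, 1, 1) + _dt.timedelta(
            days=int(rng_trials.integers(window_days + 1))
        )
        trials.append(
            TrialRecord(
                trial_id=trial_id,
                study_type="interventional",
                status="completed" if rng_trials.random() < 0.85 else "terminated",
                phases=frozenset(int(p) for p in trial_phases),
                start_date=start,
                condition_codes=conds,
                intervention_codes=ints,
                eligibility_text=eligibility,
                enrollment=enrollment,
                duration_days=duration,
            )
        )

    truth = SyntheticGroundTruth(
        templates=templates,
        template_of=template_of,
        variant_of=variant_of,
        background_latent=background_latent,
        n_variants=int(n_variants),
        duration_beta=[float(b) for b in duration_beta],
        enrollment_beta=[float(b) for b in enrollment_beta],
        duration_sub_beta=duration_sub_beta.tolist(),
        enrollment_sub_beta=enrollment_sub_beta.tolist(),
        effect_size=float(effect_size),
        seed=int(seed),
    )
    return trials, truth


def synthetic_embed(
    criteria: Sequence[CriterionRecord],
    truth: SyntheticGroundTruth,
    separation: float = 30.0,
    dim: int = 64,
    seed: int = 0,
) -> np.ndarray:
    """Template-aware embedder: template centers on a sphere plus unit noise.

    Each template gets a center drawn uniformly on the sphere of radius
    ``separation``; each of its sub-template variants sits at a small offset
    from that center (radius ``separation / 15``, well below the unit noise
    scale in high dimension, so clustering sees templates while the raw
    vectors retain the finer variant signal).  A template criterion's vector
    is its variant center plus standard Gaussian noise.

    Background criteria (template -1) form a diffuse central cloud (spread 5)
    with their latent severity encoded linearly along one fixed direction at
    scale ``separation / 6`` — readable by a linear model from the raw
    vectors, but without cluster structure of its own.  ``separation=0``
    collapses everything to a single structureless cloud.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    ss = np.random.SeedSequence(seed)
    rng_centers, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    n_templates = len(truth.templates)
    n_variants = max(truth.n_variants, 1)

    def _sphere(n: int, radius: float) -> np.ndarray:
        directions = rng_centers.normal(size=(n, dim))
        norms = np.linalg.norm(directions, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return radius * directions / norms

    centers = _sphere(n_templates, separation)
    offsets = _sphere(n_templates * n_variants, separation / 15.0).reshape(
        n_templates, n_variants, dim
    )
    latent_axis = _sphere(1, 1.0)[0]
    labels = truth.template_labels(criteria)
    variants = truth.variant_labels(criteria)
    out = np.empty((len(criteria), dim))
    is_bg = labels == -1
    fg = ~is_bg
    out[fg] = centers[labels[fg]] + offsets[labels[fg], variants[fg]]
    if is_bg.any():
        latents = np.array(
            [truth.background_latent[c.criterion_id] for c, b in zip(criteria, is_bg) if b]
        )
        bg_spread = 5.0 if separation > 0 else 0.0
        out[is_bg] = (
            (separation / 6.0) * latents[:, None] * latent_axis[None, :]
            + bg_spread * rng_noise.normal(size=(int(is_bg.sum()), dim))
        )
    out += rng_noise.normal(size=out.shape)
    return out


# ---------------------------------------------------------------------------
# Persistence in the registry dialect
# ---------------------------------------------------------------------------


def write_registry(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write trials in the CSV dialect :func:`ecclust.ingest.parse_registry` reads."""
    frame = pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "study_type": t.study_type,
                "status": t.status,
                "phases": "|".join(str(p) for p in sorted(t.phases)),
                "start_date": t.start_date.isoformat() if t.start_date else "",
                "condition_codes": "|".join(sorted(t.condition_codes)),
                "intervention_codes": "|".join(sorted(t.intervention_codes)),
                "eligibility_text": t.eligibility_text,
                "enrollment": t.enrollment,
                "duration_days": t.duration_days,
            }
            for t in trials
        ]
    )
    frame.to_csv(path, index=False, encoding="utf-8")


def write_ground_truth(truth: SyntheticGroundTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "effect_size": truth.effect_size,
        "n_variants": truth.n_variants,
        "duration_beta": truth.duration_beta,
        "enrollment_beta": truth.enrollment_beta,
        "duration_sub_beta": truth.duration_sub_beta,
        "enrollment_sub_beta": truth.enrollment_sub_beta,
        "template_of": truth.template_of,
        "variant_of": truth.variant_of,
        "background_latent": truth.background_latent,
        "templates": [
            {
                "template_id": t.template_id,
                "base_text": t.base_text,
                "kind": t.kind,
                "affinity": {"|".join(map(str, k)): v for k, v in t.affinity.items()},
            }
            for t in truth.templates
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    templates = [
        TemplateSpec(
            template_id=t["template_id"],
            base_text=t["base_text"],
            kind=t["kind"],
            affinity={
                tuple(
                    int(p) if i == 0 else p
                    for i, p in enumerate(key.split("|"))
                ): v
                for key, v in t["affinity"].items()
            },
        )
        for t in payload["templates"]
    ]
    return SyntheticGroundTruth(
        templates=templates,
        template_of={k: int(v) for k, v in payload["template_of"].items()},
        variant_of={k: int(v) for k, v in payload["variant_of"].items()},
        background_latent={k: float(v) for k, v in payload["background_latent"].items()},
        n_variants=int(payload["n_variants"]),
        duration_beta=payload["duration_beta"],
        enrollment_beta=payload["enrollment_beta"],
        duration_sub_beta=payload["duration_sub_beta"],
        enrollment_sub_beta=payload["enrollment_sub_beta"],
        effect_size=payload["effect_size"],
        seed=payload["seed"],
    )
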