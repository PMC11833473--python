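"""Registry ingestion: parsing trial exports, filtering, and criterion tokenization.

A registry export (CSV or JSON) in the style of a public trial registry is
parsed into :class:`TrialRecord` objects, filtered down to completed or
terminated interventional phase 1-4 trials started inside a date window, and
each trial's free-text eligibility section is split into individual inclusion
or exclusion rules (:class:`CriterionRecord`).  The flat criterion table can
be written to and read back from CSV.

The tokenizer dialect (header and bullet patterns, sentence splitting of
bullet-free prose, minimum criterion length) is fixed in module-level
constants so it is explicit and versioned.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TrialRecord",
    "CriterionRecord",
    "RegistrySchemaError",
    "MESH_CODE_RE",
    "parse_registry",
    "filter_trials",
    "tokenize_eligibility",
    "truncate_mesh_code",
    "mesh_level",
    "criteria_from_trial",
    "criteria_from_trials",
    "emit_criterion_table",
    "read_criterion_table",
    "DEFAULT_WINDOW",
]

# ---------------------------------------------------------------------------
# Tokenizer dialect (versioned configuration)
# ---------------------------------------------------------------------------

#: Section headers that set the kind of subsequent rules.
INCLUSION_HEADER_RE = re.compile(
    r"^\s*(?:key\s+)?inclusion\s+criteria\s*[:.\-]?\s*$", re.IGNORECASE
)
EXCLUSION_HEADER_RE = re.compile(
    r"^\s*(?:key\s+)?exclusion\s+criteria\s*[:.\-]?\s*$", re.IGNORECASE
)

#: Bullet markers that open a new rule: -, *, bullet glyphs, "1." / "1)" / "(1)".
BULLET_RE = re.compile(r"^\s*(?:[-*•·‣●▪]+|\(?\d{1,3}[.)])\s+")

#: Sentence boundary used for bullet-free prose: terminal punctuation followed
#: by whitespace and an upper-case letter or digit.
SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?;])\s+(?=[A-Z0-9])")

#: Criteria shorter than this after normalization are dropped as tokenizer noise.
MIN_CRITERION_CHARS = 3

#: MeSH tree-number grammar: root = letter + digits, deeper components numeric.
MESH_CODE_RE = re.compile(r"^[A-Z]\d+(?:\.\d+)*$")

DEFAULT_WINDOW = (_dt.date(2000, 1, 1), _dt.date(2024, 6, 1))

MANDATORY_COLUMNS = (
    "trial_id",
    "study_type",
    "status",
    "phases",
    "start_date",
    "condition_codes",
    "intervention_codes",
    "eligibility_text",
    "enrollment",
    "duration_days",
)


class RegistrySchemaError(ValueError):
    """Raised when a registry export violates the documented schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TrialRecord:
    """One registered trial with the protocol fields the pipeline consumes."""

    trial_id: str
    study_type: str  # "interventional" or "other"
    status: str  # "completed", "terminated" or "other"
    phases: frozenset[int]
    start_date: _dt.date | None
    condition_codes: frozenset[str]
    intervention_codes: frozenset[str]
    eligibility_text: str
    enrollment: int
    duration_days: float


@dataclasses.dataclass(frozen=True)
class CriterionRecord:
    """One tokenized eligibility rule, tagged inclusion / exclusion / unknown."""

    criterion_id: str
    trial_id: str
    text: str
    kind: str  # "inclusion", "exclusion" or "unknown"
    phases: frozenset[int]
    condition_codes: frozenset[str]
    intervention_codes: frozenset[str]


# ---------------------------------------------------------------------------
# MeSH tree numbers
# ---------------------------------------------------------------------------


def mesh_level(code: str) -> int:
    """Depth of a tree number: number of dot-separated components (root = 1)."""
    return code.count(".") + 1


def truncate_mesh_code(code: str, level: int) -> str:
    """Keep the first ``min(level, depth)`` components of a tree number.

    The root component counts as level 1, so ``truncate_mesh_code("C04.557.337", 2)``
    is ``"C04.557"``.  Idempotent at a fixed level.
    """
    if level < 1:
        raise ValueError(f"MeSH truncation level must be >= 1, got {level}")
    return ".".join(code.split(".")[:level])


# ---------------------------------------------------------------------------
# Registry parsing
# ---------------------------------------------------------------------------


def _parse_date(value: object) -> _dt.date | None:
    """ISO-8601 date; month-precision values resolve to day 1."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in {"nan", "none"}:
        return None
    parts = text.split("-")
    if len(parts) == 1:
        return _dt.date(int(parts[0]), 1, 1)
    if len(parts) == 2:
        return _dt.date(int(parts[0]), int(parts[1]), 1)
    return _dt.date.fromisoformat(text[:10])


def _parse_multivalue(value: object) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    if isinstance(value, (list, tuple, set, frozenset)):
        items = [str(v) for v in value]
    else:
        items = str(value).split("|")
    return frozenset(s.strip() for s in items if s.strip())


def _parse_phases(value: object) -> frozenset[int]:
    out = set()
    for item in _parse_multivalue(value):
        m = re.search(r"(\d+)", item)
        if m:
            out.add(int(m.group(1)))
    return frozenset(out)


def _record_from_mapping(row: dict, problems: list[str]) -> TrialRecord:
    trial_id = str(row["trial_id"]).strip()
    if not trial_id:
        raise RegistrySchemaError("empty trial_id")
    eligibility = row.get("eligibility_text")
    if eligibility is None or (isinstance(eligibility, float) and pd.isna(eligibility)):
        problems.append(f"trial {trial_id}: missing eligibility_text (kept, empty)")
        eligibility = ""
    try:
        enrollment = int(float(row["enrollment"])) if str(row["enrollment"]).strip() else 0
    except (TypeError, ValueError):
        problems.append(f"trial {trial_id}: unparseable enrollment, set to 0")
        enrollment = 0
    try:
        duration = float(row["duration_days"]) if str(row["duration_days"]).strip() else 0.0
    except (TypeError, ValueError):
        problems.append(f"trial {trial_id}: unparseable duration_days, set to 0")
        duration = 0.0
    try:
        start = _parse_date(row["start_date"])
    except (ValueError, TypeError):
        problems.append(f"trial {trial_id}: unparseable start_date, set to None")
        start = None
    return TrialRecord(
        trial_id=trial_id,
        study_type=str(row["study_type"]).strip().lower(),
        status=str(row["status"]).strip().lower(),
        phases=_parse_phases(row["phases"]),
        start_date=start,
        condition_codes=_parse_multivalue(row["condition_codes"]),
        intervention_codes=_parse_multivalue(row["intervention_codes"]),
        eligibility_text=str(eligibility),
        enrollment=max(enrollment, 0),
        duration_days=max(duration, 0.0),
    )


def parse_registry(
    source: str | Path, problems: list[str] | None = None
) -> list[TrialRecord]:
    """Parse a registry export (CSV, or JSON list of objects) into trial records.

    Parameters
    ----------
    source
        Path to a ``.csv`` or ``.json`` file with the documented columns.
    problems
        Optional list collecting human-readable reports for deficient rows
        (missing eligibility text, unparseable numbers).  Deficient rows are
        kept with neutral values, never silently dropped.

    Raises
    ------
    RegistrySchemaError
        If a mandatory column is missing (named in the message) or a
        ``trial_id`` is duplicated.
    """
    path = Path(source)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise RegistrySchemaError("JSON registry must be a list of objects")
        frame = pd.DataFrame(rows)
        if frame.empty:
            frame = pd.DataFrame(columns=MANDATORY_COLUMNS)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise RegistrySchemaError(f"registry missing mandatory column(s): {missing}")
    sink = problems if problems is not None else []
    records = [_record_from_mapping(row, sink) for row in frame.to_dict("records")]
    seen: set[str] = set()
    for rec in records:
        if rec.trial_id in seen:
            raise RegistrySchemaError(f"duplicate trial_id: {rec.trial_id!r}")
        seen.add(rec.trial_id)
    return records


def filter_trials(
    trials: Sequence[TrialRecord],
    window: tuple[_dt.date, _dt.date] = DEFAULT_WINDOW,
) -> list[TrialRecord]:
    """Keep interventional, completed/terminated, phase 1-4 trials started in window.

    The filter is total (no errors) and preserves input order; trials without a
    parseable start date are removed because the window rule cannot be checked.
    """
    lo, hi = window
    kept = []
    for t in trials:
        if t.study_type != "interventional":
            continue
        if t.status not in ("completed", "terminated"):
            continue
        if not (t.phases & {1, 2, 3, 4}):
            continue
        if t.start_date is None or not (lo <= t.start_date <= hi):
            continue
        kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# Criterion tokenization
# ---------------------------------------------------------------------------


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


def tokenize_eligibility(text: str) -> list[tuple[str, str]]:
    """Split an eligibility section into ordered ``(text, kind)`` rules.

    Section headers ("Inclusion Criteria", "Exclusion Criteria", optional
    punctuation, case-insensitive) set the kind of all subsequent rules and
    are not themselves emitted.  Bulleted lines start new rules and wrapped
    continuation lines are merged into the open bullet.  Bullet-free prose is
    split at sentence boundaries.  Rules outside any header get kind
    ``"unknown"``.  Empty input yields an empty list.
    """
    if not text or not text.strip():
        return []
    results: list[tuple[str, str]] = []
    kind = "unknown"
    open_bullet: list[str] | None = None  # accumulating lines of current bullet
    prose: list[str] = []  # accumulating bullet-free prose lines

    def flush_bullet() -> None:
        nonlocal open_bullet
        if open_bullet is not None:
            rule = _normalize(" ".join(open_bullet))
            if len(rule) >= MIN_CRITERION_CHARS:
                results.append((rule, kind))
            open_bullet = None

    def flush_prose() -> None:
        nonlocal prose
        if prose:
            block = _normalize(" ".join(prose))
            for sentence in SENTENCE_SPLIT_RE.split(block):
                sentence = sentence.strip()
                if len(sentence) >= MIN_CRITERION_CHARS:
                    results.append((sentence, kind))
            prose = []

    for line in text.splitlines():
        if INCLUSION_HEADER_RE.match(line) or EXCLUSION_HEADER_RE.match(line):
            flush_bullet()
            flush_prose()
            kind = "inclusion" if INCLUSION_HEADER_RE.match(line) else "exclusion"
            continue
        if not line.strip():
            flush_bullet()
            flush_prose()
            continue
        bullet = BULLET_RE.match(line)
        if bullet:
            flush_bullet()
            flush_prose()
            open_bullet = [line[bullet.end():]]
        elif open_bullet is not None:
            open_bullet.append(line.strip())  # wrapped continuation of the bullet
        else:
            prose.append(line.strip())
    flush_bullet()
    flush_prose()
    return results


def criteria_from_trial(trial: TrialRecord) -> list[CriterionRecord]:
    """Tokenize one trial's eligibility section into tagged criterion records."""
    return [
        CriterionRecord(
            criterion_id=f"{trial.trial_id}_EC{i}",
            trial_id=trial.trial_id,
            text=rule,
            kind=kind,
            phases=trial.phases,
            condition_codes=trial.condition_codes,
            intervention_codes=trial.intervention_codes,
        )
        for i, (rule, kind) in enumerate(tokenize_eligibility(trial.eligibility_text))
    ]


def criteria_from_trials(trials: Iterable[TrialRecord]) -> list[CriterionRecord]:
    out: list[CriterionRecord] = []
    for trial in trials:
        out.extend(criteria_from_trial(trial))
    return out


# ---------------------------------------------------------------------------
# Criterion table I/O
# ---------------------------------------------------------------------------

_CRITERION_COLUMNS = (
    "criterion_id",
    "trial_id",
    "text",
    "kind",
    "phases",
    "condition_codes",
    "intervention_codes",
)


def emit_criterion_table(trials: Sequence[TrialRecord], path: str | Path) -> int:
    """Write the flat criterion table (one row per tokenized rule) to CSV.

    Multi-valued fields are serialized as ``"|"``-joined sorted lists.  Returns
    the number of rows written.
    """
    criteria = criteria_from_trials(trials)
    frame = pd.DataFrame(
        [
            {
                "criterion_id": c.criterion_id,
                "trial_id": c.trial_id,
                "text": c.text,
                "kind": c.kind,
                "phases": "|".join(str(p) for p in sorted(c.phases)),
                "condition_codes": "|".join(sorted(c.condition_codes)),
                "intervention_codes": "|".join(sorted(c.intervention_codes)),
            }
            for c in criteria
        ],
        columns=list(_CRITERION_COLUMNS),
    )
    try:
        frame.to_csv(path, index=False, encoding="utf-8")
    except OSError as exc:
        raise OSError(f"failed writing criterion table to {path}: {exc}") from exc
    return len(frame)


def read_criterion_table(path: str | Path) -> list[CriterionRecord]:
    """Read back a criterion table written by :func:`emit_criterion_table`."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CRITERION_COLUMNS if c not in frame.columns]
    if missing:
        raise RegistrySchemaError(f"criterion table missing column(s): {missing}")
    return [
        CriterionRecord(
            criterion_id=row["criterion_id"],
            trial_id=row["trial_id"],
            text=row["text"],
            kind=row["kind"],
            phases=_parse_phases(row["phases"]),
            condition_codes=_parse_multivalue(row["condition_codes"]),
            intervention_codes=_parse_multivalue(row["intervention_codes"]),
        )
        for row in frame.to_dict("records")
    ]
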