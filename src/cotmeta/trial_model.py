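"""Coded-trial schema, controlled vocabularies, status workflow and repository I/O.

A *coded trial* is the structured record a trained coder extracts from a
published controlled trial of a cognition-oriented treatment: citation
metadata, design and methodological items chosen from controlled
vocabularies, the trial arms, the outcome measures, and the numeric cells
(sample size, mean, SD per arm x measure x time point x subgroup).

Trials are stored one-per-file as YAML documents in a repository directory —
a deliberately database-free layout that is diffable and trivially testable.
The coding-item catalogue (which items exist, their allowed vocabulary codes,
whether they are multi-select, and whether they are required before a coding
counts as complete) ships as package data and can be replaced at load time,
so extending the extraction form requires no code changes.
"""

from __future__ import annotations

import importlib.resources
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

SCHEMA_VERSION = 1


class StudyStatus(str, Enum):
    """Workflow state of a trial's coding."""

    QUEUED = "queued"
    IN_PROGRESS = "in_progress"
    REQUIREMENTS_MET = "requirements_met"
    REVISIONS_REQUIRED = "revisions_required"
    VERIFIED = "verified"


#: Allowed workflow transitions.  ``verified`` is terminal.
ALLOWED_TRANSITIONS: dict[StudyStatus, frozenset[StudyStatus]] = {
    StudyStatus.QUEUED: frozenset({StudyStatus.IN_PROGRESS}),
    StudyStatus.IN_PROGRESS: frozenset({StudyStatus.REQUIREMENTS_MET}),
    StudyStatus.REQUIREMENTS_MET: frozenset(
        {StudyStatus.REVISIONS_REQUIRED, StudyStatus.VERIFIED}
    ),
    StudyStatus.REVISIONS_REQUIRED: frozenset({StudyStatus.IN_PROGRESS}),
    StudyStatus.VERIFIED: frozenset(),
}


class Citation(BaseModel):
    authors: list[str]
    year: int
    title: str
    journal: str = ""
    doi: Optional[str] = None

    @field_validator("year")
    @classmethod
    def _plausible_year(cls, v: int) -> int:
        if not 1800 <= v <= 2200:
            raise ValueError(f"implausible publication year {v}")
        return v


class Dose(BaseModel):
    """Intervention dose descriptor."""

    sessions: Optional[int] = None
    minutes_per_session: Optional[float] = None
    weeks: Optional[float] = None


class Arm(BaseModel):
    arm_id: str
    role: str  # "experimental" | "control"
    intervention_label: str = ""
    dose: Optional[Dose] = None

    @field_validator("role")
    @classmethod
    def _known_role(cls, v: str) -> str:
        if v not in ("experimental", "control"):
            raise ValueError(f"arm role must be experimental or control, got {v!r}")
        return v


class MeasureSpec(BaseModel):
    measure_id: str
    name: str
    broad_domain: str
    target: str = "participant"  # participant | caregiver | clinician
    direction: str  # higher_better | lower_better
    is_primary: bool = False

    @field_validator("target")
    @classmethod
    def _known_target(cls, v: str) -> str:
        if v not in ("participant", "caregiver", "clinician"):
            raise ValueError(f"unknown measure target {v!r}")
        return v

    @field_validator("direction")
    @classmethod
    def _known_direction(cls, v: str) -> str:
        if v not in ("higher_better", "lower_better"):
            raise ValueError(f"direction must be higher_better or lower_better, got {v!r}")
        return v


class DataCell(BaseModel):
    """One (arm, measure, time point, subgroup) summary row.

    ``sd`` may be ``None`` when the study did not report a standard
    deviation; such cells load and validate but the study is automatically
    excluded from any effect-size computation that needs them.
    """

    arm_id: str
    measure_id: str
    time_point: str = "post"
    subgroup: Optional[str] = None
    n: int = Field(ge=2)
    mean: float
    sd: Optional[float] = None

    @field_validator("sd")
    @classmethod
    def _positive_sd(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("sd > 0")
        return v


class CodedTrial(BaseModel):
    schema_version: int = SCHEMA_VERSION
    trial_id: str
    citation: Citation
    status: StudyStatus = StudyStatus.QUEUED
    coding: dict[str, list[str]] = Field(default_factory=dict)
    arms: list[Arm] = Field(default_factory=list)
    measures: list[MeasureSpec] = Field(default_factory=list)
    cells: list[DataCell] = Field(default_factory=list)
    summary_text: str = ""
    audit_log: list[str] = Field(default_factory=list)

    def arm(self, arm_id: str) -> Arm:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(arm_id)

    def measure(self, measure_id: str) -> MeasureSpec:
        for m in self.measures:
            if m.measure_id == measure_id:
                return m
        raise KeyError(measure_id)

    @property
    def control_arms(self) -> list[Arm]:
        return [a for a in self.arms if a.role == "control"]

    @property
    def experimental_arms(self) -> list[Arm]:
        return [a for a in self.arms if a.role == "experimental"]

    def cells_for(self, measure_id: str, time_point: str) -> list[DataCell]:
        return [
            c for c in self.cells
            if c.measure_id == measure_id and c.time_point == time_point
        ]


# --------------------------------------------------------------------------
# Item catalogue
# --------------------------------------------------------------------------

class CatalogueItem(BaseModel):
    required: bool = False
    multi: bool = False
    codes: list[str]


class ItemCatalogue(BaseModel):
    """The data-extraction form: item keys, vocabularies, multi-select flags."""

    schema_version: int = 1
    items: dict[str, CatalogueItem]

    @classmethod
    def default(cls) -> "ItemCatalogue":
        ref = importlib.resources.files("cotmeta") / "data" / "item_catalogue.yaml"
        return cls.model_validate(yaml.safe_load(ref.read_text()))

    @classmethod
    def from_file(cls, path: str | Path) -> "ItemCatalogue":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def required_keys(self) -> list[str]:
        return [k for k, item in self.items.items() if item.required]


_DEFAULT_CATALOGUE: Optional[ItemCatalogue] = None


def default_catalogue() -> ItemCatalogue:
    global _DEFAULT_CATALOGUE
    if _DEFAULT_CATALOGUE is None:
        _DEFAULT_CATALOGUE = ItemCatalogue.default()
    return _DEFAULT_CATALOGUE


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

class Violation(BaseModel):
    """One failed invariant or completeness requirement (data, not exception)."""

    trial_id: str
    invariant: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.trial_id}: {self.invariant} ({self.detail})"


def validate_trial(
    trial: CodedTrial, catalogue: Optional[ItemCatalogue] = None
) -> list[Violation]:
    """Check structural invariants and coding completeness.

    Returns an empty list iff the trial satisfies every invariant and every
    required catalogue item is coded — the condition under which the
    ``requirements_met`` status may be set.
    """
    cat = catalogue or default_catalogue()
    out: list[Violation] = []

    def bad(invariant: str, detail: str = "") -> None:
        out.append(Violation(trial_id=trial.trial_id, invariant=invariant, detail=detail))

    arm_ids = [a.arm_id for a in trial.arms]
    if len(set(arm_ids)) != len(arm_ids):
        bad("arm_id unique within trial")
    if not trial.control_arms:
        bad("no control arm", "a controlled trial needs at least one control arm")
    if not trial.experimental_arms:
        bad("no experimental arm")

    measure_ids = [m.measure_id for m in trial.measures]
    if len(set(measure_ids)) != len(measure_ids):
        bad("measure_id unique within trial")

    seen_cells: set[tuple] = set()
    for cell in trial.cells:
        if cell.arm_id not in arm_ids:
            bad("cell references existing arm", f"unknown arm_id {cell.arm_id!r}")
        if cell.measure_id not in measure_ids:
            bad("cell references existing measure", f"unknown measure_id {cell.measure_id!r}")
        key = (cell.arm_id, cell.measure_id, cell.time_point, cell.subgroup)
        if key in seen_cells:
            bad("cell combination unique", f"duplicate cell {key}")
        seen_cells.add(key)

    for key, codes in trial.coding.items():
        if key not in cat.items:
            bad("coding key in catalogue", f"unknown item {key!r}")
            continue
        item = cat.items[key]
        unknown = [c for c in codes if c not in item.codes]
        if unknown:
            bad("coding codes in vocabulary", f"{key}: unknown codes {unknown}")
        if not item.multi and len(codes) > 1:
            bad("multi-select only where permitted", f"{key} is single-select")

    for key in cat.required_keys():
        if not trial.coding.get(key):
            bad("required coding item present", f"missing {key!r}")

    return out


def transition_status(trial: CodedTrial, new: StudyStatus) -> CodedTrial:
    """Return a copy of *trial* moved to *new* along an allowed edge.

    Raises ``ValueError`` naming both states for an illegal transition.
    Setting ``requirements_met`` additionally requires a clean validation.
    """
    new = StudyStatus(new)
    if new not in ALLOWED_TRANSITIONS[trial.status]:
        raise ValueError(
            f"illegal status transition {trial.status.value} -> {new.value}"
        )
    if new is StudyStatus.REQUIREMENTS_MET:
        violations = validate_trial(trial)
        if violations:
            raise ValueError(
                "requirements_met requires a clean validation; first violation: "
                f"{violations[0].invariant}"
            )
    updated = trial.model_copy(deep=True)
    updated.status = new
    updated.audit_log.append(f"status: {trial.status.value} -> {new.value}")
    return updated


# --------------------------------------------------------------------------
# Repository I/O
# --------------------------------------------------------------------------

class RepositoryError(Exception):
    pass


class LoadReport(BaseModel):
    """Outcome of loading a repository directory: trials plus per-file errors."""

    trials: list[CodedTrial]
    errors: list[dict] = Field(default_factory=list)


def _trial_to_dict(trial: CodedTrial) -> dict:
    return trial.model_dump(mode="json", exclude_none=True)


def write_trial(trial: CodedTrial, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_trial_to_dict(trial), sort_keys=False, allow_unicode=True)
    )


def write_repository(trials: list[CodedTrial], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial in trials:
        p = directory / f"{trial.trial_id}.yaml"
        write_trial(trial, p)
        paths.append(p)
    return paths


def load_trial(path: str | Path, catalogue: Optional[ItemCatalogue] = None) -> CodedTrial:
    """Parse one trial file and reject it on the first violated invariant."""
    raw = yaml.safe_load(Path(path).read_text())
    trial = CodedTrial.model_validate(raw)
    violations = validate_trial(trial, catalogue)
    structural = [v for v in violations if not v.invariant.startswith("required coding")]
    if structural:
        raise RepositoryError(f"{Path(path).name}: {structural[0].invariant}: {structural[0].detail}")
    return trial


def load_repository(
    directory: str | Path, catalogue: Optional[ItemCatalogue] = None
) -> LoadReport:
    """Load every ``*.yaml`` trial file under *directory*.

    Malformed files are reported (file name plus first violated invariant)
    while the remaining trials still load; a duplicate ``trial_id`` across
    files is a hard error because it poisons every downstream join.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise RepositoryError(f"repository path {directory} does not exist")
    trials: list[CodedTrial] = []
    errors: list[dict] = []
    seen: dict[str, str] = {}
    for path in sorted(directory.glob("*.yaml")):
        if path.name == "ground_truth.yaml":
            continue
        try:
            trial = load_trial(path, catalogue)
        except (RepositoryError, ValueError, yaml.YAMLError) as exc:
            errors.append({"file": path.name, "error": str(exc)})
            continue
        if trial.trial_id in seen:
            raise RepositoryError(
                f"duplicate trial_id {trial.trial_id!r} in {path.name} and {seen[trial.trial_id]}"
            )
        seen[trial.trial_id] = path.name
        trials.append(trial)
    return LoadReport(trials=trials, errors=errors)


# --------------------------------------------------------------------------
# Tabular / citation export
# --------------------------------------------------------------------------

def trials_to_tsv(trials: list[CodedTrial]) -> str:
    """Spreadsheet-friendly listing of a repository (one row per trial)."""
    import pandas as pd

    rows = []
    for t in trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "first_author": t.citation.authors[0] if t.citation.authors else "",
                "year": t.citation.year,
                "title": t.citation.title,
                "journal": t.citation.journal,
                "doi": t.citation.doi or "",
                "status": t.status.value,
                "design": ";".join(t.coding.get("design", [])),
                "population": ";".join(t.coding.get("population", [])),
                "intervention": ";".join(t.coding.get("intervention_type", [])),
                "n_arms": len(t.arms),
                "n_measures": len(t.measures),
            }
        )
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def trials_to_ris(trials: list[CodedTrial]) -> str:
    """Citations in RIS format for import into reference managers."""
    records = []
    for t in trials:
        lines = ["TY  - JOUR"]
        lines += [f"AU  - {a}" for a in t.citation.authors]
        lines.append(f"PY  - {t.citation.year}")
        lines.append(f"TI  - {t.citation.title}")
        if t.citation.journal:
            lines.append(f"JO  - {t.citation.journal}")
        if t.citation.doi:
            lines.append(f"DO  - {t.citation.doi}")
        lines.append("ER  - ")
        records.append("\n".join(lines))
    return "\n".join(records) + ("\n" if records else "")
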