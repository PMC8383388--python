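"""Methodological-quality indices computed from coded trial items.

Three common appraisal instruments are evaluated algorithmically from the
coding: the PEDro scale (11 items, 10 scored, total 0-10), the Jadad rating
(0-5), and the Cochrane Risk of Bias tool (seven domains rated
low/high/unclear).  A single published score item does not always map to a
single extraction item, so every score item is driven by a small predicate
over the coding — shipped as editable YAML rule tables, one file per index,
so the rules can be recalibrated against manual scoring without code
changes.

Missing information is never imputed: an item whose inputs are not coded is
scored unsatisfied (PEDro/Jadad) or unclear (RoB).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

Coding = dict[str, list[str]]

ROB_DOMAINS = (
    "sequence_generation",
    "allocation_concealment",
    "blinding_participants_personnel",
    "blinding_outcome_assessment",
    "incomplete_outcome_data",
    "selective_reporting",
    "other",
)


def eval_predicate(pred: dict, coding: Coding) -> bool:
    """Evaluate a rule predicate against a coding.

    Grammar: ``{item, any_of}`` leaf; ``{all: [...]}``, ``{any: [...]}``,
    ``{not: ...}`` combinators.  A leaf over an uncoded item is false, which
    is what makes the conservative missing-data policy fall out for free.
    """
    if "item" in pred:
        codes = coding.get(pred["item"], [])
        return any(c in pred["any_of"] for c in codes)
    if "all" in pred:
        return all(eval_predicate(p, coding) for p in pred["all"])
    if "any" in pred:
        return any(eval_predicate(p, coding) for p in pred["any"])
    if "not" in pred:
        return not eval_predicate(pred["not"], coding)
    raise ValueError(f"malformed predicate {pred!r}")


class ScoringRule(BaseModel):
    key: str
    scored: bool = True
    predicate: dict


class RuleTable(BaseModel):
    index: str
    items: list[ScoringRule]

    @classmethod
    def load(cls, name: str, path: Optional[str | Path] = None) -> "RuleTable":
        if path is None:
            ref = importlib.resources.files("cotmeta") / "data" / f"{name}_rules.yaml"
            raw = yaml.safe_load(ref.read_text())
        else:
            raw = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(raw)


class QualityScores(BaseModel):
    trial_id: str = ""
    pedro_total: int = Field(ge=0, le=10)
    pedro_items: dict[str, bool]
    jadad_total: int = Field(ge=0, le=5)
    jadad_items: dict[str, bool]
    rob_domains: dict[str, str]


_TABLES: dict[str, RuleTable] = {}
_ROB_RULES: Optional[dict] = None


def _table(name: str) -> RuleTable:
    if name not in _TABLES:
        _TABLES[name] = RuleTable.load(name)
    return _TABLES[name]


def _rob_rules() -> dict:
    global _ROB_RULES
    if _ROB_RULES is None:
        ref = importlib.resources.files("cotmeta") / "data" / "rob_rules.yaml"
        _ROB_RULES = yaml.safe_load(ref.read_text())["domains"]
    return _ROB_RULES


def _score_table(coding: Coding, table: RuleTable) -> tuple[int, dict[str, bool]]:
    items = {rule.key: eval_predicate(rule.predicate, coding) for rule in table.items}
    total = sum(items[rule.key] for rule in table.items if rule.scored)
    return total, items


def score_pedro(coding: Coding) -> tuple[int, dict[str, bool]]:
    """PEDro total (0-10, items 2-11) plus the per-item satisfaction map."""
    return _score_table(coding, _table("pedro"))


def score_jadad(coding: Coding) -> tuple[int, dict[str, bool]]:
    """Jadad total (0-5) plus the per-item satisfaction map."""
    return _score_table(coding, _table("jadad"))


def score_rob(coding: Coding) -> dict[str, str]:
    """Cochrane RoB domain ratings: low / high / unclear per domain."""
    rules = _rob_rules()
    out = {}
    for domain in ROB_DOMAINS:
        spec = rules[domain]
        if eval_predicate(spec["low"], coding):
            out[domain] = "low"
        elif eval_predicate(spec["high"], coding):
            out[domain] = "high"
        else:
            out[domain] = "unclear"
    return out


def score_trial(trial) -> QualityScores:
    """All three indices for one coded trial."""
    pedro_total, pedro_items = score_pedro(trial.coding)
    jadad_total, jadad_items = score_jadad(trial.coding)
    return QualityScores(
        trial_id=trial.trial_id,
        pedro_total=pedro_total,
        pedro_items=pedro_items,
        jadad_total=jadad_total,
        jadad_items=jadad_items,
        rob_domains=score_rob(trial.coding),
    )


def mean_quality(scores: list[QualityScores], index: str = "pedro") -> float:
    """Arithmetic mean of one index's totals across studies."""
    if not scores:
        raise ValueError("mean_quality needs at least one score")
    if index == "pedro":
        totals = [s.pedro_total for s in scores]
    elif index == "jadad":
        totals = [s.jadad_total for s in scores]
    else:
        raise ValueError(f"unknown quality index {index!r}")
    return sum(totals) / len(totals)


def quality_table(scores: list[QualityScores]):
    """Item-level and total quality scores as a DataFrame for export."""
    import pandas as pd

    rows = []
    for s in scores:
        row = {"trial_id": s.trial_id, "pedro_total": s.pedro_total, "jadad_total": s.jadad_total}
        row.update({f"pedro_{k}": v for k, v in s.pedro_items.items()})
        row.update({f"jadad_{k}": v for k, v in s.jadad_items.items()})
        row.update({f"rob_{k}": v for k, v in s.rob_domains.items()})
        rows.append(row)
    return pd.DataFrame(rows)
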