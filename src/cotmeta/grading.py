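"""Certainty grading and rule-generated evidence summaries.

Certainty in a pooled finding is graded from three components: the mean
methodological quality of the contributing studies, the between-study
heterogeneity, and the precision of the pooled estimate (total number of
participants).  Each component is banded favorable / intermediate /
unfavorable by configurable thresholds, and the bands combine into a
low / moderate / high certainty level:

    high     — all three components favorable
    low      — quality unfavorable, or at least two components unfavorable
    moderate — everything else

The thresholds are a declared, documented rule set held entirely in a config
file, so a recalibrated banding scheme can be dropped in without code
changes.  Recommendations follow the certainty level: high certainty with a
confidence interval excluding zero yields a strong recommendation, moderate
a modest one, and low certainty never yields a recommendation.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel

from .meta_engine import PooledResult
from .quality_scoring import QualityScores, mean_quality

BANDS = ("favorable", "intermediate", "unfavorable")
LEVELS = ("low", "moderate", "high")


class GradingConfig(BaseModel):
    quality_index: str = "pedro"
    quality_bands: dict[str, float] = {"favorable_min": 7.0, "intermediate_min": 4.0}
    heterogeneity_bands: dict[str, float] = {"favorable_max": 30.0, "intermediate_max": 60.0}
    precision_bands: dict[str, float] = {"favorable_min": 400, "intermediate_min": 100}
    magnitude_bands: dict[str, float] = {"trivial_max": 0.2, "small_max": 0.5, "moderate_max": 0.8}

    @classmethod
    def default(cls) -> "GradingConfig":
        ref = importlib.resources.files("cotmeta") / "data" / "grading.yaml"
        return cls.model_validate(yaml.safe_load(ref.read_text()))

    @classmethod
    def from_file(cls, path: str | Path) -> "GradingConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


class CertaintyRating(BaseModel):
    level: str  # low | moderate | high
    mean_quality_band: str
    heterogeneity_band: str
    precision_band: str
    mean_quality: float
    i2: float
    n_total: int


class EvidenceSummary(BaseModel):
    recommendation: str  # strong_for | modest_for | none | modest_against | strong_against
    narrative: str
    magnitude_band: str
    significant: bool
    certainty: str


def _band_higher_better(x: float, favorable_min: float, intermediate_min: float) -> str:
    if x >= favorable_min:
        return "favorable"
    if x >= intermediate_min:
        return "intermediate"
    return "unfavorable"


def _band_lower_better(x: float, favorable_max: float, intermediate_max: float) -> str:
    if x < favorable_max:
        return "favorable"
    if x <= intermediate_max:
        return "intermediate"
    return "unfavorable"


def combine_bands(quality: str, het: str, precision: str) -> str:
    """Pure band-combination rule; exhaustively testable over 27 inputs."""
    bands = (quality, het, precision)
    if any(b not in BANDS for b in bands):
        raise ValueError(f"unknown band in {bands}")
    if all(b == "favorable" for b in bands):
        return "high"
    n_unfav = sum(b == "unfavorable" for b in bands)
    if quality == "unfavorable" or n_unfav >= 2:
        return "low"
    return "moderate"


def grade_certainty(
    pooled: PooledResult,
    qualities: list[QualityScores],
    config: Optional[GradingConfig] = None,
) -> CertaintyRating:
    """Certainty rating for one pooled outcome.

    Requires one quality score per contributing study; a missing score is an
    error naming the study, never silently ignored.
    """
    config = config or GradingConfig.default()
    have = {q.trial_id for q in qualities}
    contributing = [e.trial_id for e, _ in pooled.per_study]
    missing = [t for t in contributing if t not in have]
    if missing:
        raise ValueError(f"missing quality scores for studies: {missing}")
    used = [q for q in qualities if q.trial_id in set(contributing)]
    mq = mean_quality(used, config.quality_index)
    qb = _band_higher_better(mq, **{k: config.quality_bands[k] for k in ("favorable_min", "intermediate_min")})
    hb = _band_lower_better(pooled.i2, config.heterogeneity_bands["favorable_max"],
                            config.heterogeneity_bands["intermediate_max"])
    pb = _band_higher_better(pooled.n_total, config.precision_bands["favorable_min"],
                             config.precision_bands["intermediate_min"])
    return CertaintyRating(
        level=combine_bands(qb, hb, pb),
        mean_quality_band=qb, heterogeneity_band=hb, precision_band=pb,
        mean_quality=mq, i2=pooled.i2, n_total=pooled.n_total,
    )


def magnitude_band(g: float, config: Optional[GradingConfig] = None) -> str:
    config = config or GradingConfig.default()
    a = abs(g)
    if a < config.magnitude_bands["trivial_max"]:
        return "trivial"
    if a < config.magnitude_bands["small_max"]:
        return "small"
    if a < config.magnitude_bands["moderate_max"]:
        return "moderate"
    return "large"


def summarize_evidence(
    pooled: PooledResult,
    rating: CertaintyRating,
    config: Optional[GradingConfig] = None,
) -> EvidenceSummary:
    """Recommendation and narrative for one pooled outcome.

    Significance means the HKSJ confidence interval excludes zero.  Low
    certainty always yields no recommendation; an interval covering zero
    yields none regardless of certainty.
    """
    config = config or GradingConfig.default()
    significant = pooled.ci_low > 0 or pooled.ci_high < 0
    mag = magnitude_band(pooled.mu, config)
    if rating.level == "low" or not significant:
        rec = "none"
    else:
        strength = "strong" if rating.level == "high" else "modest"
        direction = "for" if pooled.mu > 0 else "against"
        rec = f"{strength}_{direction}"

    if rec == "none":
        stance = (
            "no recommendation is made"
            if rating.level == "low"
            else "no recommendation is made because the effect is not statistically significant"
        )
    else:
        strength, direction = rec.split("_")
        stance = f"a {strength} recommendation is made {'in favor of' if direction == 'for' else 'against'} the intervention"
    narrative = (
        f"For {pooled.outcome.replace('_', ' ')} in {pooled.population.replace('_', ' ')} "
        f"({pooled.k} studies, {pooled.n_total} participants), the pooled effect was "
        f"g = {pooled.mu:.2f} (95% CI {pooled.ci_low:.2f} to {pooled.ci_high:.2f}), "
        f"a {mag} effect. The certainty of the evidence is {rating.level}; {stance}."
    )
    return EvidenceSummary(
        recommendation=rec, narrative=narrative,
        magnitude_band=mag, significant=significant, certainty=rating.level,
    )
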