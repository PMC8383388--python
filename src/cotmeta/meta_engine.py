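"""Random-effects meta-analysis: eligibility, REML heterogeneity, HKSJ intervals.

The pooling model is the standard two-stage random-effects model for
standardized mean differences: study effects y_i ~ N(theta_i, v_i) with
theta_i ~ N(mu, tau^2).  The between-study variance tau^2 is estimated by
restricted maximum likelihood (REML); the confidence interval for the pooled
effect uses the Hartung-Knapp-Sidik-Jonkman (HKSJ) variance estimator with
t(k-1) quantiles, which is insensitive to the magnitude and estimator of
tau^2.  Heterogeneity is tested with Cochran's Q (p < 0.10 flagged as
significant — a flag, never a gate on pooling) and quantified with I^2, and a
95% prediction interval (t with k-2 df) describes where the true effect of a
comparable new study is expected to fall.

Eligibility mirrors the platform's pooling rules: only studies reporting
means and SDs for each group enter an analysis, and an outcome x population
group is pooled only when at least ``min_k`` (default 3) studies contribute.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy import optimize, stats

from .effect_size import (
    DEFAULT_CORRELATION,
    EffectEstimate,
    EffectSizeError,
    combine_correlated,
    study_effect,
)
from .trial_model import CodedTrial


class MetaAnalysisSpec(BaseModel):
    """Scope of one meta-analysis request (the wizard's selections)."""

    populations: list[str] = Field(default_factory=list)   # empty = all
    targets: list[str] = Field(default_factory=lambda: ["participant"])
    broad_outcomes: list[str] = Field(default_factory=list)  # empty = all available
    specific_outcomes: list[str] = Field(default_factory=list)
    time_point: str = "post"
    r: float = DEFAULT_CORRELATION
    min_k: int = 3
    alpha_q: float = 0.10
    pi_df_convention: str = "k-2"  # or "k-1"

    def model_post_init(self, __context) -> None:
        if self.min_k < 2:
            raise ValueError("min_k must be >= 2")
        if not 0 < self.alpha_q < 1:
            raise ValueError("alpha_Q must lie in (0, 1)")
        if not -1 < self.r < 1:
            raise ValueError("correlation must lie in (-1, 1)")


class Exclusion(BaseModel):
    trial_id: Optional[str] = None
    outcome: Optional[str] = None
    population: Optional[str] = None
    reason: str


class PooledResult(BaseModel):
    outcome: str
    population: str
    k: int
    n_total: int
    mu: float
    se_hksj: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    p_q: float
    i2: float
    significant_heterogeneity: bool
    pi_low: Optional[float] = None
    pi_high: Optional[float] = None
    per_study: list[tuple[EffectEstimate, float]] = Field(default_factory=list)


class MetaAnalysisError(ValueError):
    pass


# --------------------------------------------------------------------------
# Core statistics
# --------------------------------------------------------------------------

def _restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return -0.5 * (
        np.sum(np.log(v + tau2))
        + np.log(np.sum(w))
        + np.sum(w * (y - mu) ** 2)
    )


def reml_tau2(y: Sequence[float], v: Sequence[float]) -> float:
    """REML estimate of the between-study variance tau^2 (>= 0).

    Solved by bounded scalar maximization of the restricted log-likelihood
    on [0, upper] with upper = 10 * (max v + sample variance of y); the
    boundary value 0 is compared against the interior optimum explicitly.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.size < 2:
        raise MetaAnalysisError("REML needs at least 2 studies")
    if np.any(v <= 0):
        raise MetaAnalysisError("all sampling variances must be positive")
    upper = 10.0 * (float(np.max(v)) + float(np.var(y, ddof=1)))
    upper = max(upper, 1e-4)
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(t, y, v),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded Brent essentially always converges
        raise MetaAnalysisError(f"REML did not converge: {res}")
    tau2 = float(res.x)
    if _restricted_loglik(0.0, y, v) >= _restricted_loglik(tau2, y, v):
        return 0.0
    return tau2


def pool_hksj(
    y: Sequence[float], v: Sequence[float], tau2: float, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """Random-effects pooled mean with the HKSJ interval.

    Weights w_i = 1/(v_i + tau^2); mu = sum(w y)/sum(w);
    se^2 = [sum w_i (y_i - mu)^2 / (k-1)] / sum(w); CI uses t(k-1).
    Plain HKSJ, no variance floor: with zero observed dispersion the CI
    degenerates to the point {mu} — documented behavior.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = y.size
    if k < 2:
        raise MetaAnalysisError("pooling needs at least 2 studies")
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se2 = float(np.sum(w * (y - mu) ** 2) / (k - 1) / np.sum(w))
    se = math.sqrt(se2)
    t_crit = stats.t.ppf(1 - alpha / 2, df=k - 1)
    return mu, se, mu - t_crit * se, mu + t_crit * se


def heterogeneity(y: Sequence[float], v: Sequence[float]) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p-value (k-1 df), and I^2 in percent.

    I^2 = max(0, 100 (Q - (k-1)) / Q), zero whenever Q <= k-1.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = y.size
    if k < 2:
        raise MetaAnalysisError("heterogeneity needs at least 2 studies")
    w = 1.0 / v
    y_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fe) ** 2))
    p_q = float(stats.chi2.sf(q, df=k - 1))
    i2 = max(0.0, 100.0 * (q - (k - 1)) / q) if q > 0 else 0.0
    return q, p_q, i2


def prediction_interval(
    mu: float, se_hksj: float, tau2: float, k: int,
    level: float = 0.95, df_convention: str = "k-2",
) -> tuple[float, float]:
    """95% prediction interval for the true effect of a new comparable study.

    mu +/- t_{df, (1+level)/2} sqrt(tau^2 + se^2), df = k-2 by default
    (the k-1 convention is available via ``df_convention``).
    """
    if k < 3:
        raise MetaAnalysisError("prediction interval needs at least 3 studies")
    df = k - 2 if df_convention == "k-2" else k - 1
    t_crit = stats.t.ppf((1 + level) / 2, df=df)
    half = t_crit * math.sqrt(tau2 + se_hksj**2)
    return mu - half, mu + half


# --------------------------------------------------------------------------
# Eligibility and the full pipeline
# --------------------------------------------------------------------------

def _study_contribution(
    trial: CodedTrial, domain: str, spec: MetaAnalysisSpec
) -> Optional[EffectEstimate]:
    """One effect per study per outcome group, or None if not computable.

    Within-study combining order: subgroups and multi-arm adjustment happen
    inside ``study_effect`` per measure; related measures in the same broad
    domain are then combined with the default correlation so each study
    contributes exactly one effect to the group.
    """
    measures = [
        m for m in trial.measures
        if m.broad_domain == domain
        and m.target in spec.targets
        and (not spec.specific_outcomes or m.measure_id in spec.specific_outcomes
             or m.name in spec.specific_outcomes)
    ]
    per_measure: list[EffectEstimate] = []
    for m in measures:
        try:
            per_measure.append(study_effect(trial, m.measure_id, spec.time_point))
        except EffectSizeError:
            continue
    if not per_measure:
        return None
    if len(per_measure) == 1:
        return per_measure[0]
    return combine_correlated(per_measure, r=spec.r)


def _trial_populations(trial: CodedTrial) -> list[str]:
    return trial.coding.get("population", ["unspecified"]) or ["unspecified"]


def eligible_groups(
    trials: Sequence[CodedTrial], spec: MetaAnalysisSpec
) -> tuple[dict[tuple[str, str], list[EffectEstimate]], list[Exclusion]]:
    """Group study effects by (outcome, population) and apply the pooling rules.

    Studies without usable means/SDs are automatically excluded (logged);
    groups with fewer than ``min_k`` contributing studies are dropped
    (logged).  Returns the eligible groups and the exclusion log.
    """
    if spec.broad_outcomes == [] and spec.populations == []:
        # "all available" — discover scope from the data
        pass
    domains = spec.broad_outcomes or sorted(
        {m.broad_domain for t in trials for m in t.measures}
    )
    if not domains:
        raise MetaAnalysisError("no outcomes selected")
    exclusions: list[Exclusion] = []
    groups: dict[tuple[str, str], list[EffectEstimate]] = {}
    for domain in domains:
        for trial in trials:
            if not any(m.broad_domain == domain for m in trial.measures):
                continue
            pops = [
                p for p in _trial_populations(trial)
                if not spec.populations or p in spec.populations
            ]
            if not pops:
                continue
            effect = _study_contribution(trial, domain, spec)
            if effect is None:
                exclusions.append(
                    Exclusion(
                        trial_id=trial.trial_id, outcome=domain,
                        reason="missing means or standard deviations",
                    )
                )
                continue
            for pop in pops:
                groups.setdefault((domain, pop), []).append(effect)
    eligible: dict[tuple[str, str], list[EffectEstimate]] = {}
    for key, effects in sorted(groups.items()):
        if len(effects) < spec.min_k:
            exclusions.append(
                Exclusion(
                    outcome=key[0], population=key[1],
                    reason=f"fewer than {spec.min_k} studies",
                )
            )
            continue
        eligible[key] = effects
    return eligible, exclusions


def pool_group(
    outcome: str, population: str, effects: Sequence[EffectEstimate],
    spec: Optional[MetaAnalysisSpec] = None,
) -> PooledResult:
    """REML + HKSJ pooling of one group's per-study effects."""
    spec = spec or MetaAnalysisSpec()
    y = [e.g for e in effects]
    v = [e.var for e in effects]
    k = len(effects)
    tau2 = reml_tau2(y, v)
    mu, se, ci_lo, ci_hi = pool_hksj(y, v, tau2)
    q, p_q, i2 = heterogeneity(y, v)
    pi_lo = pi_hi = None
    if k >= 3:
        pi_lo, pi_hi = prediction_interval(
            mu, se, tau2, k, df_convention=spec.pi_df_convention
        )
    w = np.array([1.0 / (vi + tau2) for vi in v])
    w = w / w.sum()
    return PooledResult(
        outcome=outcome, population=population, k=k,
        n_total=int(sum(e.n_exp + e.n_ctl for e in effects)),
        mu=mu, se_hksj=se, ci_low=ci_lo, ci_high=ci_hi,
        tau2=tau2, q=q, p_q=p_q, i2=i2,
        significant_heterogeneity=p_q < spec.alpha_q,
        pi_low=pi_lo, pi_high=pi_hi,
        per_study=[(e, float(wi)) for e, wi in zip(effects, w)],
    )


def run_meta(
    trials: Sequence[CodedTrial], spec: Optional[MetaAnalysisSpec] = None
) -> tuple[list[PooledResult], list[Exclusion]]:
    """Full pipeline: eligibility -> within-study combining -> REML -> HKSJ.

    By default every available outcome and population meeting the minimum
    criteria is analyzed; a narrower ``spec`` restricts the scope.
    """
    spec = spec or MetaAnalysisSpec()
    groups, exclusions = eligible_groups(trials, spec)
    results = []
    for (outcome, population), effects in groups.items():
        try:
            results.append(pool_group(outcome, population, effects, spec))
        except MetaAnalysisError as exc:
            raise MetaAnalysisError(f"{outcome}/{population}: {exc}") from exc
    return results, exclusions


def pooled_results_table(results: Sequence[PooledResult]):
    """Pooled results as a DataFrame for tabular export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "population": r.population,
                "k": r.k,
                "n_total": r.n_total,
                "g": r.mu,
                "se_hksj": r.se_hksj,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "tau2": r.tau2,
                "Q": r.q,
                "p_Q": r.p_q,
                "I2_pct": r.i2,
                "pi_low": r.pi_low,
                "pi_high": r.pi_high,
            }
            for r in results
        ]
    )
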