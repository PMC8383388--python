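"""Per-study standardized effect estimates (Hedges' g) and within-study combining.

All effects follow one sign convention: a positive g favors the experimental
condition.  For measures where a lower score is the better outcome
(``direction == "lower_better"``) the sign of the raw standardized mean
difference is flipped before anything else happens.

Three within-study combining steps are supported, applied in this order when
more than one applies:

1. *Independent subgroups* — when a study reports only disjoint subgroups,
   a fixed-effect (inverse-variance) combination yields the study's effect.
2. *Multi-arm comparisons* — with several experimental arms sharing one
   control arm, each pairwise comparison's standard error is inflated so
   that naive fixed-effect pooling of the adjusted comparisons reproduces
   the generalized-least-squares estimate under the full shared-arm
   covariance matrix (both point estimate and variance).
3. *Correlated outcomes* — related measures on the same participants are
   combined with the composite-outcome rule, with a default between-measure
   correlation of r = 0.50.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel
from scipy import stats

from .trial_model import CodedTrial, DataCell, MeasureSpec

DEFAULT_CORRELATION = 0.50
Z_95 = stats.norm.ppf(0.975)


class EffectSizeError(ValueError):
    pass


class EffectEstimate(BaseModel):
    """One Hedges' g with its variance, CI and provenance."""

    g: float
    var: float
    trial_id: str = ""
    experimental_arm_id: str = ""
    control_arm_id: str = ""
    measure_id: str = ""
    time_point: str = "post"
    n_exp: int = 0
    n_ctl: int = 0
    adjusted: bool = False            # SE carries the multi-arm inflation
    pooled_within_study: bool = False # subgroup or correlated-outcome composite
    raw_d: Optional[float] = None     # uncorrected SMD, kept for covariance algebra

    @property
    def se(self) -> float:
        return math.sqrt(self.var)

    @property
    def ci_low(self) -> float:
        return self.g - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.g + Z_95 * self.se


def hedges_g(
    mean_e: float, sd_e: float, n_e: int,
    mean_c: float, sd_c: float, n_c: int,
    direction: str = "higher_better",
    **provenance,
) -> EffectEstimate:
    """Small-sample-corrected standardized mean difference between two arms.

    d = (mean_e - mean_c) / s_pooled with the usual df-weighted pooled SD;
    the correction factor is J = 1 - 3 / (4(n_e + n_c - 2) - 1), g = J d and

        var(g) = J^2 [ (n_e + n_c) / (n_e n_c) + d^2 / (2 (n_e + n_c - 2)) ].

    The variance uses d^2 (not g^2) in the second term, under the J^2
    prefactor — the convention the oracle tests in the suite pin down.
    """
    if n_e < 2 or n_c < 2:
        raise EffectSizeError(f"need n >= 2 per arm, got n_e={n_e}, n_c={n_c}")
    if sd_e is None or sd_c is None or sd_e <= 0 or sd_c <= 0:
        raise EffectSizeError(f"need sd > 0 in both arms, got sd_e={sd_e}, sd_c={sd_c}")
    if direction not in ("higher_better", "lower_better"):
        raise EffectSizeError(f"unknown direction {direction!r}")

    df = n_e + n_c - 2
    s_pooled = math.sqrt(((n_e - 1) * sd_e**2 + (n_c - 1) * sd_c**2) / df)
    d = (mean_e - mean_c) / s_pooled
    if direction == "lower_better":
        d = -d
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var = j**2 * ((n_e + n_c) / (n_e * n_c) + d**2 / (2.0 * df))
    return EffectEstimate(
        g=g, var=var, n_exp=n_e, n_ctl=n_c, raw_d=d, **provenance
    )


def fixed_effect_pool(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Inverse-variance fixed-effect combination; returns (g, var)."""
    w = np.array([1.0 / e.var for e in effects])
    y = np.array([e.g for e in effects])
    return float(np.sum(w * y) / np.sum(w)), float(1.0 / np.sum(w))


def combine_subgroups(effects: Sequence[EffectEstimate]) -> EffectEstimate:
    """Combine effects from disjoint subgroups of one study by fixed-effect pooling."""
    if len(effects) < 2:
        raise EffectSizeError("subgroup combination needs >= 2 effects")
    trials = {e.trial_id for e in effects}
    measures = {e.measure_id for e in effects}
    tps = {e.time_point for e in effects}
    if len(trials) > 1 or len(measures) > 1 or len(tps) > 1:
        raise EffectSizeError(
            f"subgroups must share trial/measure/time point, got {trials}/{measures}/{tps}"
        )
    g, var = fixed_effect_pool(effects)
    proto = effects[0]
    return EffectEstimate(
        g=g, var=var,
        trial_id=proto.trial_id,
        experimental_arm_id=proto.experimental_arm_id,
        control_arm_id=proto.control_arm_id,
        measure_id=proto.measure_id,
        time_point=proto.time_point,
        n_exp=sum(e.n_exp for e in effects),
        n_ctl=sum(e.n_ctl for e in effects),
        adjusted=any(e.adjusted for e in effects),
        pooled_within_study=True,
        raw_d=None,
    )


def combine_correlated(
    effects: Sequence[EffectEstimate], r: float = DEFAULT_CORRELATION
) -> EffectEstimate:
    """Composite effect over related outcomes measured on the same participants.

    g* = mean(g_i);  var* = (1/m^2) [ sum v_i + sum_{i != j} r sqrt(v_i v_j) ].
    """
    if len(effects) < 2:
        raise EffectSizeError("correlated-outcome combination needs >= 2 effects")
    if not -1.0 < r < 1.0:
        raise EffectSizeError(f"correlation must lie in (-1, 1), got {r}")
    if len({e.trial_id for e in effects}) > 1:
        raise EffectSizeError("correlated outcomes must come from one trial")
    m = len(effects)
    g = sum(e.g for e in effects) / m
    v = [e.var for e in effects]
    cross = sum(
        r * math.sqrt(v[i] * v[j])
        for i in range(m) for j in range(m) if i != j
    )
    var = (sum(v) + cross) / m**2
    proto = effects[0]
    return EffectEstimate(
        g=g, var=var,
        trial_id=proto.trial_id,
        experimental_arm_id=proto.experimental_arm_id,
        control_arm_id=proto.control_arm_id,
        measure_id="+".join(sorted({e.measure_id for e in effects})),
        time_point=proto.time_point,
        n_exp=max(e.n_exp for e in effects),
        n_ctl=max(e.n_ctl for e in effects),
        adjusted=any(e.adjusted for e in effects),
        pooled_within_study=True,
    )


# --------------------------------------------------------------------------
# Multi-arm comparisons with shared-control SE adjustment
# --------------------------------------------------------------------------

def smd_covariance(e_k: EffectEstimate, e_l: EffectEstimate, n_shared: int) -> float:
    """Covariance between two SMD comparisons sharing their control arm.

    cov = J_k J_l [ 1/n_shared + d_k d_l / (2 (n_k + n_l + n_shared - 2)) ]

    The leading term is the shared arm's sampling-variance contribution; the
    second is the correction from the jointly estimated pooled SDs, with the
    degrees of freedom taken over all participants entering either
    comparison.  The GLS oracle in the test suite is the binding contract
    for the pooled result; this covariance function is part of that contract
    and is versioned here.
    """
    df_k = e_k.n_exp + e_k.n_ctl - 2
    df_l = e_l.n_exp + e_l.n_ctl - 2
    j_k = 1.0 - 3.0 / (4.0 * df_k - 1.0)
    j_l = 1.0 - 3.0 / (4.0 * df_l - 1.0)
    d_k = e_k.raw_d if e_k.raw_d is not None else e_k.g / j_k
    d_l = e_l.raw_d if e_l.raw_d is not None else e_l.g / j_l
    n_union = e_k.n_exp + e_l.n_exp + n_shared
    return j_k * j_l * (1.0 / n_shared + d_k * d_l / (2.0 * (n_union - 2)))


def comparison_covariance_matrix(
    effects: Sequence[EffectEstimate], n_shared: int
) -> np.ndarray:
    """Full covariance matrix of comparisons sharing one control arm."""
    k = len(effects)
    cov = np.diag([e.var for e in effects])
    for i, j in combinations(range(k), 2):
        cov[i, j] = cov[j, i] = smd_covariance(effects[i], effects[j], n_shared)
    return cov


def adjust_shared_control(
    effects: Sequence[EffectEstimate], n_shared: int
) -> list[EffectEstimate]:
    """Inflate each comparison's SE for the shared control arm.

    The adjusted variances are v*_k = 1 / (Sigma^{-1} 1)_k, so that a naive
    inverse-variance fixed-effect pool of the adjusted comparisons equals
    the GLS estimate under the full covariance matrix Sigma in both point
    estimate and variance.
    """
    cov = comparison_covariance_matrix(effects, n_shared)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-10:
        raise EffectSizeError(
            f"shared-arm covariance matrix not positive semidefinite (min eig {eigvals.min():.3g})"
        )
    w_star = np.linalg.solve(cov, np.ones(len(effects)))
    if np.any(w_star <= 0):
        raise EffectSizeError("adjusted weights not all positive; cannot express GLS as naive pool")
    out = []
    for e, w in zip(effects, w_star):
        adj = e.model_copy(deep=True)
        adj.var = float(1.0 / w)
        adj.adjusted = True
        out.append(adj)
    return out


def _whole_sample_or_combined(
    trial: CodedTrial,
    measure: MeasureSpec,
    exp_cells: list[DataCell],
    ctl_cells: list[DataCell],
    exp_arm_id: str,
    ctl_arm_id: str,
    time_point: str,
) -> EffectEstimate:
    """Effect for one arm pair, combining subgroup-only reporting if needed."""
    by_sub: dict[Optional[str], tuple[Optional[DataCell], Optional[DataCell]]] = {}
    for c in exp_cells:
        by_sub.setdefault(c.subgroup, [None, None])[0] = c
    for c in ctl_cells:
        by_sub.setdefault(c.subgroup, [None, None])[1] = c
    # prefer whole-sample cells when present
    if None in by_sub and all(x is not None for x in by_sub[None]):
        pairs = {None: by_sub[None]}
    else:
        pairs = {s: p for s, p in by_sub.items() if s is not None}
    effects = []
    for sub, (ce, cc) in sorted(pairs.items(), key=lambda kv: str(kv[0])):
        if ce is None or cc is None:
            continue
        if ce.sd is None or cc.sd is None:
            raise EffectSizeError(
                f"{trial.trial_id}: missing sd for measure {measure.measure_id} "
                f"(arms {exp_arm_id}/{ctl_arm_id}, subgroup {sub})"
            )
        effects.append(
            hedges_g(
                ce.mean, ce.sd, ce.n, cc.mean, cc.sd, cc.n,
                direction=measure.direction,
                trial_id=trial.trial_id,
                experimental_arm_id=exp_arm_id,
                control_arm_id=ctl_arm_id,
                measure_id=measure.measure_id,
                time_point=time_point,
            )
        )
    if not effects:
        raise EffectSizeError(
            f"{trial.trial_id}: no complete cell pair for measure {measure.measure_id}"
        )
    if len(effects) == 1:
        return effects[0]
    return combine_subgroups(effects)


def pairwise_comparisons(
    trial: CodedTrial, measure_id: str, time_point: str = "post"
) -> list[EffectEstimate]:
    """All pairwise comparisons for one measure/time point.

    Returns one estimate per (experimental, control) pair and per
    (experimental, experimental) pair.  When two or more
    experimental-vs-control comparisons share the control arm, their SEs
    carry the shared-control adjustment (``adjusted=True``).
    """
    measure = trial.measure(measure_id)
    cells = trial.cells_for(measure_id, time_point)
    cells_by_arm: dict[str, list[DataCell]] = {}
    for c in cells:
        cells_by_arm.setdefault(c.arm_id, []).append(c)

    exp_arms = [a for a in trial.experimental_arms if a.arm_id in cells_by_arm]
    ctl_arms = [a for a in trial.control_arms if a.arm_id in cells_by_arm]
    if len(exp_arms) + len(ctl_arms) < 2:
        return []

    results: list[EffectEstimate] = []
    for ctl in ctl_arms:
        vs_this_control = []
        for exp in exp_arms:
            vs_this_control.append(
                _whole_sample_or_combined(
                    trial, measure,
                    cells_by_arm[exp.arm_id], cells_by_arm[ctl.arm_id],
                    exp.arm_id, ctl.arm_id, time_point,
                )
            )
        if len(vs_this_control) >= 2:
            n_shared = vs_this_control[0].n_ctl
            vs_this_control = adjust_shared_control(vs_this_control, n_shared)
        results.extend(vs_this_control)

    # experimental-vs-experimental contrasts: computed and reported, but the
    # outcome-level pooling against controls never uses them
    for a, b in combinations(exp_arms, 2):
        try:
            ee = _whole_sample_or_combined(
                trial, measure,
                cells_by_arm[a.arm_id], cells_by_arm[b.arm_id],
                a.arm_id, b.arm_id, time_point,
            )
        except EffectSizeError:
            continue
        results.append(ee)
    return results


def study_effect(
    trial: CodedTrial, measure_id: str, time_point: str = "post"
) -> EffectEstimate:
    """One experimental-vs-control effect for a study on one measure.

    Two-arm studies reduce to a single Hedges' g (with subgroup combining if
    the study reported subgroups only); multi-arm studies pool the adjusted
    experimental-vs-control comparisons by fixed-effect meta-analysis.
    """
    comparisons = [
        e for e in pairwise_comparisons(trial, measure_id, time_point)
        if trial.arm(e.control_arm_id).role == "control"
    ]
    if not comparisons:
        raise EffectSizeError(
            f"{trial.trial_id}: no experimental-vs-control comparison "
            f"for measure {measure_id} at {time_point}"
        )
    if len(comparisons) == 1:
        return comparisons[0]
    g, var = fixed_effect_pool(comparisons)
    proto = comparisons[0]
    return EffectEstimate(
        g=g, var=var,
        trial_id=trial.trial_id,
        experimental_arm_id="+".join(e.experimental_arm_id for e in comparisons),
        control_arm_id=proto.control_arm_id,
        measure_id=measure_id,
        time_point=time_point,
        n_exp=sum(e.n_exp for e in comparisons),
        n_ctl=proto.n_ctl,
        adjusted=True,
        pooled_within_study=True,
    )


def effects_to_table(effects: Sequence[EffectEstimate]):
    """Effect estimates as a DataFrame, ready for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "trial_id": e.trial_id,
                "measure_id": e.measure_id,
                "time_point": e.time_point,
                "experimental_arm": e.experimental_arm_id,
                "control_arm": e.control_arm_id,
                "g": e.g,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_exp": e.n_exp,
                "n_ctl": e.n_ctl,
                "adjusted": e.adjusted,
                "pooled_within_study": e.pooled_within_study,
            }
            for e in effects
        ]
    )
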