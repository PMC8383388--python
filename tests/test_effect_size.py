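"""Hedges' g, sign convention, subgroup/correlated combining, multi-arm GLS contract."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cotmeta.effect_size import (
    EffectSizeError,
    combine_correlated,
    combine_subgroups,
    hedges_g,
    pairwise_comparisons,
    study_effect,
)
from cotmeta.trial_model import Arm, Citation, CodedTrial, DataCell

from conftest import IDEAL_CODING, make_measure


class TestHedgesG:
    def test_hand_computed_example(self):
        # d = 1, df = 38, J = 1 - 3/151, g = J*d; var = J^2*(40/400 + 1/76)
        e = hedges_g(1.0, 1.0, 20, 0.0, 1.0, 20)
        j = 1 - 3 / 151
        assert e.g == pytest.approx(j, abs=1e-12)
        assert e.g == pytest.approx(0.9801, abs=5e-5)
        assert e.var == pytest.approx(j**2 * (0.1 + 1 / 76), abs=1e-12)

    def test_zero_difference_gives_zero_and_symmetric_ci(self):
        e = hedges_g(5.0, 2.0, 15, 5.0, 2.0, 25)
        assert e.g == 0.0
        assert e.ci_low == pytest.approx(-e.ci_high)

    def test_lower_better_flips_sign_exactly(self):
        up = hedges_g(1.0, 1.0, 20, 0.0, 1.0, 20, direction="higher_better")
        down = hedges_g(1.0, 1.0, 20, 0.0, 1.0, 20, direction="lower_better")
        assert down.g == -up.g
        assert down.var == up.var

    @settings(max_examples=100, derandomize=True)
    @given(
        mean_e=st.floats(-5, 5), mean_c=st.floats(-5, 5),
        sd_e=st.floats(0.2, 4), sd_c=st.floats(0.2, 4),
        n_e=st.integers(2, 200), n_c=st.integers(2, 200),
    )
    def test_direction_flip_property(self, mean_e, mean_c, sd_e, sd_c, n_e, n_c):
        a = hedges_g(mean_e, sd_e, n_e, mean_c, sd_c, n_c, direction="higher_better")
        b = hedges_g(mean_e, sd_e, n_e, mean_c, sd_c, n_c, direction="lower_better")
        assert b.g == pytest.approx(-a.g, abs=1e-12)
        assert b.var == pytest.approx(a.var, rel=1e-12)

    def test_large_sample_variance_limit(self):
        # as d -> 0 and n -> inf, var(g) -> 1/n_e + 1/n_c
        e = hedges_g(0.0, 1.0, 10_000, 0.0, 1.0, 10_000)
        assert e.var == pytest.approx(2e-4, abs=1e-3)

    @pytest.mark.parametrize(
        "kwargs", [
            dict(mean_e=1, sd_e=1, n_e=1, mean_c=0, sd_c=1, n_c=20),
            dict(mean_e=1, sd_e=0, n_e=20, mean_c=0, sd_c=1, n_c=20),
            dict(mean_e=1, sd_e=1, n_e=20, mean_c=0, sd_c=None, n_c=20),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(EffectSizeError):
            hedges_g(**kwargs)


def _eff(g, var, trial="t", measure="m1", sub=None):
    e = hedges_g(g, 1.0, 1000, 0.0, 1.0, 1000)  # placeholder to get an object
    e = e.model_copy(update={"g": g, "var": var, "trial_id": trial, "measure_id": measure})
    return e


class TestCombineSubgroups:
    def test_equal_subgroups_halve_variance(self):
        out = combine_subgroups([_eff(0.5, 0.1), _eff(0.5, 0.1)])
        assert out.g == pytest.approx(0.5)
        assert out.var == pytest.approx(0.05)
        assert out.pooled_within_study

    def test_symmetric_effects_average(self):
        out = combine_subgroups([_eff(0.2, 0.1), _eff(0.8, 0.1)])
        assert out.g == pytest.approx(0.5)

    def test_inverse_variance_weighting_explicit(self):
        # w = (20, 10): g* = (20*0 + 10*0.6)/30 = 0.2; var* = 1/30
        out = combine_subgroups([_eff(0.0, 0.05), _eff(0.6, 0.10)])
        assert out.g == pytest.approx(0.2, abs=1e-12)
        assert out.var == pytest.approx(1 / 30, abs=1e-12)

    def test_m_identical_effects_scale_variance(self):
        for m in (2, 3, 5):
            out = combine_subgroups([_eff(0.3, 0.12) for _ in range(m)])
            assert out.g == pytest.approx(0.3)
            assert out.var == pytest.approx(0.12 / m)

    def test_mixed_trials_rejected(self):
        with pytest.raises(EffectSizeError):
            combine_subgroups([_eff(0.1, 0.1, trial="a"), _eff(0.2, 0.1, trial="b")])


class TestCombineCorrelated:
    def test_hand_computed_composite(self):
        out = combine_correlated([_eff(0.4, 0.1), _eff(0.6, 0.1)], r=0.5)
        assert out.g == pytest.approx(0.5)
        assert out.var == pytest.approx(0.075)

    def test_independent_limit(self):
        out = combine_correlated([_eff(0.2, 0.08), _eff(0.4, 0.08)], r=0.0)
        assert out.var == pytest.approx(0.04)

    def test_perfect_correlation_limit(self):
        out = combine_correlated([_eff(0.2, 0.08), _eff(0.4, 0.08)], r=0.999999)
        assert out.var == pytest.approx(0.08, rel=1e-5)

    def test_variance_monotone_in_r(self):
        effects = [_eff(0.1, 0.05), _eff(0.5, 0.12), _eff(0.3, 0.07)]
        variances = [combine_correlated(effects, r=r).var for r in (-0.3, 0.0, 0.3, 0.6, 0.9)]
        assert variances == sorted(variances)

    def test_cross_trial_rejected(self):
        with pytest.raises(EffectSizeError):
            combine_correlated([_eff(0.1, 0.1, trial="a"), _eff(0.2, 0.1, trial="b")])


# --------------------------------------------------------------------------
# Multi-arm: fixed-effect pooling of adjusted comparisons == GLS oracle
# --------------------------------------------------------------------------

def _multiarm_trial(trial_id, arms_stats):
    """arms_stats: list of (arm_id, role, n, mean, sd)."""
    return CodedTrial(
        trial_id=trial_id,
        citation=Citation(authors=["A"], year=2020, title=trial_id),
        coding={k: list(v) for k, v in IDEAL_CODING.items()},
        arms=[Arm(arm_id=a, role=r, intervention_label="cognitive_training")
              for a, r, *_ in arms_stats],
        measures=[make_measure()],
        cells=[DataCell(arm_id=a, measure_id="m1", n=n, mean=mu, sd=sd)
               for a, _, n, mu, sd in arms_stats],
    )


def _oracle_smd(mean_e, sd_e, n_e, mean_c, sd_c, n_c):
    """Independent transcription of the SMD formulas for the GLS oracle."""
    df = n_e + n_c - 2
    sp = math.sqrt(((n_e - 1) * sd_e**2 + (n_c - 1) * sd_c**2) / df)
    d = (mean_e - mean_c) / sp
    j = 1 - 3 / (4 * df - 1)
    return d, j, j * d, j * j * ((n_e + n_c) / (n_e * n_c) + d * d / (2 * df))


def _oracle_gls(arms_stats):
    """Direct GLS solve under the documented shared-control covariance."""
    ctl = next(a for a in arms_stats if a[1] == "control")
    exps = [a for a in arms_stats if a[1] == "experimental"]
    _, _, n_c, mean_c, sd_c = ctl
    comps = [_oracle_smd(mu, sd, n, mean_c, sd_c, n_c) for _, _, n, mu, sd in exps]
    kk = len(comps)
    y = np.array([c[2] for c in comps])
    cov = np.diag([c[3] for c in comps])
    for i in range(kk):
        for jx in range(i + 1, kk):
            d_i, j_i, *_ = comps[i]
            d_j, j_j, *_ = comps[jx]
            n_union = exps[i][2] + exps[jx][2] + n_c
            cov[i, jx] = cov[jx, i] = j_i * j_j * (
                1 / n_c + d_i * d_j / (2 * (n_union - 2))
            )
        sigma_inv_1 = np.linalg.solve(cov, np.ones(kk))
    mu = float(sigma_inv_1 @ y / sigma_inv_1.sum())
    return mu, float(1.0 / sigma_inv_1.sum())


class TestMultiArm:
    def test_two_arm_reduces_to_plain_hedges(self):
        trial = _multiarm_trial("t", [("ctl", "control", 25, 0.1, 1.1),
                                      ("e1", "experimental", 30, 0.7, 0.9)])
        comps = pairwise_comparisons(trial, "m1")
        assert len(comps) == 1
        assert not comps[0].adjusted
        ref = hedges_g(0.7, 0.9, 30, 0.1, 1.1, 25)
        assert comps[0].g == pytest.approx(ref.g)
        assert comps[0].var == pytest.approx(ref.var)

    def test_identical_arms_give_zero_everywhere(self):
        trial = _multiarm_trial("t", [("ctl", "control", 30, 1.0, 1.0),
                                      ("e1", "experimental", 30, 1.0, 1.0),
                                      ("e2", "experimental", 30, 1.0, 1.0)])
        pooled = study_effect(trial, "m1")
        assert pooled.g == pytest.approx(0.0, abs=1e-12)
        assert pooled.adjusted and pooled.pooled_within_study

    def test_exp_vs_exp_reported_but_not_pooled(self):
        trial = _multiarm_trial("t", [("ctl", "control", 30, 0.0, 1.0),
                                      ("e1", "experimental", 30, 0.5, 1.0),
                                      ("e2", "experimental", 30, 0.9, 1.0)])
        comps = pairwise_comparisons(trial, "m1")
        assert len(comps) == 3  # e1-ctl, e2-ctl, e1-e2
        pooled = study_effect(trial, "m1")
        assert pooled.n_ctl == 30  # control counted once

    def test_pooled_adjusted_comparisons_match_gls_oracle(self):
        """200 random 3-4 arm trials: point estimate and variance vs GLS, 1e-8."""
        rng = np.random.default_rng(20240917)
        for _ in range(200):
            n_exp_arms = int(rng.integers(2, 4))
            stats = [("ctl", "control", int(rng.integers(10, 60)),
                      float(rng.normal(0, 1)), float(rng.uniform(0.5, 2.0)))]
            for i in range(n_exp_arms):
                stats.append((f"e{i}", "experimental", int(rng.integers(10, 60)),
                              float(rng.normal(0.4, 0.5)), float(rng.uniform(0.5, 2.0))))
            trial = _multiarm_trial("t", stats)
            pooled = study_effect(trial, "m1")
            mu, var = _oracle_gls(stats)
            assert pooled.g == pytest.approx(mu, abs=1e-8)
            assert pooled.var == pytest.approx(var, abs=1e-8)

    def test_too_few_arms_with_data_yields_empty(self):
        trial = _multiarm_trial("t", [("ctl", "control", 25, 0.1, 1.1),
                                      ("e1", "experimental", 30, 0.7, 0.9)])
        trial.cells = trial.cells[:1]
        assert pairwise_comparisons(trial, "m1") == []
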