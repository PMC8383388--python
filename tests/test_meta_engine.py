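"""REML, HKSJ, heterogeneity, prediction intervals, eligibility, full pipeline."""

import math
import subprocess

import numpy as np
import pytest
from scipy import stats

from cotmeta.meta_engine import (
    MetaAnalysisError,
    MetaAnalysisSpec,
    eligible_groups,
    heterogeneity,
    pool_hksj,
    prediction_interval,
    reml_tau2,
    run_meta,
)

from conftest import two_arm_trial


def grid_reml(y, v, upper=2.0, n_grid=100_000):
    """Two-stage grid-search oracle for the restricted log-likelihood argmax."""
    y = np.asarray(y)
    v = np.asarray(v)

    def ll(tau2):
        w = 1.0 / (v[None, :] + tau2[:, None])
        mu = (w * y).sum(axis=1) / w.sum(axis=1)
        return -0.5 * (
            np.log(v[None, :] + tau2[:, None]).sum(axis=1)
            + np.log(w.sum(axis=1))
            + (w * (y[None, :] - mu[:, None]) ** 2).sum(axis=1)
        )

    grid = np.linspace(0.0, upper, n_grid)
    coarse = grid[np.argmax(ll(grid))]
    step = upper / (n_grid - 1)
    fine = np.linspace(max(0.0, coarse - step), coarse + step, n_grid)
    return float(fine[np.argmax(ll(fine))]), float(coarse)


class TestREML:
    def test_identical_effects_give_zero(self):
        assert reml_tau2([0.4, 0.4, 0.4, 0.4], [0.05, 0.02, 0.08, 0.05]) == 0.0

    def test_grid_oracle_on_spread_fixture(self):
        y, v = [0.1, 0.5, 0.9], [0.04, 0.04, 0.04]
        fine, coarse = grid_reml(y, v)
        t2 = reml_tau2(y, v)
        assert t2 == pytest.approx(fine, abs=1e-6)
        assert t2 == pytest.approx(coarse, abs=2e-5)

    def test_duplicating_studies_tracks_grid_oracle(self):
        y, v = [0.1, 0.5, 0.9], [0.04, 0.04, 0.04]
        t2_dup = reml_tau2(y * 2, v * 2)
        fine, _ = grid_reml(y * 2, v * 2)
        assert t2_dup == pytest.approx(fine, abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(MetaAnalysisError):
            reml_tau2([0.1], [0.05])
        with pytest.raises(MetaAnalysisError):
            reml_tau2([0.1, 0.2], [0.05, -0.01])

    def test_matches_metafor_reml_and_knha(self):
        """Independent R oracle: rma(method='REML', test='knha')."""
        rng = np.random.default_rng(11)
        y = rng.normal(0.3, 0.4, 8)
        v = rng.uniform(0.02, 0.12, 8)
        r_code = (
            "suppressMessages(library(metafor));"
            f"y <- c({','.join(f'{float(x):.17g}' for x in y)});"
            f"v <- c({','.join(f'{float(x):.17g}' for x in v)});"
            "fit <- rma(yi=y, vi=v, method='REML', test='knha');"
            "cat(sprintf('%.12f %.12f %.12f %.12f %.12f', fit$tau2, fit$beta, fit$se, fit$ci.lb, fit$ci.ub))"
        )
        proc = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        tau2_r, mu_r, se_r, lo_r, hi_r = map(float, proc.stdout.split())
        tau2 = reml_tau2(y, v)
        mu, se, lo, hi = pool_hksj(y, v, tau2)
        assert tau2 == pytest.approx(tau2_r, abs=1e-6)
        assert mu == pytest.approx(mu_r, abs=1e-8)
        assert se == pytest.approx(se_r, abs=1e-8)
        assert (lo, hi) == pytest.approx((lo_r, hi_r), abs=1e-7)


class TestHKSJ:
    def test_zero_dispersion_degenerates(self):
        mu, se, lo, hi = pool_hksj([0.3, 0.3, 0.3], [0.05, 0.1, 0.02], tau2=0.0)
        assert mu == pytest.approx(0.3)
        assert se == 0.0
        assert lo == hi == pytest.approx(0.3)

    def test_symmetric_inputs_center(self):
        mu, *_ = pool_hksj([0.2, 0.5, 0.8], [0.04, 0.04, 0.04], tau2=0.01)
        assert mu == pytest.approx(0.5)

    def test_formula_transcription_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.4, 0.3, 5)
        v = rng.uniform(0.03, 0.09, 5)
        tau2 = 0.02
        w = 1 / (v + tau2)
        mu_o = np.sum(w * y) / np.sum(w)
        se_o = math.sqrt(np.sum(w * (y - mu_o) ** 2) / 4 / np.sum(w))
        t = stats.t.ppf(0.975, 4)
        mu, se, lo, hi = pool_hksj(y, v, tau2)
        assert mu == pytest.approx(mu_o, abs=1e-8)
        assert se == pytest.approx(se_o, abs=1e-8)
        assert lo == pytest.approx(mu_o - t * se_o, abs=1e-8)
        assert hi == pytest.approx(mu_o + t * se_o, abs=1e-8)

    def test_ci_narrows_with_k_at_fixed_dispersion(self):
        rng = np.random.default_rng(3)
        widths = []
        for k in (3, 6, 12, 24):
            y = np.tile([0.2, 0.6], k // 2 + 1)[:k] + rng.normal(0, 1e-9, k)
            v = np.full(k, 0.05)
            _, _, lo, hi = pool_hksj(y, v, tau2=0.0)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestHeterogeneity:
    def test_hand_derived_fixture(self):
        q, p_q, i2 = heterogeneity([0.1, 0.5, 0.9], [0.04, 0.04, 0.04])
        assert q == pytest.approx(8.0, abs=1e-12)
        assert i2 == pytest.approx(75.0, abs=1e-10)
        assert p_q == pytest.approx(stats.chi2.sf(8.0, 2), abs=1e-12)

    def test_no_heterogeneity(self):
        q, p_q, i2 = heterogeneity([0.4, 0.4], [0.05, 0.07])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0
        assert p_q == pytest.approx(1.0)

    def test_i2_zero_at_q_equal_df_boundary(self):
        # Q = k-1 = 1 exactly: y gap chosen so sum w (y - ybar)^2 = 1
        # equal v=0.08, k=2: Q = (y1-y2)^2/(2v) -> gap = sqrt(2*0.08)
        gap = math.sqrt(0.16)
        q, _, i2 = heterogeneity([0.0, gap], [0.08, 0.08])
        assert q == pytest.approx(1.0, abs=1e-12)
        assert i2 == pytest.approx(0.0, abs=1e-9)

    def test_i2_invariant_to_common_rescaling(self):
        y = np.array([0.1, 0.4, 0.9, 0.3])
        v = np.array([0.03, 0.06, 0.02, 0.08])
        _, _, i2 = heterogeneity(y, v)
        for c in (0.1, 2.0, 17.0):
            _, _, i2_scaled = heterogeneity(c * y, c**2 * v)
            assert i2_scaled == pytest.approx(i2, abs=1e-9)


class TestPredictionInterval:
    def test_tau2_zero_limit(self):
        lo, hi = prediction_interval(0.3, 0.05, 0.0, k=10)
        t = stats.t.ppf(0.975, 8)
        assert (lo, hi) == pytest.approx((0.3 - t * 0.05, 0.3 + t * 0.05), abs=1e-12)

    def test_transcription_oracle_k10(self):
        lo, hi = prediction_interval(0.3, 0.05, 0.04, k=10)
        half = stats.t.ppf(0.975, 8) * math.sqrt(0.04 + 0.05**2)
        assert (lo, hi) == pytest.approx((0.3 - half, 0.3 + half), abs=1e-8)

    def test_width_monotone_in_tau2(self):
        widths = [
            prediction_interval(0.3, 0.05, t2, k=8)[1]
            - prediction_interval(0.3, 0.05, t2, k=8)[0]
            for t2 in (0.0, 0.05, 0.2, 1.0, 10.0)
        ]
        assert widths == sorted(widths)

    def test_k_below_three_rejected(self):
        with pytest.raises(MetaAnalysisError):
            prediction_interval(0.3, 0.05, 0.04, k=2)

    def test_alternative_df_convention(self):
        lo1, _ = prediction_interval(0.0, 0.1, 0.1, k=5, df_convention="k-1")
        lo2, _ = prediction_interval(0.0, 0.1, 0.1, k=5, df_convention="k-2")
        assert lo1 > lo2  # k-1 df gives the narrower interval


def _toy_repo():
    trials = [
        two_arm_trial("s1", mean_e=0.5),
        two_arm_trial("s2", mean_e=0.3),
        two_arm_trial("s3", mean_e=0.7),
        two_arm_trial("s4", mean_e=0.6, sd_e=None, sd_c=None),  # SDs not reported
        two_arm_trial("s5", mean_e=0.4, domain="delayed_recall"),
        two_arm_trial("s6", mean_e=0.2, domain="delayed_recall"),
    ]
    return trials


class TestEligibility:
    def test_missing_sd_study_excluded_and_logged(self):
        groups, exclusions = eligible_groups(_toy_repo(), MetaAnalysisSpec())
        key = ("global_cognition", "mild_cognitive_impairment")
        assert key in groups
        assert len(groups[key]) == 3
        assert {e.trial_id for e in groups[key]} == {"s1", "s2", "s3"}
        missing = [e for e in exclusions if e.trial_id == "s4"]
        assert missing and "missing means or standard deviations" in missing[0].reason

    def test_under_min_k_outcome_dropped_with_reason(self):
        groups, exclusions = eligible_groups(_toy_repo(), MetaAnalysisSpec())
        assert not any(k[0] == "delayed_recall" for k in groups)
        dropped = [e for e in exclusions if e.outcome == "delayed_recall"]
        assert dropped and "fewer than 3 studies" in dropped[0].reason

    def test_population_with_no_studies_gives_empty_map(self):
        groups, _ = eligible_groups(
            _toy_repo(), MetaAnalysisSpec(populations=["dementia"])
        )
        assert groups == {}

    def test_empty_scope_is_an_error(self):
        with pytest.raises(MetaAnalysisError, match="no outcomes selected"):
            eligible_groups([], MetaAnalysisSpec())

    def test_spec_parameter_validation(self):
        with pytest.raises(ValueError):
            MetaAnalysisSpec(min_k=1)
        with pytest.raises(ValueError):
            MetaAnalysisSpec(alpha_q=1.5)


class TestRunMeta:
    def test_single_group_bookkeeping(self):
        results, _ = run_meta(_toy_repo())
        assert len(results) == 1
        r = results[0]
        assert (r.outcome, r.population) == ("global_cognition", "mild_cognitive_impairment")
        assert r.k == 3 and len(r.per_study) == 3
        assert r.n_total == 3 * 40
        assert sum(w for _, w in r.per_study) == pytest.approx(1.0)

    def test_pi_contains_ci_when_tau2_positive(self):
        trials = [
            two_arm_trial(f"s{i}", mean_e=m, n_e=60, n_c=60)
            for i, m in enumerate([0.0, 0.3, 0.9, 1.4, -0.2])
        ]
        results, _ = run_meta(trials)
        r = results[0]
        assert r.tau2 > 0
        assert r.pi_low < r.ci_low and r.pi_high > r.ci_high

    def test_all_groups_below_min_k_gives_empty_list(self):
        trials = [two_arm_trial("a"), two_arm_trial("b")]
        results, exclusions = run_meta(trials)
        assert results == []
        assert any("fewer than 3" in e.reason for e in exclusions)
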