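"""Shared fixtures: hand-built coded trials and codings used across the suite."""

from __future__ import annotations

import pytest

from cotmeta.trial_model import (
    Arm,
    Citation,
    CodedTrial,
    DataCell,
    MeasureSpec,
)

# Coding of an exemplary double-blind RCT: every quality predicate satisfied.
IDEAL_CODING: dict[str, list[str]] = {
    "design": ["rct"],
    "setting": ["community"],
    "population": ["mild_cognitive_impairment"],
    "intervention_type": ["cognitive_training"],
    "control_type": ["active_control"],
    "target": ["participant"],
    "eligibility_criteria": ["specified"],
    "randomization": ["computer_generated"],
    "allocation_concealment": ["central_allocation"],
    "baseline_comparability": ["comparable"],
    "participant_blinding": ["blinded"],
    "therapist_blinding": ["blinded"],
    "assessor_blinding": ["blinded"],
    "retention": ["over_85_percent"],
    "intention_to_treat": ["itt"],
    "between_group_stats": ["reported"],
    "point_and_variability": ["reported"],
    "double_blind_description": ["described_double_blind"],
    "withdrawals_described": ["described"],
    "incomplete_outcome_data": ["addressed"],
    "selective_reporting": ["protocol_outcomes_reported"],
    "other_bias": ["none_apparent"],
}


def make_measure(measure_id="m1", domain="global_cognition", direction="higher_better",
                 target="participant"):
    return MeasureSpec(
        measure_id=measure_id,
        name=f"measure {measure_id}",
        broad_domain=domain,
        target=target,
        direction=direction,
    )


def two_arm_trial(
    trial_id: str,
    mean_e: float = 1.0, sd_e: float | None = 1.0, n_e: int = 20,
    mean_c: float = 0.0, sd_c: float | None = 1.0, n_c: int = 20,
    domain: str = "global_cognition",
    direction: str = "higher_better",
    population: str = "mild_cognitive_impairment",
    coding: dict | None = None,
) -> CodedTrial:
    """Minimal complete two-arm trial with one measure and one time point."""
    full_coding = {k: list(v) for k, v in (coding or IDEAL_CODING).items()}
    full_coding["population"] = [population]
    return CodedTrial(
        trial_id=trial_id,
        citation=Citation(
            authors=[f"Investigator {trial_id}"], year=2020,
            title=f"Trial {trial_id}", journal="J Trials",
        ),
        coding=full_coding,
        arms=[
            Arm(arm_id="exp", role="experimental", intervention_label="cognitive_training"),
            Arm(arm_id="ctl", role="control", intervention_label="active_control"),
        ],
        measures=[make_measure(domain=domain, direction=direction)],
        cells=[
            DataCell(arm_id="exp", measure_id="m1", n=n_e, mean=mean_e, sd=sd_e),
            DataCell(arm_id="ctl", measure_id="m1", n=n_c, mean=mean_c, sd=sd_c),
        ],
    )


@pytest.fixture
def ideal_coding():
    return {k: list(v) for k, v in IDEAL_CODING.items()}


@pytest.fixture
def complete_trial():
    return two_arm_trial("t001")
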