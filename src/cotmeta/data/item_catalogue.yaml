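# Coding-item catalogue for controlled trials of cognition-oriented treatments.
#
# Each entry defines one data-extraction item: the controlled vocabulary a
# coder may choose from, whether more than one code may be selected, and
# whether the item must be present before a trial's coding can be considered
# complete.  The catalogue is data, not code: administrators extend or amend
# items here without touching the library.
schema_version: 1
items:
  design:
    required: true
    multi: false
    codes: [rct, cluster_rct, crossover, quasi_experimental, non_randomized_controlled]
  setting:
    required: true
    multi: true
    codes: [community, residential_care, outpatient_clinic, home, remote_delivery]
  population:
    required: true
    multi: true
    codes: [healthy_older_adults, subjective_cognitive_decline, mild_cognitive_impairment,
            dementia, mixed_population]
  intervention_type:
    required: true
    multi: true
    codes: [cognitive_training, cognitive_stimulation, cognitive_rehabilitation,
            combined_cognitive, brain_training_commercial]
  control_type:
    required: true
    multi: false
    codes: [active_control, passive_control, waitlist, treatment_as_usual]
  target:
    required: true
    multi: true
    codes: [participant, caregiver, clinician]
  delivery_format:
    required: false
    multi: true
    codes: [individual, group, computerized, paper_based, telehealth]
  statistical_analyses:
    required: false
    multi: true
    codes: [ancova, anova, mixed_models, t_tests, nonparametric, regression, other]
  # --- methodological items feeding the quality indices -------------------
  eligibility_criteria:
    required: true
    multi: false
    codes: [specified, not_specified]
  randomization:
    required: true
    multi: false
    codes: [computer_generated, random_number_table, coin_toss,
            randomized_method_not_described, not_randomized, not_reported]
  allocation_concealment:
    required: true
    multi: false
    codes: [central_allocation, sealed_opaque_envelopes, not_concealed, not_reported]
  baseline_comparability:
    required: true
    multi: false
    codes: [comparable, not_comparable, not_reported]
  participant_blinding:
    required: true
    multi: false
    codes: [blinded, not_blinded, not_reported]
  therapist_blinding:
    required: true
    multi: false
    codes: [blinded, not_blinded, not_reported]
  assessor_blinding:
    required: true
    multi: false
    codes: [blinded, not_blinded, not_reported]
  retention:
    required: true
    multi: false
    codes: [over_85_percent, under_85_percent, not_reported]
  intention_to_treat:
    required: true
    multi: false
    codes: [itt, per_protocol, not_reported]
  between_group_stats:
    required: true
    multi: false
    codes: [reported, not_reported]
  point_and_variability:
    required: true
    multi: false
    codes: [reported, not_reported]
  double_blind_description:
    required: false
    multi: false
    codes: [described_double_blind, not_described]
  withdrawals_described:
    required: true
    multi: false
    codes: [described, not_described]
  incomplete_outcome_data:
    required: false
    multi: false
    codes: [addressed, not_addressed, not_reported]
  selective_reporting:
    required: false
    multi: false
    codes: [protocol_outcomes_reported, outcomes_missing, not_reported]
  other_bias:
    required: false
    multi: false
    codes: [none_apparent, present, not_reported]
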