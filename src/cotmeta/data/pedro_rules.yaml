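# PEDro scale rules: 11 items, items 2-11 scored (item 1 recorded but not
# counted in the 0-10 total).  Each predicate is evaluated over the coded
# items; a missing coding item makes the predicate false, so unscorable
# items default to "not satisfied".
index: pedro
items:
  - key: eligibility_specified
    scored: false
    predicate: {item: eligibility_criteria, any_of: [specified]}
  - key: random_allocation
    scored: true
    predicate:
      item: randomization
      any_of: [computer_generated, random_number_table, coin_toss,
               randomized_method_not_described]
  - key: concealed_allocation
    scored: true
    predicate: {item: allocation_concealment, any_of: [central_allocation, sealed_opaque_envelopes]}
  - key: baseline_comparability
    scored: true
    predicate: {item: baseline_comparability, any_of: [comparable]}
  - key: participant_blinding
    scored: true
    predicate: {item: participant_blinding, any_of: [blinded]}
  - key: therapist_blinding
    scored: true
    predicate: {item: therapist_blinding, any_of: [blinded]}
  - key: assessor_blinding
    scored: true
    predicate: {item: assessor_blinding, any_of: [blinded]}
  - key: adequate_followup
    scored: true
    predicate: {item: retention, any_of: [over_85_percent]}
  - key: intention_to_treat
    scored: true
    predicate: {item: intention_to_treat, any_of: [itt]}
  - key: between_group_comparison
    scored: true
    predicate: {item: between_group_stats, any_of: [reported]}
  - key: point_and_variability
    scored: true
    predicate: {item: point_and_variability, any_of: [reported]}
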