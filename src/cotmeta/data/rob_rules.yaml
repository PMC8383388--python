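# Cochrane Risk of Bias (first version) domain rules.  For each domain a
# low-risk predicate and a high-risk predicate are evaluated over the coded
# items; when neither fires the domain is rated "unclear".
index: rob
domains:
  sequence_generation:
    low: {item: randomization, any_of: [computer_generated, random_number_table, coin_toss]}
    high: {item: randomization, any_of: [not_randomized]}
  allocation_concealment:
    low: {item: allocation_concealment, any_of: [central_allocation, sealed_opaque_envelopes]}
    high: {item: allocation_concealment, any_of: [not_concealed]}
  blinding_participants_personnel:
    low:
      all:
        - {item: participant_blinding, any_of: [blinded]}
        - {item: therapist_blinding, any_of: [blinded]}
    high:
      any:
        - {item: participant_blinding, any_of: [not_blinded]}
        - {item: therapist_blinding, any_of: [not_blinded]}
  blinding_outcome_assessment:
    low: {item: assessor_blinding, any_of: [blinded]}
    high: {item: assessor_blinding, any_of: [not_blinded]}
  incomplete_outcome_data:
    low: {item: incomplete_outcome_data, any_of: [addressed]}
    high: {item: incomplete_outcome_data, any_of: [not_addressed]}
  selective_reporting:
    low: {item: selective_reporting, any_of: [protocol_outcomes_reported]}
    high: {item: selective_reporting, any_of: [outcomes_missing]}
  other:
    low: {item: other_bias, any_of: [none_apparent]}
    high: {item: other_bias, any_of: [present]}
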