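# Jadad rules (additive 5-point form): one point each for randomization
# mentioned, randomization method appropriate, blinding described as double
# blind, blinding appropriate, and withdrawals/dropouts described.
index: jadad
items:
  - key: randomization_mentioned
    scored: true
    predicate:
      item: randomization
      any_of: [computer_generated, random_number_table, coin_toss,
               randomized_method_not_described]
  - key: randomization_appropriate
    scored: true
    predicate: {item: randomization, any_of: [computer_generated, random_number_table, coin_toss]}
  - key: double_blind_described
    scored: true
    predicate: {item: double_blind_description, any_of: [described_double_blind]}
  - key: blinding_appropriate
    scored: true
    predicate:
      all:
        - {item: double_blind_description, any_of: [described_double_blind]}
        - {item: participant_blinding, any_of: [blinded]}
        - {item: assessor_blinding, any_of: [blinded]}
  - key: withdrawals_described
    scored: true
    predicate: {item: withdrawals_described, any_of: [described]}
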