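# Editable boilerplate and sentence templates used by the report builder.
overview: >
  Cognition-oriented treatments (COTs) are non-pharmacological interventions
  — cognitive training, cognitive stimulation, and cognitive rehabilitation —
  aimed at maintaining or improving cognitive and everyday function in older
  adults across the continuum from unimpaired cognition to dementia.  This
  report synthesizes the controlled-trial evidence available in the
  repository for the outcomes and populations selected below.
disclaimer: >
  The trial repository behind this report is under active development and
  studies are entered and verified on an ongoing basis.  Results are based on
  the trials currently coded and should be interpreted with caution; they may
  change as further studies are added.
interpretation_sentence: >-
  The treatment effect found suggests that {u3}% of the treatment group will
  be above the mean of the control group, {overlap}% of the two groups will
  overlap, and there is a {prob_superiority}% chance that a person randomly
  picked from the treatment group will have a higher score than a person
  randomly picked from the control group.
no_results_notice: >-
  No outcome met the eligibility criteria for pooling (at least {min_k}
  studies with usable means and standard deviations); no meta-analysis was
  performed.
statistical_information: >
  Pooled effects are standardized mean differences (Hedges' g) combined under
  a random-effects model.  Between-study variance (tau-squared) is estimated
  by restricted maximum likelihood; confidence intervals use the
  Hartung-Knapp-Sidik-Jonkman variance estimator with t(k-1) quantiles.
  Heterogeneity is tested with Cochran's Q (p < 0.10 flagged as significant)
  and quantified with I-squared; 95% prediction intervals describe the range
  in which the true effect of a comparable new study is expected to fall.
  Related outcomes measured on the same participants are combined within a
  study assuming a between-measure correlation of r = 0.50 unless specified
  otherwise.
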