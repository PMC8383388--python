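# Certainty-grading thresholds.  Each of the three components (mean
# methodological quality, heterogeneity, precision) is banded as
# favorable / intermediate / unfavorable; the overall level is then
#   high     <- all three favorable
#   low      <- quality unfavorable, or >= 2 components unfavorable
#   moderate <- anything else
# All cut-offs are data so they can be recalibrated without code changes.
quality_index: pedro          # which scale feeds "mean methodological quality"
quality_bands:                # mean PEDro total
  favorable_min: 7.0
  intermediate_min: 4.0
heterogeneity_bands:          # I^2, percent
  favorable_max: 30.0
  intermediate_max: 60.0
precision_bands:              # total participants across contributing studies
  favorable_min: 400
  intermediate_min: 100
magnitude_bands:              # |g| cut points for narrative wording
  trivial_max: 0.2
  small_max: 0.5
  moderate_max: 0.8
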