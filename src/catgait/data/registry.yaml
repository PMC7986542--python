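# Canonical CatWalk parameter registry.
#
# Each entry maps one canonical parameter to its export aliases in the two
# CatWalk run-statistics header dialects ("xt" and "7.1").  For per-paw and
# all-paw parameters the alias carries a "{PAW}" placeholder expanded to
# RF/LF/RH/LH, and the canonical key gains a lower-case paw suffix
# (e.g. stand_time_rf).  scope:
#   per_paw  - one value per paw, left/right-averaged into forepaw_*/hindpaw_*
#   all_paw  - one value per paw, averaged over all four (body speed)
#   run      - one value per run, passed through
#   support  - Support_* time percentages, combined into support_number
# intensity: true marks green-pixel-intensity parameters, excluded from the
# candidate set (too sensitive to walkway moisture / experimental setting).
parameters:
  - canonical: stand_time
    unit: s
    scope: per_paw
    aliases: {xt: "{PAW}_Stand_Mean", "7.1": "Stand_{PAW}"}
  - canonical: swing_time
    unit: s
    scope: per_paw
    aliases: {xt: "{PAW}_Swing_Mean", "7.1": "Swing_{PAW}"}
  - canonical: step_cycle
    unit: s
    scope: per_paw
    aliases: {xt: "{PAW}_StepCycle_Mean", "7.1": "StepCycle_{PAW}"}
  - canonical: stride_length
    unit: cm
    scope: per_paw
    aliases: {xt: "{PAW}_StrideLength_Mean", "7.1": "StrideLength_{PAW}"}
  - canonical: swing_speed
    unit: cm/s
    scope: per_paw
    aliases: {xt: "{PAW}_SwingSpeed_Mean", "7.1": "SwingSpeed_{PAW}"}
  - canonical: duty_cycle
    unit: "%"
    scope: per_paw
    aliases: {xt: "{PAW}_DutyCycle_Mean", "7.1": "DutyCycle_{PAW}"}
  - canonical: max_contact_at
    unit: "%"
    scope: per_paw
    aliases: {xt: "{PAW}_MaxContactAt_Mean", "7.1": "MaxContactAt_{PAW}"}
  - canonical: body_speed
    unit: cm/s
    scope: all_paw
    aliases: {xt: "{PAW}_BodySpeed_Mean", "7.1": "BodySpeed_{PAW}"}
  - canonical: mean_intensity
    unit: px
    scope: per_paw
    intensity: true
    aliases: {xt: "{PAW}_MeanIntensity_Mean", "7.1": "MeanIntensity_{PAW}"}
  - canonical: max_intensity
    unit: px
    scope: per_paw
    intensity: true
    aliases: {xt: "{PAW}_MaxIntensity_Mean", "7.1": "MaxIntensity_{PAW}"}
  - canonical: regularity_index
    unit: "%"
    scope: run
    aliases: {xt: "RegularityIndex_Mean", "7.1": "RI"}
  - canonical: ab_sequence
    unit: "%"
    scope: run
    aliases: {xt: "StepSequence_AB", "7.1": "Sequence_AB"}
  - canonical: forepaw_bos
    unit: cm
    scope: run
    aliases: {xt: "BOS_FrontPaws_Mean", "7.1": "BOS_Front"}
  - canonical: hindpaw_bos
    unit: cm
    scope: run
    aliases: {xt: "BOS_HindPaws_Mean", "7.1": "BOS_Hind"}
  - canonical: print_position_right
    unit: cm
    scope: run
    aliases: {xt: "PrintPositions_RightPaws_Mean", "7.1": "PrintPosition_Right"}
  - canonical: print_position_left
    unit: cm
    scope: run
    aliases: {xt: "PrintPositions_LeftPaws_Mean", "7.1": "PrintPosition_Left"}
  - canonical: support_pct_zero
    unit: "%"
    scope: support
    aliases: {xt: "Support_Zero", "7.1": "Support_Zero"}
  - canonical: support_pct_one
    unit: "%"
    scope: support
    aliases: {xt: "Support_Single", "7.1": "Support_One"}
  - canonical: support_pct_diagonal
    unit: "%"
    scope: support
    aliases: {xt: "Support_Diagonal", "7.1": "Support_Diagonal"}
  - canonical: support_pct_girdle
    unit: "%"
    scope: support
    aliases: {xt: "Support_Girdle", "7.1": "Support_Girdle"}
  - canonical: support_pct_lateral
    unit: "%"
    scope: support
    aliases: {xt: "Support_Lateral", "7.1": "Support_Lateral"}
  - canonical: support_pct_three
    unit: "%"
    scope: support
    aliases: {xt: "Support_Three", "7.1": "Support_Three"}
  - canonical: support_pct_four
    unit: "%"
    scope: support
    aliases: {xt: "Support_Four", "7.1": "Support_Four"}
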