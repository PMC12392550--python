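# Provisional category -> behavior mapping for the eleven-category time-use
# diary. The app's authoritative intensity/posture classification is published
# separately; this file implements the uncontroversial assignments and serves
# as a documented stand-in. Override any rule by supplying your own file with
# the same schema. A rule without a qualifier applies to every qualifier of
# that category unless a more specific rule matches first.
rules:
  - {category: "sleeping", behavior: SLEEP}
  - {category: "playing", behavior: PA}                    # default: active
  - {category: "playing", qualifier: "active", behavior: PA}
  - {category: "playing", qualifier: "calm", behavior: SB}
  - {category: "active transport", behavior: PA}
  - {category: "passive transport", behavior: SB}
  - {category: "screen use", behavior: SB}
  - {category: "sitting/lying calmly", behavior: SB}
  - {category: "eating/drinking", behavior: SB}
  - {category: "personal care", behavior: SB}
  # 'other activity', 'I don't know', 'my child was with someone else' are
  # forced to EXCLUDED by the loader; listed here for completeness.
  - {category: "other activity", behavior: EXCLUDED}
  - {category: "I don't know", behavior: EXCLUDED}
  - {category: "my child was with someone else", behavior: EXCLUDED}
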