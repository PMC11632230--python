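# Default 40-item health-deficit catalogue for a self-report frailty index.
#
# The item set covers chronic diseases, basic/instrumental/mobility-related
# activities of daily living, somatic symptoms, negative affect, sensory
# impairment, physical inactivity, self-rated health and cognition.  Names are
# descriptive defaults and user-overridable; category-to-score mappings for
# the ordinal items are declared assumptions (levels on the unit interval).
#
# volatility drives the synthetic generator's wave-to-wave re-drawing:
#   none  -> chronic, persists within person across waves
#   low   -> occasionally switching
#   high  -> frequently switching (mobility/instrumental ADL, cognition, ...)
deficits:
  - {name: heart_disease,       levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: lung_disease,        levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: diabetes,            levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: osteoarthritis,      levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: dementia,            levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: hypotension,         levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: stroke,              levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: cancer,              levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: renal_disease,       levels: [0, 1],                  group: chronic_disease, volatility: none}
  - {name: dressing,            levels: [0, 1],                  group: adl,             volatility: high}
  - {name: bathing,             levels: [0, 1],                  group: adl,             volatility: low}
  - {name: eating,              levels: [0, 1],                  group: adl,             volatility: low}
  - {name: toileting,           levels: [0, 1],                  group: adl,             volatility: low}
  - {name: transferring,        levels: [0, 1],                  group: adl,             volatility: low}
  - {name: shopping,            levels: [0, 1],                  group: iadl,            volatility: high}
  - {name: cooking,             levels: [0, 1],                  group: iadl,            volatility: low}
  - {name: housework,           levels: [0, 1],                  group: iadl,            volatility: low}
  - {name: managing_money,      levels: [0, 1],                  group: iadl,            volatility: low}
  - {name: taking_medication,   levels: [0, 1],                  group: iadl,            volatility: low}
  - {name: walking_100m,        levels: [0, 1],                  group: mobility,        volatility: high}
  - {name: climbing_stairs,     levels: [0, 1],                  group: mobility,        volatility: high}
  - {name: carrying_5kg,        levels: [0, 1],                  group: mobility,        volatility: high}
  - {name: physical_inactivity, levels: [0, 1],                  group: mobility,        volatility: high}
  - {name: memory,              levels: [0, 1],                  group: cognition,       volatility: high}
  - {name: attention,           levels: [0, 1],                  group: cognition,       volatility: high}
  - {name: dizziness,           levels: [0, 1],                  group: somatic,         volatility: high}
  - {name: pain,                levels: [0, 0.5, 1],             group: somatic,         volatility: low}
  - {name: breathlessness,      levels: [0, 0.5, 1],             group: somatic,         volatility: low}
  - {name: tiredness,           levels: [0, 0.5, 1],             group: somatic,         volatility: low}
  - {name: sleep_problems,      levels: [0, 0.5, 1],             group: somatic,         volatility: low}
  - {name: incontinence,        levels: [0, 1],                  group: somatic,         volatility: low}
  - {name: weight_loss,         levels: [0, 1],                  group: somatic,         volatility: low}
  - {name: chewing_problems,    levels: [0, 1],                  group: somatic,         volatility: low}
  - {name: grip_weakness,       levels: [0, 1],                  group: somatic,         volatility: low}
  - {name: hearing,             levels: [0, 0.5, 1],             group: sensory,         volatility: low}
  - {name: vision,              levels: [0, 0.5, 1],             group: sensory,         volatility: low}
  - {name: depressed,           levels: [0, 0.5, 1],             group: affect,          volatility: low}
  - {name: sad,                 levels: [0, 0.5, 1],             group: affect,          volatility: low}
  - {name: lonely,              levels: [0, 0.5, 1],             group: affect,          volatility: low}
  - {name: self_rated_health,   levels: [0, 0.25, 0.5, 0.75, 1], group: other,           volatility: low}
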