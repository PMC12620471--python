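# Study-shaped survey: 163 respondents, decision classes 14/41/108,
# the ten published conjunction rules planted exclusively at the integer
# support counts implied by their published within-class coverages.
n_objects: 163
decision_attribute: satisfaction
condition_attributes:
  - safety
  - usefulness
  - smart_technology
  - health_management
  - economic_affordability
  - digital_inclusion
  - cultural_adaptability
  - cost_control
  - inclusive_policies
class_sizes:
  1: 14
  2: 41
  3: 108
noise: 0.10
seed: 0
planted_rules:
  - {literals: {safety: 2, usefulness: 2}, decision: 1, target_count: 5}
  - {literals: {economic_affordability: 3, cost_control: 2}, decision: 1, target_count: 5}
  - {literals: {smart_technology: 1, economic_affordability: 1}, decision: 1, target_count: 2}
  - {literals: {safety: 1, smart_technology: 1}, decision: 1, target_count: 2}
  - {literals: {usefulness: 1, health_management: 1}, decision: 1, target_count: 2}
  - {literals: {safety: 5, cost_control: 5}, decision: 3, target_count: 49}
  - {literals: {safety: 5, digital_inclusion: 3, inclusive_policies: 5}, decision: 3, target_count: 12}
  - {literals: {usefulness: 4, cultural_adaptability: 5}, decision: 3, target_count: 19}
  - {literals: {usefulness: 4, health_management: 4}, decision: 3, target_count: 22}
  - {literals: {digital_inclusion: 5, inclusive_policies: 3}, decision: 3, target_count: 15}
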