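# Study-shaped expert panel: 18 experts scoring twelve candidate criteria
# on the 1-10 scale; importance levels reflect which criteria the screening
# retained (high ~8.2) versus excluded (borderline ~6.0).
n_experts: 18
interval_width: 2.5
score_sd: 0.8
outlier_rate: 0.05
seed: 0
criteria:
  - {name: safety, importance: 8.2}
  - {name: usefulness, importance: 8.2}
  - {name: smart_technology, importance: 8.2}
  - {name: ease_of_use, importance: 6.0}
  - {name: health_management, importance: 8.2}
  - {name: economic_affordability, importance: 8.2}
  - {name: psychological_resilience, importance: 6.0}
  - {name: digital_inclusion, importance: 8.2}
  - {name: spatial_adaptability, importance: 6.0}
  - {name: cultural_adaptability, importance: 8.2}
  - {name: cost_control, importance: 8.2}
  - {name: inclusive_policies, importance: 8.2}
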