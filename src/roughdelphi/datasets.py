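"""Published inputs from the elderly home-treatment-device satisfaction study.

The study screened 12 candidate criteria with an 18-expert fuzzy Delphi
panel and then surveyed 163 elderly respondents on the nine retained
criteria (5-point Likert conditions, 3-level satisfaction decision).  The
raw expert scores and survey rows are not deposited; what the study prints
are the aggregated fuzzy-number parameters per criterion, the decision-class
sizes, and the ten filtered decision rules with their within-class
coverages.  Those printed quantities are inputs here: the screening
parameters drive the consensus computation directly, and the rules/class
sizes parameterise the synthetic survey generator.
"""

from __future__ import annotations

# Per criterion: (criterion_id, C_U, O_L, C_M, O_M) — upper bound and mode of
# the conservative fuzzy number, lower bound and mode of the optimistic one,
# as published after outlier trimming of the 18-expert panel.
SCREENING_PARAMS: list[tuple[str, float, float, float, float]] = [
    ("safety", 8.0, 6.0, 6.0666, 8.4),
    ("usefulness", 9.0, 7.0, 6.9333, 9.1333),
    ("smart_technology", 8.0, 7.0, 6.7333, 8.9333),
    ("ease_of_use", 7.0, 5.0, 4.4666, 7.4667),
    ("health_management", 8.0, 7.0, 6.0, 8.4),
    ("economic_affordability", 8.0, 7.0, 5.5333, 8.5333),
    ("psychological_resilience", 7.0, 6.0, 5.6667, 8.0667),
    ("digital_inclusion", 8.0, 7.0, 6.0, 8.3333),
    ("spatial_adaptability", 7.0, 6.0, 5.7333, 8.2),
    ("cultural_adaptability", 7.0, 7.0, 5.6667, 7.9333),
    ("cost_control", 8.0, 6.0, 5.8667, 8.3333),
    ("inclusive_policies", 8.0, 7.0, 5.9333, 8.5333),
]

# The nine criteria retained at threshold 7, in survey column order.
CONDITION_ATTRIBUTES: list[str] = [
    "safety",
    "usefulness",
    "smart_technology",
    "health_management",
    "economic_affordability",
    "digital_inclusion",
    "cultural_adaptability",
    "cost_control",
    "inclusive_policies",
]

DECISION_ATTRIBUTE = "satisfaction"

# Decision-class sizes of the 163-respondent survey
# (1 = dissatisfied, 2 = neutral, 3 = satisfied).
STUDY_CLASS_SIZES: dict[int, int] = {1: 14, 2: 41, 3: 108}

# The ten published decision rules: (literals, decision class, support count).
# Support counts are the integer numerators of the published within-class
# coverages over the class sizes above (e.g. 49/108 = 45.37%, 5/14 = 35.71%).
STUDY_RULES: list[tuple[dict[str, int], int, int]] = [
    ({"safety": 2, "usefulness": 2}, 1, 5),
    ({"economic_affordability": 3, "cost_control": 2}, 1, 5),
    ({"smart_technology": 1, "economic_affordability": 1}, 1, 2),
    ({"safety": 1, "smart_technology": 1}, 1, 2),
    ({"usefulness": 1, "health_management": 1}, 1, 2),
    ({"safety": 5, "cost_control": 5}, 3, 49),
    ({"safety": 5, "digital_inclusion": 3, "inclusive_policies": 5}, 3, 12),
    ({"usefulness": 4, "cultural_adaptability": 5}, 3, 19),
    ({"usefulness": 4, "health_management": 4}, 3, 22),
    ({"digital_inclusion": 5, "inclusive_policies": 3}, 3, 15),
]
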