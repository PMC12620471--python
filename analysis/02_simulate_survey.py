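#!/usr/bin/env python
"""Stage 2 — generate the study-shaped satisfaction survey.

Builds the 163-respondent synthetic decision table: nine Likert condition
attributes, decision classes of 14 dissatisfied / 41 neutral / 108
satisfied respondents, and the ten published condition configurations
planted exclusively at the integer support counts implied by their
published within-class coverages.  The coverage table confirms the
planting is exact.
"""

from pathlib import Path

import pandas as pd

from roughdelphi.datasets import STUDY_CLASS_SIZES, STUDY_RULES
from roughdelphi.rules import rule_stats
from roughdelphi.simulate import generate_survey, study_survey_spec

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 1
table = generate_survey(study_survey_spec(seed=SEED))
table.to_csv(OUT / "survey.csv")
print(f"wrote {table.n_objects} respondents (seed {SEED}) to results/survey.csv")
sizes = {v: len(table.decision_class(v)) for v in (1, 2, 3)}
print(f"decision-class sizes: {sizes}\n")

rows = []
for literals, decision, count in STUDY_RULES:
    conds = tuple(sorted(literals.items()))
    support, coverage, certainty = rule_stats(conds, decision, table)
    rows.append(
        {
            "conditions": " and ".join(f"({a} = {v})" for a, v in conds),
            "decision": decision,
            "support": support,
            "class_size": STUDY_CLASS_SIZES[decision],
            "coverage_pct": round(coverage * 100, 2),
            "certainty": certainty,
        }
    )
coverage = pd.DataFrame(rows)
coverage.to_csv(OUT / "rule_coverage.csv", index=False)
print("planted configuration coverages (exact by construction):")
print(coverage.to_string(index=False))
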