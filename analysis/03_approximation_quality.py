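#!/usr/bin/env python
"""Stage 3 — rough-set approximation quality of the survey table.

Computes lower/upper approximations and accuracy per decision class, the
overall quality of classification gamma, and the reducts and core of the
condition set, for both the study-shaped fixture and the consistent
variant (whose profile determines the decision, so gamma is exactly 1).
"""

import json
from pathlib import Path

import pandas as pd

from roughdelphi.roughset import approximate, dependency, find_reducts
from roughdelphi.simulate import (
    consistent_survey_spec,
    generate_survey,
    study_survey_spec,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 1
for label, spec in (
    ("fixture", study_survey_spec(seed=SEED)),
    ("consistent", consistent_survey_spec(seed=SEED)),
):
    table = generate_survey(spec)
    conditions = table.condition_attributes
    dep = dependency(table, conditions)
    rows = []
    for value in table.decision_values():
        approx = approximate(table, conditions, table.decision_class(value))
        rows.append(
            {
                "class": value,
                "n_objects": len(approx.target),
                "lower": len(approx.lower),
                "upper": len(approx.upper),
                "accuracy": round(approx.accuracy, 4),
            }
        )
    quality = pd.DataFrame(rows).sort_values("class")
    quality["quality_of_classification"] = round(dep.gamma, 4)
    quality.to_csv(OUT / f"quality_{label}.csv", index=False)
    print(f"{label} table (seed {SEED}):")
    print(quality.to_string(index=False))

    reducts = find_reducts(table)
    with open(OUT / f"reducts_{label}.json", "w") as fh:
        json.dump(
            {
                "gamma": dep.gamma,
                "n_reducts": len(reducts.reducts),
                "smallest_reducts": [
                    list(r)
                    for r in sorted(reducts.reducts, key=len)[:5]
                ],
                "core": list(reducts.core),
            },
            fh,
            indent=2,
        )
    print(
        f"  {len(reducts.reducts)} reducts; core = "
        f"{list(reducts.core) or 'empty'}\n"
    )
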