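#!/usr/bin/env python
"""Stage 4 — decision-rule induction, filtering and flow graphs.

Induces the full set of certain rules from the survey fixture, filters at
the 10% within-class coverage threshold over the dissatisfied (1) and
satisfied (3) classes, and renders the surviving configurations as
decision flow graphs (one per outcome, conditions layer to decision
layer).  The filtered table is the analogue of the published rule list:
distinct conjunctions of condition levels forming alternative pathways to
each satisfaction outcome.
"""

from pathlib import Path

import pandas as pd

from roughdelphi.flowgraph import build_flow_graph, to_dot
from roughdelphi.rules import RuleSet, filter_rules, induce_rules
from roughdelphi.simulate import generate_survey, study_survey_spec

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 1
table = generate_survey(study_survey_spec(seed=SEED))
full = induce_rules(table, table_ref=f"synthetic survey seed {SEED}")
filtered = filter_rules(full, min_coverage=0.10, keep_classes=[1, 3])


def frame(ruleset):
    return pd.DataFrame(
        [
            {
                "rule": i,
                "conditions": " and ".join(
                    f"({a} = {v})" for a, v in r.conditions
                ),
                "decision": r.decision,
                "support": r.support,
                "coverage_pct": round(r.coverage * 100, 2),
            }
            for i, r in enumerate(ruleset, start=1)
        ]
    )


frame(full).to_csv(OUT / "rules_full.csv", index=False)
frame(filtered).to_csv(OUT / "rules_filtered.csv", index=False)
print(
    f"induced {len(full)} certain rules; "
    f"{len(filtered)} survive the 10% coverage filter over classes {{1, 3}}\n"
)
print(frame(filtered).to_string(index=False))

for decision, name in ((1, "flow_dissatisfied.dot"), (3, "flow_satisfied.dot")):
    subset = RuleSet(
        rules=tuple(r for r in filtered if r.decision == decision)
    )
    flow = build_flow_graph(subset)
    (OUT / name).write_text(to_dot(flow))
    print(
        f"decision {decision}: {len(flow.condition_nodes)} condition nodes, "
        f"{flow.n_edges} edges -> results/{name}"
    )
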