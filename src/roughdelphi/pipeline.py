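"""End-to-end pipeline: screen criteria, analyse the survey, report.

``run_pipeline`` realises the three-stage design — fuzzy Delphi screening
of candidate criteria, rough-set approximation/quality analysis of the
survey decision table, and minimal-covering rule induction with coverage
filtering, cross-validation and flow-graph rendering — writing every stage
artifact plus a MANIFEST with content hashes into the output directory.
All randomness flows from the single ``seed`` in the configuration, so a
rerun with an identical configuration reproduces every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import simulate
from .fdm import ExpertPanel, consensus_report, screen_criteria, screening_summary
from .flowgraph import build_flow_graph, to_dot
from .roughset import approximate, dependency, find_reducts
from .rules import cross_validate, filter_rules, induce_rules
from .table import DecisionTable

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("roughdelphi")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run.

    Paths left as ``None`` are filled by the synthetic generators (seeded),
    so the pipeline runs end to end without external data.
    """

    panel_path: str | None = None
    table_path: str | None = None
    decision_attribute: str = "satisfaction"
    fdm_threshold: float = Field(default=7.0, ge=1.0, le=10.0)
    central: str = "geometric"
    min_coverage: float = Field(default=0.10, ge=0.0, le=1.0)
    keep_classes: list[int] = [1, 3]
    folds: int = Field(default=10, ge=2)
    cv_on_filtered: bool = False
    seed: int = 0
    out_dir: str = "run_output"

    @field_validator("central")
    @classmethod
    def _check_central(cls, v: str) -> str:
        if v not in ("geometric", "arithmetic"):
            raise ValueError("central must be 'geometric' or 'arithmetic'")
        return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifacts; returns the manifest dict.

    Stage failures raise :class:`PipelineError` naming the stage; artifacts
    written before the failure are retained and the MANIFEST marks the run
    incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    manifest: dict = {"complete": False, "stages": [], "files": {}}

    def _record(name: str) -> None:
        manifest["files"][name] = _sha256(out / name)

    def _fail(stage: str, err: Exception):
        manifest["stages"].append({"stage": stage, "ok": False, "error": str(err)})
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    # stage 1: fuzzy Delphi screening ------------------------------------
    try:
        if config.panel_path:
            panel = ExpertPanel.from_csv(config.panel_path)
        else:
            panel = simulate.generate_panel(
                simulate.study_panel_spec(seed=config.seed)
            )
        consensus = screen_criteria(
            panel, threshold=config.fdm_threshold, central=config.central
        )
        consensus_report(consensus).to_csv(out / "consensus.csv", index=False)
        (out / "screening_summary.json").write_text(
            json.dumps(screening_summary(consensus), indent=2) + "\n"
        )
        _record("consensus.csv")
        _record("screening_summary.json")
        manifest["stages"].append({"stage": "fdm_screening", "ok": True})
        log.info(
            "screening retained %d of %d criteria",
            sum(r.retained for r in consensus),
            len(consensus),
        )
    except Exception as err:  # noqa: BLE001 - reported via manifest
        _fail("fdm_screening", err)

    # stage 2: survey decision table --------------------------------------
    try:
        if config.table_path:
            table = DecisionTable.from_csv(
                config.table_path, decision=config.decision_attribute
            )
        else:
            table = simulate.generate_survey(
                simulate.study_survey_spec(seed=config.seed)
            )
        table.to_csv(out / "decision_table.csv")
        _record("decision_table.csv")
        manifest["stages"].append({"stage": "decision_table", "ok": True})
    except Exception as err:  # noqa: BLE001
        _fail("decision_table", err)

    # stage 3: approximation quality and reducts --------------------------
    try:
        conditions = table.condition_attributes
        dep = dependency(table, conditions)
        rows = []
        for class_value in table.decision_values():
            approx = approximate(
                table, conditions, table.decision_class(class_value)
            )
            rows.append(
                {
                    "class": class_value,
                    "n_objects": len(approx.target),
                    "lower": len(approx.lower),
                    "upper": len(approx.upper),
                    "accuracy": round(approx.accuracy, 4),
                }
            )
        quality = pd.DataFrame(rows)
        quality["quality_of_classification"] = round(dep.gamma, 4)
        reducts = find_reducts(table)
        quality.to_csv(out / "quality.csv", index=False)
        (out / "reducts.json").write_text(
            json.dumps(
                {
                    "gamma": dep.gamma,
                    "reducts": [list(r) for r in reducts.reducts],
                    "core": list(reducts.core),
                    "exhaustive": reducts.exhaustive,
                },
                indent=2,
            )
            + "\n"
        )
        _record("quality.csv")
        _record("reducts.json")
        manifest["stages"].append({"stage": "approximation_quality", "ok": True})
        log.info("quality of classification %.4f", dep.gamma)
    except Exception as err:  # noqa: BLE001
        _fail("approximation_quality", err)

    # stage 4: rule induction and filtering -------------------------------
    try:
        full = induce_rules(table, table_ref=str(config.table_path or "synthetic"))
        filtered = filter_rules(full, config.min_coverage, config.keep_classes)
        for name, ruleset in (("rules_full", full), ("rules_filtered", filtered)):
            frame = pd.DataFrame(
                [
                    {
                        "rule": i,
                        "conditions": " and ".join(
                            f"({a} = {v})" for a, v in r.conditions
                        ),
                        "decision": r.decision,
                        "support": r.support,
                        "coverage": round(r.coverage, 4),
                        "certainty": round(r.certainty, 4),
                    }
                    for i, r in enumerate(ruleset, start=1)
                ],
                columns=[
                    "rule",
                    "conditions",
                    "decision",
                    "support",
                    "coverage",
                    "certainty",
                ],
            )
            frame.to_csv(out / f"{name}.csv", index=False)
            _record(f"{name}.csv")
        manifest["stages"].append({"stage": "rule_induction", "ok": True})
        log.info("induced %d rules, %d after filtering", len(full), len(filtered))
    except Exception as err:  # noqa: BLE001
        _fail("rule_induction", err)

    # stage 5: cross-validation -------------------------------------------
    try:
        cv = cross_validate(
            table,
            n_folds=config.folds,
            seed=config.seed,
            min_coverage=config.min_coverage if config.cv_on_filtered else 0.0,
            keep_classes=config.keep_classes if config.cv_on_filtered else None,
        )
        pd.DataFrame(
            {
                "fold": range(1, cv.n_folds + 1),
                "accuracy": [round(a, 4) for a in cv.per_fold_accuracy],
            }
        ).to_csv(out / "cv.csv", index=False)
        (out / "cv_summary.json").write_text(
            json.dumps(
                {
                    "n_folds": cv.n_folds,
                    "mean_accuracy": cv.mean_accuracy,
                    "seed": cv.seed,
                },
                indent=2,
            )
            + "\n"
        )
        _record("cv.csv")
        _record("cv_summary.json")
        manifest["stages"].append({"stage": "cross_validation", "ok": True})
        log.info("mean CV accuracy %.4f over %d folds", cv.mean_accuracy, cv.n_folds)
    except Exception as err:  # noqa: BLE001
        _fail("cross_validation", err)

    # stage 6: decision flow graph ----------------------------------------
    try:
        source = filtered if len(filtered) else full
        flow = build_flow_graph(source)
        (out / "flow_graph.dot").write_text(to_dot(flow))
        _record("flow_graph.dot")
        manifest["stages"].append({"stage": "flow_graph", "ok": True})
    except Exception as err:  # noqa: BLE001
        _fail("flow_graph", err)

    manifest["complete"] = True
    _record("config.json")
    (out / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
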