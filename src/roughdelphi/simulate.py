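"""Seeded generators for expert panels and Likert survey decision tables.

The survey generator emulates an ordinal satisfaction questionnaire: each
respondent rates a fixed set of condition attributes on a 1-5 Likert scale
and reports an overall satisfaction class (1 = dissatisfied, 2 = neutral,
3 = satisfied).  Decision-class sizes are fixed exactly.  Conjunction rules
can be *planted*: a planted rule pins its literal pattern onto a designed
number of members of its class, and (when exclusive, the default) the
generator guarantees that no object outside the class matches the pattern —
so the planted conjunction is a certain rule with coverage exactly
``target_count / class size``.  All other cells are drawn from
class-conditional categorical distributions (satisfied respondents skew
high on the Likert scale, dissatisfied respondents skew low) and optionally
perturbed by noise; a repair pass restores exact planted counts afterwards.

The panel generator emulates interval elicitation from an expert panel:
per expert and criterion a conservative and an optimistic score on the 1-10
integer scale, centred on the criterion's true importance, with optional
aberrant scores injected to exercise two-standard-deviation trimming.

Both generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .fdm import ExpertPanel
from .table import DecisionTable

__all__ = [
    "PlantingError",
    "PlantedRule",
    "SurveySpec",
    "PanelSpec",
    "generate_survey",
    "generate_panel",
    "study_survey_spec",
    "consistent_survey_spec",
    "study_panel_spec",
    "load_survey_spec",
    "load_panel_spec",
]

LIKERT_DOMAIN = (1, 2, 3, 4, 5)

# Class-conditional Likert response profiles.  Dissatisfied respondents
# skew low and satisfied respondents skew high on every condition; a
# neutral respondent is modelled as a respondent-level mixture — they adopt
# either the low-leaning or the high-leaning response style wholesale —
# rather than as a distinctive centred style of their own, so overall
# neutrality is not trivially recoverable from any single condition.
DEFAULT_CLASS_PROFILES: dict[int, object] = {
    1: (0.35, 0.35, 0.18, 0.08, 0.04),
    2: {"mixture_of": [1, 3], "weights": [0.5, 0.5]},
    3: (0.03, 0.07, 0.15, 0.35, 0.40),
}

_MAX_REPAIR_PASSES = 200


class PlantingError(ValueError):
    """A planted-rule specification is infeasible or self-contradictory."""


@dataclass(frozen=True)
class PlantedRule:
    """A conjunction to embed in the survey at a designed support count.

    ``exclusive`` (default) guarantees no object outside ``decision``'s
    class satisfies the literals, making the planted conjunction a certain
    rule with coverage exactly ``target_count / class_size``.
    """

    literals: tuple[tuple[str, int], ...]
    decision: int
    target_count: int
    exclusive: bool = True

    def __post_init__(self) -> None:
        attrs = [a for a, _ in self.literals]
        if len(attrs) != len(set(attrs)):
            raise PlantingError(f"attribute repeated in literals: {attrs}")
        if self.target_count <= 0:
            raise PlantingError("target_count must be positive")


@dataclass(frozen=True)
class SurveySpec:
    """Full specification of a synthetic survey decision table."""

    n_objects: int
    condition_attributes: tuple[str, ...]
    class_sizes: dict[int, int]
    planted_rules: tuple[PlantedRule, ...] = ()
    noise: float = 0.0
    seed: int = 0
    decision_attribute: str = "satisfaction"
    domain: tuple[int, ...] = LIKERT_DOMAIN
    class_profiles: dict[int, object] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROFILES)
    )
    # fraction of each planted rule's carriers packed onto respondents that
    # already carry a compatible pattern (condition configurations co-occur);
    # the remainder are fresh carriers exclusive to the rule, so every
    # planted pattern keeps a region only it explains and the class retains
    # pattern-free members
    pack_fraction: float = 0.75
    consistent: bool = False

    def __post_init__(self) -> None:
        if sum(self.class_sizes.values()) != self.n_objects:
            raise PlantingError(
                f"class sizes {self.class_sizes} do not sum to {self.n_objects}"
            )
        if not 0.0 <= self.noise <= 1.0:
            raise PlantingError("noise must lie in [0, 1]")
        if not 0.0 <= self.pack_fraction <= 1.0:
            raise PlantingError("pack_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic expert panel.

    ``criteria`` maps criterion id to its true importance (the centre of
    the conservative/optimistic interval on the 1-10 scale);
    ``interval_width`` is the mean optimistic-conservative gap.
    """

    n_experts: int = 18
    criteria: tuple[tuple[str, float], ...] = ()
    interval_width: float = 2.0
    score_sd: float = 0.8
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError("need at least 2 experts")


# ---------------------------------------------------------------------------
# survey generation


def _validate_planting(spec: SurveySpec) -> None:
    attrs = set(spec.condition_attributes)
    seen_exclusive: dict[frozenset, PlantedRule] = {}
    for rule in spec.planted_rules:
        for attr, value in rule.literals:
            if attr not in attrs:
                raise PlantingError(f"planted literal uses unknown attribute {attr!r}")
            if value not in spec.domain:
                raise PlantingError(f"planted value {value!r} outside the domain")
        if rule.decision not in spec.class_sizes:
            raise PlantingError(f"planted decision {rule.decision!r} has no class")
        if rule.target_count > spec.class_sizes[rule.decision]:
            raise PlantingError(
                f"target_count {rule.target_count} exceeds class "
                f"{rule.decision} size {spec.class_sizes[rule.decision]}"
            )
        if rule.exclusive:
            key = frozenset(rule.literals)
            if key in seen_exclusive:
                raise PlantingError(
                    f"two exclusive planted rules request the same literal "
                    f"pattern {sorted(rule.literals)}"
                )
            seen_exclusive[key] = rule


def _assign_carriers(
    spec: SurveySpec, class_positions: dict[int, list[int]]
) -> tuple[dict[int, list[int]], dict[int, dict[str, int]]]:
    """Choose which class members carry each planted pattern.

    Patterns of the same class may share carriers (needed when target
    counts sum past the class size) provided their literals do not
    conflict on a shared attribute.  Returns carrier lists per rule index
    and the pinned (attribute -> value) cells per object position.
    """
    # how many of each rule's carriers to pack onto already-pinned members:
    # the voluntary share is pack_fraction of the target; any overlap the
    # counts force beyond that (targets summing past the class size) is
    # assigned to the largest rules, which keep exclusive carriers anyway —
    # a small rule whose whole region is absorbed by other patterns would
    # be invisible to minimal-covering induction
    by_class: dict[int, list[int]] = {}
    for ridx, rule in enumerate(spec.planted_rules):
        by_class.setdefault(rule.decision, []).append(ridx)
    want_packed = {}
    for class_value, ridxs in by_class.items():
        for k, ridx in enumerate(ridxs):
            target = spec.planted_rules[ridx].target_count
            cap = target - 1
            want_packed[ridx] = 0 if k == 0 else min(
                cap, round(spec.pack_fraction * target)
            )
        shortfall = sum(
            spec.planted_rules[r].target_count for r in ridxs
        ) - spec.class_sizes[class_value] - sum(want_packed[r] for r in ridxs)
        for ridx in sorted(
            ridxs[1:],
            key=lambda r: -spec.planted_rules[r].target_count,
        ):
            if shortfall <= 0:
                break
            cap = spec.planted_rules[ridx].target_count - 1
            extra = min(shortfall, cap - want_packed[ridx])
            want_packed[ridx] += extra
            shortfall -= extra

    pinned: dict[int, dict[str, int]] = {}
    carriers: dict[int, list[int]] = {}
    for ridx, rule in enumerate(spec.planted_rules):
        members = class_positions[rule.decision]
        compatible = [
            pos
            for pos in members
            if not any(
                pinned.get(pos, {}).get(a, v) != v for a, v in rule.literals
            )
        ]
        n_fresh = rule.target_count - want_packed[ridx]
        fresh = [pos for pos in compatible if not pinned.get(pos)][:n_fresh]
        chosen = list(fresh)
        packed_order = sorted(
            (pos for pos in compatible if pos not in set(chosen)),
            key=lambda pos: (-len(pinned.get(pos, {})), members.index(pos)),
        )
        for pos in packed_order:
            if len(chosen) == rule.target_count:
                break
            chosen.append(pos)
        if len(chosen) < rule.target_count:
            raise PlantingError(
                f"cannot place planted rule {rule.literals} -> "
                f"{rule.decision}: only {len(chosen)} compatible members "
                f"for target {rule.target_count}"
            )
        carriers[ridx] = chosen
        for pos in chosen:
            pinned.setdefault(pos, {}).update(dict(rule.literals))
    return carriers, pinned


def _repair(
    spec: SurveySpec,
    values: dict[str, np.ndarray],
    decisions: np.ndarray,
    carriers: dict[int, list[int]],
    pinned: dict[int, dict[str, int]],
    rng: np.random.Generator,
) -> None:
    """Flip free cells until every planted count is exact and exclusive.

    A non-carrier accidentally matching a pattern gets one of the pattern's
    attributes (not pinned for that object) redrawn to a different value.
    """
    domain = np.asarray(spec.domain)
    for _ in range(_MAX_REPAIR_PASSES):
        dirty = False
        for ridx, rule in enumerate(spec.planted_rules):
            match = np.ones(spec.n_objects, dtype=bool)
            for attr, value in rule.literals:
                match &= values[attr] == value
            carrier_set = set(carriers[ridx])
            for pos in np.flatnonzero(match):
                pos = int(pos)
                if pos in carrier_set:
                    continue
                in_class = decisions[pos] == rule.decision
                if not in_class and not rule.exclusive:
                    continue  # non-exclusive: outside matches are allowed
                own_pins = pinned.get(pos, {})
                free = [a for a, _ in rule.literals if a not in own_pins]
                if not free:
                    raise PlantingError(
                        f"object {pos} is pinned into pattern "
                        f"{rule.literals} but may not match it; "
                        f"planting is infeasible"
                    )
                attr = free[int(rng.integers(len(free)))]
                forbidden = dict(rule.literals)[attr]
                alternatives = domain[domain != forbidden]
                values[attr][pos] = int(
                    alternatives[int(rng.integers(len(alternatives)))]
                )
                dirty = True
        if not dirty:
            return
    raise PlantingError("planting repair did not converge; patterns conflict")


def _diversify_carriers(
    spec: SurveySpec,
    values: dict[str, np.ndarray],
    carriers: dict[int, list[int]],
    pinned: dict[int, dict[str, int]],
    rng: np.random.Generator,
) -> bool:
    """Break accidental constant columns across a rule's carrier set.

    If every carrier of a planted rule shares the same value on some
    attribute outside the rule's literals, that coincidental literal
    explains the carrier region as well as the planted conjunction does
    and minimal-covering induction may prefer it.  One free cell is
    redrawn whenever this happens, so the planted literals are the only
    description common to the whole region.  Returns whether anything
    changed.
    """
    domain = np.asarray(spec.domain)
    changed = False
    for ridx, rule in enumerate(spec.planted_rules):
        carr = carriers[ridx]
        if len(carr) < 2:
            continue
        pattern_attrs = {a for a, _ in rule.literals}
        for attr in spec.condition_attributes:
            if attr in pattern_attrs:
                continue
            if len({int(values[attr][p]) for p in carr}) > 1:
                continue
            free = [p for p in carr if attr not in pinned.get(p, {})]
            if not free:
                continue  # fully pinned by overlapping patterns: best effort
            pos = free[int(rng.integers(len(free)))]
            current = int(values[attr][pos])
            alternatives = domain[domain != current]
            values[attr][pos] = int(
                alternatives[int(rng.integers(len(alternatives)))]
            )
            changed = True
    return changed


def _repair_consistency(
    spec: SurveySpec,
    values: dict[str, np.ndarray],
    decisions: np.ndarray,
    pinned: dict[int, dict[str, int]],
    rng: np.random.Generator,
) -> bool:
    """Perturb duplicated condition profiles that straddle decision classes
    so the table is consistent (the profile determines the decision).
    Returns whether anything was changed."""
    attrs = spec.condition_attributes
    domain = np.asarray(spec.domain)
    changed = False
    for _ in range(_MAX_REPAIR_PASSES):
        profiles: dict[tuple, int] = {}
        clash = None
        for pos in range(spec.n_objects):
            key = tuple(int(values[a][pos]) for a in attrs)
            if key in profiles and decisions[profiles[key]] != decisions[pos]:
                clash = pos
                break
            profiles.setdefault(key, pos)
        if clash is None:
            return changed
        own_pins = pinned.get(clash, {})
        free = [a for a in attrs if a not in own_pins]
        if not free:
            raise PlantingError("cannot make table consistent: object fully pinned")
        attr = free[int(rng.integers(len(free)))]
        current = int(values[attr][clash])
        alternatives = domain[domain != current]
        values[attr][clash] = int(alternatives[int(rng.integers(len(alternatives)))])
        changed = True
    raise PlantingError("consistency repair did not converge")


def generate_survey(spec: SurveySpec) -> DecisionTable:
    """Generate a survey decision table according to ``spec``.

    Deterministic under ``spec.seed``: the same spec yields a byte-identical
    table.  Class sizes are exact; every planted rule is satisfied by
    exactly ``target_count`` members of its class (and, when exclusive, by
    no other object).  With ``spec.consistent`` the condition profile
    determines the decision, so the quality of classification is 1.
    """
    _validate_planting(spec)
    rng = np.random.default_rng(spec.seed)

    # decision column: exact class sizes, shuffled row order
    decisions = np.concatenate(
        [
            np.full(size, class_value)
            for class_value, size in sorted(spec.class_sizes.items())
        ]
    )
    decisions = decisions[rng.permutation(spec.n_objects)]
    class_positions = {
        cv: [int(p) for p in np.flatnonzero(decisions == cv)]
        for cv in spec.class_sizes
    }

    carriers, pinned = _assign_carriers(spec, class_positions)

    # fill every cell from the respondent's response profile, then pin
    # planted cells; a mixture profile assigns each respondent of that
    # class one component style wholesale (their answers lean consistently)
    values: dict[str, np.ndarray] = {
        attr: np.empty(spec.n_objects, dtype=np.int64)
        for attr in spec.condition_attributes
    }
    domain = np.asarray(spec.domain)
    uniform = np.ones(len(domain)) / len(domain)

    def _resolve(profile_spec, depth: int = 0):
        if depth > 3:
            raise PlantingError("circular mixture in class profiles")
        if isinstance(profile_spec, dict):
            weights = np.asarray(profile_spec["weights"], dtype=float)
            weights = weights / weights.sum()
            component = profile_spec["mixture_of"][
                int(rng.choice(len(weights), p=weights))
            ]
            return _resolve(spec.class_profiles.get(component, uniform), depth + 1)
        return np.asarray(profile_spec, dtype=float)

    for class_value, positions in class_positions.items():
        profile_spec = spec.class_profiles.get(class_value, uniform)
        for pos in positions:
            profile = _resolve(profile_spec)
            profile = profile / profile.sum()
            draws = rng.choice(domain, size=len(spec.condition_attributes), p=profile)
            for attr, value in zip(spec.condition_attributes, draws):
                values[attr][pos] = value
    if spec.noise > 0.0:
        for attr in spec.condition_attributes:
            flip = rng.random(spec.n_objects) < spec.noise
            redraw = rng.choice(domain, size=spec.n_objects)
            values[attr] = np.where(flip, redraw, values[attr])
    for pos, cells in pinned.items():
        for attr, value in cells.items():
            values[attr][pos] = value

    # alternate the planting, diversification and consistency repairs
    # until all are stable
    for _ in range(_MAX_REPAIR_PASSES):
        _repair(spec, values, decisions, carriers, pinned, rng)
        changed = _diversify_carriers(spec, values, carriers, pinned, rng)
        if spec.consistent:
            changed |= _repair_consistency(spec, values, decisions, pinned, rng)
        if not changed:
            break
    else:
        raise PlantingError("planting and consistency repairs did not settle")
    _assert_planting(spec, values, decisions, carriers)

    frame = pd.DataFrame(
        {attr: values[attr] for attr in spec.condition_attributes}
    )
    frame[spec.decision_attribute] = decisions
    frame.index = [f"r{i + 1}" for i in range(spec.n_objects)]
    return DecisionTable(frame, decision=spec.decision_attribute)


def _assert_planting(
    spec: SurveySpec,
    values: dict[str, np.ndarray],
    decisions: np.ndarray,
    carriers: dict[int, list[int]],
) -> None:
    for ridx, rule in enumerate(spec.planted_rules):
        match = np.ones(spec.n_objects, dtype=bool)
        for attr, value in rule.literals:
            match &= values[attr] == value
        in_class = match & (decisions == rule.decision)
        if int(in_class.sum()) != rule.target_count:
            raise PlantingError(
                f"planted count drifted for {rule.literals}: "
                f"{int(in_class.sum())} != {rule.target_count}"
            )
        if rule.exclusive and int((match & ~(decisions == rule.decision)).sum()):
            raise PlantingError(f"exclusivity violated for {rule.literals}")


# ---------------------------------------------------------------------------
# panel generation


def generate_panel(spec: PanelSpec) -> ExpertPanel:
    """Generate an expert panel of interval judgments.

    Per expert and criterion, a latent midpoint is drawn around the
    criterion's importance; the conservative and optimistic scores sit half
    the interval width below and above it, rounded to the 1-10 integer
    scale with conservative <= optimistic.  With probability
    ``outlier_rate`` a score is replaced by an aberrant value on the far
    side of the scale (low aberrations for important criteria, high for
    unimportant ones), exercising the two-standard-deviation trim.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    half = spec.interval_width / 2.0
    for expert in range(1, spec.n_experts + 1):
        for criterion, importance in spec.criteria:
            mid = importance + rng.normal(0.0, spec.score_sd)
            cons = int(np.clip(round(mid - half), 1, 10))
            opt = int(np.clip(round(mid + half), 1, 10))
            if rng.random() < spec.outlier_rate:
                # an aberrant expert judges the whole interval from the far
                # side of the scale, so each score series is contaminated
                # at exactly the outlier rate and the deviation stays large
                # relative to the (inflated) series spread
                aberrant = (
                    int(rng.integers(1, 3))
                    if importance >= 5.5
                    else int(rng.integers(9, 11))
                )
                cons = opt = aberrant
            if cons > opt:
                cons, opt = opt, cons
            rows.append(
                {
                    "expert_id": f"e{expert}",
                    "criterion_id": criterion,
                    "conservative": cons,
                    "optimistic": opt,
                }
            )
    return ExpertPanel(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# bundled study-shaped specifications


def study_survey_spec(seed: int = 0, noise: float = 0.10) -> SurveySpec:
    """The study-shaped survey: 163 respondents, classes 14/41/108, and the
    ten published conjunction rules planted exclusively at the integer
    support counts implied by their published coverages."""
    planted = tuple(
        PlantedRule(
            literals=tuple(sorted(literals.items())),
            decision=decision,
            target_count=count,
        )
        for literals, decision, count in datasets.STUDY_RULES
    )
    return SurveySpec(
        n_objects=sum(datasets.STUDY_CLASS_SIZES.values()),
        condition_attributes=tuple(datasets.CONDITION_ATTRIBUTES),
        class_sizes=dict(datasets.STUDY_CLASS_SIZES),
        planted_rules=planted,
        noise=noise,
        seed=seed,
    )


def recovery_survey_spec(seed: int = 0) -> SurveySpec:
    """A parameter-recovery benchmark for the planting machinery.

    Planted conjunctions get generous, fully exclusive carrier regions
    (no packing, no noise) over a uniform response background, so each
    planted pattern is the dominant certain description of its region and
    minimal-covering induction recovers it (possibly condition-minimised)
    with at least the designed support.  The study-shaped fixture keeps
    the published counts instead, which force carrier overlap; this spec
    isolates the recovery property from that structure.
    """
    uniform = (0.2, 0.2, 0.2, 0.2, 0.2)
    planted = (
        PlantedRule(
            literals=(("safety", 2), ("usefulness", 2)),
            decision=1,
            target_count=12,
        ),
        PlantedRule(
            literals=(("economic_affordability", 3), ("cost_control", 2)),
            decision=1,
            target_count=9,
        ),
        PlantedRule(
            literals=(("safety", 5), ("cost_control", 5)),
            decision=3,
            target_count=25,
        ),
        PlantedRule(
            literals=(("usefulness", 4), ("cultural_adaptability", 5)),
            decision=3,
            target_count=18,
        ),
        PlantedRule(
            literals=(("digital_inclusion", 5), ("inclusive_policies", 3)),
            decision=3,
            target_count=12,
        ),
    )
    return SurveySpec(
        n_objects=163,
        condition_attributes=tuple(datasets.CONDITION_ATTRIBUTES),
        class_sizes={1: 30, 2: 43, 3: 90},
        planted_rules=planted,
        noise=0.0,
        seed=seed,
        class_profiles={1: uniform, 2: uniform, 3: uniform},
        pack_fraction=0.0,
    )


def consistent_survey_spec(seed: int = 0) -> SurveySpec:
    """A consistent 163-respondent table (condition profile determines the
    decision), for approximation-quality checks."""
    return replace(study_survey_spec(seed=seed, noise=0.0), consistent=True)


def study_panel_spec(seed: int = 0, outlier_rate: float = 0.05) -> PanelSpec:
    """An 18-expert panel over the twelve candidate criteria, with
    importance levels reflecting which criteria the study retained."""
    importance = {
        name: 8.2 if retained else 6.0
        for name, retained in [
            ("safety", True),
            ("usefulness", True),
            ("smart_technology", True),
            ("ease_of_use", False),
            ("health_management", True),
            ("economic_affordability", True),
            ("psychological_resilience", False),
            ("digital_inclusion", True),
            ("spatial_adaptability", False),
            ("cultural_adaptability", True),
            ("cost_control", True),
            ("inclusive_policies", True),
        ]
    }
    return PanelSpec(
        n_experts=18,
        criteria=tuple(importance.items()),
        interval_width=2.5,
        score_sd=0.8,
        outlier_rate=outlier_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML round-trip for bundled spec files


def load_survey_spec(path) -> SurveySpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    planted = tuple(
        PlantedRule(
            literals=tuple((a, int(v)) for a, v in sorted(r["literals"].items())),
            decision=int(r["decision"]),
            target_count=int(r["target_count"]),
            exclusive=bool(r.get("exclusive", True)),
        )
        for r in raw.get("planted_rules", [])
    )
    return SurveySpec(
        n_objects=int(raw["n_objects"]),
        condition_attributes=tuple(raw["condition_attributes"]),
        class_sizes={int(k): int(v) for k, v in raw["class_sizes"].items()},
        planted_rules=planted,
        noise=float(raw.get("noise", 0.0)),
        seed=int(raw.get("seed", 0)),
        decision_attribute=raw.get("decision_attribute", "satisfaction"),
        consistent=bool(raw.get("consistent", False)),
    )


def load_panel_spec(path) -> PanelSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PanelSpec(
        n_experts=int(raw.get("n_experts", 18)),
        criteria=tuple((c["name"], float(c["importance"])) for c in raw["criteria"]),
        interval_width=float(raw.get("interval_width", 2.0)),
        score_sd=float(raw.get("score_sd", 0.8)),
        outlier_rate=float(raw.get("outlier_rate", 0.0)),
        seed=int(raw.get("seed", 0)),
    )
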