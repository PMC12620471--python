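"""Minimal-covering induction of certain decision rules, and classification.

Rules have the form "if a1=v1 and a2=v2 ... then d=k".  A rule is *certain*
when every object matching its conditions carries its decision (certainty
1); certain rules are exactly the conjunctions whose match set lies inside
the lower approximation of the decision class.  Induction here is a
LEM2-style greedy minimal covering: per decision class, literals are picked
to cover as much of the still-uncovered lower approximation as possible,
each resulting conjunction is minimised literal by literal, and rules are
added until the lower approximation is fully covered.

Rule statistics follow the standard definitions: support is the number of
objects satisfying conditions and decision together, coverage divides the
support by the size of the decision class in the full table, and certainty
divides it by the number of objects matching the conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .roughset import approximate
from .table import DecisionTable

__all__ = [
    "DecisionRule",
    "RuleSet",
    "CrossValidationResult",
    "induce_rules",
    "rule_stats",
    "filter_rules",
    "classify",
    "cross_validate",
]


@dataclass(frozen=True)
class DecisionRule:
    """A conjunction of attribute=value literals implying a decision class."""

    conditions: tuple[tuple[str, object], ...]
    decision: object
    support: int
    coverage: float
    certainty: float

    def __post_init__(self) -> None:
        attrs = [a for a, _ in self.conditions]
        if len(attrs) != len(set(attrs)):
            raise ValueError(f"attribute repeated in conditions: {attrs}")

    def describe(self) -> str:
        if self.conditions:
            phi = " and ".join(f"({a} = {v})" for a, v in self.conditions)
        else:
            phi = "(true)"
        return f"{phi} => (decision = {self.decision})"


@dataclass(frozen=True)
class RuleSet:
    """An ordered rule collection with provenance and filter metadata."""

    rules: tuple[DecisionRule, ...]
    table_ref: str = ""
    min_coverage: float = 0.0
    kept_classes: tuple | None = None

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


@dataclass(frozen=True)
class CrossValidationResult:
    """Per-fold and mean holdout accuracy of the induced classifier."""

    n_folds: int
    per_fold_accuracy: tuple[float, ...]
    mean_accuracy: float
    seed: int


# ---------------------------------------------------------------------------
# matching helpers


def _literal_masks(table: DecisionTable) -> dict[tuple[str, object], np.ndarray]:
    """Boolean match vector for every (attribute, value) literal."""
    masks: dict[tuple[str, object], np.ndarray] = {}
    for attr in table.condition_attributes:
        col = table.frame[attr].to_numpy()
        for v in dict.fromkeys(col.tolist()):
            masks[(attr, v)] = col == v
    return masks


def _match_mask(
    table: DecisionTable, conditions: Sequence[tuple[str, object]]
) -> np.ndarray:
    """Boolean vector of objects satisfying all literals (all-true if none)."""
    mask = np.ones(table.n_objects, dtype=bool)
    for attr, value in conditions:
        mask &= table.frame[attr].to_numpy() == value
    return mask


# ---------------------------------------------------------------------------
# statistics


def rule_stats(
    conditions: Sequence[tuple[str, object]],
    decision,
    table: DecisionTable,
) -> tuple[int, float, float]:
    """(support, coverage, certainty) of a candidate rule on a table.

    An empty condition matches every object.  A decision value absent from
    the table has no class to divide by and raises ``ZeroDivisionError``.
    """
    for attr, value in conditions:
        table.validate_attributes([attr])
        if not (table.frame[attr] == value).any():
            raise KeyError(f"value {value!r} never occurs for attribute {attr!r}")
    matches = _match_mask(table, conditions)
    class_mask = table.frame[table.decision_attribute].to_numpy() == decision
    class_size = int(class_mask.sum())
    if class_size == 0:
        raise ZeroDivisionError(
            f"decision value {decision!r} has no objects: coverage undefined"
        )
    support = int((matches & class_mask).sum())
    coverage = support / class_size
    n_matches = int(matches.sum())
    certainty = support / n_matches if n_matches else 0.0
    return support, coverage, certainty


def _with_stats(
    conditions: Sequence[tuple[str, object]], decision, table: DecisionTable
) -> DecisionRule:
    support, coverage, certainty = rule_stats(conditions, decision, table)
    return DecisionRule(
        conditions=tuple(conditions),
        decision=decision,
        support=support,
        coverage=coverage,
        certainty=certainty,
    )


# ---------------------------------------------------------------------------
# LEM2-style induction


def _induce_class(
    table: DecisionTable,
    class_value,
    masks: dict[tuple[str, object], np.ndarray],
) -> list[tuple[tuple[str, object], ...]]:
    """Minimal covering of one class's lower approximation by certain rules."""
    conditions = table.condition_attributes
    attr_order = {a: i for i, a in enumerate(conditions)}
    target = table.decision_class(class_value)
    lower = approximate(table, conditions, target).lower
    lower_mask = np.zeros(table.n_objects, dtype=bool)
    lower_mask[table.positions(lower)] = True
    if not lower_mask.any():
        return []

    uncovered = lower_mask.copy()
    rule_conditions: list[tuple[tuple[str, object], ...]] = []
    while uncovered.any():
        chosen: list[tuple[str, object]] = []
        block = np.ones(table.n_objects, dtype=bool)
        local_goal = uncovered.copy()
        while not chosen or not (block.any() and not (block & ~lower_mask).any()):
            used = {a for a, _ in chosen}
            best = None
            best_key = None
            for (attr, value), mask in masks.items():
                if attr in used:
                    continue
                gain = int((mask & local_goal).sum())
                if gain == 0:
                    continue
                outside = int((mask & block & ~lower_mask).sum())
                # max gain, then fewest matches outside the class lower
                # approximation, then attribute order, then value
                key = (-gain, outside, attr_order[attr], repr(value))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (attr, value)
            if best is None:  # cannot happen on a coverable goal set
                raise RuntimeError("LEM2 ran out of literals")
            chosen.append(best)
            block &= masks[best]
            local_goal &= masks[best]
        # drop redundant literals (keep the conjunction certain)
        i = 0
        while i < len(chosen) and len(chosen) > 1:
            trial = chosen[:i] + chosen[i + 1 :]
            trial_block = np.ones(table.n_objects, dtype=bool)
            for lit in trial:
                trial_block &= masks[lit]
            if trial_block.any() and not (trial_block & ~lower_mask).any():
                chosen = trial
            else:
                i += 1
        final_block = np.ones(table.n_objects, dtype=bool)
        for lit in chosen:
            final_block &= masks[lit]
        rule_conditions.append(tuple(chosen))
        uncovered &= ~final_block

    # drop rules made redundant by the others (union must still cover)
    blocks = []
    for conds in rule_conditions:
        b = np.ones(table.n_objects, dtype=bool)
        for lit in conds:
            b &= masks[lit]
        blocks.append(b)
    kept_idx = list(range(len(rule_conditions)))
    for i in range(len(rule_conditions)):
        if len(kept_idx) == 1:
            break
        others = np.zeros(table.n_objects, dtype=bool)
        for j in kept_idx:
            if j != i:
                others |= blocks[j]
        if not (blocks[i] & lower_mask & ~others).any():
            kept_idx.remove(i)  # everything it covers is covered elsewhere
    return [rule_conditions[i] for i in kept_idx]


def induce_rules(table: DecisionTable, table_ref: str = "") -> RuleSet:
    """Induce a minimal-covering set of certain rules for every class.

    For each decision class (order of first appearance) the rules' match
    sets jointly cover the class's lower approximation exactly; each rule is
    condition-minimal — dropping any literal would admit objects outside the
    lower approximation.  Inconsistent tables simply yield rules covering
    the lower approximations only.
    """
    if table.n_objects == 0:
        raise ValueError("cannot induce rules from an empty table")
    masks = _literal_masks(table)
    rules: list[DecisionRule] = []
    for class_value in table.decision_values():
        for conds in _induce_class(table, class_value, masks):
            rules.append(_with_stats(conds, class_value, table))
    return RuleSet(rules=tuple(rules), table_ref=table_ref)


def filter_rules(
    rules: RuleSet,
    min_coverage: float,
    keep_classes: Iterable | None = None,
) -> RuleSet:
    """Keep rules with coverage >= ``min_coverage`` in the kept classes.

    Order-stable; a rule whose coverage equals the bound exactly is kept.
    ``keep_classes=None`` keeps every decision class.
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError(f"min_coverage must lie in [0, 1], got {min_coverage}")
    kept_classes = None if keep_classes is None else set(keep_classes)
    selected = tuple(
        r
        for r in rules
        if r.coverage >= min_coverage
        and (kept_classes is None or r.decision in kept_classes)
    )
    return RuleSet(
        rules=selected,
        table_ref=rules.table_ref,
        min_coverage=min_coverage,
        kept_classes=None if kept_classes is None else tuple(sorted(kept_classes)),
    )


# ---------------------------------------------------------------------------
# classification and cross-validation


def classify(object_row: dict, rules: RuleSet):
    """Predict a decision value for one object described by its conditions.

    Rules whose every literal is satisfied vote for their class, weighted by
    support.  If no rule matches exactly, the rule with the largest fraction
    of satisfied literals wins (ties: higher support, then rule order).
    Deterministic given a fixed rule order; never abstains on a nonempty
    rule set.
    """
    if not len(rules):
        raise ValueError("cannot classify with an empty rule set")
    votes: dict = {}
    for rule in rules:
        if all(object_row.get(a) == v for a, v in rule.conditions):
            votes[rule.decision] = votes.get(rule.decision, 0) + rule.support
    if votes:
        # max total support; ties broken by class value representation
        return max(votes, key=lambda k: (votes[k], -_stable_rank(k, votes)))
    best_rule = None
    best_key = None
    for i, rule in enumerate(rules):
        if not rule.conditions:
            frac = 1.0
        else:
            hits = sum(1 for a, v in rule.conditions if object_row.get(a) == v)
            frac = hits / len(rule.conditions)
        key = (-frac, -rule.support, i)
        if best_key is None or key < best_key:
            best_key = key
            best_rule = rule
    return best_rule.decision


def _stable_rank(value, votes: dict) -> int:
    ordered = sorted(votes, key=repr)
    return ordered.index(value)


def _stratified_folds(
    table: DecisionTable, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal each class's shuffled members round-robin across folds.

    A single counter runs across classes so every fold receives objects
    even when individual classes are smaller than the fold count.
    """
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    i = 0
    for class_value in table.decision_values():
        members = table.positions(table.decision_class(class_value))
        members = members[rng.permutation(len(members))]
        for pos in members:
            folds[i % n_folds].append(int(pos))
            i += 1
    return [np.asarray(sorted(f)) for f in folds]


def cross_validate(
    table: DecisionTable,
    n_folds: int = 10,
    seed: int = 0,
    min_coverage: float = 0.0,
    keep_classes: Iterable | None = None,
) -> CrossValidationResult:
    """Stratified k-fold holdout accuracy of the induced rule classifier.

    Folds are stratified by decision class with a seeded shuffle.  Per fold,
    rules are induced on the training rows (optionally filtered with
    ``min_coverage``/``keep_classes``) and the held-out rows are classified;
    accuracy is the fraction predicted correctly.  If some training split
    would lose a decision class entirely, the offending fold is merged into
    its neighbour (with a warning) and the split is redone.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if table.n_objects < n_folds:
        raise ValueError("more folds than objects")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(table, n_folds, rng)

    # a singleton class makes one training split empty for that class; merge
    while len(folds) > 2:
        all_dec = table.frame[table.decision_attribute].to_numpy()
        bad = None
        for i, fold in enumerate(folds):
            train_mask = np.ones(table.n_objects, dtype=bool)
            train_mask[fold] = False
            if set(all_dec.tolist()) - set(all_dec[train_mask].tolist()):
                bad = i
                break
        if bad is None:
            break
        warnings.warn(
            "a training split lost a decision class; merging folds",
            stacklevel=2,
        )
        merge_into = bad - 1 if bad > 0 else 1
        folds[merge_into] = np.asarray(
            sorted(np.concatenate([folds[merge_into], folds[bad]]))
        )
        del folds[bad]

    frame = table.frame
    decision = table.decision_attribute
    accuracies = []
    for fold in folds:
        test_mask = np.zeros(table.n_objects, dtype=bool)
        test_mask[fold] = True
        train = DecisionTable(
            frame[~test_mask].reset_index(drop=True), decision=decision
        )
        rules = induce_rules(train)
        if min_coverage > 0.0 or keep_classes is not None:
            rules = filter_rules(rules, min_coverage, keep_classes)
        if not len(rules):
            # degenerate training split: fall back to the majority class
            majority = frame[~test_mask][decision].mode().iloc[0]
            rules = RuleSet(
                rules=(
                    DecisionRule(
                        conditions=(),
                        decision=majority,
                        support=int((frame[~test_mask][decision] == majority).sum()),
                        coverage=1.0,
                        certainty=1.0,
                    ),
                )
            )
        correct = 0
        for pos in fold:
            row = frame.iloc[int(pos)]
            pred = classify(
                {a: row[a] for a in table.condition_attributes}, rules
            )
            correct += pred == row[decision]
        accuracies.append(correct / len(fold))
    mean = float(np.mean(accuracies))
    return CrossValidationResult(
        n_folds=len(folds),
        per_fold_accuracy=tuple(float(a) for a in accuracies),
        mean_accuracy=mean,
        seed=seed,
    )
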