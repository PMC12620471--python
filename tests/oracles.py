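"""Independent brute-force implementations used as test oracles.

Everything here is deliberately naive — O(n^2) pairwise comparisons and
full enumerations — and shares no code with the package's implementations.
"""

from __future__ import annotations

import itertools

from roughdelphi.table import DecisionTable


def pairwise_partition(table: DecisionTable, attrs) -> list[list]:
    """Equivalence classes by O(n^2) pairwise indiscernibility checks."""
    objs = list(table.objects)
    assigned: dict = {}
    blocks: list[list] = []
    for x in objs:
        placed = False
        for block in blocks:
            rep = block[0]
            if all(table.value(x, a) == table.value(rep, a) for a in attrs):
                block.append(x)
                placed = True
                break
        if not placed:
            blocks.append([x])
        assigned[x] = True
    return blocks


def naive_approximation(table: DecisionTable, attrs, target) -> tuple[set, set]:
    """(lower, upper) by direct set comparison of every block."""
    target = set(target)
    lower: set = set()
    upper: set = set()
    for block in pairwise_partition(table, attrs):
        bset = set(block)
        if bset & target:
            upper |= bset
        if bset <= target:
            lower |= bset
    return lower, upper


def naive_gamma(table: DecisionTable, attrs) -> float:
    """Dependency degree from scratch via naive approximations."""
    total = 0
    for value in table.decision_values():
        lower, _ = naive_approximation(
            table, attrs, table.decision_class(value)
        )
        total += len(lower)
    return total / table.n_objects


def naive_reducts(table: DecisionTable) -> tuple[list[tuple], list]:
    """(reducts, core) by full subset enumeration plus a minimality filter."""
    conditions = table.condition_attributes
    gamma_full = naive_gamma(table, conditions)
    preserving = [
        combo
        for size in range(len(conditions) + 1)
        for combo in itertools.combinations(conditions, size)
        if naive_gamma(table, combo) == gamma_full
    ]
    reducts = [
        combo
        for combo in preserving
        if not any(set(o) < set(combo) for o in preserving)
    ]
    core = [
        a
        for a in conditions
        if all(a in r for r in reducts)
    ]
    return reducts, core


def minimal_certain_rules(
    table: DecisionTable, max_len: int = 3
) -> dict[object, set[tuple]]:
    """All condition-minimal certain conjunctions up to ``max_len`` literals.

    Returns, per decision class, the set of (sorted literal tuple)s whose
    matches are nonempty, lie entirely in the class, and which have no
    certain proper sub-conjunction.
    """
    frame = table.frame
    conditions = table.condition_attributes
    decision = table.decision_attribute
    values = {a: sorted(set(frame[a])) for a in conditions}

    def matches(conjunction) -> list:
        out = []
        for obj in table.objects:
            if all(table.value(obj, a) == v for a, v in conjunction):
                out.append(obj)
        return out

    certain: dict[object, set[tuple]] = {v: set() for v in table.decision_values()}
    all_certain: set[tuple] = set()
    for size in range(1, max_len + 1):
        for attr_combo in itertools.combinations(conditions, size):
            for value_combo in itertools.product(*(values[a] for a in attr_combo)):
                conj = tuple(sorted(zip(attr_combo, value_combo)))
                matched = matches(conj)
                if not matched:
                    continue
                classes = {table.value(o, decision) for o in matched}
                if len(classes) != 1:
                    continue
                sub_certain = any(
                    tuple(sorted(sub)) in all_certain
                    for k in range(1, size)
                    for sub in itertools.combinations(conj, k)
                )
                all_certain.add(conj)
                if not sub_certain:
                    certain[classes.pop()].add(conj)
    return certain
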