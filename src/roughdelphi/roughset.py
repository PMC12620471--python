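"""Classical rough-set algebra over decision tables.

Indiscernibility partitions, lower/upper approximations, accuracy and
quality of classification, the dependency degree gamma, and exhaustive
reduct/core search.  Objects that agree on every attribute of a subset B
are indiscernible under B; the equivalence classes of that relation are the
granules from which every other quantity here is assembled.

All outputs are reported in table order (objects) and input order
(attributes) so repeated runs are reproducible byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .table import DecisionTable

__all__ = [
    "Partition",
    "ApproximationResult",
    "DependencyReport",
    "ReductSet",
    "partition",
    "approximate",
    "dependency",
    "quality_of_classification",
    "find_reducts",
]

EXHAUSTIVE_ATTRIBUTE_LIMIT = 20


@dataclass(frozen=True)
class Partition:
    """Equivalence classes of the indiscernibility relation IND(B)."""

    blocks: tuple[tuple, ...]
    generated_by: tuple[str, ...]


@dataclass(frozen=True)
class ApproximationResult:
    """Lower/upper approximation of a target object set under IND(B).

    ``accuracy`` is |lower| / |upper|, defined as 1.0 for an empty target
    (vacuously exact: both approximations are empty).
    """

    target: tuple
    lower: tuple
    upper: tuple
    boundary: tuple
    accuracy: float


@dataclass(frozen=True)
class DependencyReport:
    """Dependency gamma_B(d) of the decision on an attribute subset B.

    gamma is the fraction of objects lying in the lower approximation of
    their own decision class; 1.0 means B classifies the table consistently.
    """

    attribute_subset: tuple[str, ...]
    gamma: float
    per_class_lower_sizes: dict


@dataclass(frozen=True)
class ReductSet:
    """All minimal attribute subsets preserving gamma_C(d), plus their core."""

    reducts: tuple[tuple[str, ...], ...]
    core: tuple[str, ...]
    gamma: float
    exhaustive: bool


def _block_positions(table: DecisionTable, attrs: Sequence[str]) -> list[np.ndarray]:
    """Equivalence-class positions under value agreement on ``attrs``.

    Blocks appear in order of their first object; positions within a block
    are in table order.
    """
    n = table.n_objects
    if not attrs:
        return [np.arange(n)]
    keys = np.stack([table.codes(a) for a in attrs], axis=1)
    groups: dict[tuple, list[int]] = {}
    for pos in range(n):
        groups.setdefault(tuple(keys[pos]), []).append(pos)
    return [np.asarray(v) for v in groups.values()]


def partition(table: DecisionTable, attrs: Iterable[str]) -> Partition:
    """Partition U into the equivalence classes of IND(attrs).

    The empty attribute set discerns nothing and yields the single block U.
    The decision attribute may be included (used to form decision classes).
    """
    attrs = tuple(attrs)
    table.validate_attributes(attrs, allow_decision=True)
    objs = table.objects
    blocks = tuple(
        tuple(objs[p] for p in positions)
        for positions in _block_positions(table, attrs)
    )
    return Partition(blocks=blocks, generated_by=attrs)


def approximate(
    table: DecisionTable, attrs: Iterable[str], target: Iterable
) -> ApproximationResult:
    """Lower and upper approximation of ``target`` under IND(attrs)."""
    attrs = tuple(attrs)
    table.validate_attributes(attrs, allow_decision=True)
    target = tuple(target)
    target_pos = set(table.positions(target))

    lower: set[int] = set()
    upper: set[int] = set()
    for block in _block_positions(table, attrs):
        bset = set(block.tolist())
        inter = bset & target_pos
        if inter:
            upper |= bset
            if bset <= target_pos:
                lower |= bset
    objs = table.objects
    order = lambda posset: tuple(objs[p] for p in range(len(objs)) if p in posset)
    accuracy = 1.0 if not upper else len(lower) / len(upper)
    return ApproximationResult(
        target=target,
        lower=order(lower),
        upper=order(upper),
        boundary=order(upper - lower),
        accuracy=accuracy,
    )


def _gamma(table: DecisionTable, attrs: Sequence[str]) -> tuple[float, dict]:
    """(gamma_B(d), per-class lower-approximation sizes) without validation."""
    dec = table.codes(table.decision_attribute)
    frame_dec = list(table.frame[table.decision_attribute])
    lower_sizes = {v: 0 for v in table.decision_values()}
    for block in _block_positions(table, attrs):
        codes = dec[block]
        if (codes == codes[0]).all():
            # block is pure: contributes to the lower approximation
            value = frame_dec[int(block[0])]
            lower_sizes[value] += len(block)
    gamma = sum(lower_sizes.values()) / table.n_objects
    return gamma, lower_sizes


def dependency(table: DecisionTable, attrs: Iterable[str]) -> DependencyReport:
    """Dependency degree gamma_B(d) of the decision attribute on B ⊆ C."""
    attrs = tuple(attrs)
    table.validate_attributes(attrs, allow_decision=False)
    gamma, lower_sizes = _gamma(table, attrs)
    return DependencyReport(
        attribute_subset=attrs, gamma=gamma, per_class_lower_sizes=lower_sizes
    )


def quality_of_classification(table: DecisionTable) -> float:
    """gamma_C(d): the quality of classification under all conditions."""
    return dependency(table, table.condition_attributes).gamma


def find_reducts(
    table: DecisionTable, allow_heuristic: bool = False
) -> ReductSet:
    """All minimal attribute subsets B with gamma_B(d) = gamma_C(d).

    Exhaustive lattice search (smallest subsets first, pruning supersets of
    found reducts) up to 20 condition attributes.  Beyond that the search
    space is too large; pass ``allow_heuristic=True`` for a greedy backward
    elimination that returns a single (not necessarily minimal-cardinality,
    clearly flagged non-exhaustive) reduct.

    The core — attributes indispensable for the dependency — is the
    intersection of all reducts and may be empty.
    """
    conditions = table.condition_attributes
    gamma_full, _ = _gamma(table, conditions)

    if len(conditions) > EXHAUSTIVE_ATTRIBUTE_LIMIT:
        if not allow_heuristic:
            raise ValueError(
                f"{len(conditions)} condition attributes exceed the exhaustive "
                f"search bound ({EXHAUSTIVE_ATTRIBUTE_LIMIT}); rerun with "
                f"allow_heuristic=True for greedy backward elimination"
            )
        kept = list(conditions)
        for attr in conditions:
            trial = [a for a in kept if a != attr]
            if trial and _gamma(table, trial)[0] == gamma_full:
                kept = trial
        reducts = (tuple(kept),)
        return ReductSet(
            reducts=reducts, core=tuple(kept), gamma=gamma_full, exhaustive=False
        )

    reducts: list[tuple[str, ...]] = []
    for size in range(0, len(conditions) + 1):
        for combo in itertools.combinations(conditions, size):
            combo_set = set(combo)
            if any(set(r) <= combo_set for r in reducts):
                continue  # proper superset of a known reduct: not minimal
            if _gamma(table, combo)[0] == gamma_full:
                reducts.append(combo)
    core_set = set(conditions)
    for r in reducts:
        core_set &= set(r)
    core = tuple(a for a in conditions if a in core_set)
    return ReductSet(
        reducts=tuple(reducts), core=core, gamma=gamma_full, exhaustive=True
    )
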