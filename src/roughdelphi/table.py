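"""Decision tables: the information system S = (U, C ∪ {d}, V, f).

A :class:`DecisionTable` is a complete categorical data matrix: a finite
ordered object set U, an ordered set of condition attributes C, and one
decision attribute d.  Values are compared by equality only (classical
indiscernibility); ordinal Likert codes are treated as categories.
Missing cells are rejected at load.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DecisionTable", "read_isf", "write_isf"]


class DecisionTable:
    """An information system with one decision attribute.

    Parameters
    ----------
    frame:
        One row per object; columns are the condition attributes plus the
        decision attribute.  The index holds object identifiers (a default
        RangeIndex is relabelled ``o1..oN``).
    decision:
        Name of the decision column.  Defaults to the last column.
    """

    def __init__(self, frame: pd.DataFrame, decision: str | None = None):
        if frame.empty or frame.shape[1] < 2:
            raise ValueError("a decision table needs >=1 object and >=2 columns")
        if frame.isna().any().any():
            bad = frame[frame.isna().any(axis=1)]
            raise ValueError(
                f"decision table has missing cells in rows: {list(bad.index)}"
            )
        if decision is None:
            decision = str(frame.columns[-1])
        if decision not in frame.columns:
            raise KeyError(f"decision attribute {decision!r} not in columns")
        frame = frame.copy()
        if isinstance(frame.index, pd.RangeIndex):
            frame.index = [f"o{i + 1}" for i in range(len(frame))]
        if frame.index.has_duplicates:
            raise ValueError("duplicate object identifiers")
        self._frame = frame
        self._decision = decision
        self._conditions = tuple(str(c) for c in frame.columns if c != decision)
        # integer codes per attribute for fast grouping
        self._codes: dict[str, np.ndarray] = {}
        for col in frame.columns:
            codes, _ = pd.factorize(frame[col], use_na_sentinel=False)
            self._codes[str(col)] = codes.astype(np.int64)

    # -- basic accessors ---------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def objects(self) -> tuple:
        return tuple(self._frame.index)

    @property
    def n_objects(self) -> int:
        return len(self._frame)

    @property
    def condition_attributes(self) -> tuple[str, ...]:
        return self._conditions

    @property
    def decision_attribute(self) -> str:
        return self._decision

    def value(self, obj, attribute: str):
        return self._frame.at[obj, attribute]

    def decision_values(self) -> list:
        """Distinct decision values, in order of first appearance."""
        return list(dict.fromkeys(self._frame[self._decision]))

    def decision_class(self, value) -> tuple:
        """Objects carrying the given decision value, in table order."""
        mask = self._frame[self._decision] == value
        return tuple(self._frame.index[mask])

    def codes(self, attribute: str) -> np.ndarray:
        """Integer value codes for one attribute (internal fast path)."""
        return self._codes[attribute]

    def positions(self, objs: Iterable) -> np.ndarray:
        idx = self._frame.index.get_indexer(list(objs))
        if (idx < 0).any():
            missing = [o for o, i in zip(objs, idx) if i < 0]
            raise KeyError(f"unknown objects: {missing}")
        return idx

    def validate_attributes(self, attrs: Sequence[str], allow_decision: bool = False):
        allowed = set(self._conditions)
        if allow_decision:
            allowed.add(self._decision)
        unknown = [a for a in attrs if a not in allowed]
        if unknown:
            raise KeyError(f"unknown attributes: {unknown}")

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, decision: str | None = None) -> "DecisionTable":
        return cls(pd.read_csv(path), decision=decision)

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DecisionTable({self.n_objects} objects, "
            f"{len(self._conditions)} conditions, "
            f"decision={self._decision!r})"
        )


def read_isf(path) -> DecisionTable:
    """Read a decision table in the ISF dialect used by rough-set tools.

    Layout::

        **ATTRIBUTES
        attr: [v1, v2, ...]
        ...
        decision: attr_name
        **EXAMPLES
        v v v ... v
        **END
    """
    attrs: list[str] = []
    decision: str | None = None
    rows: list[list[int]] = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            upper = line.upper()
            if upper.startswith("**ATTRIBUTES"):
                section = "attributes"
                continue
            if upper.startswith("**EXAMPLES"):
                section = "examples"
                continue
            if upper.startswith("**END"):
                break
            if section == "attributes":
                name, _, rest = line.partition(":")
                name = name.strip()
                rest = rest.strip()
                if name.lower() == "decision":
                    decision = rest
                else:
                    attrs.append(name)
            elif section == "examples":
                rows.append([int(tok) for tok in line.replace(",", " ").split()])
    if decision is None:
        raise ValueError("ISF file does not declare a decision attribute")
    if decision not in attrs:
        raise ValueError(f"decision {decision!r} not among declared attributes")
    frame = pd.DataFrame(rows, columns=attrs)
    return DecisionTable(frame, decision=decision)


def write_isf(table: DecisionTable, path) -> None:
    """Write a decision table in the ISF dialect (see :func:`read_isf`)."""
    with open(path, "w") as fh:
        fh.write("**ATTRIBUTES\n")
        for attr in (*table.condition_attributes, table.decision_attribute):
            values = sorted(set(table.frame[attr]))
            joined = ", ".join(str(v) for v in values)
            fh.write(f"{attr}: [{joined}]\n")
        fh.write(f"decision: {table.decision_attribute}\n")
        fh.write("**EXAMPLES\n")
        for _, row in table.frame.iterrows():
            fh.write(" ".join(str(v) for v in row) + "\n")
        fh.write("**END\n")
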