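"""Fuzzy Delphi consensus screening with double triangular fuzzy numbers.

Each expert scores every candidate criterion twice on a 1-10 scale: a
conservative score C (the lowest importance they would defend) and an
optimistic score O (the highest).  Per criterion the two score series are
trimmed of outliers, summarised as triangular fuzzy numbers
(min, geometric mean, max), and the overlap between the conservative and
optimistic fuzzy numbers is examined.  When the expert panel converges, a
defuzzified consensus value G is computed and compared against a retention
threshold (7 out of 10 by default); criteria at or above the threshold are
kept as antecedent conditions for the downstream configurational analysis.

The convergence test is the gray-zone criterion for double triangular
fuzzy numbers: with Z = C_U - O_L (the gray zone) and M = O_M - C_M (the
gap between the two modes),

* C_U < O_L      -> full overlap; G = (C_M + O_M) / 2
* Z <= M         -> acceptable partial overlap;
                    G = (C_U * O_M - O_L * C_M) / ((C_U - C_M) + (O_M - O_L))
* otherwise      -> no consensus; the criterion is flagged for a second
                    survey round rather than scored.

At the branch boundary C_U = O_L = k the partial-overlap formula reduces
algebraically to k, which is the behaviour required of a consensus score
when the conservative maximum meets the optimistic minimum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCORE_MIN = 1.0
SCORE_MAX = 10.0
DEFAULT_THRESHOLD = 7.0
# a consensus value equal to the threshold retains the criterion; the
# comparison allows for float round-off in the gray-zone quotient so a
# boundary case that is exactly the threshold in exact arithmetic retains
RETENTION_TOLERANCE = 1e-9

__all__ = [
    "PanelError",
    "DegeneratePanelError",
    "TriangularFuzzyNumber",
    "GrayZoneResult",
    "CriterionConsensus",
    "ExpertPanel",
    "trim_outliers",
    "build_tfn",
    "consensus_value",
    "consensus_from_params",
    "screen_criteria",
    "consensus_report",
    "screening_summary",
]


class PanelError(ValueError):
    """An expert panel violates a structural precondition."""


class DegeneratePanelError(PanelError):
    """Both fuzzy numbers collapse so that the gray-zone formula is 0/0-free
    in the denominator but not the numerator; no consensus value exists."""


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A triangular fuzzy number (low, mode, high) with low <= mode <= high."""

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mode <= self.high):
            raise ValueError(
                f"invalid triangular fuzzy number: "
                f"({self.low}, {self.mode}, {self.high})"
            )


@dataclass(frozen=True)
class GrayZoneResult:
    """Outcome of the convergence test for one criterion.

    ``consensus`` is ``None`` when the panel did not converge.
    """

    gray_zone: float
    mode_gap: float
    converged: bool
    consensus: float | None


@dataclass(frozen=True)
class CriterionConsensus:
    """Full per-criterion screening record."""

    criterion_id: str
    conservative_tfn: TriangularFuzzyNumber
    optimistic_tfn: TriangularFuzzyNumber
    gray_zone: float
    mode_gap: float
    converged: bool
    consensus: float | None
    retained: bool
    n_used_conservative: int
    n_used_optimistic: int


def trim_outliers(scores: Sequence[float]) -> list[float]:
    """Drop scores farther than two sample standard deviations from the mean.

    A single pass: the mean and sd (n-1 denominator) are computed once on the
    full series and every score with ``|x - mean| <= 2 * sd`` is kept, in the
    original order.  A zero-variance series is returned unchanged.
    """
    vals = [float(s) for s in scores]
    if len(vals) < 2:
        raise PanelError(f"need at least 2 scores to trim, got {len(vals)}")
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return vals
    mean = float(arr.mean())
    return [v for v in vals if abs(v - mean) <= 2.0 * sd]


def build_tfn(
    scores: Sequence[float], central: str = "geometric"
) -> TriangularFuzzyNumber:
    """Summarise a score series as (min, central tendency, max).

    ``central`` selects the mode statistic: ``"geometric"`` (the default,
    requiring strictly positive scores) or ``"arithmetic"``.  By the AM-GM
    inequality the geometric mode never exceeds the arithmetic mean.
    """
    vals = [float(s) for s in scores]
    if not vals:
        raise PanelError("cannot build a fuzzy number from an empty series")
    if central == "geometric":
        if any(v <= 0 for v in vals):
            raise PanelError("geometric mean requires strictly positive scores")
        mode = float(np.exp(np.mean(np.log(vals))))
    elif central == "arithmetic":
        mode = float(np.mean(vals))
    else:
        raise ValueError(f"unknown central statistic {central!r}")
    lo, hi = min(vals), max(vals)
    # guard against floating round-off pushing the mode a ulp outside [lo, hi]
    mode = min(max(mode, lo), hi)
    return TriangularFuzzyNumber(lo, mode, hi)


def consensus_from_params(
    c_u: float, o_l: float, c_m: float, o_m: float
) -> GrayZoneResult:
    """Convergence test and consensus value from the four defining scores.

    ``c_u``/``c_m`` are the upper bound and mode of the conservative fuzzy
    number, ``o_l``/``o_m`` the lower bound and mode of the optimistic one.
    """
    gray_zone = c_u - o_l
    mode_gap = o_m - c_m
    if c_u < o_l:
        return GrayZoneResult(gray_zone, mode_gap, True, (c_m + o_m) / 2.0)
    if gray_zone <= mode_gap:
        denom = (c_u - c_m) + (o_m - o_l)
        numer = c_u * o_m - o_l * c_m
        if denom == 0.0:
            if numer == 0.0:
                # both fuzzy numbers are the same point mass k; G = k
                return GrayZoneResult(
                    gray_zone, mode_gap, True, (c_m + o_m) / 2.0
                )
            raise DegeneratePanelError(
                "gray-zone consensus undefined: C_U = C_M and O_M = O_L"
            )
        return GrayZoneResult(gray_zone, mode_gap, True, numer / denom)
    return GrayZoneResult(gray_zone, mode_gap, False, None)


def consensus_value(
    conservative_tfn: TriangularFuzzyNumber,
    optimistic_tfn: TriangularFuzzyNumber,
) -> GrayZoneResult:
    """Convergence test for a (conservative, optimistic) fuzzy-number pair."""
    return consensus_from_params(
        conservative_tfn.high,
        optimistic_tfn.low,
        conservative_tfn.mode,
        optimistic_tfn.mode,
    )


class ExpertPanel:
    """Long-form panel of expert interval judgments.

    One row per expert x criterion with a conservative and an optimistic
    score, both on the 1-10 scale with conservative <= optimistic.  Invalid
    rows are rejected at construction with a listing of the offenders.
    """

    REQUIRED_COLUMNS = ("expert_id", "criterion_id", "conservative", "optimistic")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise PanelError(f"panel is missing columns: {missing}")
        frame = frame.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        if frame[["conservative", "optimistic"]].isna().any().any():
            raise PanelError("panel contains missing scores")
        frame["conservative"] = frame["conservative"].astype(float)
        frame["optimistic"] = frame["optimistic"].astype(float)
        bad_range = frame[
            (frame["conservative"] < SCORE_MIN)
            | (frame["conservative"] > SCORE_MAX)
            | (frame["optimistic"] < SCORE_MIN)
            | (frame["optimistic"] > SCORE_MAX)
        ]
        if not bad_range.empty:
            raise PanelError(
                "scores outside the 1-10 scale in rows:\n"
                + bad_range.to_string()
            )
        inverted = frame[frame["conservative"] > frame["optimistic"]]
        if not inverted.empty:
            raise PanelError(
                "conservative score exceeds optimistic score in rows:\n"
                + inverted.to_string()
            )
        self._frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "ExpertPanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def criteria(self) -> list[str]:
        """Criterion ids in order of first appearance."""
        return list(dict.fromkeys(self._frame["criterion_id"]))

    def scores(self, criterion_id: str) -> tuple[list[float], list[float]]:
        rows = self._frame[self._frame["criterion_id"] == criterion_id]
        if rows.empty:
            raise KeyError(criterion_id)
        return list(rows["conservative"]), list(rows["optimistic"])

    def subset(self, criteria: Iterable[str]) -> "ExpertPanel":
        keep = set(criteria)
        return ExpertPanel(
            self._frame[self._frame["criterion_id"].isin(keep)]
        )


def screen_criteria(
    panel: ExpertPanel,
    threshold: float = DEFAULT_THRESHOLD,
    central: str = "geometric",
) -> list[CriterionConsensus]:
    """Screen every criterion of a panel against the retention threshold.

    Per criterion the conservative and optimistic series are trimmed
    separately (two-sd rule), summarised as fuzzy numbers, and put through
    the convergence test.  ``retained`` is true iff the panel converged and
    G >= threshold (a tie at the threshold retains).  Non-convergent
    criteria are reported with ``converged=False``, never dropped.
    """
    results: list[CriterionConsensus] = []
    for criterion in panel.criteria:
        cons_raw, opt_raw = panel.scores(criterion)
        cons = trim_outliers(cons_raw)
        opt = trim_outliers(opt_raw)
        if len(cons) < 2 or len(opt) < 2:
            raise PanelError(
                f"criterion {criterion!r} has fewer than 2 scores after trimming"
            )
        cons_tfn = build_tfn(cons, central=central)
        opt_tfn = build_tfn(opt, central=central)
        gz = consensus_value(cons_tfn, opt_tfn)
        retained = bool(
            gz.converged
            and gz.consensus is not None
            and gz.consensus >= threshold - RETENTION_TOLERANCE
        )
        results.append(
            CriterionConsensus(
                criterion_id=criterion,
                conservative_tfn=cons_tfn,
                optimistic_tfn=opt_tfn,
                gray_zone=gz.gray_zone,
                mode_gap=gz.mode_gap,
                converged=gz.converged,
                consensus=gz.consensus,
                retained=retained,
                n_used_conservative=len(cons),
                n_used_optimistic=len(opt),
            )
        )
    return results


def consensus_report(results: Sequence[CriterionConsensus]) -> pd.DataFrame:
    """Tabulate screening results (scores rounded to 4 decimals)."""
    rows = []
    for r in results:
        rows.append(
            {
                "criterion_id": r.criterion_id,
                "C_L": round(r.conservative_tfn.low, 4),
                "C_M": round(r.conservative_tfn.mode, 4),
                "C_U": round(r.conservative_tfn.high, 4),
                "O_L": round(r.optimistic_tfn.low, 4),
                "O_M": round(r.optimistic_tfn.mode, 4),
                "O_U": round(r.optimistic_tfn.high, 4),
                "Z": round(r.gray_zone, 4),
                "M": round(r.mode_gap, 4),
                "converged": r.converged,
                "G": round(r.consensus, 4) if r.consensus is not None else None,
                "retained": r.retained,
            }
        )
    return pd.DataFrame(rows)


def screening_summary(results: Sequence[CriterionConsensus]) -> dict:
    """Summary listing retained, excluded and non-convergent criteria."""
    return {
        "n_criteria": len(results),
        "retained": [r.criterion_id for r in results if r.retained],
        "excluded": [
            r.criterion_id for r in results if r.converged and not r.retained
        ],
        "needs_resurvey": [r.criterion_id for r in results if not r.converged],
    }
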