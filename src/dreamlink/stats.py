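"""Outcome aggregation, inter-rater agreement, and chance-level analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import scipy.stats

from .consensus import Outcome, OutcomeCategory

__all__ = [
    "OutcomeCounts",
    "SessionSummary",
    "ContingencyTable2x2",
    "ChanceReport",
    "round1",
    "tally",
    "summarize",
    "fleiss_kappa",
    "fisher_exact",
    "chance_analyses",
]


def round1(x: float) -> float:
    """Round half-up to one decimal (table formatting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OutcomeCounts:
    """Per-task outcome counts with derived percentages."""

    n_trials: int
    correct: int
    incorrect: int
    ambiguous: int
    no_response: int

    def __post_init__(self) -> None:
        parts = self.correct + self.incorrect + self.ambiguous + self.no_response
        if parts != self.n_trials:
            raise ValueError(f"outcome counts sum to {parts}, not n_trials={self.n_trials}")
        if min(self.correct, self.incorrect, self.ambiguous, self.no_response) < 0:
            raise ValueError("counts must be non-negative")

    def pct(self, which: str) -> float:
        if self.n_trials == 0:
            return 0.0
        return round1(100.0 * getattr(self, which) / self.n_trials)

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(
            self.n_trials + other.n_trials,
            self.correct + other.correct,
            self.incorrect + other.incorrect,
            self.ambiguous + other.ambiguous,
            self.no_response + other.no_response,
        )

    @property
    def responses(self) -> int:
        """Any detectable response: correct + incorrect + ambiguous."""
        return self.correct + self.incorrect + self.ambiguous


@dataclass(frozen=True)
class SessionSummary:
    rows: tuple[tuple[str, OutcomeCounts], ...]
    total: Optional[OutcomeCounts]

    def row(self, key: str) -> OutcomeCounts:
        for k, v in self.rows:
            if k == key:
                return v
        raise KeyError(key)


def tally(outcomes: Iterable[Union[Outcome, OutcomeCategory]]) -> OutcomeCounts:
    """Count gated outcomes into one row (excluded trials are skipped)."""
    c = i = a = n = 0
    for o in outcomes:
        if isinstance(o, Outcome):
            if not o.counted:
                continue
            cat = o.category
        else:
            cat = o
        if cat is OutcomeCategory.CORRECT:
            c += 1
        elif cat is OutcomeCategory.INCORRECT:
            i += 1
        elif cat is OutcomeCategory.AMBIGUOUS:
            a += 1
        else:
            n += 1
    return OutcomeCounts(c + i + a + n, c, i, a, n)


def summarize(rows: Mapping[str, OutcomeCounts]) -> SessionSummary:
    """Per-task rows plus a total row; empty input yields an empty summary."""
    items = tuple(rows.items())
    if not items:
        return SessionSummary((), None)
    total = items[0][1]
    for _, counts in items[1:]:
        total = total + counts
    return SessionSummary(items, total)


def fleiss_kappa(rating_matrix: Sequence[Sequence[int]]) -> float:
    """Fleiss' kappa for a subjects x categories count matrix.

    Every subject must be rated by the same number of raters. Degenerate
    case: if expected chance agreement is 1 (all ratings in one category),
    kappa is defined as 1.0 when observed agreement is also perfect.
    """
    m = np.asarray(rating_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 subjects")
    n_raters = m.sum(axis=1)
    if not np.all(n_raters == n_raters[0]):
        raise ValueError("every subject must have the same number of ratings")
    n = float(n_raters[0])
    if n < 2:
        raise ValueError("need at least 2 raters")
    n_subjects = m.shape[0]

    p_i = ((m**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = m.sum(axis=0) / (n_subjects * n)
    p_e = float((p_j**2).sum())
    if p_e == 1.0:
        if p_bar == 1.0:
            return 1.0
        raise ValueError("degenerate category distribution with imperfect agreement")
    return (p_bar - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(
    table: Union[ContingencyTable2x2, Sequence[Sequence[int]]],
    sided: str = "greater",
) -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    Defaults to one-sided ("greater": the first row's first-column rate
    exceeds the second row's), matching the directional chance analyses.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    return float(scipy.stats.fisher_exact(arr, alternative=sided)[1])


@dataclass(frozen=True)
class ChanceReport:
    lucid_table: ContingencyTable2x2
    lucid_vs_nonlucid_p: float
    sham_table: Optional[ContingencyTable2x2]
    stimulation_vs_sham_p: Optional[float]
    response_definition: str


def chance_analyses(
    lucid_trials: OutcomeCounts,
    nonlucid_trials: OutcomeCounts,
    sham_blocks: Optional[tuple[int, int]] = None,
    stim_contraction_counts: Optional[tuple[int, int]] = None,
    response_definition: str = "any",
) -> ChanceReport:
    """Build both chance-control contingency tables and their Fisher p-values.

    ``sham_blocks`` is (n_sham_markers, n_sham_contractions);
    ``stim_contraction_counts`` is (n_responses, n_trials) for the stimulated
    condition of the facial task. ``response_definition``: "any" counts
    correct+incorrect+ambiguous as responses; "correct_only" counts only
    correct ones.
    """

    def _resp(counts: OutcomeCounts) -> int:
        return counts.correct if response_definition == "correct_only" else counts.responses

    lucid_table = ContingencyTable2x2(
        _resp(lucid_trials),
        lucid_trials.n_trials - _resp(lucid_trials),
        _resp(nonlucid_trials),
        nonlucid_trials.n_trials - _resp(nonlucid_trials),
    )
    p1 = fisher_exact(lucid_table, sided="greater")

    sham_table = None
    p2 = None
    if sham_blocks is not None and stim_contraction_counts is not None:
        n_markers, n_sham_responses = sham_blocks
        n_stim_responses, n_stim_trials = stim_contraction_counts
        sham_table = ContingencyTable2x2(
            n_stim_responses,
            n_stim_trials - n_stim_responses,
            n_sham_responses,
            n_markers - n_sham_responses,
        )
        p2 = fisher_exact(sham_table, sided="greater")

    return ChanceReport(lucid_table, p1, sham_table, p2, response_definition)
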