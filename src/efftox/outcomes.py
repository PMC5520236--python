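"""Compact outcome nomenclature for phase I/II dose-finding paths.

Each patient experiences exactly one of four outcomes:

* ``E`` — efficacy without toxicity, (a, b) = (1, 0)
* ``T`` — toxicity without efficacy, (a, b) = (0, 1)
* ``B`` — both, (1, 1)
* ``N`` — neither, (0, 0)

A cohort's outcomes are written as the dose level followed by one symbol
per patient, e.g. ``2EET`` for a cohort of three at dose 2; cohorts are
concatenated with whitespace, e.g. ``"2EET 3EBB"``. Per-patient (a, b)
pairs are preserved — ``3NTE`` and ``3NNB`` tally the same events but
are different data, because efficacy and toxicity may be associated
within a patient.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, NamedTuple

__all__ = [
    "PatientRecord",
    "CohortOutcome",
    "OutcomePathError",
    "SYMBOL_TO_AB",
    "AB_TO_SYMBOL",
    "parse_path",
    "format_path",
    "to_patient_records",
    "enumerate_cohort_outcomes",
]

#: canonical within-cohort symbol order (exchangeable patients)
SYMBOL_ORDER = "NETB"

SYMBOL_TO_AB: dict[str, tuple[int, int]] = {
    "N": (0, 0),
    "E": (1, 0),
    "T": (0, 1),
    "B": (1, 1),
}
AB_TO_SYMBOL: dict[tuple[int, int], str] = {v: k for k, v in SYMBOL_TO_AB.items()}

_RANK = {s: i for i, s in enumerate(SYMBOL_ORDER)}
_TOKEN_RE = re.compile(r"^(\d+)([A-Za-z]+)$")


class PatientRecord(NamedTuple):
    """One patient's dose assignment and binary outcomes."""

    dose_level: int  # 1-based index into the dose grid
    efficacy: int  # a
    toxicity: int  # b


class OutcomePathError(ValueError):
    """Malformed outcome path string; carries the offending token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (token {position})")
        self.position = position


def canonical_symbols(symbols: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(symbols, key=_RANK.__getitem__))


@dataclass(frozen=True)
class CohortOutcome:
    """Outcomes of one cohort: dose level plus a multiset of symbols."""

    dose_level: int
    outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.dose_level < 1:
            raise ValueError("dose_level must be >= 1")
        if not self.outcomes:
            raise ValueError("a cohort must contain at least one patient")
        for s in self.outcomes:
            if s not in SYMBOL_TO_AB:
                raise ValueError(f"unknown outcome symbol {s!r}")
        object.__setattr__(self, "outcomes", canonical_symbols(self.outcomes))

    def __str__(self) -> str:
        return f"{self.dose_level}{''.join(self.outcomes)}"


def parse_path(text: str, n_doses: int | None = None) -> list[CohortOutcome]:
    """Parse an outcome path string into cohorts.

    ``"2EET 3EBB"`` parses to two cohorts; symbols within a cohort are
    canonicalised to the order N < E < T < B. When ``n_doses`` is given,
    dose prefixes are validated against the grid size.
    """
    cohorts: list[CohortOutcome] = []
    for pos, token in enumerate(text.split(), start=1):
        m = _TOKEN_RE.match(token)
        if m is None:
            if token[0].isdigit():
                raise OutcomePathError(f"malformed token {token!r}", pos)
            raise OutcomePathError(f"missing dose prefix in token {token!r}", pos)
        dose = int(m.group(1))
        symbols = m.group(2).upper()
        bad = [s for s in symbols if s not in SYMBOL_TO_AB]
        if bad:
            raise OutcomePathError(f"unknown symbol {bad[0]!r} in token {token!r}", pos)
        if dose < 1 or (n_doses is not None and dose > n_doses):
            raise OutcomePathError(f"dose level {dose} outside grid in token {token!r}", pos)
        cohorts.append(CohortOutcome(dose_level=dose, outcomes=tuple(symbols)))
    return cohorts


def format_path(cohorts: Iterable[CohortOutcome]) -> str:
    """Format cohorts back to the canonical path string."""
    return " ".join(str(c) for c in cohorts)


def to_patient_records(path: Iterable[CohortOutcome]) -> list[PatientRecord]:
    """Expand cohorts to one :class:`PatientRecord` per symbol."""
    records: list[PatientRecord] = []
    for cohort in path:
        for s in cohort.outcomes:
            a, b = SYMBOL_TO_AB[s]
            records.append(PatientRecord(cohort.dose_level, a, b))
    return records


def records_to_path(records: Iterable[PatientRecord], cohort_size: int) -> str:
    """Group consecutive records into cohorts of ``cohort_size`` and format."""
    records = list(records)
    cohorts = []
    for i in range(0, len(records), cohort_size):
        chunk = records[i : i + cohort_size]
        doses = {r.dose_level for r in chunk}
        if len(doses) != 1:
            raise ValueError("records within a cohort must share one dose")
        symbols = tuple(AB_TO_SYMBOL[(r.efficacy, r.toxicity)] for r in chunk)
        cohorts.append(CohortOutcome(dose_level=chunk[0].dose_level, outcomes=symbols))
    return format_path(cohorts)


def enumerate_cohort_outcomes(cohort_size: int) -> list[tuple[str, ...]]:
    """All distinct outcome multisets for one cohort, in canonical order.

    With 4 patient outcomes the count is C(cohort_size + 3, 3); for
    cohorts of three that is 20, from NNN through BBB.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    return [tuple(c) for c in combinations_with_replacement(SYMBOL_ORDER, cohort_size)]
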