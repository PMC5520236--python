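"""Whole-trial simulation and operating characteristics.

Given assumed true efficacy/toxicity probabilities per dose, the
simulator runs the adaptive design end to end — cohort by cohort, with
a fresh posterior computation and dose decision after every cohort —
and aggregates, over many replicated trials, the probability each dose
is finally selected, the probability of stopping with no selection, and
the mean number of patients allocated per dose.

Per-patient outcomes are generated from the scenario's marginal
probabilities; efficacy and toxicity are independent by default, with
an optional odds-style association on the same tanh(psi/2) scale the
inference model uses. Per-replication seeds derive deterministically
from the master seed via ``numpy.random.SeedSequence(seed,
spawn_key=(i,))``, so results are independent of execution order and
parallelism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DegenerateWeightsWarning, EffToxDesign, EffToxModel, _joint_cell, recommend_dose
from .outcomes import PatientRecord, records_to_path

__all__ = [
    "ScenarioSpec",
    "TrialRecord",
    "OperatingCharacteristics",
    "simulate_patient",
    "run_trial",
    "operating_characteristics",
    "summarise_correct_decision",
    "replication_seed",
]

#: importance draws per dose decision inside simulated trials (a
#: speed/precision trade-off for thousands of replications; interactive
#: fits default to 100,000)
SIM_N_SAMPLES = 10_000


@dataclass(frozen=True)
class ScenarioSpec:
    """Assumed true dose-outcome probabilities for simulation."""

    true_eff: tuple[float, ...]
    true_tox: tuple[float, ...]
    true_association: float = 0.0  # psi-style; 0 means independent outcomes
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.true_eff) != len(self.true_tox):
            raise ValueError("true_eff and true_tox must have equal length")
        for v in (*self.true_eff, *self.true_tox):
            if not 0.0 <= v <= 1.0:
                raise ValueError("scenario probabilities must be in [0, 1]")

    @property
    def n_doses(self) -> int:
        return len(self.true_eff)

    def cell_probs(self, dose_level: int) -> np.ndarray:
        """Joint probabilities of (a, b) in order N, E, T, B."""
        pe = self.true_eff[dose_level - 1]
        pt = self.true_tox[dose_level - 1]
        psi = self.true_association
        cells = np.array(
            [
                _joint_cell(pe, pt, psi, 0, 0),
                _joint_cell(pe, pt, psi, 1, 0),
                _joint_cell(pe, pt, psi, 0, 1),
                _joint_cell(pe, pt, psi, 1, 1),
            ]
        )
        return np.clip(cells, 0.0, 1.0)


_AB = [(0, 0), (1, 0), (0, 1), (1, 1)]  # N, E, T, B


def simulate_patient(
    dose_level: int, scenario: ScenarioSpec, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw one patient's (efficacy, toxicity) outcomes at a dose."""
    if not 1 <= dose_level <= scenario.n_doses:
        raise ValueError(f"dose_level {dose_level} outside scenario")
    cells = scenario.cell_probs(dose_level)
    idx = rng.choice(4, p=cells / cells.sum())
    return _AB[idx]


@dataclass
class TrialRecord:
    """Result of one simulated trial."""

    selection: int | None  # final recommended dose; None means stopped/no dose
    stopped_early: bool
    path: str
    allocation: tuple[int, ...]  # patients per dose
    n_patients: int


def run_trial(
    design: EffToxDesign,
    scenario: ScenarioSpec,
    seed: int | None = None,
    n_samples: int = SIM_N_SAMPLES,
) -> TrialRecord:
    """Simulate one complete trial under the design and scenario.

    Cohorts are dosed per the design's recommendations starting at the
    start dose; the trial ends at a stop decision or at the maximum
    sample size (a final partial cohort is allowed). The selection is
    the dose recommended after all patients are treated and assessed.
    """
    if scenario.n_doses != design.n_doses:
        raise ValueError("scenario length must match the design's dose grid")
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    dose = design.start_dose
    selection: int | None = None
    stopped = False
    while len(records) < design.max_patients:
        m = min(design.cohort_size, design.max_patients - len(records))
        for _ in range(m):
            a, b = simulate_patient(dose, scenario, rng)
            records.append(PatientRecord(dose, a, b))
        model = EffToxModel(design, records)
        rec = recommend_dose(
            model, seed=int(rng.integers(2**31)), n_samples=n_samples
        )
        if rec.stop:
            stopped = True
            selection = None
            break
        selection = rec.dose_level
        dose = rec.dose_level
    allocation = tuple(
        sum(1 for r in records if r.dose_level == d) for d in range(1, design.n_doses + 1)
    )
    return TrialRecord(
        selection=selection,
        stopped_early=stopped,
        path=records_to_path(records, design.cohort_size),
        allocation=allocation,
        n_patients=len(records),
    )


def replication_seed(master_seed: int, i: int) -> int:
    """Deterministic, order-invariant seed for replication ``i``."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(i,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class OperatingCharacteristics:
    """Aggregate behaviour of a design under one scenario."""

    scenario: ScenarioSpec
    selection_probs: tuple[float, ...]  # per dose
    stop_prob: float
    mean_allocation: tuple[float, ...]  # mean patients per dose
    mean_n_patients: float
    replications: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """One-row-per-dose table in the style of published OC tables."""
        n = len(self.selection_probs)
        frame = pd.DataFrame(
            {
                "dose_level": list(range(1, n + 1)) + ["stop"],
                "true_eff": list(self.scenario.true_eff) + [np.nan],
                "true_tox": list(self.scenario.true_tox) + [np.nan],
                "selection_prob": list(self.selection_probs) + [self.stop_prob],
                "mean_allocation": list(self.mean_allocation) + [np.nan],
            }
        )
        frame.insert(0, "scenario", self.scenario.label)
        return frame


def operating_characteristics(
    design: EffToxDesign,
    scenario: ScenarioSpec,
    replications: int = 1000,
    seed: int = 0,
    n_samples: int = SIM_N_SAMPLES,
    workers: int = 1,
) -> OperatingCharacteristics:
    """Replicate :func:`run_trial` and aggregate selection and allocation.

    Replication ``i`` always uses :func:`replication_seed` (master seed,
    i), so the aggregate is invariant to execution order and to
    ``workers``; selection probabilities and the stop probability sum to
    1 up to rounding.
    """
    if replications < 100:
        raise ValueError("replications must be >= 100")

    def one(i: int) -> TrialRecord:
        # weight-degeneracy warnings are expected occasionally across
        # thousands of replicated decisions and are not actionable here
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateWeightsWarning)
            return run_trial(design, scenario, seed=replication_seed(seed, i), n_samples=n_samples)

    if workers > 1:
        from joblib import Parallel, delayed  # optional; sequential path needs no extra dep

        trials = Parallel(n_jobs=workers)(delayed(one)(i) for i in range(replications))
    else:
        trials = [one(i) for i in range(replications)]

    n_doses = design.n_doses
    sel = np.zeros(n_doses)
    stop = 0
    alloc = np.zeros(n_doses)
    total = 0.0
    for t in trials:
        if t.selection is None:
            stop += 1
        else:
            sel[t.selection - 1] += 1
        alloc += np.asarray(t.allocation)
        total += t.n_patients
    return OperatingCharacteristics(
        scenario=scenario,
        selection_probs=tuple(float(v) for v in sel / replications),
        stop_prob=stop / replications,
        mean_allocation=tuple(float(v) for v in alloc / replications),
        mean_n_patients=total / replications,
        replications=replications,
        seed=seed,
    )


def summarise_correct_decision(
    oc_list: Sequence[OperatingCharacteristics],
    correct: Sequence[int | str],
) -> float:
    """Mean probability of the correct action across scenarios.

    ``correct`` holds, per scenario, a 1-based dose level or ``"stop"``.
    """
    if len(oc_list) != len(correct):
        raise ValueError("oc_list and correct must have equal length")
    probs = []
    for oc, action in zip(oc_list, correct):
        if action == "stop":
            probs.append(oc.stop_prob)
        else:
            probs.append(oc.selection_probs[int(action) - 1])
    return float(np.mean(probs))
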