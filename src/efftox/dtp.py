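"""Dose-transition pathways, dose ambivalence, and outcome-ambiguity checks.

A *dose-transition pathway* (DTP) enumerates every feasible outcome of
the next cohort(s) at the currently recommended dose and records the
design's dose decision in each — making the design's future behaviour
auditable before outcomes arrive. With four patient outcomes and
cohorts of three there are 20 distinct cohort outcomes, so a horizon of
h cohorts has up to 20^h pathways.

*Dose ambivalence* is the design recommending different doses for the
same data across re-runs of the (Monte Carlo) posterior computation —
a signal that two doses have nearly equal posterior utility, or that a
dose sits on the admissibility boundary. :func:`assess_ambivalence`
quantifies it by re-running the decision across seeds.

*Outcome ambiguity* is a temporarily unassessed patient outcome; the
decision is nonetheless determined when every completion of the pending
outcomes yields the same recommendation
(:func:`resolvable_under_missing`).
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .model import EffToxModel, Recommendation, recommend_dose
from .outcomes import (
    AB_TO_SYMBOL,
    CohortOutcome,
    canonical_symbols,
    enumerate_cohort_outcomes,
    records_to_path,
    to_patient_records,
)

__all__ = [
    "DtpNode",
    "AmbivalenceReport",
    "MissingnessResolution",
    "path_seed",
    "compute_dtp",
    "dtp_table",
    "dtp_tree_text",
    "assess_ambivalence",
    "resolvable_under_missing",
]

DEFAULT_N_SAMPLES = 100_000


def path_seed(base_seed: int, path: str) -> int:
    """Deterministic per-path seed below 2**31.

    Derived by hashing (base_seed, path) so published DTP tables are
    re-derivable while distinct pathways use independent randomisation.
    """
    digest = hashlib.sha256(f"{base_seed}|{path}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class DtpNode:
    """One node of a dose-transition-pathway tree.

    ``path`` is the outcome string of the *future* cohorts leading to
    this node (empty at the root); ``recommendation`` is the design's
    decision given the trial state plus those outcomes. Stop nodes and
    horizon leaves have no children.
    """

    path: str
    recommendation: Recommendation
    children: dict[str, "DtpNode"] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def compute_dtp(
    model: EffToxModel,
    horizon: int,
    base_seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> DtpNode:
    """Enumerate dose-transition pathways for the next ``horizon`` cohorts.

    Each node's recommendation is computed with a seed derived from
    (``base_seed``, node path), so the table is reproducible yet paths
    are independently randomised. Stop decisions prune the subtree.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    design = model.design
    if model.n_patients >= design.max_patients:
        raise ValueError("trial already at its maximum sample size")

    def build(state: EffToxModel, path: str, remaining: int) -> DtpNode:
        rec = recommend_dose(state, seed=path_seed(base_seed, path), n_samples=n_samples)
        node = DtpNode(path=path, recommendation=rec)
        if rec.stop or remaining == 0 or state.n_patients >= design.max_patients:
            return node
        dose = rec.dose_level
        m = min(design.cohort_size, design.max_patients - state.n_patients)
        for symbols in enumerate_cohort_outcomes(m):
            cohort = CohortOutcome(dose_level=dose, outcomes=symbols)
            token = str(cohort)
            child_path = f"{path} {token}".strip()
            child_state = state.extend(to_patient_records([cohort]))
            node.children[token] = build(child_state, child_path, remaining - 1)
        return node

    return build(model, "", horizon)


def _leaves(node: DtpNode):
    if node.is_leaf:
        yield node
    else:
        for child in node.children.values():
            yield from _leaves(child)


def dtp_table(root: DtpNode) -> pd.DataFrame:
    """Flatten a DTP tree to one row per pathway leaf.

    Columns: ``path`` (future outcome string), ``recommendation``
    (dose level as text, or ``"stop"``).
    """
    rows = [
        {"path": leaf.path, "recommendation": str(leaf.recommendation.dose_level)
         if not leaf.recommendation.stop else "stop"}
        for leaf in _leaves(root)
    ]
    return pd.DataFrame(rows, columns=["path", "recommendation"])


def dtp_tree_text(root: DtpNode) -> str:
    """Indented plain-text rendering of a DTP tree."""
    lines: list[str] = []

    def walk(node: DtpNode, depth: int) -> None:
        label = node.path.split()[-1] if node.path else "(current state)"
        lines.append("  " * depth + f"{label} -> {node.recommendation}")
        for child in node.children.values():
            walk(child, depth + 1)

    walk(root, 0)
    return "\n".join(lines)


@dataclass
class AmbivalenceReport:
    """Stability of a dose decision across repeated posterior computations."""

    path: str
    recommendations: dict[str, int]
    modal_share: float
    n_runs: int

    @property
    def modal_recommendation(self) -> str:
        return max(self.recommendations, key=self.recommendations.get)


def assess_ambivalence(
    model: EffToxModel,
    n_runs: int = 100,
    base_seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> AmbivalenceReport:
    """Re-run the dose decision across seeds and tally the recommendations.

    ``modal_share`` near 1 indicates a stable decision; materially lower
    values flag dose ambivalence (near-equal utilities or a dose on the
    admissibility boundary), which merits review rather than more
    Monte Carlo precision.
    """
    if n_runs < 10:
        raise ValueError("n_runs must be >= 10")
    tally: Counter[str] = Counter()
    for i in range(n_runs):
        rec = recommend_dose(model, seed=path_seed(base_seed, f"run:{i}"), n_samples=n_samples)
        tally[str(rec.dose_level) if not rec.stop else "stop"] += 1
    modal = tally.most_common(1)[0][1] / n_runs
    path = records_to_path(model.records, model.design.cohort_size) if model.records else ""
    return AmbivalenceReport(
        path=path, recommendations=dict(tally), modal_share=modal, n_runs=n_runs
    )


@dataclass
class MissingnessResolution:
    """Whether pending outcomes can change the dose decision."""

    resolved: bool
    recommendation: Recommendation | None
    by_completion: dict[str, str]


def resolvable_under_missing(
    model: EffToxModel,
    pending: int,
    seed: int = 0,
    dose_level: int | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> MissingnessResolution:
    """Decide whether a dose decision survives ``pending`` missing outcomes.

    The current cohort has ``design.cohort_size`` patients of which
    ``pending`` are not yet assessed; the assessed ones must already be
    in ``model.records`` (at ``dose_level``, inferred from the last
    record when omitted). Every completion of the pending outcomes (as a
    deduplicated multiset) is evaluated with the same per-pathway seed
    derivation as :func:`compute_dtp`; the decision is *resolved* iff
    all completions agree.
    """
    design = model.design
    m = design.cohort_size
    if not 0 <= pending <= m:
        raise ValueError("pending must be between 0 and the cohort size")
    if pending == 0:
        rec = recommend_dose(model, seed=path_seed(seed, ""), n_samples=n_samples)
        return MissingnessResolution(True, rec, {})

    n_observed = m - pending
    if len(model.records) < n_observed:
        raise ValueError("fewer records than assessed patients in the current cohort")
    observed = model.records[len(model.records) - n_observed :]
    prior_records = model.records[: len(model.records) - n_observed]
    if dose_level is None:
        doses = {r.dose_level for r in observed}
        if len(doses) == 1:
            dose_level = doses.pop()
        elif model.records:
            dose_level = model.records[-1].dose_level
        else:
            raise ValueError("dose_level required when no records identify the cohort")
    if any(r.dose_level != dose_level for r in observed):
        raise ValueError("assessed current-cohort records are not all at dose_level")

    observed_symbols = tuple(AB_TO_SYMBOL[(r.efficacy, r.toxicity)] for r in observed)
    base = EffToxModel(design, prior_records)
    by_completion: dict[str, str] = {}
    recs: dict[str, Recommendation] = {}
    seen: set[tuple[str, ...]] = set()
    for completion in enumerate_cohort_outcomes(pending):
        full = canonical_symbols(observed_symbols + completion)
        if full in seen:
            continue
        seen.add(full)
        cohort = CohortOutcome(dose_level=dose_level, outcomes=full)
        token = str(cohort)
        state = base.extend(to_patient_records([cohort]))
        rec = recommend_dose(state, seed=path_seed(seed, token), n_samples=n_samples)
        key = str(rec.dose_level) if not rec.stop else "stop"
        by_completion[token] = key
        recs[key] = rec
    if len(recs) == 1:
        return MissingnessResolution(True, next(iter(recs.values())), by_completion)
    return MissingnessResolution(False, None, by_completion)
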