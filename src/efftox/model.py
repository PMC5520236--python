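"""The six-parameter Bayesian efficacy-toxicity dose-finding model.

Marginal probabilities at codified dose x:

    logit pi_E(x, theta) = mu_E + beta_E1 * x + beta_E2 * x^2
    logit pi_T(x, theta) = mu_T + beta_T * x

so toxicity is monotone in dose when beta_T > 0, while the quadratic
term lets efficacy plateau or turn over. Binary outcomes (a, b) per
patient are tied together by an association parameter psi through

    pi_ab = pi_E^a (1-pi_E)^(1-a) pi_T^b (1-pi_T)^(1-b)
            + (-1)^(a+b) pi_E (1-pi_E) pi_T (1-pi_T) * tanh(psi / 2)

(a Farlie-Gumbel-Morgenstern-type correction; tanh(psi/2) equals
(e^psi - 1)/(e^psi + 1)). Independent univariate normal priors are
placed on theta = (mu_E, beta_E1, beta_E2, mu_T, beta_T, psi); the
posterior is approximated by self-normalised importance sampling with
the prior as proposal.

Dose selection maximises the posterior mean of an L^p utility contour
(see :mod:`efftox.utility`) over the *admissible* doses — those with

    Pr(pi_E(x) > pi_E_min | D) > p_E   and   Pr(pi_T(x) < pi_T_max | D) > p_T

— subject to no-skip rules for untried doses. An empty admissible set
stops the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .doses import DoseGrid
from .outcomes import PatientRecord, parse_path, to_patient_records
from .utility import UtilityContour, utility

__all__ = [
    "PARAM_NAMES",
    "ThetaParams",
    "PriorSpec",
    "AdmissibilityRules",
    "EffToxDesign",
    "EffToxModel",
    "EffToxResults",
    "PosteriorDraws",
    "PosteriorSummary",
    "Recommendation",
    "DegenerateWeightsWarning",
    "prob_efficacy",
    "prob_toxicity",
    "joint_outcome_prob",
    "log_likelihood",
    "posterior_samples",
    "summarise_posterior",
    "admissible_set",
    "recommend_dose",
]

PARAM_NAMES = ("mu_E", "beta_E1", "beta_E2", "mu_T", "beta_T", "psi")

#: utility differences below this are treated as exact ties (lower dose wins)
UTILITY_TIE_TOL = 1e-9

#: cell probabilities in [-CELL_CLAMP_TOL, 0) are clamped to 0
CELL_CLAMP_TOL = 1e-12


class DegenerateWeightsWarning(UserWarning):
    """Importance weights have collapsed onto very few draws."""


class ThetaParams(NamedTuple):
    """Model parameters on their natural (unbounded) scale."""

    mu_E: float
    beta_E1: float
    beta_E2: float
    mu_T: float
    beta_T: float
    psi: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def _theta_array(theta) -> np.ndarray:
    """Coerce ThetaParams or array-like to an (..., 6) float array."""
    arr = np.asarray(theta, dtype=float)
    if arr.shape[-1] != 6:
        raise ValueError("theta must have 6 components")
    if not np.all(np.isfinite(arr)):
        raise ValueError("theta components must be finite")
    return arr


@dataclass(frozen=True)
class PriorSpec:
    """Independent univariate normal priors on each theta component."""

    loc: tuple[float, ...]
    scale: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.loc) != 6 or len(self.scale) != 6:
            raise ValueError("prior loc and scale must each have 6 components")
        if any(s <= 0 for s in self.scale):
            raise ValueError("all prior scales must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        loc = np.asarray(self.loc)
        scale = np.asarray(self.scale)
        return loc + scale * rng.standard_normal((n, 6))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": PARAM_NAMES, "loc": self.loc, "scale": self.scale})


@dataclass(frozen=True)
class AdmissibilityRules:
    """Posterior exceedance criteria defining the admissible dose set.

    A dose is admissible when the posterior probability that its
    efficacy exceeds ``pi_E_min`` is above ``p_E``, and the posterior
    probability that its toxicity is below ``pi_T_max`` is above
    ``p_T``.
    """

    pi_E_min: float
    pi_T_max: float
    p_E: float
    p_T: float

    def __post_init__(self) -> None:
        for name in ("pi_E_min", "pi_T_max", "p_E", "p_T"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# probability model


def prob_efficacy(x, theta):
    """Marginal efficacy probability at codified dose(s) x.

    ``theta`` may be a :class:`ThetaParams` or an (n, 6) array of draws;
    ``x`` may be a scalar or an array of codified doses. Shapes
    broadcast: draws (n, 6) with doses (k,) give an (n, k) result.
    """
    arr = _theta_array(theta)
    x = np.asarray(x, dtype=float)
    mu_E = arr[..., 0, None] if x.ndim and arr.ndim > 1 else arr[..., 0]
    bE1 = arr[..., 1, None] if x.ndim and arr.ndim > 1 else arr[..., 1]
    bE2 = arr[..., 2, None] if x.ndim and arr.ndim > 1 else arr[..., 2]
    eta = mu_E + bE1 * x + bE2 * x * x
    out = expit(eta)
    return out if np.ndim(out) else float(out)


def prob_toxicity(x, theta):
    """Marginal toxicity probability at codified dose(s) x.

    Strictly increasing in x exactly when beta_T > 0.
    """
    arr = _theta_array(theta)
    x = np.asarray(x, dtype=float)
    mu_T = arr[..., 3, None] if x.ndim and arr.ndim > 1 else arr[..., 3]
    bT = arr[..., 4, None] if x.ndim and arr.ndim > 1 else arr[..., 4]
    out = expit(mu_T + bT * x)
    return out if np.ndim(out) else float(out)


def _joint_cell(pi_E, pi_T, psi, a: int, b: int):
    """Eq-style joint cell probability pi_ab with FGM association."""
    base = (pi_E if a else 1.0 - pi_E) * (pi_T if b else 1.0 - pi_T)
    corr = pi_E * (1.0 - pi_E) * pi_T * (1.0 - pi_T) * np.tanh(psi / 2.0)
    cell = base + ((-1.0) ** (a + b)) * corr
    return cell


def joint_outcome_prob(x, theta, a: int, b: int):
    """Joint probability of (efficacy=a, toxicity=b) at codified dose x."""
    if a not in (0, 1) or b not in (0, 1):
        raise ValueError("a and b must be binary")
    pi_E = prob_efficacy(x, theta)
    pi_T = prob_toxicity(x, theta)
    psi = _theta_array(theta)[..., 5]
    if np.ndim(pi_E) > np.ndim(psi):
        psi = np.asarray(psi)[..., None]
    cell = _joint_cell(np.asarray(pi_E), np.asarray(pi_T), psi, a, b)
    cell = np.asarray(cell, dtype=float)
    if np.any(cell < -CELL_CLAMP_TOL) or np.any(cell > 1.0 + CELL_CLAMP_TOL):
        raise RuntimeError("joint cell probability outside [0, 1] beyond tolerance")
    cell = np.clip(cell, 0.0, 1.0)
    return cell if cell.ndim else float(cell)


def log_likelihood(
    records: Sequence[PatientRecord], grid: DoseGrid, theta
) -> Union[float, np.ndarray]:
    """Log-likelihood of patient records; vectorised over theta draws.

    Returns a scalar for a single ThetaParams, or an (n,) array for
    (n, 6) draws. A record with zero probability yields -inf.
    """
    arr = _theta_array(theta)
    single = arr.ndim == 1
    draws = arr[None, :] if single else arr

    counts: dict[tuple[int, int, int], int] = {}
    for r in records:
        if not 1 <= r.dose_level <= grid.n_doses:
            raise ValueError(f"record dose_level {r.dose_level} outside grid")
        key = (r.dose_level, int(r.efficacy), int(r.toxicity))
        counts[key] = counts.get(key, 0) + 1

    ll = np.zeros(draws.shape[0])
    if counts:
        psi = draws[:, 5]
        by_dose: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for (dose, a, b), k in counts.items():
            if dose not in by_dose:
                x = grid.codified_dose(dose)
                by_dose[dose] = (prob_efficacy(x, draws), prob_toxicity(x, draws))
            pi_E, pi_T = by_dose[dose]
            cell = _joint_cell(pi_E, pi_T, psi, a, b)
            cell = np.clip(cell, 0.0, 1.0)
            with np.errstate(divide="ignore"):
                ll += k * np.log(cell)
    return float(ll[0]) if single else ll


# ---------------------------------------------------------------------------
# design and trial state


@dataclass(frozen=True)
class EffToxDesign:
    """A complete dose-finding design specification."""

    grid: DoseGrid
    prior: PriorSpec
    contour: UtilityContour
    rules: AdmissibilityRules
    cohort_size: int
    max_patients: int
    start_dose: int
    no_skip_escalation: bool = True
    no_skip_deescalation: bool = True

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.max_patients < self.cohort_size:
            raise ValueError("max_patients must be >= cohort_size")
        if not 1 <= self.start_dose <= self.grid.n_doses:
            raise ValueError("start_dose outside the dose grid")

    @property
    def n_doses(self) -> int:
        return self.grid.n_doses


@dataclass
class PosteriorDraws:
    """Weighted importance-sample approximation to the posterior."""

    theta: np.ndarray  # (n, 6)
    weights: np.ndarray  # (n,), normalised
    ess: float  # effective sample size of the weights
    seed: int | None

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]


SUMMARY_COLUMNS = [
    "dose_level",
    "raw_dose",
    "mean_eff",
    "mean_tox",
    "pr_eff_exceeds",
    "pr_tox_below",
    "mean_utility",
    "admissible",
]


@dataclass
class PosteriorSummary:
    """Per-dose posterior quantities driving dose selection.

    ``frame`` has one row per dose with columns ``dose_level``,
    ``raw_dose``, ``mean_eff``, ``mean_tox``, ``pr_eff_exceeds``
    (Pr(pi_E > pi_E_min | D)), ``pr_tox_below`` (Pr(pi_T < pi_T_max |
    D)), ``mean_utility`` and ``admissible``. ``utility_draws`` holds
    the per-draw utilities (n_draws x n_doses) behind ``mean_utility``,
    with ``weights`` their importance weights.
    """

    frame: pd.DataFrame
    utility_draws: np.ndarray
    weights: np.ndarray

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=2)


@dataclass(frozen=True)
class Recommendation:
    """Outcome of a dose-selection decision."""

    dose_level: int | None  # None means stop
    stop: bool
    tie: bool = False

    def __str__(self) -> str:
        return "stop" if self.stop else f"dose {self.dose_level}"


def posterior_samples(
    design: EffToxDesign,
    records: Sequence[PatientRecord],
    n_samples: int = 100_000,
    seed: int | None = None,
) -> PosteriorDraws:
    """Draw a weighted posterior sample by prior-proposal importance sampling.

    Weights are proportional to the likelihood and self-normalised, so
    with no data every weight is 1/n and prior moments are recovered. A
    :class:`DegenerateWeightsWarning` is raised when the effective
    sample size of the weights falls below 50.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    rng = np.random.default_rng(seed)
    theta = design.prior.sample(n_samples, rng)
    if records:
        ll = log_likelihood(records, design.grid, theta)
        ll = ll - np.max(ll)
        w = np.exp(ll)
    else:
        w = np.ones(n_samples)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("all importance weights are zero; data impossible under model")
    w = w / total
    ess = 1.0 / np.sum(w**2)
    if ess < 50:
        warnings.warn(
            f"importance-weight effective sample size {ess:.1f} < 50; "
            "posterior summaries may be unreliable",
            DegenerateWeightsWarning,
            stacklevel=2,
        )
    return PosteriorDraws(theta=theta, weights=w, ess=float(ess), seed=seed)


def summarise_posterior(draws: PosteriorDraws, design: EffToxDesign) -> PosteriorSummary:
    """Per-dose posterior means, exceedance probabilities and utilities."""
    x = np.asarray(design.grid.codified)
    w = draws.weights
    pi_E = prob_efficacy(x, draws.theta)  # (n, k)
    pi_T = prob_toxicity(x, draws.theta)
    u = utility(pi_E, pi_T, design.contour)

    rules = design.rules
    mean_eff = w @ pi_E
    mean_tox = w @ pi_T
    pr_eff = w @ (pi_E > rules.pi_E_min)
    pr_tox = w @ (pi_T < rules.pi_T_max)
    mean_u = w @ u
    admissible = (pr_eff > rules.p_E) & (pr_tox > rules.p_T)

    frame = pd.DataFrame(
        {
            "dose_level": np.arange(1, design.n_doses + 1),
            "raw_dose": design.grid.raw_doses,
            "mean_eff": mean_eff,
            "mean_tox": mean_tox,
            "pr_eff_exceeds": pr_eff,
            "pr_tox_below": pr_tox,
            "mean_utility": mean_u,
            "admissible": admissible,
        }
    )
    return PosteriorSummary(frame=frame, utility_draws=u, weights=w)


def admissible_set(summary: PosteriorSummary, rules: AdmissibilityRules) -> set[int]:
    """Dose levels passing both posterior exceedance criteria."""
    f = summary.frame
    ok = (f["pr_eff_exceeds"] > rules.p_E) & (f["pr_tox_below"] > rules.p_T)
    return set(f.loc[ok, "dose_level"].astype(int))


def _skip_allowed(dose: int, tried: set[int], design: EffToxDesign) -> bool:
    """Whether selecting ``dose`` respects the no-skip rules."""
    if not tried or dose in tried:
        return True
    hi, lo = max(tried), min(tried)
    if dose > hi and design.no_skip_escalation and dose > hi + 1:
        return False
    if dose < lo and design.no_skip_deescalation and dose < lo - 1:
        return False
    return True


def select_dose(
    summary: PosteriorSummary,
    design: EffToxDesign,
    records: Sequence[PatientRecord],
) -> Recommendation:
    """Pick the utility-maximal admissible dose subject to no-skip rules."""
    tried = {r.dose_level for r in records}
    adm = admissible_set(summary, design.rules)
    candidates = [d for d in sorted(adm) if _skip_allowed(d, tried, design)]
    if not candidates:
        return Recommendation(dose_level=None, stop=True)
    utilities = summary.frame.set_index("dose_level")["mean_utility"]
    best_u = max(utilities[d] for d in candidates)
    tied = [d for d in candidates if utilities[d] >= best_u - UTILITY_TIE_TOL]
    return Recommendation(dose_level=min(tied), stop=False, tie=len(tied) > 1)


def recommend_dose(
    model: "EffToxModel",
    seed: int | None = None,
    n_samples: int = 100_000,
) -> Recommendation:
    """Dose recommendation for the next cohort given the trial state.

    With no patients treated yet, the configured start dose is
    recommended without a posterior computation. Otherwise the posterior
    is sampled, the admissible set formed, and the utility-maximal
    admissible dose chosen subject to the no-skip rules; an empty
    candidate set means stop. Deterministic given (state, seed,
    n_samples); exact utility ties select the lower dose and set the
    ``tie`` flag.
    """
    if not model.records:
        if model.design.start_dose is None:  # pragma: no cover - design validates
            raise ValueError("no records and no start dose configured")
        return Recommendation(dose_level=model.design.start_dose, stop=False)
    results = model.fit(n_samples=n_samples, seed=seed)
    return results.recommendation


# ---------------------------------------------------------------------------
# Model / Results


class EffToxModel:
    """A dose-finding trial state: a design plus observed patient records.

    Examples
    --------
    >>> from efftox import matchpoint
    >>> model = EffToxModel.from_path(matchpoint(), "3TTT")
    >>> results = model.fit(n_samples=20_000, seed=1)
    >>> results.recommendation.dose_level in {1, 2} or results.recommendation.stop
    True
    """

    def __init__(self, design: EffToxDesign, records: Iterable[PatientRecord] = ()):
        self.design = design
        self.records: tuple[PatientRecord, ...] = tuple(records)
        if len(self.records) > design.max_patients:
            raise ValueError("more records than the design's maximum sample size")
        for r in self.records:
            if not 1 <= r.dose_level <= design.n_doses:
                raise ValueError(f"record dose_level {r.dose_level} outside grid")

    @classmethod
    def from_path(cls, design: EffToxDesign, path: str) -> "EffToxModel":
        """Build trial state from an outcome path string like ``"3TTT 2NEE"``."""
        cohorts = parse_path(path, n_doses=design.n_doses)
        return cls(design, to_patient_records(cohorts))

    def extend(self, records: Iterable[PatientRecord]) -> "EffToxModel":
        """A new model with additional patient records appended."""
        return EffToxModel(self.design, self.records + tuple(records))

    @property
    def n_patients(self) -> int:
        return len(self.records)

    def fit(self, n_samples: int = 100_000, seed: int | None = None) -> "EffToxResults":
        """Run the prior-to-posterior analysis and dose selection."""
        draws = posterior_samples(self.design, self.records, n_samples, seed)
        summary = summarise_posterior(draws, self.design)
        rec = select_dose(summary, self.design, self.records)
        return EffToxResults(model=self, draws=draws, posterior=summary, recommendation=rec)


@dataclass
class EffToxResults:
    """Fitted posterior state: summaries, admissibility and recommendation."""

    model: EffToxModel
    draws: PosteriorDraws
    posterior: PosteriorSummary
    recommendation: Recommendation

    @property
    def summary_frame(self) -> pd.DataFrame:
        return self.posterior.frame

    @property
    def admissible_doses(self) -> set[int]:
        return admissible_set(self.posterior, self.model.design.rules)

    def utility_draws(self, dose_level: int) -> tuple[np.ndarray, np.ndarray]:
        """(utility draws, weights) for one dose."""
        if not 1 <= dose_level <= self.model.design.n_doses:
            raise ValueError(f"unknown dose level {dose_level}")
        return self.posterior.utility_draws[:, dose_level - 1], self.posterior.weights

    def summary(self) -> str:
        """Human-readable per-dose posterior table plus the decision."""
        frame = self.posterior.frame.copy()
        for col in ("mean_eff", "mean_tox", "pr_eff_exceeds", "pr_tox_below", "mean_utility"):
            frame[col] = frame[col].round(3)
        lines = [
            "EffTox posterior summary",
            f"  patients observed: {self.model.n_patients}"
            f" / {self.model.design.max_patients}",
            f"  importance-weight ESS: {self.draws.ess:,.0f}"
            f" of {self.draws.n_samples:,} draws",
            "",
            frame.to_string(index=False),
            "",
            f"  recommendation: {self.recommendation}"
            + ("  (utility tie; lower dose chosen)" if self.recommendation.tie else ""),
        ]
        return "\n".join(lines)
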