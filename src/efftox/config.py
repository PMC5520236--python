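"""Trial design configuration files (YAML/JSON) and packaged fixtures."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .doses import codify_doses
from .model import AdmissibilityRules, EffToxDesign, PriorSpec
from .priors import ElicitedPrior, calibrate_ess, fit_prior_means
from .utility import UtilityContour, solve_contour_p

__all__ = ["load_design", "design_from_dict", "matchpoint", "load_scenarios", "apply_overrides"]


def _load_mapping(path: str | Path) -> dict[str, Any]:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def apply_overrides(config: Mapping[str, Any], overrides: Sequence[str]) -> dict[str, Any]:
    """Apply ``key=value`` overrides (dotted keys reach nested blocks).

    Values are parsed as YAML scalars, so ``p_E=0.03`` and
    ``no_skip_deescalation=false`` work as expected.
    """
    out: dict[str, Any] = json.loads(json.dumps(dict(config)))  # deep copy
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        key, raw = item.split("=", 1)
        node = out
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = yaml.safe_load(raw)
    return out


def design_from_dict(config: Mapping[str, Any]) -> EffToxDesign:
    """Build an :class:`EffToxDesign` from a config mapping.

    The contour block needs ``pi1E`` and ``pi2T`` plus either an
    explicit exponent ``p`` or an interior equal-utility ``hinge``
    point. The prior is either given explicitly (``prior: {loc: [...],
    scale: [...]}``) or calibrated from ``prior_eff``/``prior_tox`` and
    ``ess``.
    """
    grid = codify_doses(config["doses"])

    c = config["contour"]
    if "p" in c:
        contour = UtilityContour(pi1E=float(c["pi1E"]), pi2T=float(c["pi2T"]), p=float(c["p"]))
    else:
        e3, t3 = c["hinge"]
        contour = solve_contour_p(
            (float(c["pi1E"]), 0.0), (1.0, float(c["pi2T"])), (float(e3), float(t3))
        )

    adm = config["admissibility"]
    rules = AdmissibilityRules(
        pi_E_min=float(adm["pi_E_min"]),
        pi_T_max=float(adm["pi_T_max"]),
        p_E=float(adm["p_E"]),
        p_T=float(adm["p_T"]),
    )

    if "prior" in config:
        pr = config["prior"]
        prior = PriorSpec(loc=tuple(map(float, pr["loc"])), scale=tuple(map(float, pr["scale"])))
    else:
        elicited = ElicitedPrior(
            eta_E=tuple(map(float, config["prior_eff"])),
            eta_T=tuple(map(float, config["prior_tox"])),
            ess_target=float(config["ess"]),
        )
        means = fit_prior_means(elicited, grid)
        prior = calibrate_ess(
            means,
            elicited,
            grid,
            psi_scale=float(config.get("psi_scale", 1.0)),
            n_draws=int(config.get("calibration_draws", 100_000)),
            seed=int(config.get("calibration_seed", 0)),
        )

    return EffToxDesign(
        grid=grid,
        prior=prior,
        contour=contour,
        rules=rules,
        cohort_size=int(config["cohort_size"]),
        max_patients=int(config["max_patients"]),
        start_dose=int(config["start_dose"]),
        no_skip_escalation=bool(config.get("no_skip_escalation", True)),
        no_skip_deescalation=bool(config.get("no_skip_deescalation", True)),
    )


def load_design(path: str | Path, overrides: Sequence[str] = ()) -> EffToxDesign:
    """Load a design from a YAML/JSON config file, with optional overrides."""
    config = _load_mapping(path)
    if overrides:
        config = apply_overrides(config, overrides)
    return design_from_dict(config)


@lru_cache(maxsize=4)
def _matchpoint_cached(p_E: float) -> EffToxDesign:
    with resources.as_file(resources.files("efftox.data") / "matchpoint.yaml") as p:
        config = _load_mapping(p)
    config["admissibility"]["p_E"] = p_E
    return design_from_dict(config)


def matchpoint(p_E: float = 0.03) -> EffToxDesign:
    """The packaged Matchpoint trial design (optionally with another p_E)."""
    return _matchpoint_cached(p_E)


def load_scenarios(path: str | Path | None = None) -> list[dict[str, Any]]:
    """Load simulation scenarios; defaults to the packaged six-scenario set.

    Returns a list of dicts with keys ``label``, ``true_eff``,
    ``true_tox`` and (optionally) ``correct``.
    """
    if path is None:
        with resources.as_file(resources.files("efftox.data") / "matchpoint_scenarios.yaml") as p:
            return _load_mapping(p)["scenarios"]
    return _load_mapping(path)["scenarios"]
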