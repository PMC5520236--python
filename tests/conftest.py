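import pytest

import efftox as et
from efftox.model import EffToxDesign, PriorSpec
from efftox.utility import UtilityContour


@pytest.fixture(scope="session")
def matchpoint_design() -> EffToxDesign:
    """The packaged four-dose design (prior calibrated once per session)."""
    return et.matchpoint()


@pytest.fixture(scope="session")
def matchpoint_contour() -> UtilityContour:
    return et.solve_contour_p((0.40, 0.0), (1.0, 0.70), (0.50, 0.40))


@pytest.fixture(scope="session")
def toy2_design() -> EffToxDesign:
    """Two-dose toy with a tight explicit prior; used for oracle checks.

    The association prior is essentially degenerate at zero, so the
    likelihood factorises into efficacy and toxicity blocks and the
    posterior admits an accurate dense-grid quadrature oracle.
    """
    return EffToxDesign(
        grid=et.codify_doses([10.0, 20.0]),
        prior=PriorSpec(
            loc=(0.0, 1.0, 0.0, -1.0, 1.0, 0.0),
            scale=(0.8, 0.8, 0.8, 0.8, 0.8, 1e-3),
        ),
        contour=UtilityContour(pi1E=0.40, pi2T=0.70, p=2.0),
        rules=et.AdmissibilityRules(pi_E_min=0.45, pi_T_max=0.40, p_E=0.1, p_T=0.1),
        cohort_size=3,
        max_patients=12,
        start_dose=1,
    )


@pytest.fixture(scope="session")
def mini_design() -> EffToxDesign:
    """Three-dose, two-cohort design with an explicit prior for fast trials."""
    return EffToxDesign(
        grid=et.codify_doses([10.0, 20.0, 40.0]),
        prior=PriorSpec(
            loc=(0.0, 0.8, 0.0, -1.5, 1.0, 0.0),
            scale=(1.5, 1.5, 1.5, 1.5, 1.5, 1.0),
        ),
        contour=UtilityContour(pi1E=0.40, pi2T=0.70, p=2.0),
        rules=et.AdmissibilityRules(pi_E_min=0.30, pi_T_max=0.50, p_E=0.05, p_T=0.05),
        cohort_size=3,
        max_patients=6,
        start_dose=2,
    )


@pytest.fixture()
def cli_config(tmp_path):
    """A design config with an explicit prior (no calibration at load time)."""
    text = """\
label: cli-test
doses: [7.5, 15, 30, 45]
prior: {loc: [-0.525, 1.046, 0.146, -2.476, 1.356, 0.0],
        scale: [2.0, 2.0, 2.0, 2.0, 2.0, 1.0]}
contour: {pi1E: 0.40, pi2T: 0.70, p: 2.07}
admissibility: {pi_E_min: 0.45, pi_T_max: 0.40, p_E: 0.03, p_T: 0.05}
cohort_size: 3
max_patients: 30
start_dose: 3
"""
    path = tmp_path / "design.yaml"
    path.write_text(text)
    return path
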