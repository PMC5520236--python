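import itertools
import math

import numpy as np
import pandas as pd
import pytest

import efftox as et
from efftox.model import (
    DegenerateWeightsWarning,
    PosteriorSummary,
    ThetaParams,
    select_dose,
)
from efftox.outcomes import PatientRecord

THETA_ZERO = ThetaParams(0, 0, 0, 0, 0, 0)


def make_summary(pr_eff, pr_tox, utilities, n_doses=4):
    """Hand-built per-dose summary for decision-logic tests."""
    frame = pd.DataFrame(
        {
            "dose_level": np.arange(1, n_doses + 1),
            "raw_dose": np.arange(1, n_doses + 1) * 10.0,
            "mean_eff": 0.5,
            "mean_tox": 0.2,
            "pr_eff_exceeds": pr_eff,
            "pr_tox_below": pr_tox,
            "mean_utility": utilities,
            "admissible": True,
        }
    )
    return PosteriorSummary(frame=frame, utility_draws=np.zeros((1, n_doses)), weights=np.ones(1))


class TestMarginalProbabilities:
    def test_zero_linear_predictor_gives_half(self):
        assert et.prob_efficacy(0.0, THETA_ZERO) == pytest.approx(0.5)
        assert et.prob_toxicity(0.0, THETA_ZERO) == pytest.approx(0.5)

    def test_cancelling_efficacy_terms(self):
        theta = ThetaParams(0, 1, -1, 0, 0, 0)
        assert et.prob_efficacy(1.0, theta) == pytest.approx(0.5)

    def test_known_linear_predictor_value(self):
        # logit(pi_E) = 1 + 2*0.42 + 0.5*0.42^2 = 1.9282
        theta = ThetaParams(1, 2, 0.5, 0, 0, 0)
        expected = 1 / (1 + math.exp(-1.9282))
        assert et.prob_efficacy(0.42, theta) == pytest.approx(expected, rel=1e-12)

    def test_toxicity_linear_predictor_zero(self):
        theta = ThetaParams(0, 0, 0, -1, 2, 0)
        assert et.prob_toxicity(0.5, theta) == pytest.approx(0.5)

    def test_flat_toxicity_when_slope_zero(self):
        theta = ThetaParams(0, 0, 0, 0.3, 0, 0)
        values = [et.prob_toxicity(x, theta) for x in (-1, 0, 1)]
        assert len(set(values)) == 1

    def test_toxicity_monotone_iff_positive_slope(self):
        up = ThetaParams(0, 0, 0, 0, 1.5, 0)
        xs = np.linspace(-1, 1, 7)
        vals = [et.prob_toxicity(x, up) for x in xs]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestJointOutcomeProb:
    def test_independence_when_psi_zero(self):
        theta = ThetaParams(0.3, 0.5, -0.2, -0.5, 1.0, 0.0)
        x = 0.7
        pe, pt = et.prob_efficacy(x, theta), et.prob_toxicity(x, theta)
        for a, b in itertools.product((0, 1), repeat=2):
            expected = (pe if a else 1 - pe) * (pt if b else 1 - pt)
            assert et.joint_outcome_prob(x, theta, a, b) == pytest.approx(expected)

    def test_association_cell_hand_value(self):
        # pi_E = pi_T = 0.5 and psi = ln 3: (e^psi-1)/(e^psi+1) = 0.5,
        # so pi_11 = 0.25 + 0.0625 * 0.5 = 0.28125
        theta = ThetaParams(0, 0, 0, 0, 0, math.log(3))
        assert et.joint_outcome_prob(0.0, theta, 1, 1) == pytest.approx(0.28125)

    def test_cells_sum_to_one_and_recover_marginals(self):
        rng = np.random.default_rng(20240917)
        n = 10_000
        theta = rng.normal(scale=2.0, size=(n, 6))
        x = rng.uniform(-2, 2)
        cells = {
            (a, b): np.asarray(et.joint_outcome_prob(x, theta, a, b))
            for a, b in itertools.product((0, 1), repeat=2)
        }
        total = sum(cells.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        pi_E = np.asarray(et.prob_efficacy(x, theta))
        pi_T = np.asarray(et.prob_toxicity(x, theta))
        np.testing.assert_allclose(cells[(1, 0)] + cells[(1, 1)], pi_E, atol=1e-12)
        np.testing.assert_allclose(cells[(0, 1)] + cells[(1, 1)], pi_T, atol=1e-12)

    def test_binary_outcomes_enforced(self):
        with pytest.raises(ValueError):
            et.joint_outcome_prob(0.0, THETA_ZERO, 2, 0)


class TestLogLikelihood:
    def test_empty_data_is_zero(self, toy2_design):
        assert et.log_likelihood([], toy2_design.grid, THETA_ZERO) == 0.0

    def test_independence_factorisation(self, toy2_design):
        theta = ThetaParams(0.4, 0.7, -0.1, -1.0, 1.2, 0.0)
        grid = toy2_design.grid
        rec = PatientRecord(2, 1, 0)
        x = grid.codified_dose(2)
        pe, pt = et.prob_efficacy(x, theta), et.prob_toxicity(x, theta)
        expected = math.log(pe) + math.log(1 - pt)
        assert et.log_likelihood([rec], grid, theta) == pytest.approx(expected)

    def test_identical_records_scale_linearly(self, toy2_design):
        theta = ThetaParams(0.4, 0.7, -0.1, -1.0, 1.2, 0.8)
        rec = PatientRecord(1, 0, 1)
        one = et.log_likelihood([rec], toy2_design.grid, theta)
        three = et.log_likelihood([rec] * 3, toy2_design.grid, theta)
        assert three == pytest.approx(3 * one)

    def test_impossible_record_gives_minus_infinity(self, toy2_design):
        # mu_E = +40 makes pi_E = 1 to double precision, so a = 0 is impossible
        theta = ThetaParams(40, 0, 0, 0, 0, 0)
        ll = et.log_likelihood([PatientRecord(1, 0, 0)], toy2_design.grid, theta)
        assert ll == -np.inf


class TestPosterior:
    def test_no_data_recovers_prior_moments(self, toy2_design):
        n = 50_000
        draws = et.posterior_samples(toy2_design, [], n_samples=n, seed=3)
        means = draws.weights @ draws.theta
        for k, (loc, scale) in enumerate(zip(toy2_design.prior.loc, toy2_design.prior.scale)):
            mc_se = scale / math.sqrt(n)
            assert abs(means[k] - loc) < 3 * mc_se

    def test_same_seed_reproduces_summaries(self, toy2_design):
        recs = [PatientRecord(1, 1, 0), PatientRecord(2, 0, 1), PatientRecord(2, 1, 1)]
        m = et.EffToxModel(toy2_design, recs)
        r1 = m.fit(n_samples=5_000, seed=11)
        r2 = m.fit(n_samples=5_000, seed=11)
        pd.testing.assert_frame_equal(r1.summary_frame, r2.summary_frame)
        assert r1.recommendation == r2.recommendation

    def test_heavy_efficacy_data_approaches_observed_proportion(self, toy2_design):
        # conjugate oracle ignoring the dose model: beta-moment-matched
        # prior at the dose, updated with k successes in k trials
        design = toy2_design
        rng = np.random.default_rng(0)
        prior_draws = design.prior.sample(100_000, rng)
        x = design.grid.codified_dose(1)
        pe = np.asarray(et.prob_efficacy(x, prior_draws))
        m, v = pe.mean(), pe.var()
        ab = m * (1 - m) / v - 1
        alpha, beta_ = m * ab, (1 - m) * ab
        k = 30
        oracle = (alpha + k) / (alpha + beta_ + k)

        recs = [PatientRecord(1, 1, 0)] * k
        draws = et.posterior_samples(design, recs, n_samples=200_000, seed=5)
        summary = et.summarise_posterior(draws, design)
        mean_eff = summary.frame.loc[0, "mean_eff"]
        assert mean_eff == pytest.approx(oracle, abs=0.05)
        # and with 30/30 efficacy the posterior mean is pulled far above the prior
        assert mean_eff > m + 0.2

    def test_degenerate_weights_warn(self, toy2_design):
        # 12 highly surprising outcomes collapse the prior-proposal weights
        recs = [PatientRecord(1, 1, 1)] * 12
        with pytest.warns(DegenerateWeightsWarning):
            et.posterior_samples(toy2_design, recs, n_samples=1_000, seed=2)

    def test_minimum_sample_size_enforced(self, toy2_design):
        with pytest.raises(ValueError):
            et.posterior_samples(toy2_design, [], n_samples=100, seed=0)

    def test_summary_probabilities_in_unit_interval(self, toy2_design):
        recs = [PatientRecord(2, 1, 1), PatientRecord(1, 0, 0)]
        draws = et.posterior_samples(toy2_design, recs, n_samples=5_000, seed=9)
        summary = et.summarise_posterior(draws, toy2_design)
        f = summary.frame
        for col in ("mean_eff", "mean_tox", "pr_eff_exceeds", "pr_tox_below"):
            assert ((f[col] >= 0) & (f[col] <= 1)).all()

    def test_prior_mean_toxicity_monotone_given_positive_slope(self, toy2_design):
        rng = np.random.default_rng(4)
        draws = toy2_design.prior.sample(50_000, rng)
        draws = draws[draws[:, 4] > 0]  # condition on beta_T > 0
        x = np.asarray(toy2_design.grid.codified)
        pi_T = np.asarray(et.prob_toxicity(x, draws))
        means = pi_T.mean(axis=0)
        assert np.all(np.diff(means) > 0)


class TestQuadratureOracle:
    """Importance sampling vs dense-grid quadrature of the posterior
    integral on a two-dose toy whose association prior is (numerically)
    a point mass at zero, so the posterior factorises into an efficacy
    block over (mu_E, beta_E1, beta_E2) and a toxicity block over
    (mu_T, beta_T), each integrable on a dense trapezoidal grid."""

    @staticmethod
    def _block_grid(locs, scales, n_nodes, half_width=6.0):
        axes = [
            np.linspace(l - half_width * s, l + half_width * s, n_nodes)
            for l, s in zip(locs, scales)
        ]
        mesh = np.array(list(itertools.product(*axes)))
        log_prior = sum(
            -0.5 * ((mesh[:, k] - locs[k]) / scales[k]) ** 2 for k in range(len(locs))
        )
        return mesh, log_prior

    @classmethod
    def quadrature_summaries(cls, design, records, n_nodes=61):
        from scipy.special import expit

        locs = np.asarray(design.prior.loc)
        scales = np.asarray(design.prior.scale)
        x = np.asarray(design.grid.codified)
        rules = design.rules

        # efficacy block
        mesh_E, logp_E = cls._block_grid(locs[:3], scales[:3], n_nodes)
        pi_E = expit(mesh_E[:, [0]] + mesh_E[:, [1]] * x + mesh_E[:, [2]] * x * x)
        ll_E = np.zeros(len(mesh_E))
        for r in records:
            p = pi_E[:, r.dose_level - 1]
            ll_E += np.log(p if r.efficacy else 1 - p)
        w_E = np.exp(logp_E + ll_E - (logp_E + ll_E).max())
        w_E /= w_E.sum()

        # toxicity block
        mesh_T, logp_T = cls._block_grid(locs[3:5], scales[3:5], 201)
        pi_T = expit(mesh_T[:, [0]] + mesh_T[:, [1]] * x)
        ll_T = np.zeros(len(mesh_T))
        for r in records:
            p = pi_T[:, r.dose_level - 1]
            ll_T += np.log(p if r.toxicity else 1 - p)
        w_T = np.exp(logp_T + ll_T - (logp_T + ll_T).max())
        w_T /= w_T.sum()

        return {
            "pr_eff": w_E @ (pi_E > rules.pi_E_min),
            "pr_tox": w_T @ (pi_T < rules.pi_T_max),
            "mean_eff": w_E @ pi_E,
            "mean_tox": w_T @ pi_T,
        }

    def test_exceedance_probabilities_match_quadrature(self, toy2_design):
        records = [
            PatientRecord(1, 0, 0),
            PatientRecord(1, 1, 0),
            PatientRecord(2, 1, 1),
            PatientRecord(2, 1, 0),
            PatientRecord(2, 0, 1),
        ]
        oracle = self.quadrature_summaries(toy2_design, records)
        draws = et.posterior_samples(toy2_design, records, n_samples=200_000, seed=13)
        summary = et.summarise_posterior(draws, toy2_design)
        f = summary.frame
        np.testing.assert_allclose(f["pr_eff_exceeds"], oracle["pr_eff"], atol=0.02)
        np.testing.assert_allclose(f["pr_tox_below"], oracle["pr_tox"], atol=0.02)
        np.testing.assert_allclose(f["mean_eff"], oracle["mean_eff"], atol=0.02)
        np.testing.assert_allclose(f["mean_tox"], oracle["mean_tox"], atol=0.02)


TABLE4_PR_EFF = (0.079, 0.037, 0.060, 0.200)
TABLE4_PR_TOX = (0.919, 0.758, 0.051, 0.005)
TABLE4_UTILITY = (-0.489, -0.534, -0.777, -0.817)


class TestAdmissibilityAndSelection:
    def test_degenerate_certainties(self):
        s = make_summary(TABLE4_PR_EFF, TABLE4_PR_TOX, TABLE4_UTILITY)
        lax = et.AdmissibilityRules(0.45, 0.40, p_E=1e-9, p_T=1e-9)
        assert et.admissible_set(s, lax) == {1, 2, 3, 4}
        strict = et.AdmissibilityRules(0.45, 0.40, p_E=1 - 1e-9, p_T=1 - 1e-9)
        assert et.admissible_set(s, strict) == set()

    def test_published_exceedance_rows_give_published_admissible_sets(self):
        s = make_summary(TABLE4_PR_EFF, TABLE4_PR_TOX, TABLE4_UTILITY)
        assert et.admissible_set(s, et.AdmissibilityRules(0.45, 0.40, 0.05, 0.05)) == {1, 3}
        assert et.admissible_set(s, et.AdmissibilityRules(0.45, 0.40, 0.03, 0.05)) == {1, 2, 3}

    def _design_with(self, base, p_E):
        from dataclasses import replace

        return replace(base, rules=replace(base.rules, p_E=p_E))

    def test_after_three_toxicities_low_certainty_allows_deescalation(self, matchpoint_design):
        # tried = {3}; dose 1 is blocked by no-skip-in-de-escalation, so the
        # decision hinges on dose 2's admissibility
        s = make_summary(TABLE4_PR_EFF, TABLE4_PR_TOX, TABLE4_UTILITY)
        records = [PatientRecord(3, 0, 1)] * 3
        design = self._design_with(matchpoint_design, p_E=0.03)
        rec = select_dose(s, design, records)
        assert (rec.dose_level, rec.stop) == (2, False)

    def test_after_three_toxicities_higher_certainty_blocks_deescalation(self, matchpoint_design):
        s = make_summary(TABLE4_PR_EFF, TABLE4_PR_TOX, TABLE4_UTILITY)
        records = [PatientRecord(3, 0, 1)] * 3
        design = self._design_with(matchpoint_design, p_E=0.05)
        rec = select_dose(s, design, records)
        # dose 2 inadmissible and untried: the design cannot de-escalate;
        # it holds at dose 3
        assert (rec.dose_level, rec.stop) == (3, False)
        # ... and if dose 3's toxicity probability slips below p_T, it stops
        pr_tox_slip = (0.919, 0.758, 0.049, 0.005)
        s2 = make_summary(TABLE4_PR_EFF, pr_tox_slip, TABLE4_UTILITY)
        rec2 = select_dose(s2, design, records)
        assert rec2.stop

    def test_empty_admissible_set_stops(self, matchpoint_design):
        s = make_summary((0.01,) * 4, (0.01,) * 4, TABLE4_UTILITY)
        rec = select_dose(s, matchpoint_design, [PatientRecord(3, 0, 1)])
        assert rec.stop and rec.dose_level is None

    def test_single_admissible_dose_selected(self, matchpoint_design):
        s = make_summary((0.9, 0.01, 0.01, 0.01), (0.9, 0.9, 0.9, 0.9), TABLE4_UTILITY)
        rec = select_dose(s, matchpoint_design, [PatientRecord(2, 1, 0)])
        assert rec.dose_level == 1 and not rec.stop

    def test_no_skip_in_escalation(self, matchpoint_design):
        # dose 4 has the highest utility but only doses 1..2 were tried
        s = make_summary((0.9,) * 4, (0.9,) * 4, (-0.5, -0.3, 0.1, 0.4))
        rec = select_dose(s, matchpoint_design, [PatientRecord(2, 1, 0)])
        assert rec.dose_level == 3

    def test_skip_allowed_when_rule_disabled(self, matchpoint_design):
        from dataclasses import replace

        design = replace(matchpoint_design, no_skip_escalation=False)
        s = make_summary((0.9,) * 4, (0.9,) * 4, (-0.5, -0.3, 0.1, 0.4))
        rec = select_dose(s, design, [PatientRecord(2, 1, 0)])
        assert rec.dose_level == 4

    def test_exact_ties_pick_lower_dose_and_flag(self, matchpoint_design):
        s = make_summary((0.9,) * 4, (0.9,) * 4, (0.2, 0.2, 0.1, 0.0))
        rec = select_dose(s, matchpoint_design, [PatientRecord(1, 1, 0)])
        assert rec.dose_level == 1 and rec.tie

    def test_empty_trial_recommends_start_dose(self, matchpoint_design):
        model = et.EffToxModel(matchpoint_design)
        rec = et.recommend_dose(model, seed=0)
        assert rec.dose_level == matchpoint_design.start_dose
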