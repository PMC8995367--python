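"""Generative SDT observer: sessions, expected maps, expected CMI, cohorts."""

import numpy as np
import pandas as pd
import pytest

from metaconf import (CohortSpec, DesignSpec, ObserverParams, cmi,
                      expected_choice_map, expected_cmi, idealized_observer,
                      sigma_c_for_cmi, simulate_cohort, simulate_session)
from metaconf.confidence import fit_confidence_sets
from metaconf.design import decisions_long
from metaconf.observer import simulate_decisions


def session_cmi(params, seed):
    fit_c, fit_u = fit_confidence_sets(simulate_session(params, seed=seed))
    return cmi(fit_c.sensitivity, fit_u.sensitivity)


class TestSimulateSession:
    def test_deterministic_given_seed(self):
        p = ObserverParams(sigma_s=5.0, sigma_c=0.5)
        a = simulate_session(p, seed=3)
        b = simulate_session(p, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_easy_trials_more_accurate(self):
        p = ObserverParams(sigma_s=6.0)
        dec = decisions_long(simulate_session(p, seed=5))
        acc = dec[dec["correct"] != "arbitrary"].assign(
            ok=lambda d: d["correct"] == "correct",
            diff=lambda d: d["delta"].abs()).groupby("diff")["ok"].mean()
        assert acc[9.0] > acc[3.0]

    def test_unbiased_observer_pse_near_zero(self):
        p = ObserverParams(sigma_s=5.0, sigma_c=0.5)
        mus = []
        for seed in range(15):
            _, fit_u = fit_confidence_sets(simulate_session(p, seed=seed))
            mus.append(fit_u.mu)
        assert abs(np.mean(mus)) < 0.5

    def test_rts_respect_anticipation_bound(self, noisy_session):
        assert (noisy_session[["rt1_ms", "rt2_ms"]] >= 100.0).all().all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="sigma_s"):
            ObserverParams(sigma_s=-1.0).validate()
        with pytest.raises(ValueError, match="lapse"):
            ObserverParams(lapse=0.5).validate()


class TestConfidenceNoiseEffects:
    def test_huge_confidence_noise_kills_cmi(self):
        p = ObserverParams(sigma_s=6.0, sigma_c=1e6)
        values = [session_cmi(p, seed) for seed in range(30)]
        assert abs(np.mean(values)) < 5.0

    def test_ideal_observer_has_positive_cmi(self):
        p = idealized_observer(6.0)
        values = [session_cmi(p, seed) for seed in range(30)]
        assert np.mean(values) > 20.0

    def test_expected_cmi_decreases_with_confidence_noise(self):
        cmis = [expected_cmi(ObserverParams(sigma_s=5.0, sigma_c=sc))
                for sc in (0.0, 1.0, 3.0)]
        assert cmis[0] > cmis[1] > cmis[2] > 0

    def test_sigma_c_inversion_round_trip(self):
        for target, ss in [(23.0, 6.0), (31.0, 4.2)]:
            sc = sigma_c_for_cmi(target, ss)
            assert expected_cmi(ObserverParams(sigma_s=ss, sigma_c=sc)) == \
                pytest.approx(target, abs=1.0)


class TestExpectedChoiceMap:
    @pytest.mark.parametrize("sigma_c", [0.0, 1.0])
    def test_aggregate_symmetry(self, sigma_c):
        p = ObserverParams(sigma_s=6.0, sigma_c=sigma_c, lapse=0.02)
        g = expected_choice_map(p, condition="aggregate").grid.to_numpy()
        assert np.allclose(g + g.T, 1.0, atol=1e-9)

    def test_same_condition_diagonal_is_half(self):
        p = ObserverParams(sigma_s=6.0, sigma_c=0.5)
        g = expected_choice_map(p, condition="higher_higher").grid.to_numpy()
        assert np.allclose(np.diag(g), 0.5, atol=1e-9)

    @pytest.mark.parametrize("sigma_c", [0.0, 0.8])
    def test_matches_monte_carlo(self, sigma_c):
        p = ObserverParams(sigma_s=6.0, sigma_c=sigma_c, lapse=0.02)
        m = expected_choice_map(p, condition="aggregate").grid
        rng = np.random.default_rng(17)
        n = 200_000
        for a, b in [(-9.0, 3.0), (0.0, 0.0), (6.0, -6.0)]:
            _, _, choose1, _, _ = simulate_decisions(
                p, np.full(n, a), np.full(n, b), rng)
            est = choose1.mean()
            se = np.sqrt(est * (1 - est) / n)
            assert abs(m.loc[a, b] - est) < 3 * se + 1e-12

    def test_aggregate_monotone_in_first_task_strength(self):
        p = ObserverParams(sigma_s=6.0, sigma_c=0.5)
        g = expected_choice_map(p, condition="aggregate").grid
        col = g[3.0]  # fixed second-task delta
        pos = col.loc[[0.0, 3.0, 6.0, 9.0]].to_numpy()
        neg = col.loc[[0.0, -3.0, -6.0, -9.0]].to_numpy()
        assert (np.diff(pos) > 0).all() and (np.diff(neg) > 0).all()

    def test_empirical_map_converges_to_expected(self):
        p = ObserverParams(sigma_s=6.0, sigma_c=0.5)
        expected = expected_choice_map(p, condition="aggregate").grid
        rng = np.random.default_rng(23)
        spec = DesignSpec()
        deltas = spec.deltas
        n_per_cell = 6000  # ~ 500 sessions' worth per cell on average
        max_dev = 0.0
        for a in deltas:
            _, _, choose1, _, _ = simulate_decisions(
                p, np.full(n_per_cell * 7, a),
                np.tile(deltas, n_per_cell), rng)
            est = choose1.reshape(n_per_cell, 7).mean(axis=0)
            max_dev = max(max_dev, np.max(np.abs(est - expected.loc[a])))
        assert max_dev < 0.02


class TestSimulateCohort:
    def test_bitwise_reproducible(self):
        spec = CohortSpec(n_per_group=3, seed=8)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for pid in a.sessions:
            pd.testing.assert_frame_equal(a.sessions[pid], b.sessions[pid])

    def test_group_structure(self):
        coh = simulate_cohort(CohortSpec(n_per_group=12, seed=21))
        truth = coh.truth.groupby("age_group")
        assert truth["sigma_s"].mean()["older"] > \
            truth["sigma_s"].mean()["younger"]
        parts = coh.participants.groupby("age_group")
        assert parts["dsst"].mean()["older"] < parts["dsst"].mean()["younger"]
        assert parts["tmt_b_s"].mean()["older"] > \
            parts["tmt_b_s"].mean()["younger"]
        assert len(coh.participants) == 24
        assert all(len(s) == 420 for s in coh.sessions.values())

    def test_infeasible_ef_link_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            CohortSpec(ef_link=0.98).validate()

    def test_older_group_less_sensitive_unsorted(self):
        coh = simulate_cohort(CohortSpec(n_per_group=10, seed=31))
        sens = {}
        for group in ("older", "younger"):
            pids = coh.truth.loc[coh.truth["age_group"] == group,
                                 "participant_id"]
            sens[group] = np.mean([
                fit_confidence_sets(coh.sessions[p])[1].sensitivity
                for p in pids])
        assert sens["older"] < sens["younger"]
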