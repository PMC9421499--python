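"""Synthetic cohort generator: calibration, determinism, observation rules."""

import numpy as np
import pytest

from healthexp.chain import step_transition_matrix
from healthexp.cohort import (SimulationConfig, default_true_params,
                              generate_cohort, preset,
                              simulate_individual_path)
from healthexp.io import write_panel_csv
from healthexp.params import TransitionParams


def _zero_hazard_params(**kw):
    return TransitionParams(intercepts=[-1e3] * 4, age_slopes=np.zeros(4), **kw)


class TestConfigValidation:
    def test_bad_prevalence_rejected(self, true_params):
        with pytest.raises(ValueError, match="prevalence"):
            preset("cohort1921", covariate_prevalences={
                "education": 1.2, "obese": .1, "smoker": .1, "exercise": .9})

    def test_empty_schedule_rejected(self, true_params):
        with pytest.raises(ValueError, match="schedule"):
            preset("cohort1921", wave_offsets_months=())

    def test_nonincreasing_schedule_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            preset("cohort1921", wave_offsets_months=(0, 36, 36))


class TestGenerateCohort:
    def test_no_mortality_full_response_gives_complete_panel(self):
        cfg = preset("cohort1921", n_individuals=40, seed=1,
                     wave_response_prob=1.0,
                     true_params=_zero_hazard_params(),
                     covariate_prevalences={})
        ds = generate_cohort(cfg)
        n_waves = len(cfg.wave_offsets_months)
        assert all(len(r.waves) == n_waves for r in ds)
        assert all(not r.died for r in ds)
        assert all(w.state == 0 for r in ds for w in r.waves)

    def test_obesity_prevalence_within_three_binomial_se(self):
        n, p = 10_000, 0.134
        cfg = preset("cohort1921", n_individuals=n, seed=99,
                     wave_offsets_months=(0,))
        ds = generate_cohort(cfg)
        obese = np.mean([r.obese for r in ds])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(obese - p) < 3 * se

    def test_same_seed_is_byte_identical(self, tmp_path):
        paths = []
        for name in ("a.csv", "b.csv"):
            cfg = preset("cohort1946", n_individuals=150, seed=5)
            write_panel_csv(generate_cohort(cfg), tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_baseline_ages_match_cohort_window(self):
        ds = generate_cohort(preset("cohort1921", n_individuals=300, seed=2,
                                    interview_jitter_days=0))
        ages = [(w0.date.year - r.birth_year) for r in ds
                for w0 in r.waves[:1]]
        assert min(ages) >= 69 and max(ages) <= 76

    def test_death_between_waves_absorbing_bookkeeping(self):
        ds = generate_cohort(preset("cohort1921", n_individuals=400, seed=3,
                                    wave_response_prob=1.0))
        died = [r for r in ds if r.died]
        assert died, "old cohort over 20 years must contain deaths"
        for r in died:
            d = r.death_age_months()
            from healthexp.panel import age_in_months
            for w in r.waves:
                assert age_in_months(r.birth_year, r.birth_month, w.date) <= d

    def test_zero_response_keeps_only_baseline_and_deaths(self):
        ds = generate_cohort(preset("cohort1921", n_individuals=120, seed=4,
                                    wave_response_prob=0.0))
        assert all(len(r.waves) == 1 for r in ds)
        assert any(r.died for r in ds)

    def test_nonresponse_recorded_as_unknown_when_requested(self):
        ds = generate_cohort(preset("cohort1921", n_individuals=120, seed=4,
                                    wave_response_prob=0.0,
                                    record_nonresponse=True))
        survivors = [r for r in ds if not r.died]
        assert any(len(r.waves) > 1 for r in survivors)
        assert all(w.state == -1 for r in survivors for w in r.waves[1:])


class TestLatentProcess:
    def test_zero_hazards_give_constant_path(self, rng):
        path = simulate_individual_path(70.0, {}, _zero_hazard_params(),
                                        80.0, rng)
        assert np.all(path.states == 0)
        assert len(path.states) == 121

    def test_death_absorbing_in_every_path(self, rng, true_params):
        prof = dict(education=0, obese=1, smoker=1, exercise=0)
        for _ in range(200):
            path = simulate_individual_path(85.0, prof, true_params, 100.0, rng)
            dead = np.flatnonzero(path.states == 2)
            if dead.size:
                assert np.all(path.states[dead[0]:] == 2)
                assert dead[0] == len(path.states) - 1  # truncated at death

    def test_geometric_survival_closed_form(self, rng):
        q = 0.02
        a = float(np.log(q / (1 - q)))
        params = TransitionParams(intercepts=[-1e3, a, -1e3, a],
                                  age_slopes=np.zeros(4))
        from healthexp.cohort import _simulate_state_matrix
        n = 10_000
        t0 = 70 * 12
        S = _simulate_state_matrix(np.full(n, t0), t0 + 600,
                                   np.zeros((n, 0)), params, rng)
        first_dead = np.argmax(S == 2, axis=1)
        assert np.all(S[:, -1] == 2), "horizon long enough to absorb all"
        months = first_dead - 1  # transition occurred during that month
        s = 1 - q
        expect = s / (12 * (1 - s))
        got = np.mean(months) / 12
        mc_se = np.std(months, ddof=1) / np.sqrt(n) / 12
        assert abs(got - expect) < 3 * mc_se

    def test_monthly_transition_frequencies_match_step_matrix(self, rng,
                                                              true_params):
        """>= 1e5 simulated person-months at a fixed age reproduce the
        one-step probabilities within 4 binomial SEs."""
        prof = dict(education=1, obese=0, smoker=1, exercise=1)
        n = 120_000
        M = step_transition_matrix(80.0, prof, true_params)
        x = true_params.profile_vector(prof)
        from healthexp.cohort import _simulate_state_matrix
        S = _simulate_state_matrix(np.full(n, 80 * 12), 80 * 12 + 1,
                                   np.tile(x, (n, 1)), true_params, rng)
        nxt = S[:, 1]
        for j in range(3):
            phat = np.mean(nxt == j)
            p = M[0, j]
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(phat - p) < 4 * se + 1e-12

    def test_death_rate_nondecreasing_in_age(self, rng):
        """With an age-increasing death logit, the empirical monthly death
        rate among survivors rises across 10-year age bins (10,000 paths)."""
        params = TransitionParams(intercepts=[-1e3, -6.0, -1e3, -6.0],
                                  age_slopes=[0.0, 0.1, 0.0, 0.1],
                                  age_center=70.0)
        from healthexp.cohort import _simulate_state_matrix
        n = 10_000
        t0 = 70 * 12
        S = _simulate_state_matrix(np.full(n, t0), 100 * 12,
                                   np.zeros((n, 0)), params, rng)
        alive = S[:, :-1] == 0
        dies = (S[:, :-1] == 0) & (S[:, 1:] == 2)
        edges = [(0, 120), (120, 240), (240, 360)]
        rates = [dies[:, lo:hi].sum() / alive[:, lo:hi].sum()
                 for lo, hi in edges]
        assert rates[0] < rates[1] < rates[2]


class TestPresetCalibration:
    @pytest.mark.parametrize("name,n_waves,span_years", [
        ("cohort1921", 16, 20), ("cohort1946", 8, 20)])
    def test_wave_schedules(self, name, n_waves, span_years):
        cfg = preset(name)
        assert len(cfg.wave_offsets_months) == n_waves
        assert cfg.wave_offsets_months[-1] == span_years * 12

    def test_prevalences_sit_in_unit_interval(self):
        for name in ("cohort1921", "cohort1946"):
            for p in preset(name).covariate_prevalences.values():
                assert 0.0 <= p <= 1.0
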