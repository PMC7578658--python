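"""Statistical fidelity of the track generator to the model it emulates."""
import numpy as np
import pandas as pd
import pytest

import telemove as tm
from telemove.model import stationary_distribution, transition_matrix


@pytest.fixture(scope="module")
def nocov_tracks(big_landscape, ref_spec_nocov):
    return tm.simulate_tracks(ref_spec_nocov, big_landscape, n_tracks=30, n_steps=400, seed=21)


def _pooled_steps_angles(tracks):
    states = np.concatenate([tr.true_states[1:] for tr in tracks])
    steps = np.concatenate([np.hypot(*np.diff(tr.positions, axis=0).T) for tr in tracks])
    angles = np.concatenate([
        tm.wrap_angle(np.diff(tr.bearings))[0:] for tr in tracks
    ])
    return states, steps, angles


def test_step_moments_per_state(nocov_tracks, ref_spec_nocov):
    em = ref_spec_nocov.emissions
    states, steps, _ = _pooled_steps_angles(nocov_tracks)
    for k in range(3):
        s = steps[states == k + 1]
        n = s.size
        se_mean = em.step_sd[k] / np.sqrt(n)
        assert abs(s.mean() - em.step_mean[k]) < 3 * se_mean
        se_sd = em.step_sd[k] / np.sqrt(2 * n)  # approximate SE of a sample SD
        assert abs(s.std() - em.step_sd[k]) < 3 * se_sd


def test_turning_angle_circular_moments_per_state(nocov_tracks, ref_spec_nocov):
    em = ref_spec_nocov.emissions
    states = np.concatenate([tr.true_states[1:] for tr in nocov_tracks])
    turns = np.concatenate([
        tm.wrap_angle(np.diff(tr.bearings)) for tr in nocov_tracks
    ])
    from telemove.model import mean_resultant_length
    for k in range(3):
        a = turns[states == k + 1]
        n = a.size
        rho_true = mean_resultant_length(em.angle_conc[k])
        c, s = np.cos(a).mean(), np.sin(a).mean()
        rho_hat = np.hypot(c, s)
        # SE of rho_hat is below 1/sqrt(2n) for these weak concentrations
        assert abs(rho_hat - rho_true) < 3 / np.sqrt(2 * n)
        mean_hat = np.arctan2(s, c)
        se_mean = 1 / np.sqrt(n * rho_true**2 * em.angle_conc[k])
        assert abs(tm.wrap_angle(mean_hat - em.angle_mean[k])) < 3 * max(se_mean, 0.05)
        sd_hat = np.sqrt(-2 * np.log(rho_hat))
        sd_true = tm.circular_sd_kappa(em.angle_conc[k], "to_sd")
        assert sd_hat == pytest.approx(sd_true, rel=0.1)


def test_empirical_transition_frequencies(nocov_tracks, ref_spec_nocov):
    gamma = transition_matrix(ref_spec_nocov.transitions)
    counts = np.zeros((3, 3))
    for tr in nocov_tracks:
        s = tr.true_states[1:] - 1
        for a, b in zip(s[:-1], s[1:]):
            counts[a, b] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freq = counts / totals
    se = np.sqrt(gamma * (1 - gamma) / totals)
    assert np.all(np.abs(freq - gamma) < 3 * se)


def test_dwell_time_matches_geometric(nocov_tracks, ref_spec_nocov):
    gamma = transition_matrix(ref_spec_nocov.transitions)
    runs = {k: [] for k in range(3)}
    for tr in nocov_tracks:
        s = tr.true_states[1:]
        run = 1
        for a, b in zip(s[:-1], s[1:]):
            if a == b:
                run += 1
            else:
                runs[a - 1].append(run)
                run = 1
    for k in range(3):
        r = np.asarray(runs[k], dtype=float)
        expected = 1.0 / (1.0 - gamma[k, k])
        se = expected * np.sqrt(gamma[k, k]) / np.sqrt(r.size)  # geometric SD / sqrt(n)
        assert abs(r.mean() - expected) < 3 * se


def test_single_state_mean_step(big_landscape):
    em = tm.EmissionParams([1.2], [0.4], [0.0], [1.0])
    spec = tm.HMMSpec(em, tm.TransitionModel(1, np.zeros((1, 0))))
    tracks = tm.simulate_tracks(spec, big_landscape, 5, 500, seed=3)
    _, steps, _ = _pooled_steps_angles(tracks)
    assert abs(steps.mean() - 1.2) < 3 * 0.4 / np.sqrt(steps.size)


def test_straight_line_limit(big_landscape):
    em = tm.EmissionParams([0.1], [1e-6], [0.0], [1e6])
    spec = tm.HMMSpec(em, tm.TransitionModel(1, np.zeros((1, 0))))
    tracks = tm.simulate_tracks(spec, big_landscape, 1, 50, seed=4)
    tr = tracks[0]
    net = np.hypot(*(tr.positions[-1] - tr.positions[0]))
    assert net == pytest.approx(50 * 0.1, rel=1e-2)


def test_seeded_determinism(landscape, ref_spec_nocov):
    a = tm.simulate_tracks(ref_spec_nocov, landscape, 3, 50, seed=9)
    b = tm.simulate_tracks(ref_spec_nocov, landscape, 3, 50, seed=9)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.positions, tb.positions)
        assert np.array_equal(ta.true_states, tb.true_states)


def test_tracks_stay_in_bounds(landscape, ref_spec_nocov):
    tracks = tm.simulate_tracks(ref_spec_nocov, landscape, 5, 300, seed=10)
    xmin, xmax, ymin, ymax = landscape.extent
    for tr in tracks:
        assert tr.positions[:, 0].min() >= xmin and tr.positions[:, 0].max() <= xmax
        assert tr.positions[:, 1].min() >= ymin and tr.positions[:, 1].max() <= ymax


def test_round_trip_recovers_generator_draws(big_landscape, ref_spec_nocov):
    tracks = tm.simulate_tracks(ref_spec_nocov, big_landscape, 3, 200, seed=12)
    recs = tm.steps_and_angles(tm.regularize(tm.tracks_to_fixes(tracks), 80))
    for tr in tracks:
        sub = recs[recs["id"] == tr.individual_id]
        true_steps = np.hypot(*np.diff(tr.positions, axis=0).T)
        assert np.allclose(sub["step_km"].to_numpy(), true_steps, atol=1e-9)
        true_angles = tm.wrap_angle(np.diff(tr.bearings))
        got = sub["angle_rad"].to_numpy()[1:]
        assert np.allclose(got, true_angles[1:], atol=1e-9)


class TestInjectResting:
    def test_zero_probability_is_identity(self, landscape, ref_spec_nocov):
        tracks = tm.simulate_tracks(ref_spec_nocov, landscape, 2, 40, seed=1)
        fixes = tm.inject_resting(tracks, 0.0, seed=2)
        pd.testing.assert_frame_equal(fixes, tm.tracks_to_fixes(tracks))

    def test_resting_fraction_binomial(self, big_landscape):
        # fast emissions so genuine steps are never below the threshold
        em = tm.EmissionParams([2.0], [0.3], [0.0], [1.0])
        spec = tm.HMMSpec(em, tm.TransitionModel(1, np.zeros((1, 0))))
        tracks = tm.simulate_tracks(spec, big_landscape, 2, 500, seed=5)
        fixes = tm.inject_resting(tracks, 0.2, seed=6)
        recs = tm.steps_and_angles(fixes)
        n = len(recs)
        n_short = int((recs["step_km"] < 0.2).sum())
        se = np.sqrt(n * 0.2 * 0.8)
        # a rest also perturbs the following step, so allow a margin above pure binomial
        assert abs(n_short - 0.2 * n) < 3 * se + 0.1 * n_short

    def test_determinism(self, landscape, ref_spec_nocov):
        tracks = tm.simulate_tracks(ref_spec_nocov, landscape, 2, 60, seed=7)
        a = tm.inject_resting(tracks, 0.3, seed=8)
        b = tm.inject_resting(tracks, 0.3, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_probability(self, landscape, ref_spec_nocov):
        tracks = tm.simulate_tracks(ref_spec_nocov, landscape, 1, 10, seed=1)
        with pytest.raises(ValueError):
            tm.inject_resting(tracks, 1.0)
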