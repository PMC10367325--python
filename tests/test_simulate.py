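import numpy as np
import pytest
from scipy.stats import ks_2samp

from sshmm import simulate
from sshmm.sensor_fusion import FORAGE, REST, TRAVEL
from sshmm.simulate import (
    SimConfig,
    default_transition,
    effective_emissions,
    inject_gaps,
    simulate_dataset,
    simulate_moves,
    simulate_sensors,
    simulate_states,
)
from sshmm.track_prep import compute_move_metrics, regularize


class TestSimulateStates:
    def test_identity_chain_is_constant(self):
        s = simulate_states(500, np.eye(3), seed=0)
        assert (s == s[0]).all()

    def test_uniform_chain_frequencies(self):
        g = np.full((3, 3), 1 / 3)
        s = simulate_states(30_000, g, seed=1)
        freqs = np.bincount(s, minlength=3) / len(s)
        sd = np.sqrt((1 / 3) * (2 / 3) / len(s))
        np.testing.assert_allclose(freqs, 1 / 3, atol=3 * sd)

    def test_default_self_transition_frequencies(self):
        """Self-transition rates match the configured diagonal
        (0.82 rest, 0.59 forage, 0.76 travel) on a long chain."""
        g = default_transition()
        s = simulate_states(100_000, g, seed=2)
        for i, target in enumerate([0.82, 0.59, 0.76]):
            at_i = s[:-1] == i
            stay = (s[1:][at_i] == i).mean()
            assert stay == pytest.approx(target, abs=0.02)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            simulate_states(10, np.ones((3, 3)), seed=0)


class TestSimulateMoves:
    def test_high_concentration_straight_track(self):
        em = simulate.default_emissions()
        em.kappa[:] = 1e4
        states = np.full(50, TRAVEL)
        raw = simulate_moves(states, em, seed=3)
        mv = compute_move_metrics(regularize(raw))
        assert np.nanmax(np.abs(mv.angle)) < 0.2

    def test_rest_step_moment(self):
        em = simulate.default_emissions()
        states = np.full(100_001, REST)
        raw = simulate_moves(states, em, seed=4)
        mv = compute_move_metrics(regularize(raw))
        assert np.nanmean(mv.step) == pytest.approx(em.step_mean[REST], rel=0.01)

    def test_metrics_recover_generated_distribution(self):
        """The forward step/angle convention of the generator matches the
        metric computation: angles drawn ~ vonMises come back out."""
        em = simulate.default_emissions()
        states = np.full(5000, FORAGE)
        raw = simulate_moves(states, em, seed=5)
        mv = compute_move_metrics(regularize(raw))
        ang = mv.angle[~np.isnan(mv.angle)]
        r = np.hypot(np.cos(ang).mean(), np.sin(ang).mean())
        # mean resultant length of vonMises(kappa=0.5) is I1/I0(0.5) ~ 0.2425
        assert r == pytest.approx(0.2425, abs=0.03)

    def test_full_overlap_merges_step_distributions(self):
        """At overlap 1 the forage and travel step samples are draws from
        the same distribution (two-sample KS at alpha = 0.01)."""
        rejections = 0
        for seed in range(30):
            cfg = SimConfig(overlap_level=1.0, seed=seed)
            em = effective_emissions(cfg)
            rng = np.random.default_rng(seed)
            a = rng.gamma(em.gamma_shape[FORAGE], em.gamma_scale[FORAGE], 800)
            b = rng.gamma(em.gamma_shape[TRAVEL], em.gamma_scale[TRAVEL], 800)
            if ks_2samp(a, b).pvalue < 0.01:
                rejections += 1
        assert rejections <= 2  # >= 95% of replicates pass

    def test_zero_overlap_keeps_presets(self):
        em = effective_emissions(SimConfig(overlap_level=0.0))
        np.testing.assert_array_equal(em.step_mean, [30, 600, 2500])


class TestSimulateSensors:
    def cfg(self, **kw):
        return SimConfig(n_trips=1, fixes_per_trip=kw.pop("t", 100), **kw)

    def test_zero_coverage_all_missing(self):
        states = simulate_states(200, default_transition(), 0)
        out = simulate_sensors(states, self.cfg(sensor_coverage=0.0), seed=1)
        assert out.isna().all().all()

    def test_perfect_sensors_follow_rules(self):
        states = simulate_states(2000, default_transition(), 1)
        cfg = self.cfg(
            sensor_coverage=1.0, dive_detect_prob=1.0, wet_noise=0.0, conflict_rate=0.0
        )
        out = simulate_sensors(states, cfg, seed=2)
        rest = states == REST
        travel = states == TRAVEL
        forage = states == FORAGE
        assert (out.loc[rest, "prop_wet"] == 1.0).all()
        assert (out.loc[travel, "prop_wet"] == 0.0).all()
        dives = out.loc[forage, ["dives_acc", "dives_tdr"]].fillna(0).sum(axis=1)
        assert (dives >= 1).all()

    def test_conflict_rate_binomial(self):
        states = simulate_states(10_000, default_transition(), 3)
        cfg = self.cfg(sensor_coverage=1.0, conflict_rate=0.01, wet_noise=0.0)
        out = simulate_sensors(states, cfg, seed=4)
        conflicted = ((out["prop_wet"] == 0.0) & (out["prop_on_water"] > 0.5)).sum()
        sd = np.sqrt(10_000 * 0.01 * 0.99)
        assert abs(conflicted - 100) <= 3 * sd


class TestInjectGaps:
    def make_track(self, n, seed=0):
        states = simulate_states(n, default_transition(), seed)
        return simulate_moves(states, simulate.default_emissions(), seed + 1)

    def test_zero_rate_unchanged(self):
        raw = self.make_track(500)
        out = inject_gaps(raw, 0.0, seed=1)
        np.testing.assert_array_equal(out.times, raw.times)

    def test_gap_incidence_matches_targets(self):
        raw = self.make_track(100_000)
        out = inject_gaps(raw, 1.0, seed=2)
        gaps = np.diff(out.times)
        n = len(out.times)
        short = ((gaps > 300) & (gaps <= 1200)).sum() / n
        long = (gaps > 1200).sum() / n
        sd_s = np.sqrt(0.015 * 0.985 / n)
        sd_l = np.sqrt(0.004 * 0.996 / n)
        assert short == pytest.approx(0.015, abs=3 * sd_s)
        assert long == pytest.approx(0.004, abs=3 * sd_l)

    def test_long_gaps_split_on_regularization(self):
        raw = self.make_track(20_000)
        out = inject_gaps(raw, 1.0, seed=3)
        gaps = np.diff(out.times)
        long_gaps = (gaps > 1200).sum()
        reg = regularize(out)
        assert len(reg.segments) == long_gaps + 1


class TestSimulateDataset:
    def test_pure_function_of_config(self):
        a = simulate_dataset(SimConfig(n_trips=3, fixes_per_trip=40, seed=9))
        b = simulate_dataset(SimConfig(n_trips=3, fixes_per_trip=40, seed=9))
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.x, tb.x)
        assert a.sensors.equals(b.sensors)
        assert a.truth.equals(b.truth)

    def test_per_trip_coverage(self):
        sim = simulate_dataset(
            SimConfig(n_trips=40, fixes_per_trip=30, seed=10, sensor_coverage=0.5)
        )
        per_trip = sim.truth.groupby("trip_id")["covered"].mean()
        assert set(np.round(per_trip.unique(), 6)) <= {0.0, 1.0}

    def test_truth_aligned_with_tracks(self):
        sim = simulate_dataset(SimConfig(n_trips=3, fixes_per_trip=50, seed=11))
        for track in sim.tracks:
            tr = sim.truth[sim.truth["trip_id"] == track.trip_id]
            # every surviving fix has a truth row at its timestamp
            assert np.isin(track.times, tr["timestamp"].to_numpy()).all()
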