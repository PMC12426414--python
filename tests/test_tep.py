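import numpy as np
import pytest

from tmsreact import (Montage, average_tep, epoch, extract_peaks, gmfa,
                      interpolate_artifact, local_tep, map_m1_sides,
                      reject_epochs)
from tmsreact.containers import RestingRecording, TepEpochs
from tmsreact.simulate import TepComponent, TepSimSpec, simulate_tep_epochs
from tmsreact.tep import EvokedTrace


def make_epochs(data, montage=None, fs=1000.0):
    data = np.asarray(data, float)
    n_t = data.shape[2]
    times = np.arange(n_t) - n_t // 2  # ms, centered on 0
    montage = montage or Montage(
        names=tuple(f"ch{i}" for i in range(data.shape[1])), clusters={})
    return TepEpochs(data=data, times=times.astype(float), montage=montage, fs=fs)


class TestEpoching:
    def test_100_events_on_long_record(self):
        mont = Montage(names=("A", "B"), clusters={})
        rec = RestingRecording(np.zeros((2, 310_000)), 1000.0, mont)
        events = 2.0 + 3.0 * np.arange(100)
        ep = epoch(rec, events)
        assert ep.n_trials == 100
        assert ep.data.shape == (100, 2, 2001)
        assert 0.0 in ep.times

    def test_event_near_edge_dropped(self):
        mont = Montage(names=("A",), clusters={})
        rec = RestingRecording(np.zeros((1, 10_000)), 1000.0, mont)
        with pytest.warns(UserWarning, match="dropped 1"):
            ep = epoch(rec, [0.5, 5.0])
        assert ep.n_trials == 1
        assert ep.meta["n_events_dropped"] == 1

    def test_constant_channel_yields_constant_epochs(self):
        mont = Montage(names=("A",), clusters={})
        rec = RestingRecording(np.full((1, 20_000), 3.5), 1000.0, mont)
        ep = epoch(rec, [5.0, 10.0])
        assert np.all(ep.data == 3.5)

    def test_pulse_sample_lands_at_time_zero(self):
        mont = Montage(names=("A",), clusters={})
        data = np.zeros((1, 20_000))
        data[0, 7000] = 9.0
        rec = RestingRecording(data, 1000.0, mont)
        ep = epoch(rec, [7.0])
        assert ep.data[0, 0, ep.time_index(0.0)] == 9.0


class TestInterpolation:
    def test_cubic_reproduces_straight_line(self):
        t = np.arange(-50, 51, dtype=float)
        line = 0.3 * t + 2.0
        data = np.tile(line, (2, 3, 1)).astype(float)
        spiked = data.copy()
        ep = make_epochs(spiked)
        win = (ep.times > -5) & (ep.times < 15)
        ep.data[:, :, win] += 500.0
        out = interpolate_artifact(ep, (-5.0, 15.0))
        assert np.allclose(out.data, data, atol=1e-9)

    def test_samples_outside_window_bit_identical(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((3, 2, 201)))
        out = interpolate_artifact(ep, (-5.0, 15.0))
        outside = (ep.times <= -5.0) | (ep.times >= 15.0)
        assert np.array_equal(out.data[:, :, outside], ep.data[:, :, outside])
        assert out.interpolated_window == (-5.0, 15.0)

    def test_zero_artifact_interpolation_close_to_smooth_truth(self, montage):
        noise_sd = 1.0
        spec = TepSimSpec(n_trials=30, noise_sd=noise_sd, seed=3,
                          components=(TepComponent("P60", 60.0, 5.0),))
        ep = simulate_tep_epochs(spec, montage)
        out = interpolate_artifact(ep)
        evoked_in = average_tep(ep, baseline_ms=None)
        evoked_out = average_tep(out, baseline_ms=None)
        win = (ep.times > -5) & (ep.times < 15)
        assert np.abs(evoked_out[:, win] - evoked_in[:, win]).max() < 4 * noise_sd

    def test_window_covering_epoch_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 201)))
        with pytest.raises(ValueError, match="strictly inside"):
            interpolate_artifact(ep, (-200.0, 200.0))


class TestRejection:
    def test_quiet_trials_all_kept(self):
        ep = make_epochs(np.full((5, 2, 201), 50.0))
        out = reject_epochs(ep, 100.0)
        assert out.n_trials == 5
        assert out.rejected_trials == []

    def test_large_excursion_trial_rejected(self):
        data = np.zeros((4, 2, 401))
        data[2, 1, 350] = 500.0  # +200 ms region (index 350 -> t = +150)
        ep = make_epochs(data)
        out = reject_epochs(ep, 100.0)
        assert out.rejected_trials == [2]
        assert out.n_trials == 3

    def test_excursion_inside_excluded_window_ignored(self):
        data = np.zeros((3, 1, 201))
        ep = make_epochs(data)
        at5 = ep.time_index(5.0)
        ep.data[1, 0, at5] = 500.0
        out = reject_epochs(ep, 100.0, exclude_window_ms=(-5.0, 15.0))
        assert out.rejected_trials == []
        assert out.n_trials == 3

    def test_all_rejected_raises(self):
        ep = make_epochs(np.full((2, 1, 201), 900.0))
        with pytest.raises(RuntimeError, match="100"):
            reject_epochs(ep, 100.0)


class TestAveraging:
    def test_noiseless_component_amplitude_preserved(self, montage):
        spec = TepSimSpec(n_trials=5, noise_sd=0.0, seed=0, components=(
            TepComponent("P60", 60.0, 5.0),))
        ep = simulate_tep_epochs(spec, montage)
        evoked = average_tep(ep)
        assert evoked[:, ep.time_index(60.0)] == pytest.approx(5.0, abs=1e-6)

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((4, 3, 2001)))
        evoked = average_tep(ep, baseline_ms=(-500.0, -50.0))
        sel = (ep.times >= -500) & (ep.times <= -50)
        assert np.allclose(evoked[:, sel].mean(axis=1), 0.0, atol=1e-9)

    def test_opposite_trials_cancel(self):
        data = np.stack([np.ones((2, 201)), -np.ones((2, 201))])
        evoked = average_tep(make_epochs(data), baseline_ms=None)
        assert np.allclose(evoked, 0.0)


class TestGmfa:
    def test_uniform_field_gives_zero(self):
        t = np.arange(5.0)
        assert np.allclose(gmfa(np.ones((4, 5)), t).values, 0.0)

    def test_two_channel_antisymmetric_field(self):
        ev = np.array([[1.0], [-1.0]])
        assert gmfa(ev, np.array([0.0])).values[0] == pytest.approx(1.0)

    def test_four_channel_hand_computation(self):
        ev = np.array([[2.0], [2.0], [-2.0], [-2.0]])
        assert gmfa(ev, np.array([0.0])).values[0] == pytest.approx(2.0)

    def test_matches_bruteforce_population_sd(self):
        rng = np.random.default_rng(2)
        ev = rng.standard_normal((59, 400))
        trace = gmfa(ev, np.arange(400.0))
        oracle = np.array([np.sqrt(np.mean((ev[:, t] - ev[:, t].mean()) ** 2))
                           for t in range(400)])
        assert np.allclose(trace.values, oracle, atol=1e-12)

    def test_offset_invariance_and_absolute_scaling(self):
        rng = np.random.default_rng(3)
        ev = rng.standard_normal((10, 50))
        t = np.arange(50.0)
        base = gmfa(ev, t).values
        shifted = gmfa(ev + 7.3, t).values
        assert np.allclose(shifted, base, atol=1e-12)
        scaled = gmfa(-2.0 * ev, t).values
        assert np.allclose(scaled, 2.0 * base, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="two channels"):
            gmfa(np.ones((1, 5)), np.arange(5.0))


class TestLocalTep:
    def test_identical_cluster_channels(self, montage):
        ev = np.zeros((59, 11))
        idx = montage.cluster_indices("m1_left")
        ev[idx, :] = 4.0
        trace = local_tep(ev, np.arange(11.0), montage, "m1_left")
        assert np.allclose(trace.values, 4.0)

    def test_cluster_local_exceeds_gmfa_for_focal_pattern(self, montage):
        # 9-of-59 focal pattern: local mean = amplitude, GMFA smaller
        ev = np.zeros((59, 1))
        idx = montage.cluster_indices("m1_left")
        ev[idx, 0] = 5.0
        local = local_tep(ev, np.array([0.0]), montage, "m1_left").values[0]
        g = gmfa(ev, np.array([0.0])).values[0]
        assert local == pytest.approx(5.0)
        k, n = len(idx), 59
        expected_g = 5.0 * np.sqrt(k / n * (1 - k / n))
        assert g == pytest.approx(expected_g, abs=1e-12)
        assert g < local

    def test_lateralized_component_favors_its_side(self, montage):
        ev = np.zeros((59, 1))
        ev[montage.cluster_indices("m1_left"), 0] = 3.0
        left = local_tep(ev, np.array([0.0]), montage, "m1_left").values[0]
        right = local_tep(ev, np.array([0.0]), montage, "m1_right").values[0]
        assert left > right

    def test_missing_cluster_rejected(self, montage):
        with pytest.raises(KeyError, match="nope"):
            local_tep(np.zeros((59, 5)), np.arange(5.0), montage, "nope")


class TestPeaks:
    @staticmethod
    def trace(values, kind="local"):
        values = np.asarray(values, float)
        return EvokedTrace(kind=kind, times=np.arange(values.size, dtype=float),
                           values=values, n_trials=1)

    def test_noiseless_planted_p60(self, montage):
        spec = TepSimSpec(n_trials=3, noise_sd=0.0, seed=0, components=(
            TepComponent("P60", 60.0, 5.0),))
        ep = simulate_tep_epochs(spec, montage)
        evoked = average_tep(ep)
        trace = local_tep(evoked, ep.times, montage, "m1_left")
        pk = extract_peaks(trace)["P60"]
        assert pk.found
        assert pk.latency_ms == pytest.approx(60.0, abs=1.0)
        assert pk.amplitude_uv == pytest.approx(5.0, rel=1e-3)

    def test_monotone_trace_has_no_peak(self):
        tr = self.trace(np.linspace(0, 10, 300))
        pk = extract_peaks(tr, {"P30": (20.0, 40.0)})["P30"]
        assert not pk.found

    def test_largest_extremum_wins(self):
        t = np.arange(0.0, 120.0)
        y = (4.0 * np.exp(-0.5 * ((t - 50) / 3) ** 2)
             + 6.0 * np.exp(-0.5 * ((t - 70) / 3) ** 2))
        tr = EvokedTrace(kind="local", times=t, values=y, n_trials=1)
        pk = extract_peaks(tr, {"P60": (45.0, 80.0)})["P60"]
        assert pk.latency_ms == pytest.approx(70.0, abs=1.0)
        assert pk.amplitude_uv == pytest.approx(6.0, rel=0.01)

    def test_equal_extrema_tie_break_earliest(self):
        t = np.arange(0.0, 100.0)
        y = (5.0 * np.exp(-0.5 * ((t - 60) / 2) ** 2)
             + 5.0 * np.exp(-0.5 * ((t - 75) / 2) ** 2))
        tr = EvokedTrace(kind="local", times=t, values=y, n_trials=1)
        pk = extract_peaks(tr, {"P60": (55.0, 80.0)})["P60"]
        assert pk.latency_ms == pytest.approx(60.0, abs=1.0)

    def test_n_component_takes_minima_on_local_trace(self):
        t = np.arange(0.0, 200.0)
        y = -4.0 * np.exp(-0.5 * ((t - 100) / 5) ** 2)
        tr = EvokedTrace(kind="local", times=t, values=y, n_trials=1)
        pk = extract_peaks(tr, {"N100": (85.0, 140.0)})["N100"]
        assert pk.found
        assert pk.amplitude_uv == pytest.approx(-4.0, rel=0.01)

    def test_gmfa_trace_all_components_are_maxima(self):
        t = np.arange(0.0, 200.0)
        y = 3.0 * np.exp(-0.5 * ((t - 100) / 5) ** 2)
        tr = EvokedTrace(kind="gmfa", times=t, values=y, n_trials=1)
        pk = extract_peaks(tr, {"N100": (85.0, 140.0)})["N100"]
        assert pk.found and pk.amplitude_uv > 0

    def test_amplitude_ladder_is_monotone(self, montage):
        # increasing planted P60 strictly increases the GMFA peak
        peaks = []
        topo = tuple(1.0 if n in montage.clusters["m1_left"] else 0.0
                     for n in montage.names)
        for amp in (2.0, 3.0, 4.0, 5.0, 6.0):
            spec = TepSimSpec(n_trials=2, noise_sd=0.0, seed=0, components=(
                TepComponent("P60", 60.0, amp, topography=topo),))
            ep = simulate_tep_epochs(spec, montage)
            tr = gmfa(average_tep(ep), ep.times)
            peaks.append(extract_peaks(tr)["P60"].amplitude_uv)
        assert np.all(np.diff(peaks) > 0)


class TestSideMapping:
    def test_contralateral_rule(self):
        assert map_m1_sides("right") == {"M1plus": "left", "M1minus": "right"}
        assert map_m1_sides("left") == {"M1plus": "right", "M1minus": "left"}

    def test_involution(self):
        for side in ("left", "right"):
            assert map_m1_sides(map_m1_sides(side)["M1plus"])["M1plus"] == side

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError, match="unknown side"):
            map_m1_sides("both")
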