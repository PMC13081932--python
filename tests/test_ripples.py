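"""Sharp-wave-ripple detection, clustering and peri-event statistics."""

import numpy as np
import pytest
from scipy import signal as sps

from _helpers import chain_clusters_oracle, match_events
from voltscope.ripples import (
    EventSet,
    assign_frames_to_events,
    cluster_onsets,
    detect_ripples,
    framewise_ripple_power,
    peri_event_average,
    quantify_event_response,
)
from voltscope.synthetic import simulate_lfp_with_ripples
from voltscope.timeseries import TimeSeries


def _oracle_first_crossing(lfp, band=(130.0, 200.0), thresh_sd=3.0):
    """Brute-force onset oracle: band-pass, envelope, first upward crossing."""
    sos = sps.bessel(4, band, btype="bandpass", fs=lfp.rate_hz, output="sos")
    env = np.abs(sps.hilbert(sps.sosfiltfilt(sos, lfp.values)))
    level = env.mean() + thresh_sd * env.std()
    above = env > level
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return idx / lfp.rate_hz


class TestDetect:
    def test_infinite_threshold_gives_no_events(self):
        lfp, _ = simulate_lfp_with_ripples(duration_s=10, seed=0)
        assert detect_ripples(lfp, thresh_sd=np.inf).onset_times_s.size == 0

    def test_injected_burst_matches_oracle_crossing(self):
        lfp, gt = simulate_lfp_with_ripples(duration_s=30, seed=1, ripple_times_s=[10.0])
        det = detect_ripples(lfp)
        oracle = _oracle_first_crossing(lfp)
        # the onset nearest the burst agrees with the oracle crossing
        d_det = det.onset_times_s[np.argmin(np.abs(det.onset_times_s - 10.0))]
        d_or = oracle[np.argmin(np.abs(oracle - 10.0))]
        assert abs(d_det - d_or) <= 0.005
        # and the burst stands out in envelope SD units
        i = int(np.argmin(np.abs(det.onset_times_s - d_det)))
        assert det.peak_envelope_sd[i] > 5

    def test_scaling_invariance(self):
        lfp, _ = simulate_lfp_with_ripples(duration_s=20, seed=2)
        a = detect_ripples(lfp).onset_times_s
        b = detect_ripples(lfp.copy(values=37.0 * lfp.values)).onset_times_s
        np.testing.assert_allclose(a, b)

    def test_null_crossings_match_oracle_rate(self):
        # threshold crossings on ripple-free 1/f noise equal the brute-force
        # oracle's crossing count after the 20-ms merge
        for seed in range(3):
            lfp, _ = simulate_lfp_with_ripples(duration_s=30, seed=seed,
                                               ripple_rate_hz=0.0)
            det = detect_ripples(lfp)
            oracle = _oracle_first_crossing(lfp)
            merged = [oracle[0]] if oracle.size else []
            for t in oracle[1:]:
                if t - merged[-1] > 0.02:
                    merged.append(t)
            assert det.onset_times_s.size == len(merged)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_ripples(TimeSeries(np.zeros(500), 1000.0))


class TestCluster:
    def test_chained_onsets_share_cluster(self):
        ev = EventSet(onset_times_s=np.array([0.0, 0.5, 0.9, 5.0]))
        cl = cluster_onsets(ev, eps_s=1.0)
        assert cl.cluster_id[0] == cl.cluster_id[1] == cl.cluster_id[2]
        assert cl.cluster_id[3] != cl.cluster_id[0]
        np.testing.assert_allclose(cl.representatives_s, [0.0, 5.0])

    def test_empty_input(self):
        cl = cluster_onsets(EventSet(onset_times_s=np.array([])))
        assert cl.onset_times_s.size == 0

    def test_isolated_onsets_all_representative(self):
        ev = EventSet(onset_times_s=np.array([0.0, 3.0, 7.0]))
        cl = cluster_onsets(ev, eps_s=1.0)
        assert cl.is_representative.all()

    def test_equals_transitive_closure_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            onsets = np.sort(rng.uniform(0, 30, rng.integers(2, 25)))
            cl = cluster_onsets(EventSet(onset_times_s=onsets), eps_s=1.0)
            oracle = chain_clusters_oracle(onsets, 1.0)
            # same partition (labels up to renaming)
            for lab in np.unique(cl.cluster_id):
                members = np.flatnonzero(cl.cluster_id == lab)
                assert len(set(oracle[members])) == 1
            assert len(np.unique(cl.cluster_id)) == len(np.unique(oracle))


class TestFramewisePower:
    def test_frame_aligned_ramp(self):
        env = TimeSeries(np.repeat(np.arange(1.0, 21.0), 10), 100.0)
        frames = np.arange(20) * 0.1
        out = framewise_ripple_power(env, frames)
        ramp = np.arange(1.0, 21.0)
        np.testing.assert_allclose(out.values, ramp / ramp.std(), rtol=1e-9)

    def test_constant_envelope_degenerate_zeros(self):
        env = TimeSeries(np.full(1000, 2.0), 100.0)
        out = framewise_ripple_power(env, np.arange(10) * 1.0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_single_frame_burst_is_max(self):
        vals = np.zeros(1000)
        vals[500:510] = 5.0
        out = framewise_ripple_power(TimeSeries(vals, 100.0), np.arange(10) * 1.0)
        assert np.argmax(out.values) == 5

    def test_frames_outside_support_rejected(self):
        env = TimeSeries(np.ones(100), 100.0)
        with pytest.raises(ValueError):
            framewise_ripple_power(env, [0.5, 2.0])


def _ripple_session(reps, profile, n_cells=4, n_animals=2, dur=60.0, rate=288.0,
                    noise=0.002, seed=0):
    rng = np.random.default_rng(seed)
    n = int(dur * rate)
    t = np.arange(n) / rate
    cells, animals = [], []
    for ci in range(n_cells):
        vals = noise * rng.standard_normal(n)
        for r in reps:
            vals += profile(t - r)
        cells.append(TimeSeries(vals, rate))
        animals.append(f"m{ci % n_animals}")
    return cells, animals


class TestPeriEvent:
    def test_no_frame_double_counted(self):
        rate = 288.0
        frames = np.arange(int(20 * rate)) / rate
        reps = np.array([5.0, 5.2, 5.5, 12.0])
        assign = assign_frames_to_events(frames, reps, window=(-0.3, 0.4))
        # oracle: count appearances of each frame across event windows
        assert assign.max() < len(reps)
        used = assign[assign >= 0]
        # every used frame appears exactly once by construction of the vector;
        # check window membership and nearest-event rule
        for fi in np.flatnonzero(assign >= 0):
            rel = frames[fi] - reps
            inside = np.flatnonzero((rel >= -0.3) & (rel <= 0.4))
            assert assign[fi] in inside
            d = np.abs(rel[inside])
            assert np.abs(frames[fi] - reps[assign[fi]]) == d.min()

    def test_flat_traces_give_flat_average(self):
        cells, animals = _ripple_session([10.0], lambda dt: 0.0 * dt, noise=0.0)
        res = peri_event_average(cells, animals, [10.0])
        np.testing.assert_allclose(res.grand_mean, 0.0, atol=1e-12)

    def test_single_animal_sem_undefined(self):
        cells, animals = _ripple_session([10.0], lambda dt: 0.0 * dt, n_animals=1)
        res = peri_event_average(cells, animals, [10.0])
        assert np.isnan(res.sem).all()

    def test_stereotyped_response_peak_position(self):
        def profile(dt):
            return 0.02 * ((dt >= 0.0) & (dt < 0.05))
        reps = np.arange(5.0, 55.0, 5.0)
        cells, animals = _ripple_session(reps, profile, seed=1)
        res = peri_event_average(cells, animals, reps)
        peak_t = res.time_s[np.nanargmax(res.grand_mean)]
        assert 0.0 <= peak_t <= 0.05 + 1.0 / res.frame_rate_hz


class TestQuantify:
    def _session_with_peak_trough(self, sign=1.0, seed=0):
        def profile(dt):
            out = np.zeros_like(dt)
            out += 0.02 * np.exp(-((dt - 0.021) ** 2) / (2 * 0.015 ** 2))
            out -= 0.01 * np.exp(-((dt - 0.114) ** 2) / (2 * 0.012 ** 2))
            return sign * out
        reps = np.arange(5.0, 55.0, 5.0)
        cells, animals = _ripple_session(reps, profile, n_cells=6, n_animals=3,
                                         seed=seed)
        return peri_event_average(cells, animals, reps)

    def test_peak_then_trough_locations_and_significance(self):
        res = self._session_with_peak_trough()
        q = quantify_event_response(res)
        frame = 1.0 / res.frame_rate_hz
        assert abs(q["peak_time_s"] - 0.021) <= frame + 1e-9
        assert abs(q["trough_time_s"] - 0.114) <= frame + 1e-9
        assert q["peak_time_s"] < q["trough_time_s"]
        assert q["p_peak"] < 0.05 and q["p_trough"] < 0.05
        assert (q["peak_responses"] > 0).all()
        assert (q["trough_responses"] < 0).all()

    def test_hyperpolarization_only_profile(self):
        # a dip with no depolarizing lobe: the trough test fires, and the
        # peak response is an order of magnitude smaller than the trough
        def profile(dt):
            return -0.02 * np.exp(-((dt - 0.021) ** 2) / (2 * 0.015 ** 2))
        reps = np.arange(5.0, 55.0, 5.0)
        cells, animals = _ripple_session(reps, profile, n_cells=6, n_animals=3,
                                         seed=3)
        q = quantify_event_response(peri_event_average(cells, animals, reps))
        assert q["p_trough"] < 0.05
        assert abs(np.mean(q["trough_responses"])) > 3 * abs(np.mean(q["peak_responses"]))

    def test_flat_traces_nonsignificant(self):
        cells, animals = _ripple_session([10.0, 20.0, 30.0], lambda dt: 0.0 * dt,
                                         n_cells=6, n_animals=3, seed=2)
        res = peri_event_average(cells, animals, [10.0, 20.0, 30.0])
        q = quantify_event_response(res)
        assert q["p_peak"] > 0.05 and q["p_trough"] > 0.05


class TestEndToEnd:
    def test_detected_ripples_drive_peri_event_ordering(self):
        lfp, gt = simulate_lfp_with_ripples(duration_s=60, seed=5, ripple_rate_hz=0.2)
        det = detect_ripples(lfp)
        tp, n_true, _ = match_events(det.onset_times_s, gt.ripple_times_s, 0.02)
        assert tp == n_true        # all injected bursts found
        clustered = cluster_onsets(det)
        assert clustered.representatives_s.size <= det.onset_times_s.size
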