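"""Synthetic session generator with known ground truth.

Every input the analysis stages consume -- pose tracks, turn events,
spike trains, photometry traces, EMG recordings, projection-density
tables -- can be generated here with configurable direction selectivity,
turning speed, noise level and laterality bias, so each estimator can be
validated against the parameters that produced its input.

The body model is a rigid four-landmark frame (nose 1.5 cm ahead of the
ear midpoint, tail base 3 cm behind, ears +/-0.5 cm off the trunk axis)
rotating about the ear midpoint according to a turn schedule; no
biomechanical realism is attempted beyond that. Spikes are an
inhomogeneous Poisson process with multiplicative direction-specific
gains inside post-turn response windows. Photometry is a baseline
fluorescence modulated by a difference-of-exponentials calcium kernel.
EMG bursts are amplitude-normalized rectified-noise envelopes. Densities
are log-normal draws around per-side means.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .emg import EMGTrace
from .events import TurnEvent
from .kinematics import PoseTrack
from .photometry import PhotometrySignal
from .spiketrains import SpikeTrain

# rigid body geometry (cm), fixed so the head-trunk angle is 0 by construction
NOSE_AHEAD_CM = 1.5
TAIL_BEHIND_CM = 3.0
EAR_HALF_SPAN_CM = 0.5


@dataclass(frozen=True)
class TurnBout:
    """One scheduled turning bout of the behavior protocol."""

    onset_s: float
    direction: str  # "ipsi" | "contra"
    total_angle_deg: float
    angular_speed_dps: float

    @property
    def duration_s(self) -> float:
        return self.total_angle_deg / self.angular_speed_dps


@dataclass
class BehaviorProtocol:
    """Structure of a simulated turning session.

    ``immobile_fraction`` is the fraction of inter-bout time spent fully
    immobile; the remainder drifts slowly (below the default immobility
    threshold) to mimic non-turning activity.
    """

    session_duration: float = 60.0
    frame_rate: float = 30.0
    turn_schedule: Sequence[TurnBout] = field(default_factory=list)
    immobile_fraction: float = 1.0
    landmark_noise_sd: float = 0.0  # cm
    drift_speed_dps: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError("immobile_fraction must be in [0, 1]")
        bouts = sorted(self.turn_schedule, key=lambda b: b.onset_s)
        for b in bouts:
            if b.angular_speed_dps <= 0:
                raise ValueError("angular_speed must be positive")
            if b.onset_s < 0 or b.onset_s + b.duration_s > self.session_duration:
                raise ValueError(f"bout at {b.onset_s}s exceeds the session")
        for a, b in zip(bouts, bouts[1:]):
            if a.onset_s + a.duration_s > b.onset_s:
                raise ValueError(
                    f"overlapping bouts at {a.onset_s}s and {b.onset_s}s"
                )
        self.turn_schedule = bouts


@dataclass(frozen=True)
class StimProtocol:
    """Optogenetic stimulation schedule (pulse train metadata)."""

    duration_s: float = 10.0
    pulse_width_ms: float = 5.0
    frequency_hz: float = 20.0
    n_trains: int = 6
    inter_train_interval_s: float = 2.0
    power_label_mw: str = "5-8"

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.pulse_width_ms * self.frequency_hz > 1000.0:
            raise ValueError("duty cycle exceeds 100% (pulse_width*frequency > 1000)")

    def train_onsets(self, first_onset_s: float = 0.0) -> np.ndarray:
        step = self.duration_s + self.inter_train_interval_s
        return first_onset_s + step * np.arange(self.n_trains)


@dataclass(frozen=True)
class TuningSpec:
    """Ground-truth direction tuning of a simulated unit.

    Firing rate is ``baseline_rate`` everywhere, multiplied by
    ``ipsi_gain`` (resp. ``contra_gain``) within
    ``[onset+latency, onset+latency+duration]`` of each ipsi (contra)
    turn event.
    """

    baseline_rate: float = 5.0
    ipsi_gain: float = 1.0
    contra_gain: float = 1.0
    response_latency: float = 0.0
    response_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.ipsi_gain < 0 or self.contra_gain < 0:
            raise ValueError("rates and gains must be nonnegative")
        if self.response_duration <= 0:
            raise ValueError("response_duration must be positive")


@dataclass(frozen=True)
class CalciumKernel:
    """Difference-of-exponentials calcium impulse response.

    Defaults approximate slow genetically encoded indicator dynamics
    (rise ~0.2 s, decay ~1.5 s). The kernel is normalized so its peak
    equals ``amplitude`` (in dF/F units).
    """

    rise_tau: float = 0.2
    decay_tau: float = 1.5
    amplitude: float = 0.05

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("require decay_tau > rise_tau > 0")

    @property
    def peak_time(self) -> float:
        r, d = self.rise_tau, self.decay_tau
        return r * d / (d - r) * np.log(d / r)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Kernel evaluated at times ``t`` (seconds; 0 before t=0)."""
        t = np.asarray(t, dtype=float)
        tc = np.maximum(t, 0.0)
        raw = np.where(
            t >= 0, np.exp(-tc / self.decay_tau) - np.exp(-tc / self.rise_tau), 0.0
        )
        tp = self.peak_time
        peak = np.exp(-tp / self.decay_tau) - np.exp(-tp / self.rise_tau)
        return self.amplitude * raw / peak


def _bout_sign(direction: str, hemisphere: str) -> float:
    """Heading-change sign of a bout: +1 = increasing heading (leftward)."""
    ipsi_sign = 1.0 if hemisphere == "left" else -1.0
    return ipsi_sign if direction == "ipsi" else -ipsi_sign


def gen_pose(
    protocol: BehaviorProtocol, hemisphere: str, seed: int
) -> tuple[PoseTrack, list[TurnEvent]]:
    """Generate a rigid-body pose track following the turn schedule.

    Returns the track and the ground-truth turn events with directions
    resolved against ``hemisphere``.
    """
    rng = np.random.default_rng(seed)
    fr = protocol.frame_rate
    n = int(round(protocol.session_duration * fr)) + 1
    t = np.arange(n) / fr

    omega = np.zeros(n)  # deg/s heading rate per frame
    for bout in protocol.turn_schedule:
        sign = _bout_sign(bout.direction, hemisphere)
        in_bout = (t >= bout.onset_s) & (t < bout.onset_s + bout.duration_s)
        omega[in_bout] = sign * bout.angular_speed_dps

    if protocol.immobile_fraction < 1.0:
        # slow drift in the middle portion of each inter-bout gap
        gaps = []
        prev_end = 0.0
        for bout in protocol.turn_schedule:
            gaps.append((prev_end, bout.onset_s))
            prev_end = bout.onset_s + bout.duration_s
        gaps.append((prev_end, protocol.session_duration))
        for g0, g1 in gaps:
            span = g1 - g0
            if span <= 0:
                continue
            active = span * (1.0 - protocol.immobile_fraction)
            c = 0.5 * (g0 + g1)
            sel = (t >= c - active / 2) & (t < c + active / 2) & (omega == 0)
            omega[sel] = protocol.drift_speed_dps * rng.choice([-1.0, 1.0])

    heading = np.deg2rad(np.concatenate(([0.0], np.cumsum(omega[:-1]) / fr)))
    u = np.stack([np.cos(heading), np.sin(heading)], axis=1)  # trunk axis
    left_n = np.stack([-np.sin(heading), np.cos(heading)], axis=1)  # animal's left

    mid = np.zeros((n, 2))
    nose = mid + NOSE_AHEAD_CM * u
    tail = mid - TAIL_BEHIND_CM * u
    lear = mid + EAR_HALF_SPAN_CM * left_n
    rear = mid - EAR_HALF_SPAN_CM * left_n

    if protocol.landmark_noise_sd > 0:
        noise = rng.normal(0.0, protocol.landmark_noise_sd, size=(4, n, 2))
        nose = nose + noise[0]
        lear = lear + noise[1]
        rear = rear + noise[2]
        tail = tail + noise[3]

    track = PoseTrack(
        time=t, nose=nose, left_ear=lear, right_ear=rear, tailbase=tail,
        frame_rate=fr, hemisphere=hemisphere,
    )
    events = [
        TurnEvent(b.onset_s, b.direction, b.total_angle_deg, b.angular_speed_dps)
        for b in protocol.turn_schedule
    ]
    return track, events


def gen_spikes(
    spec: TuningSpec,
    events: Sequence[TurnEvent],
    duration: float,
    seed: int,
    unit_id: str = "u0",
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train with direction-gain windows.

    The rate is piecewise constant: ``baseline_rate`` everywhere,
    multiplied by the direction gain inside each event's response window
    (gains multiply where windows overlap).
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    for e in events:
        if not 0 <= e.onset_s <= duration:
            raise ValueError(f"event at {e.onset_s}s outside [0, {duration}]")
    rng = np.random.default_rng(seed)

    # breakpoints of the piecewise-constant rate
    edges = {0.0, duration}
    for e in events:
        w0 = e.onset_s + spec.response_latency
        w1 = w0 + spec.response_duration
        edges.add(min(max(w0, 0.0), duration))
        edges.add(min(max(w1, 0.0), duration))
    bk = np.array(sorted(edges))

    times = []
    for a, b in zip(bk[:-1], bk[1:]):
        if b <= a:
            continue
        rate = spec.baseline_rate
        for e in events:
            w0 = e.onset_s + spec.response_latency
            if w0 <= a and b <= w0 + spec.response_duration:
                rate *= spec.ipsi_gain if e.direction == "ipsi" else spec.contra_gain
        if rate <= 0:
            continue
        k = rng.poisson(rate * (b - a))
        if k:
            times.append(rng.uniform(a, b, size=k))
    spike_times = np.sort(np.concatenate(times)) if times else np.array([])
    return SpikeTrain(unit_id=unit_id, spike_times=spike_times, session_duration=duration)


def gen_photometry(
    events: Sequence[TurnEvent],
    kernel: CalciumKernel,
    gains: dict[str, float],
    sample_rate: float,
    duration: float,
    noise_sd: float = 0.0,
    baseline_F: float = 100.0,
    seed: int = 0,
    hemisphere: str = "right",
) -> PhotometrySignal:
    """Fluorescence trace: F = F0 * (1 + sum of gain-scaled kernels) + noise."""
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    resp = np.zeros(n)
    for e in events:
        resp += gains[e.direction] * kernel(t - e.onset_s)
    F = baseline_F * (1.0 + resp)
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, size=n)
    return PhotometrySignal(time=t, F=F, sample_rate=sample_rate, hemisphere=hemisphere)


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="same")


DEFAULT_FREQ_GAIN = {1.0: 0.0, 5.0: 0.7, 10.0: 0.85, 20.0: 1.0, 40.0: 1.1}


def gen_emg(
    stim: StimProtocol,
    onsets: Sequence[float],
    side_gain: float,
    latency: float,
    seed: int,
    sample_rate: float = 1000.0,
    noise_sd: float = 0.02,
    burst_amplitude: float = 2.0,
    burst_duration: float = 0.5,
    freq_gain_map: dict[float, float] | None = None,
    duration: float | None = None,
    side: str = "ipsi",
) -> EMGTrace:
    """EMG trace: baseline noise plus one burst per stimulation onset.

    Each burst is a rectified, smoothed noise carrier under a fast-rise /
    slow-decay envelope, normalized so its peak equals
    ``burst_amplitude * side_gain * freq_gain(frequency)`` exactly; the
    burst starts ``latency`` seconds after the onset. A ``side_gain`` of 0
    leaves pure baseline noise.
    """
    freq_gain_map = DEFAULT_FREQ_GAIN if freq_gain_map is None else freq_gain_map
    amp = burst_amplitude * side_gain * freq_gain_map.get(stim.frequency_hz, 1.0)
    rng = np.random.default_rng(seed)
    onsets = np.asarray(onsets, dtype=float)
    if duration is None:
        duration = float(onsets.max()) + 6.0 if onsets.size else 10.0
    n = int(round(duration * sample_rate)) + 1
    value = rng.normal(0.0, noise_sd, size=n)

    nb = int(round(burst_duration * sample_rate))
    tb = np.arange(nb) / sample_rate
    envelope = (1.0 - np.exp(-tb / 0.005)) * np.exp(-tb / 0.1)
    for onset in onsets:
        i0 = int(round((onset + latency) * sample_rate))
        if i0 >= n or amp <= 0:
            continue
        carrier = _smooth(
            np.abs(_smooth(rng.standard_normal(nb), max(1, int(0.002 * sample_rate)))),
            max(1, int(0.010 * sample_rate)),
        )
        burst = envelope * carrier
        burst *= amp / burst.max()
        stop = min(n, i0 + nb)
        value[i0:stop] += burst[: stop - i0]

    t = np.arange(n) / sample_rate
    return EMGTrace(
        time=t, value=value, sample_rate=sample_rate, side=side,
        stim_onsets=onsets,
    )


def gen_density(
    n_regions: int,
    ipsi_mean: float,
    contra_mean: float,
    cv: float,
    n_samples_per_side: int,
    seed: int,
    region_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Log-normal density table with columns animal_id, region, side, density.

    Per region, ``n_samples_per_side`` animals contribute one measurement
    per side, drawn log-normally around ``ipsi_mean`` / ``contra_mean``
    with coefficient of variation ``cv`` (``cv=0`` gives exact means).
    """
    if region_names is None:
        region_names = [f"region{i + 1}" for i in range(n_regions)]
    if len(region_names) != n_regions:
        raise ValueError("region_names length must equal n_regions")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    rows = []
    for region in region_names:
        for side, mean in (("ipsi", ipsi_mean), ("contra", contra_mean)):
            if cv == 0:
                vals = np.full(n_samples_per_side, mean)
            else:
                mu = np.log(mean) - sigma2 / 2
                vals = rng.lognormal(mu, sigma, size=n_samples_per_side)
            for animal, v in enumerate(vals, start=1):
                rows.append(
                    {"animal_id": f"m{animal}", "region": region,
                     "side": side, "density": float(v)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers (CSV dialects matching the stage readers) + parameter sidecar
# ---------------------------------------------------------------------------

def write_spikes_csv(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    rows = [
        {"unit_id": tr.unit_id, "spike_time_s": t}
        for tr in trains
        for t in tr.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(path, index=False)


def write_emg_csv(trace: EMGTrace, path: str | Path, onsets_path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "value_mv": trace.value}).to_csv(
        path, index=False
    )
    pd.DataFrame({"onset_s": trace.stim_onsets}).to_csv(onsets_path, index=False)


def write_density_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_sidecar(params: dict, seed: int, path: str | Path) -> None:
    """Record generator parameters and the seed next to the data files."""

    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    payload = {"seed": seed, "params": params}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
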