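"""End-to-end orchestration of synthetic or file-based analysis runs.

A flat key-value config (YAML mapping, one level deep) plus a seed fully
determines every output byte. Stages run in dependency order; each writes
its CSV outputs into the run directory and contributes a section to a
machine-readable ``summary.json`` that echoes every numerically relevant
parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from . import densitometry, emg, kinematics, photometry, spiketrains, synthetic
from .events import split_by_direction, write_events_csv
from .synthetic import BehaviorProtocol, CalciumKernel, StimProtocol, TuningSpec, TurnBout

logger = logging.getLogger(__name__)

STAGES = ("simulate", "kinematics", "photometry", "spikes", "emg", "density")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained on disk."""


@dataclass
class RunConfig:
    """Flat run configuration. Every field affecting numerics is echoed
    into the summary JSON."""

    hemisphere: str = "right"
    # behavior / kinematics
    session_duration: float = 120.0
    frame_rate: float = 30.0
    n_ipsi_bouts: int = 6
    n_contra_bouts: int = 4
    bout_angle_deg: float = 360.0
    bout_speed_dps: float = 90.0
    landmark_noise_sd: float = 0.05
    immobile_threshold_dps: float = 20.0
    min_bout_s: float = 0.5
    heading_smooth_s: float = 0.2
    turn_min_angle_deg: float = 60.0
    # photometry
    photometry_sample_rate: float = 50.0
    calcium_rise_tau: float = 0.2
    calcium_decay_tau: float = 1.5
    calcium_amplitude: float = 0.05
    photometry_ipsi_gain: float = 3.0
    photometry_contra_gain: float = 1.0
    photometry_noise_sd: float = 0.3
    photometry_baseline_f: float = 100.0
    align_pre_s: float = -2.0
    align_post_s: float = 5.0
    response_window_s: float = 2.0
    # spikes
    n_units: int = 20
    frac_ipsi_tuned: float = 0.51
    frac_contra_tuned: float = 0.33
    unit_baseline_hz: float = 5.0
    tuned_gain: float = 4.0
    spike_response_window_s: float = 0.5
    n_perm: int = 1000
    alpha: float = 0.05
    # emg
    emg_sample_rate: float = 1000.0
    emg_noise_sd: float = 0.02
    emg_burst_amplitude: float = 2.0
    emg_ipsi_gain: float = 1.0
    emg_contra_gain: float = 0.3
    emg_latency_s: float = 0.05
    emg_n_stim: int = 6
    stim_frequency_hz: float = 20.0
    # density
    density_n_regions: int = 2
    density_ipsi_mean: float = 2.0
    density_contra_mean: float = 1.0
    density_cv: float = 0.3
    density_n_per_side: int = 4
    # optional file-based inputs (synthetic generation used when absent)
    pose_csv: str = ""
    events_csv: str = ""
    photometry_csv: str = ""
    spikes_csv: str = ""
    emg_csv: str = ""
    emg_onsets_csv: str = ""
    density_csv: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _round_floats(obj, sig: int = 9):
    """Round all floats to `sig` significant digits for stable serialization."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def _behavior_protocol(config: RunConfig, rng: np.random.Generator) -> BehaviorProtocol:
    """Randomly interleave the configured ipsi/contra bouts over the session."""
    n_bouts = config.n_ipsi_bouts + config.n_contra_bouts
    bout_dur = config.bout_angle_deg / config.bout_speed_dps
    gap = (config.session_duration - n_bouts * bout_dur) / (n_bouts + 1)
    if gap <= 1.0:
        raise PipelineError("session too short for the configured bouts")
    dirs = ["ipsi"] * config.n_ipsi_bouts + ["contra"] * config.n_contra_bouts
    rng.shuffle(dirs)
    schedule = [
        TurnBout(
            onset_s=gap + i * (bout_dur + gap),
            direction=d,
            total_angle_deg=config.bout_angle_deg,
            angular_speed_dps=config.bout_speed_dps,
        )
        for i, d in enumerate(dirs)
    ]
    return BehaviorProtocol(
        session_duration=config.session_duration,
        frame_rate=config.frame_rate,
        turn_schedule=schedule,
        landmark_noise_sd=config.landmark_noise_sd,
    )


def tuning_mixture_population(
    n_ipsi: int = 66,
    n_contra: int = 43,
    n_untuned: int = 21,
    n_trials_per_side: int = 30,
    baseline_hz: float = 5.0,
    tuned_gain: float = 4.0,
    response_window_s: float = 0.5,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Simulate and classify a mixed-tuning unit population.

    Generates ``n_ipsi + n_contra + n_untuned`` Poisson units with the
    stated per-category gains, ``n_trials_per_side`` turn events per
    direction, classifies each unit with the permutation MI rule, and
    returns the population summary together with per-category recovery
    rates against ground truth.
    """
    rng = np.random.default_rng(seed)
    trial_spacing = 2.0
    n_trials = 2 * n_trials_per_side
    duration = trial_spacing * (n_trials + 1)
    onsets = trial_spacing * np.arange(1, n_trials + 1)
    from .events import TurnEvent

    events = [
        TurnEvent(float(t), "ipsi" if i % 2 == 0 else "contra")
        for i, t in enumerate(onsets)
    ]
    ipsi_ev, contra_ev = split_by_direction(events)

    truth = ["ipsi"] * n_ipsi + ["contra"] * n_contra + ["none"] * n_untuned
    results = []
    for i, true_label in enumerate(truth):
        spec = TuningSpec(
            baseline_rate=baseline_hz,
            ipsi_gain=tuned_gain if true_label == "ipsi" else 1.0,
            contra_gain=tuned_gain if true_label == "contra" else 1.0,
            response_latency=0.0,
            response_duration=response_window_s,
        )
        train = synthetic.gen_spikes(
            spec, events, duration, seed=int(rng.integers(2**31)), unit_id=f"u{i:03d}"
        )
        results.append(
            spiketrains.classify_unit(
                train, ipsi_ev, contra_ev,
                response_window=(0.0, response_window_s),
                n_perm=n_perm, alpha=alpha, rng=rng,
            )
        )
    summary = spiketrains.population_summary(results)
    recovery = {}
    for lab, n_true in (("ipsi", n_ipsi), ("contra", n_contra), ("none", n_untuned)):
        hits = sum(
            r.label == lab for r, t in zip(results, truth) if t == lab
        )
        recovery[lab] = hits / n_true if n_true else float("nan")
    summary["recovery"] = recovery
    summary["ground_truth_counts"] = {
        "ipsi": n_ipsi, "contra": n_contra, "none": n_untuned
    }
    return summary


def run_pipeline(
    config: RunConfig,
    seed: int,
    out_dir: str | Path,
    stages: Sequence[str] = STAGES,
) -> dict:
    """Execute the requested stages and write outputs under ``out_dir``.

    Returns the summary dict (also written as ``summary.json``). Raises
    :class:`PipelineError` on stage failure; outputs of completed stages
    remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}; valid: {STAGES}")

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("lateralis")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    summary: dict = {
        "lateralis_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config.to_dict(),
        "stages": {},
    }
    rng = np.random.default_rng(seed)
    track = events = signal = None

    try:
        want = set(stages)
        need_behavior = want & {"simulate", "kinematics", "photometry", "spikes"}

        if need_behavior:
            if config.pose_csv:
                track = kinematics.read_pose_csv(
                    config.pose_csv, config.frame_rate, config.hemisphere
                )
                if not config.events_csv:
                    raise PipelineError(
                        "config field 'events_csv' is required when pose_csv is set "
                        "and photometry/spike stages are requested"
                    )
                from .events import read_events_csv

                events = read_events_csv(config.events_csv)
            else:
                protocol = _behavior_protocol(config, rng)
                track, events = synthetic.gen_pose(
                    protocol, config.hemisphere, seed=int(rng.integers(2**31))
                )
                if "simulate" in want:
                    kinematics.write_pose_csv(track, out / "pose.csv")
                    write_events_csv(events, out / "events.csv")
                    synthetic.write_sidecar(
                        {"behavior": dataclasses.asdict(protocol)}, seed,
                        out / "params.json",
                    )
            summary["stages"]["simulate"] = {
                "n_frames": track.n_frames, "n_events": len(events)
            }

        if "kinematics" in want:
            series = kinematics.angular_velocity(
                track, smooth_s=config.heading_smooth_s
            )
            n_ipsi, n_contra = kinematics.count_rotations(series)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pct = (
                    kinematics.ipsi_percentage(n_ipsi, n_contra)
                    if n_ipsi + n_contra
                    else float("nan")
                )
                mav = kinematics.mean_angular_velocity(
                    series, config.immobile_threshold_dps, config.min_bout_s
                )
            detected = kinematics.detect_turn_events(
                series, min_angle=config.turn_min_angle_deg,
                min_speed=config.immobile_threshold_dps,
            )
            write_events_csv(detected, out / "detected_events.csv")
            summary["stages"]["kinematics"] = {
                "n_ipsi_rotations": n_ipsi,
                "n_contra_rotations": n_contra,
                "ipsi_percentage": pct,
                "mean_angular_velocity_dps": mav,
                "n_detected_turns": len(detected),
            }

        if "photometry" in want:
            if config.photometry_csv:
                signal = photometry.read_photometry_csv(
                    config.photometry_csv, config.hemisphere
                )
            else:
                kernel = CalciumKernel(
                    config.calcium_rise_tau,
                    config.calcium_decay_tau,
                    config.calcium_amplitude,
                )
                signal = synthetic.gen_photometry(
                    events, kernel,
                    {"ipsi": config.photometry_ipsi_gain,
                     "contra": config.photometry_contra_gain},
                    sample_rate=config.photometry_sample_rate,
                    duration=config.session_duration,
                    noise_sd=config.photometry_noise_sd,
                    baseline_F=config.photometry_baseline_f,
                    seed=int(rng.integers(2**31)),
                    hemisphere=config.hemisphere,
                )
                photometry.write_photometry_csv(signal, out / "photometry.csv")
            matrix = photometry.align_trials(
                signal, events, window=(config.align_pre_s, config.align_post_s)
            )
            photometry.write_trial_matrix_csv(matrix, out / "trial_matrix.csv")
            ipsi_m, contra_m = matrix.select("ipsi"), matrix.select("contra")
            res = photometry.compare_directions(
                ipsi_m, contra_m, response_window=(0.0, config.response_window_s)
            )
            mean_i, _ = photometry.average_response(ipsi_m)
            mean_c, _ = photometry.average_response(contra_m)
            summary["stages"]["photometry"] = {
                "n_trials": matrix.n_trials,
                "n_dropped": matrix.n_dropped,
                "peak_mean_dff_ipsi": float(mean_i.max()),
                "peak_mean_dff_contra": float(mean_c.max()),
                "direction_comparison": res.to_dict(),
                "baseline_mode": "per_trial_pre_event",
            }

        if "spikes" in want:
            ipsi_ev, contra_ev = split_by_direction(events)
            n_ipsi_u = int(round(config.frac_ipsi_tuned * config.n_units))
            n_contra_u = int(round(config.frac_contra_tuned * config.n_units))
            n_none_u = config.n_units - n_ipsi_u - n_contra_u
            truth = ["ipsi"] * n_ipsi_u + ["contra"] * n_contra_u + ["none"] * n_none_u
            trains, results = [], []
            for i, lab in enumerate(truth):
                spec = TuningSpec(
                    baseline_rate=config.unit_baseline_hz,
                    ipsi_gain=config.tuned_gain if lab == "ipsi" else 1.0,
                    contra_gain=config.tuned_gain if lab == "contra" else 1.0,
                    response_duration=config.spike_response_window_s,
                )
                if config.spikes_csv:
                    break
                train = synthetic.gen_spikes(
                    spec, events, config.session_duration,
                    seed=int(rng.integers(2**31)), unit_id=f"u{i:03d}",
                )
                trains.append(train)
            if config.spikes_csv:
                trains = spiketrains.read_spikes_csv(
                    config.spikes_csv, config.session_duration
                )
            else:
                synthetic.write_spikes_csv(trains, out / "spikes.csv")
            for train in trains:
                results.append(
                    spiketrains.classify_unit(
                        train, ipsi_ev, contra_ev,
                        response_window=(0.0, config.spike_response_window_s),
                        n_perm=config.n_perm, alpha=config.alpha, rng=rng,
                    )
                )
            spiketrains.write_tuning_csv(results, out / "tuning.csv")
            summary["stages"]["spikes"] = spiketrains.population_summary(results)

        if "emg" in want:
            stim = StimProtocol(frequency_hz=config.stim_frequency_hz)
            onsets = 5.0 + 8.0 * np.arange(config.emg_n_stim)
            if config.emg_csv:
                traces = {
                    "ipsi": emg.read_emg_csv(
                        config.emg_csv, config.emg_onsets_csv or None, side="ipsi"
                    )
                }
            else:
                traces = {
                    side: synthetic.gen_emg(
                        stim, onsets, gain, config.emg_latency_s,
                        seed=int(rng.integers(2**31)),
                        sample_rate=config.emg_sample_rate,
                        noise_sd=config.emg_noise_sd,
                        burst_amplitude=config.emg_burst_amplitude,
                        side=side,
                    )
                    for side, gain in (
                        ("ipsi", config.emg_ipsi_gain),
                        ("contra", config.emg_contra_gain),
                    )
                }
                synthetic.write_emg_csv(
                    traces["ipsi"], out / "emg_ipsi.csv", out / "emg_onsets.csv"
                )
            tables = {
                side: emg.per_onset_table(tr) for side, tr in traces.items()
            }
            emg_summary = {}
            for side, tbl in tables.items():
                tbl.to_csv(out / f"emg_{side}_per_onset.csv", index=False)
                emg_summary[side] = {
                    "n_repetitions": len(tbl),
                    "median_peak_mv": float(tbl["peak_amplitude_mv"].median()),
                    "median_latency_s": float(tbl["latency_s"].median()),
                }
            if len(tables) == 2:
                res = emg.compare_peaks(
                    tables["ipsi"]["peak_amplitude_mv"].tolist(),
                    tables["contra"]["peak_amplitude_mv"].tolist(),
                    paired=True,
                )
                emg_summary["side_comparison"] = res.to_dict()
            summary["stages"]["emg"] = emg_summary

        if "density" in want:
            if config.density_csv:
                table = densitometry.read_density_csv(config.density_csv)
            else:
                table = synthetic.gen_density(
                    config.density_n_regions,
                    config.density_ipsi_mean,
                    config.density_contra_mean,
                    config.density_cv,
                    config.density_n_per_side,
                    seed=int(rng.integers(2**31)),
                )
                synthetic.write_density_csv(table, out / "density.csv")
            indexed = densitometry.density_index(table)
            indexed.to_csv(out / "density_index.csv", index=False)
            dens_summary = {}
            for region in indexed["region"].unique():
                res = densitometry.compare_sides(indexed, region)
                sub = indexed[indexed["region"] == region]
                dens_summary[str(region)] = {
                    "mean_ipsi_index": float(
                        sub.loc[sub["side"] == "ipsi", "density_index"].mean()
                    ),
                    "mean_contra_index": float(
                        sub.loc[sub["side"] == "contra", "density_index"].mean()
                    ),
                    "comparison": res.to_dict(),
                }
            summary["stages"]["density"] = dens_summary

    except PipelineError:
        raise
    except Exception as exc:  # stage failure: retain partial outputs
        raise PipelineError(f"stage failure: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    summary = _round_floats(summary)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return summary
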