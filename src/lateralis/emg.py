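"""Stimulus-evoked EMG quantification.

Peak response amplitude is the maximum rectified deviation from the
pre-stimulus baseline median within a post-stimulation window (5 s by
default); rectifying around the baseline median makes the measure
invariant to DC offset. Response latency is the first sustained
threshold crossing (k standard deviations of the baseline) after the
onset. Group comparisons use Wilcoxon tests; at least five valid
stimulus repetitions per animal are expected for aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .stats import StatResult, two_group

logger = logging.getLogger(__name__)

MIN_REPETITIONS = 5


@dataclass
class EMGTrace:
    """A single-muscle EMG recording with its stimulation onsets."""

    time: np.ndarray
    value: np.ndarray  # mV
    sample_rate: float
    side: str = "ipsi"  # {ipsi, contra}
    stim_onsets: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must share shape")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.stim_onsets.size and (
            self.stim_onsets.min() < self.time[0]
            or self.stim_onsets.max() > self.time[-1]
        ):
            raise ValueError("stimulation onsets must lie within the recording")
        if self.stim_onsets.size < MIN_REPETITIONS:
            logger.info(
                "only %d stimulus repetitions (>= %d recommended)",
                self.stim_onsets.size, MIN_REPETITIONS,
            )

    def _idx(self, t: float) -> int:
        return int(round((t - self.time[0]) * self.sample_rate))


def _baseline(trace: EMGTrace, onset: float, pre_s: float = 1.0):
    """Median and SD of the pre-stimulus baseline [onset-pre_s, onset)."""
    i0 = max(0, trace._idx(onset - pre_s))
    i1 = trace._idx(onset)
    seg = trace.value[i0:i1]
    if seg.size < 2:
        raise ValueError(f"no baseline samples before onset at {onset}s")
    return float(np.median(seg)), float(np.std(seg))


def peak_amplitude(
    trace: EMGTrace, onset: float, window: float = 5.0, baseline_pre_s: float = 1.0
) -> float | None:
    """Maximum rectified amplitude within ``window`` s after ``onset``, mV.

    Computed as max |value - baseline_median| over (onset, onset+window].
    Returns None (with a log entry) when the window would be truncated by
    the end of the recording.
    """
    i0 = trace._idx(onset)
    i1 = trace._idx(onset + window)
    if i1 >= trace.value.size:
        logger.warning("onset at %.3fs: post-stimulation window truncated; skipped", onset)
        return None
    med, _ = _baseline(trace, onset, baseline_pre_s)
    return float(np.max(np.abs(trace.value[i0 + 1 : i1 + 1] - med)))


def response_latency(
    trace: EMGTrace,
    onset: float,
    k_sd: float = 3.0,
    sustain_s: float = 0.010,
    window: float = 5.0,
    baseline_pre_s: float = 1.0,
) -> float:
    """Latency to the first sustained threshold crossing after onset, s.

    The threshold is ``k_sd`` baseline standard deviations around the
    baseline median and must be exceeded continuously for ``sustain_s``.
    NaN (flagged via warning) when never crossed within the window.
    """
    med, sd = _baseline(trace, onset, baseline_pre_s)
    i0 = trace._idx(onset)
    i1 = min(trace.value.size, trace._idx(onset + window) + 1)
    dev = np.abs(trace.value[i0:i1] - med)
    above = dev > k_sd * sd
    need = max(1, int(round(sustain_s * trace.sample_rate)))
    # first index where `need` consecutive samples are above threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            start = i - need + 1
            return float(start / trace.sample_rate)
    warnings.warn(f"onset at {onset}s: threshold never crossed; latency undefined")
    return float("nan")


def per_onset_table(
    trace: EMGTrace, window: float = 5.0, k_sd: float = 3.0
) -> pd.DataFrame:
    """Peak amplitude and latency for every stimulation onset."""
    rows = []
    for onset in trace.stim_onsets:
        amp = peak_amplitude(trace, onset, window=window)
        if amp is None:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lat = response_latency(trace, onset, k_sd=k_sd, window=window)
        rows.append(
            {"onset_s": onset, "side": trace.side,
             "peak_amplitude_mv": amp, "latency_s": lat}
        )
    df = pd.DataFrame(rows, columns=["onset_s", "side", "peak_amplitude_mv", "latency_s"])
    if len(df) < MIN_REPETITIONS:
        warnings.warn(
            f"only {len(df)} valid repetitions; >= {MIN_REPETITIONS} expected"
        )
    return df


def compare_peaks(
    group_a: list[float], group_b: list[float], paired: bool = True
) -> StatResult:
    """Wilcoxon comparison of peak amplitudes between two conditions.

    Signed-rank when paired (same animal, both sides), rank-sum otherwise.
    Warns below five pairs; refuses below two.
    """
    if min(len(group_a), len(group_b)) < MIN_REPETITIONS:
        warnings.warn("fewer than 5 observations per group; low power")
    return two_group(group_a, group_b, paired=paired)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_emg_csv(
    path: str | Path, onsets_path: str | Path | None = None, side: str = "ipsi"
) -> EMGTrace:
    """Read an EMG CSV (time_s, value_mv), optionally with an onsets CSV."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    onsets = np.array([])
    if onsets_path is not None:
        onsets = pd.read_csv(onsets_path)["onset_s"].to_numpy(dtype=float)
    return EMGTrace(
        time=t, value=df["value_mv"].to_numpy(dtype=float),
        sample_rate=fs, side=side, stim_onsets=onsets,
    )
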