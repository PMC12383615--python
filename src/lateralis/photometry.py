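"""Fiber-photometry dF/F computation and turn-aligned trial analysis.

The normalized fluorescence change is dF/F = (F - F0)/F0, where F0 is the
baseline fluorescence. Two baseline conventions are supported: a per-trial
pre-event mean (applied during trial alignment, invariant to affine sensor
rescaling) and a session-wide running percentile (robust to slow drift).
Trials are aligned on turn onsets into a trials x time matrix sharing one
relative-time axis, then averaged (mean +/- SEM) and compared between turn
directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import TurnEvent
from .stats import StatResult

logger = logging.getLogger(__name__)


@dataclass
class PhotometrySignal:
    """Uniformly sampled raw fluorescence trace (arbitrary units)."""

    time: np.ndarray
    F: np.ndarray
    sample_rate: float
    hemisphere: str = "right"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time.shape != self.F.shape:
            raise ValueError("time and F must share shape")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            nominal = 1.0 / self.sample_rate
            if np.any(np.abs(dt - nominal) > 1e-6 * nominal):
                raise ValueError("sampling must be uniform within 1 ppm")


@dataclass
class TrialMatrix:
    """Event-aligned dF/F, one row per trial on a common relative-time axis."""

    data: np.ndarray  # (n_trials, n_samples)
    rel_time: np.ndarray  # seconds, event at 0
    directions: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.rel_time = np.asarray(self.rel_time, dtype=float)
        if self.data.shape[0] and self.data.shape[1] != self.rel_time.size:
            raise ValueError("rows must match rel_time length")
        if self.data.shape[0] != len(self.directions):
            raise ValueError("one direction label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, direction: str) -> "TrialMatrix":
        keep = [i for i, d in enumerate(self.directions) if d == direction]
        return TrialMatrix(
            self.data[keep], self.rel_time, [self.directions[i] for i in keep]
        )


def compute_dff(
    signal: PhotometrySignal,
    method: str = "running_percentile",
    percentile: float = 10.0,
    window_s: float = 60.0,
    f0: float | np.ndarray | None = None,
) -> np.ndarray:
    """Session-wide dF/F = (F - F0)/F0.

    Parameters
    ----------
    method : {"running_percentile", "constant"}
        ``running_percentile`` estimates F0 as a centered running
        percentile of F (default 10th over 60 s), tracking slow drift.
        ``constant`` uses ``f0`` (scalar or per-sample array), or the
        session mean when ``f0`` is None.

    Raises
    ------
    ValueError
        If the F0 estimate is not strictly positive everywhere.
    """
    if method == "running_percentile":
        w = max(1, int(round(window_s * signal.sample_rate)))
        F0 = (
            pd.Series(signal.F)
            .rolling(w, center=True, min_periods=1)
            .quantile(percentile / 100.0)
            .to_numpy()
        )
    elif method == "constant":
        F0 = np.broadcast_to(
            np.asarray(signal.F.mean() if f0 is None else f0, dtype=float),
            signal.F.shape,
        )
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    bad = F0 <= 0
    if np.any(bad):
        raise ValueError(
            f"baseline F0 <= 0 at {int(bad.sum())} samples "
            f"(first at t={signal.time[np.argmax(bad)]:.3f}s); "
            "dF/F undefined -- check the baseline method/params"
        )
    return (signal.F - F0) / F0


def align_trials(
    signal: PhotometrySignal,
    events: Sequence[TurnEvent],
    window: tuple[float, float] = (-2.0, 5.0),
    baseline_window: tuple[float, float] = (-2.0, -0.5),
    dff: np.ndarray | None = None,
) -> TrialMatrix:
    """Align dF/F segments on turn onsets.

    With ``dff=None`` each trial is normalized by its own pre-event
    baseline: F0 = mean F over ``baseline_window`` relative to onset (the
    per-trial mode, invariant under F -> aF). Passing a precomputed
    session ``dff`` array instead slices it directly. Events whose window
    would run off the recording are dropped and logged.
    """
    pre, post = window
    if post <= pre:
        raise ValueError("window must satisfy post > pre")
    fs = signal.sample_rate
    i_pre = int(round(pre * fs))
    i_post = int(round(post * fs))
    rel_time = np.arange(i_pre, i_post + 1) / fs
    source = signal.F if dff is None else np.asarray(dff, dtype=float)

    rows, dirs, dropped = [], [], 0
    t0 = signal.time[0]
    for e in events:
        center = int(round((e.onset_s - t0) * fs))
        lo, hi = center + i_pre, center + i_post
        b_lo = center + int(round(baseline_window[0] * fs))
        b_hi = center + int(round(baseline_window[1] * fs))
        need_lo = min(lo, b_lo) if dff is None else lo
        if need_lo < 0 or hi >= signal.time.size:
            dropped += 1
            logger.info("dropping event at %.3fs: window exceeds recording", e.onset_s)
            continue
        seg = source[lo : hi + 1]
        if dff is None:
            F0 = float(np.mean(source[b_lo : b_hi + 1]))
            if F0 <= 0:
                raise ValueError(f"per-trial baseline <= 0 for event at {e.onset_s}s")
            seg = (seg - F0) / F0
        rows.append(seg)
        dirs.append(e.direction)

    if not rows:
        logger.warning("no usable events: empty trial matrix")
        return TrialMatrix(np.empty((0, rel_time.size)), rel_time, [], dropped)
    return TrialMatrix(np.vstack(rows), rel_time, dirs, dropped)


def average_response(matrix: TrialMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SEM across trials."""
    if matrix.n_trials == 0:
        raise ValueError("empty trial matrix")
    mean = matrix.data.mean(axis=0)
    if matrix.n_trials == 1:
        sem = np.zeros_like(mean)
    else:
        sem = matrix.data.std(axis=0, ddof=1) / np.sqrt(matrix.n_trials)
    return mean, sem


def compare_directions(
    ipsi: TrialMatrix,
    contra: TrialMatrix,
    response_window: tuple[float, float] = (0.0, 2.0),
    test: str = "t",
) -> StatResult:
    """Compare per-trial mean dF/F between turn directions.

    Each trial is summarized as its mean dF/F within ``response_window``;
    the two samples are compared with an unpaired t test (default, as the
    trial-averaged signals are) or a rank-sum test (``test="wilcoxon"``).
    The effect size reported is mean(ipsi) - mean(contra).
    """
    if ipsi.n_trials < 2 or contra.n_trials < 2:
        raise ValueError("need at least 2 trials per direction")
    sel_i = (ipsi.rel_time >= response_window[0]) & (ipsi.rel_time <= response_window[1])
    sel_c = (contra.rel_time >= response_window[0]) & (
        contra.rel_time <= response_window[1]
    )
    a = ipsi.data[:, sel_i].mean(axis=1)
    b = contra.data[:, sel_c].mean(axis=1)
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups; test undefined")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=True)
        name = "unpaired t"
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "rank-sum"
    else:
        raise ValueError(f"unknown test {test!r}")
    return StatResult(
        test=name,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        effect=float(a.mean() - b.mean()),
        n=(len(a), len(b)),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_photometry_csv(
    path: str | Path, hemisphere: str = "right"
) -> PhotometrySignal:
    """Read a photometry CSV with columns time_s, F."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return PhotometrySignal(
        time=t, F=df["F"].to_numpy(dtype=float), sample_rate=fs, hemisphere=hemisphere
    )


def write_photometry_csv(signal: PhotometrySignal, path: str | Path) -> None:
    pd.DataFrame({"time_s": signal.time, "F": signal.F}).to_csv(path, index=False)


def write_trial_matrix_csv(matrix: TrialMatrix, path: str | Path) -> None:
    """Export trials x time dF/F with the rel_time axis as header row."""
    df = pd.DataFrame(matrix.data, columns=[f"{t:.6g}" for t in matrix.rel_time])
    df.insert(0, "direction", matrix.directions)
    df.to_csv(path, index=False)
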