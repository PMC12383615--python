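"""Spike-train analysis: PSTH, direction tuning, and unit classification.

Each unit's direction preference is summarized by the modulation index

    MI = (R_ipsi - R_contra) / (R_ipsi + R_contra)

where R_ipsi and R_contra are mean firing rates in a post-turn response
window (default 0-0.5 s after turn initiation, where turn-locked spiking
concentrates). MI is bounded in [-1, 1]; its sign gives the preferred
direction. Significance comes from a label-permutation test on per-trial
spike counts, and units are labeled ipsi / contra / none accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import TurnEvent
from .stats import StatResult

LABELS = ("ipsi", "contra", "none")


@dataclass
class SpikeTrain:
    """Sorted spike times of one well-isolated unit."""

    unit_id: str
    spike_times: np.ndarray
    session_duration: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.session_duration < 0:
            raise ValueError("session_duration must be nonnegative")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < 0):
                raise ValueError("spike_times must be nondecreasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] > self.session_duration:
                raise ValueError("spike_times must lie within [0, session_duration]")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class PSTH:
    """Trial-averaged firing rate aligned on an event.

    Satisfies the mass identity
    sum(rate) * bin_width * n_trials = total in-window spike count.
    """

    bin_edges: np.ndarray  # seconds relative to event, len = n_bins + 1
    rate: np.ndarray  # Hz per bin
    n_trials: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class TuningResult:
    """Per-unit direction-tuning summary."""

    unit_id: str
    r_ipsi: float
    r_contra: float
    mi: float  # NaN when both rates are 0
    p_perm: float
    label: str
    flagged: bool = False  # insufficient trials or zero activity

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


def _event_times(events: Sequence[TurnEvent] | Sequence[float]) -> np.ndarray:
    return np.asarray(
        [e.onset_s if isinstance(e, TurnEvent) else float(e) for e in events]
    )


def _trial_counts(
    train: SpikeTrain, event_times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Spike count in [onset+w0, onset+w1) for each event."""
    lo = np.searchsorted(train.spike_times, event_times + window[0], side="left")
    hi = np.searchsorted(train.spike_times, event_times + window[1], side="left")
    return (hi - lo).astype(float)


def psth(
    train: SpikeTrain,
    events: Sequence[TurnEvent] | Sequence[float],
    window: tuple[float, float] = (-1.0, 1.0),
    bin_width: float = 0.05,
) -> PSTH:
    """Peri-stimulus time histogram: counts / (n_trials * bin_width)."""
    times = _event_times(events)
    if times.size == 0:
        raise ValueError("need at least one event")
    span = window[1] - window[0]
    n_bins = int(round(span / bin_width))
    if abs(n_bins * bin_width - span) > 1e-9 * max(1.0, span):
        raise ValueError("bin_width must divide the window length")
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    rel = (train.spike_times[None, :] - times[:, None]).ravel()
    counts, _ = np.histogram(rel, bins=edges)
    return PSTH(edges, counts / (times.size * bin_width), times.size)


def direction_rates(
    train: SpikeTrain,
    ipsi_events: Sequence[TurnEvent] | Sequence[float],
    contra_events: Sequence[TurnEvent] | Sequence[float],
    response_window: tuple[float, float] = (0.0, 0.5),
) -> tuple[float, float]:
    """Mean firing rate (Hz) in the response window per direction."""
    ti, tc = _event_times(ipsi_events), _event_times(contra_events)
    if ti.size == 0 or tc.size == 0:
        raise ValueError("need events of both directions")
    width = response_window[1] - response_window[0]
    r_ipsi = _trial_counts(train, ti, response_window).mean() / width
    r_contra = _trial_counts(train, tc, response_window).mean() / width
    return float(r_ipsi), float(r_contra)


def modulation_index(r_ipsi: float, r_contra: float) -> float:
    """MI = (R_ipsi - R_contra)/(R_ipsi + R_contra); NaN when both are 0."""
    if r_ipsi < 0 or r_contra < 0:
        raise ValueError("rates must be nonnegative")
    denom = r_ipsi + r_contra
    if denom == 0:
        return float("nan")
    return (r_ipsi - r_contra) / denom


def classify_unit(
    train: SpikeTrain,
    ipsi_events: Sequence[TurnEvent] | Sequence[float],
    contra_events: Sequence[TurnEvent] | Sequence[float],
    response_window: tuple[float, float] = (0.0, 0.5),
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_trials: int = 5,
    rng: np.random.Generator | int | None = None,
) -> TuningResult:
    """Label a unit ipsi / contra / none by a permutation test on |MI|.

    Direction labels are shuffled across trials ``n_perm`` times; the
    add-one-smoothed p-value is the fraction of permutations with
    |MI_perm| >= |MI_obs|. Significant units (p < alpha) take the sign of
    MI; others (and units with too few trials or no spikes) are "none".
    :func:`classify_unit_ttest` offers a Welch t test on per-trial rates
    as an alternative rule.
    """
    rng = np.random.default_rng(rng)
    ti, tc = _event_times(ipsi_events), _event_times(contra_events)
    width = response_window[1] - response_window[0]
    if ti.size < min_trials or tc.size < min_trials:
        r_i = _trial_counts(train, ti, response_window).mean() / width if ti.size else 0.0
        r_c = _trial_counts(train, tc, response_window).mean() / width if tc.size else 0.0
        return TuningResult(
            train.unit_id, float(r_i), float(r_c),
            modulation_index(float(r_i), float(r_c)), 1.0, "none", flagged=True,
        )

    ci = _trial_counts(train, ti, response_window)
    cc = _trial_counts(train, tc, response_window)
    r_ipsi, r_contra = ci.mean() / width, cc.mean() / width
    mi = modulation_index(r_ipsi, r_contra)
    if np.isnan(mi):  # zero spikes in every window
        return TuningResult(
            train.unit_id, r_ipsi, r_contra, mi, 1.0, "none", flagged=True
        )

    pooled = np.concatenate([ci, cc])
    n_i = ci.size
    perm = rng.permuted(
        np.broadcast_to(pooled, (n_perm, pooled.size)).copy(), axis=1
    )
    mean_i = perm[:, :n_i].mean(axis=1)
    mean_c = perm[:, n_i:].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mi_perm = (mean_i - mean_c) / (mean_i + mean_c)
    mi_perm = np.nan_to_num(mi_perm, nan=0.0)
    p = (1.0 + np.sum(np.abs(mi_perm) >= abs(mi))) / (n_perm + 1.0)

    label = ("ipsi" if mi > 0 else "contra") if p < alpha else "none"
    return TuningResult(train.unit_id, float(r_ipsi), float(r_contra), float(mi),
                        float(p), label)


def classify_unit_ttest(
    train: SpikeTrain,
    ipsi_events: Sequence[TurnEvent] | Sequence[float],
    contra_events: Sequence[TurnEvent] | Sequence[float],
    response_window: tuple[float, float] = (0.0, 0.5),
    alpha: float = 0.05,
    min_trials: int = 5,
) -> TuningResult:
    """Alternative classification rule: Welch t test on per-trial rates."""
    ti, tc = _event_times(ipsi_events), _event_times(contra_events)
    width = response_window[1] - response_window[0]
    ci = _trial_counts(train, ti, response_window) / width
    cc = _trial_counts(train, tc, response_window) / width
    r_ipsi, r_contra = float(ci.mean()), float(cc.mean())
    mi = modulation_index(r_ipsi, r_contra)
    if ti.size < min_trials or tc.size < min_trials or np.isnan(mi) or (
        np.var(ci) == 0 and np.var(cc) == 0
    ):
        return TuningResult(train.unit_id, r_ipsi, r_contra, mi, 1.0, "none", True)
    p = float(stats.ttest_ind(ci, cc, equal_var=False).pvalue)
    label = ("ipsi" if mi > 0 else "contra") if p < alpha else "none"
    return TuningResult(train.unit_id, r_ipsi, r_contra, float(mi), p, label)


def _round_half_up(x: float) -> int:
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def population_summary(results: Sequence[TuningResult]) -> dict:
    """Population split over classified units.

    Returns counts, raw fractions, and integer percentages rounded
    half-away-from-zero.
    """
    results = list(results)
    if not results:
        raise ValueError("no units to summarize")
    n = len(results)
    counts = {lab: sum(r.label == lab for r in results) for lab in LABELS}
    fractions = {lab: counts[lab] / n for lab in LABELS}
    percentages = {lab: _round_half_up(100.0 * fractions[lab]) for lab in LABELS}
    return {
        "n_units": n,
        "counts": counts,
        "fractions": fractions,
        "percentages": percentages,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spikes_csv(path: str | Path, session_duration: float) -> list[SpikeTrain]:
    """Read a spikes CSV (unit_id, spike_time_s) into per-unit trains."""
    df = pd.read_csv(path)
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain(
                unit_id=str(unit_id),
                spike_times=np.sort(grp["spike_time_s"].to_numpy(dtype=float)),
                session_duration=session_duration,
            )
        )
    return trains


def write_tuning_csv(results: Sequence[TuningResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "r_ipsi_hz": r.r_ipsi,
                "r_contra_hz": r.r_contra,
                "mi": r.mi,
                "p_perm": r.p_perm,
                "label": r.label,
                "flagged": r.flagged,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_psth_csv(p: PSTH, path: str | Path) -> None:
    pd.DataFrame(
        {"bin_start_s": p.bin_edges[:-1], "bin_end_s": p.bin_edges[1:], "rate_hz": p.rate}
    ).to_csv(path, index=False)
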