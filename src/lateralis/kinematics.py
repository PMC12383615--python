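"""Pose-derived rotational kinematics.

Computes heading, signed angular velocity, mean angular velocity during
active rotation, head-trunk angle, full-rotation counts, and automatic
turn-event detection from four tracked body landmarks (nose, left ear,
right ear, tail base).

Conventions
-----------
* Heading is the orientation of the tail-base-to-nose vector, ``atan2``
  convention, degrees in (-180, 180].
* Angular velocity is the wrapped frame-to-frame heading difference times
  the frame rate, with sign mapped so that **positive = ipsiversive**
  (toward the declared hemisphere). In a mathematical y-up frame an
  increasing heading is a leftward turn, hence ipsiversive when the
  recorded hemisphere is the left one; in image coordinates (y down) the
  visual rotation sense is mirrored but the code is unchanged.
* Angles in degrees, time in seconds, frames 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import TurnEvent

logger = logging.getLogger(__name__)

HEMISPHERES = ("left", "right")

#: Default threshold below which the animal counts as immobile (deg/s).
IMMOBILE_THRESHOLD_DPS = 20.0
#: Minimum duration an active bout must be sustained (s).
MIN_BOUT_S = 0.5

BODYPARTS = ("nose", "left_ear", "right_ear", "tailbase")


@dataclass
class PoseTrack:
    """Per-frame 2-D coordinates of the four tracked landmarks.

    Coordinates are in cm (any consistent unit works: all derived
    quantities are translation- and scale-invariant). ``valid`` flags
    frames whose landmarks are usable; invalid frames propagate as masked
    values downstream rather than being interpolated.
    """

    time: np.ndarray
    nose: np.ndarray
    left_ear: np.ndarray
    right_ear: np.ndarray
    tailbase: np.ndarray
    frame_rate: float
    hemisphere: str
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("nose", "left_ear", "right_ear", "tailbase"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.time.size, 2):
                raise ValueError(f"{name} must have shape (n_frames, 2)")
            setattr(self, name, arr)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.valid is None:
            finite = np.ones(self.time.size, dtype=bool)
            for name in ("nose", "left_ear", "right_ear", "tailbase"):
                finite &= np.isfinite(getattr(self, name)).all(axis=1)
            self.valid = finite
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.time.shape:
                raise ValueError("valid mask must match n_frames")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def ipsi_sign(self) -> int:
        """Sign mapping heading increase onto the ipsiversive direction."""
        return 1 if self.hemisphere == "left" else -1


@dataclass
class AngularSeries:
    """Signed angular velocity between consecutive frames.

    ``velocity[i]`` covers the interval between frames ``i`` and ``i+1``;
    ``time[i]`` is the midpoint of that interval. Positive values are
    ipsiversive. ``valid`` masks intervals touching an invalid frame.
    """

    time: np.ndarray
    velocity: np.ndarray
    valid: np.ndarray
    frame_rate: float
    #: width (in samples) of the heading smoother that produced the series;
    #: lets downstream estimators discount smoothing-contaminated bout edges
    smooth_frames: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.time.shape == self.velocity.shape == self.valid.shape):
            raise ValueError("time, velocity, valid must share shape")
        if np.any(~np.isfinite(self.velocity[self.valid])):
            raise ValueError("velocity must be finite where valid")


@dataclass(frozen=True)
class RotationSummary:
    """Session-level rotation metrics."""

    n_ipsi_rotations: int
    n_contra_rotations: int
    ipsi_percentage: float  # NaN when no rotations at all
    mean_angular_velocity: float  # deg/s over active bouts; NaN if none


def heading_series(track: PoseTrack) -> np.ndarray:
    """Orientation of the tailbase-to-nose vector per frame, degrees.

    Frames where nose and tail base coincide (or are invalid) yield NaN.
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    d = track.nose - track.tailbase
    with np.errstate(invalid="ignore"):
        heading = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    degenerate = np.hypot(d[:, 0], d[:, 1]) == 0
    heading[degenerate | ~track.valid] = np.nan
    # atan2 returns [-180, 180]; fold -180 onto +180 for the (-180, 180] range
    heading[heading == -180.0] = 180.0
    return heading


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences onto the shortest signed arc (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def angular_velocity(track: PoseTrack, smooth_s: float = 0.0) -> AngularSeries:
    """Signed angular velocity series (deg/s, positive = ipsiversive).

    Parameters
    ----------
    track : PoseTrack
    smooth_s : float
        Width of a moving-average filter applied to the unwrapped heading
        before differencing, in seconds. 0 disables smoothing. Landmark
        jitter enters the frame-to-frame difference amplified by the frame
        rate, so a fraction-of-a-second window is recommended for noisy
        tracking; the filter is exact on constant-rate rotations away from
        the series edges (edge frames are masked).
    """
    heading = heading_series(track)
    valid = np.isfinite(heading)
    n = heading.size

    # unwrap over valid frames only, then optionally smooth
    unwrapped = np.full(n, np.nan)
    idx = np.flatnonzero(valid)
    if idx.size >= 2:
        h = heading[idx]
        unwrapped[idx] = h[0] + np.concatenate(([0.0], np.cumsum(_wrap_deg(np.diff(h)))))

    edge_mask = np.zeros(n, dtype=bool)
    w = 1
    if smooth_s > 0:
        w = max(1, int(round(smooth_s * track.frame_rate)))
        if w > 1:
            if np.all(valid):
                kernel = np.ones(w) / w
                sm = np.convolve(unwrapped, kernel, mode="same")
                half = w // 2
                edge_mask[:half] = True
                edge_mask[n - (w - 1 - half):] = True
                unwrapped = sm
            else:
                # masked smoothing: average over valid neighbours in the window
                vals = np.where(valid, unwrapped, 0.0)
                cnt = valid.astype(float)
                kernel = np.ones(w)
                num = np.convolve(vals, kernel, mode="same")
                den = np.convolve(cnt, kernel, mode="same")
                with np.errstate(invalid="ignore", divide="ignore"):
                    sm = num / den
                half = w // 2
                edge_mask[:half] = True
                edge_mask[n - (w - 1 - half):] = True
                unwrapped = np.where(valid, sm, np.nan)

    dh = np.diff(unwrapped)
    pair_valid = valid[:-1] & valid[1:] & ~(edge_mask[:-1] | edge_mask[1:])
    vel = np.where(pair_valid, dh * track.frame_rate * track.ipsi_sign, np.nan)
    mid_t = 0.5 * (track.time[:-1] + track.time[1:])
    return AngularSeries(
        mid_t, vel, pair_valid, track.frame_rate, smooth_frames=(w if w > 1 else 0)
    )


def _active_mask(
    series: AngularSeries, immobile_threshold: float, min_bout: float
) -> np.ndarray:
    """Frames in active rotation: |v| >= threshold sustained >= min_bout."""
    fast = series.valid & (np.abs(series.velocity) >= immobile_threshold)
    min_frames = max(1, int(round(min_bout * series.frame_rate)))
    out = np.zeros_like(fast)
    for start, stop in _runs(fast):
        if stop - start >= min_frames:
            out[start:stop] = True
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as [start, stop) pairs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(m.astype(np.int8)))
    starts = list(edges[m[edges + 1]] + 1)
    stops = list(edges[~m[edges + 1]] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(m.size)
    return list(zip(starts, stops))


def mean_angular_velocity(
    series: AngularSeries,
    immobile_threshold: float = IMMOBILE_THRESHOLD_DPS,
    min_bout: float = MIN_BOUT_S,
    signed: bool = False,
) -> float:
    """Mean angular velocity over active rotation periods, deg/s.

    Immobile phases -- frames where |velocity| stays below
    ``immobile_threshold`` or active stretches shorter than ``min_bout``
    seconds -- are excluded. By default the mean of |velocity| is returned
    (magnitude comparison across conditions); ``signed=True`` averages the
    signed values instead. Returns NaN when no active frames exist.

    When the series was produced with heading smoothing, the moving
    average spreads each bout edge over the smoothing window, ramping the
    velocity there; those contaminated edge samples are trimmed from every
    active run (by ``smooth_frames`` per side, keeping the central samples
    of short runs) before averaging. Bout eligibility (``min_bout``) is
    judged on the untrimmed run.
    """
    if series.velocity.size == 0:
        raise ValueError("empty angular series")
    fast = series.valid & (np.abs(series.velocity) >= immobile_threshold)
    min_frames = max(1, int(round(min_bout * series.frame_rate)))
    trim = series.smooth_frames
    chunks = []
    for start, stop in _runs(fast):
        if stop - start < min_frames:
            continue
        lo, hi = start + trim, stop - trim
        if hi <= lo:  # run shorter than twice the trim: keep its center
            mid = (start + stop) // 2
            lo, hi = mid, mid + 1
        chunks.append(series.velocity[lo:hi])
    if not chunks:
        warnings.warn("no active rotation frames; mean angular velocity undefined")
        return float("nan")
    v = np.concatenate(chunks)
    return float(np.mean(v if signed else np.abs(v)))


def head_trunk_angle(track: PoseTrack) -> np.ndarray:
    """Head deflection from the trunk axis per frame, degrees in [0, 180].

    The head segment runs from the ear midpoint to the nose; the trunk
    segment from the tail base to the ear midpoint. A straight body gives
    0 deg. Frames with a zero-length segment are NaN.
    """
    mid = 0.5 * (track.left_ear + track.right_ear)
    head = track.nose - mid
    trunk = mid - track.tailbase
    nh = np.hypot(head[:, 0], head[:, 1])
    nt = np.hypot(trunk[:, 0], trunk[:, 1])
    # atan2(|cross|, dot) is well conditioned near 0 and 180 deg
    cross = head[:, 0] * trunk[:, 1] - head[:, 1] * trunk[:, 0]
    dot = (head * trunk).sum(axis=1)
    ang = np.degrees(np.arctan2(np.abs(cross), dot))
    ang[(nh == 0) | (nt == 0) | ~track.valid] = np.nan
    return ang


def count_rotations(series: AngularSeries) -> tuple[int, int]:
    """Count completed 360-degree rotations in each direction.

    The signed angular velocity is integrated over time; whenever the
    running angle since the last counted rotation reaches +360 deg the
    ipsiversive count increments (resp. -360 deg, contraversive), and 360
    deg is carried out of the accumulator so partial overshoot is not
    lost. Invalid frames contribute zero velocity (with a warning).
    """
    v = series.velocity.copy()
    if np.any(~series.valid):
        warnings.warn(
            f"{int((~series.valid).sum())} invalid frames treated as zero velocity"
        )
        v[~series.valid] = 0.0
    dtheta = v / series.frame_rate
    n_ipsi = n_contra = 0
    acc = 0.0
    for d in dtheta:
        acc += d
        while acc >= 360.0:
            n_ipsi += 1
            acc -= 360.0
        while acc <= -360.0:
            n_contra += 1
            acc += 360.0
    return n_ipsi, n_contra


def ipsi_percentage(n_ipsi: int, n_contra: int) -> float:
    """Percentage of ipsiversive rotations, 100*N_ipsi/(N_ipsi+N_contra).

    NaN (with a warning) when both counts are zero.
    """
    if n_ipsi < 0 or n_contra < 0:
        raise ValueError("rotation counts must be nonnegative")
    total = n_ipsi + n_contra
    if total == 0:
        warnings.warn("no rotations in either direction; percentage undefined")
        return float("nan")
    return 100.0 * n_ipsi / total


def detect_turn_events(
    series: AngularSeries,
    min_angle: float = 60.0,
    min_speed: float = IMMOBILE_THRESHOLD_DPS,
) -> list[TurnEvent]:
    """Detect turn onsets from the angular-velocity series.

    Contiguous stretches of same-sign velocity with |v| >= ``min_speed``
    whose accumulated angle reaches ``min_angle`` degrees become events;
    the onset is the first frame of the stretch and the direction follows
    the sign (positive = ipsi).
    """
    fast = series.valid & (np.abs(series.velocity) >= min_speed)
    dt = 1.0 / series.frame_rate
    out: list[TurnEvent] = []
    for start, stop in _runs(fast):
        signs = np.sign(series.velocity[start:stop])
        # split the run at sign changes
        seg_start = start
        for i in range(start + 1, stop + 1):
            if i == stop or signs[i - start] != signs[seg_start - start]:
                seg = series.velocity[seg_start:i]
                total = float(np.sum(np.abs(seg)) * dt)
                if total >= min_angle:
                    direction = "ipsi" if seg[0] > 0 else "contra"
                    out.append(
                        TurnEvent(
                            onset_s=float(series.time[seg_start]),
                            direction=direction,
                            total_angle_deg=total,
                            angular_speed_dps=float(np.mean(np.abs(seg))),
                        )
                    )
                seg_start = i
    return out


def summarize_rotation(
    track: PoseTrack,
    immobile_threshold: float = IMMOBILE_THRESHOLD_DPS,
    min_bout: float = MIN_BOUT_S,
    smooth_s: float = 0.0,
) -> RotationSummary:
    """Convenience wrapper: angular velocity -> counts, percentage, mean speed."""
    series = angular_velocity(track, smooth_s=smooth_s)
    n_ipsi, n_contra = count_rotations(series)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pct = ipsi_percentage(n_ipsi, n_contra) if (n_ipsi + n_contra) else float("nan")
        mav = mean_angular_velocity(series, immobile_threshold, min_bout)
    return RotationSummary(n_ipsi, n_contra, pct, mav)


# ---------------------------------------------------------------------------
# pose CSV I/O (three-row-header tracking dialect)
# ---------------------------------------------------------------------------

def read_pose_csv(
    path: str | Path,
    frame_rate: float,
    hemisphere: str,
    bodypart_map: dict[str, str] | None = None,
    likelihood_cutoff: float = 0.9,
    interpolate_max_frames: int = 0,
) -> PoseTrack:
    """Read a pose-tracking CSV in the three-row-header dialect.

    Header rows are scorer / bodyparts / coords, with per-frame ``x``,
    ``y`` and optionally ``likelihood`` columns per bodypart (the layout
    markerless-tracking tools export). Frames where any landmark's
    likelihood falls below ``likelihood_cutoff`` are masked invalid; with
    ``interpolate_max_frames`` > 0, gaps up to that many frames are filled
    by linear interpolation instead.

    Parameters
    ----------
    bodypart_map : dict, optional
        Maps the canonical names (``nose``, ``left_ear``, ``right_ear``,
        ``tailbase``) to the bodypart labels used in the file.
    """
    bodypart_map = bodypart_map or {bp: bp for bp in BODYPARTS}
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns = df.columns.droplevel(0)  # scorer row is cosmetic

    coords: dict[str, np.ndarray] = {}
    n = len(df)
    valid = np.ones(n, dtype=bool)
    for canonical in BODYPARTS:
        label = bodypart_map[canonical]
        if (label, "x") not in df.columns:
            raise ValueError(f"{path}: bodypart {label!r} not found")
        xy = df[[(label, "x"), (label, "y")]].to_numpy(dtype=float)
        if (label, "likelihood") in df.columns:
            lik = df[(label, "likelihood")].to_numpy(dtype=float)
            bad = lik < likelihood_cutoff
            if interpolate_max_frames > 0:
                ser = pd.DataFrame(np.where(bad[:, None], np.nan, xy))
                ser = ser.interpolate(
                    method="linear", limit=interpolate_max_frames,
                    limit_area="inside",
                )
                xy = ser.to_numpy()
                bad = np.isnan(xy).any(axis=1)
            else:
                xy = np.where(bad[:, None], np.nan, xy)
            valid &= ~bad
        valid &= np.isfinite(xy).all(axis=1)
        coords[canonical] = xy

    time = np.arange(n) / frame_rate
    return PoseTrack(
        time=time,
        nose=coords["nose"],
        left_ear=coords["left_ear"],
        right_ear=coords["right_ear"],
        tailbase=coords["tailbase"],
        frame_rate=frame_rate,
        hemisphere=hemisphere,
        valid=valid,
    )


def write_pose_csv(
    track: PoseTrack, path: str | Path, scorer: str = "synthetic"
) -> None:
    """Write a PoseTrack in the same three-row-header dialect readers consume."""
    cols = {}
    for bp in BODYPARTS:
        arr = getattr(track, bp)
        cols[(scorer, bp, "x")] = arr[:, 0]
        cols[(scorer, bp, "y")] = arr[:, 1]
        cols[(scorer, bp, "likelihood")] = np.where(track.valid, 1.0, 0.0)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["scorer", "bodyparts", "coords"]
    )
    df.to_csv(path, index_label=None)
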