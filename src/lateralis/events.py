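"""Turn-event containers and CSV I/O shared across all analysis stages.

A turn event is a time-stamped behavioral annotation: the moment a mouse
initiates a body rotation, labeled ``ipsi`` or ``contra`` relative to the
recorded (or stimulated) hemisphere. Events drive trial alignment for
photometry and spike-train analysis and serve as ground truth for the
kinematic turn detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DIRECTIONS = ("ipsi", "contra")


@dataclass(frozen=True)
class TurnEvent:
    """A single turn onset.

    Parameters
    ----------
    onset_s : float
        Turn-initiation time in seconds from session start.
    direction : str
        ``"ipsi"`` or ``"contra"``, relative to the declared hemisphere.
    total_angle_deg : float, optional
        Total unsigned rotation of the bout, when known (generator ground
        truth or kinematic detection); ``None`` for plain annotations.
    angular_speed_dps : float, optional
        Mean angular speed of the bout in deg/s, when known.
    """

    onset_s: float
    direction: str
    total_angle_deg: float | None = None
    angular_speed_dps: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")


def split_by_direction(
    events: Iterable[TurnEvent],
) -> tuple[list[TurnEvent], list[TurnEvent]]:
    """Partition events into (ipsi, contra) lists, preserving order."""
    evs = list(events)
    return (
        [e for e in evs if e.direction == "ipsi"],
        [e for e in evs if e.direction == "contra"],
    )


def write_events_csv(events: Sequence[TurnEvent], path: str | Path) -> None:
    """Write events as CSV with columns onset_s, direction, total_angle_deg."""
    df = pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "direction": [e.direction for e in events],
            "total_angle_deg": [e.total_angle_deg for e in events],
        }
    )
    df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[TurnEvent]:
    """Read a turn-event CSV.

    Accepts ``onset_s`` or ``time_s`` as the time column; ``total_angle_deg``
    is optional.
    """
    df = pd.read_csv(path)
    time_col = "onset_s" if "onset_s" in df.columns else "time_s"
    if time_col not in df.columns or "direction" not in df.columns:
        raise ValueError(
            f"{path}: need columns (onset_s|time_s, direction), got {list(df.columns)}"
        )
    has_angle = "total_angle_deg" in df.columns
    out = []
    for _, row in df.iterrows():
        angle = row["total_angle_deg"] if has_angle else None
        if angle is not None and pd.isna(angle):
            angle = None
        out.append(
            TurnEvent(
                onset_s=float(row[time_col]),
                direction=str(row["direction"]),
                total_angle_deg=None if angle is None else float(angle),
            )
        )
    return out
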