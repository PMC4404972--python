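"""Trajectory serialization: lossless CSV round-trip.

Columns are ``time,x1,x2,y,event,limit`` where ``event`` is ``none`` or
the impulse kind and ``limit`` is ``left``/``right`` on the paired rows an
impulse produces (empty elsewhere). Floats are written with 17 significant
digits so a read-back reproduces the states bitwise.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .integrate import Trajectory, TrajectoryEvent
from .model import SystemState

__all__ = ["write_trajectory", "read_trajectory"]

_HEADER = "time,x1,x2,y,event,limit"


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV (17 significant digits, lossless)."""
    lines = [_HEADER]
    for t, s, kind, side in zip(
        trajectory.times,
        trajectory.states,
        trajectory.event_kind,
        trajectory.limit_side,
    ):
        lines.append(
            f"{t:.17g},{s[0]:.17g},{s[1]:.17g},{s[2]:.17g},{kind},{side}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path, period: float = np.nan,
                    n_periods: int = 0) -> Trajectory:
    """Read a trajectory CSV back into a :class:`Trajectory`.

    Impulse records are reconstructed from the paired left/right rows.
    """
    df = pd.read_csv(
        path,
        keep_default_na=False,
        dtype={"event": str, "limit": str},
        float_precision="round_trip",
    )
    times = df["time"].to_numpy(dtype=float)
    states = df[["x1", "x2", "y"]].to_numpy(dtype=float)
    kinds = [str(k) for k in df["event"]]
    sides = [str(s) for s in df["limit"]]
    events: list[TrajectoryEvent] = []
    for i, side in enumerate(sides):
        if side == "left":
            before = SystemState.from_array(states[i])
            after = SystemState.from_array(states[i + 1])
            events.append(TrajectoryEvent(float(times[i]), kinds[i], before, after))
    return Trajectory(
        times=times,
        states=states,
        event_kind=kinds,
        limit_side=sides,
        events=events,
        period=period,
        n_periods=n_periods,
    )
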