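"""Visual stimulus specifications for the 1-mm simulated arena.

Stimuli are one-dimensional space-time indicator functions s(x, t) on a
horizontal arena, sampled every ``dt`` milliseconds.  Two families are used
throughout: horizontally moving bright bars (the motion protocol) and
full-field flashes.  A "masked" variant holds selected x-ranges at the
background level, mimicking partial occlusion of the display.

Conventions
-----------
* space in micrometres, time in milliseconds;
* velocity in mm/s, which conveniently equals um/ms;
* ``direction`` is +1 for left-to-right motion, -1 for right-to-left;
* stimulus intensity is 1, background 0 (arbitrary units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass(frozen=True)
class StimulusSpec:
    """Space-time description of one stimulus over the arena.

    A bar of physical length ``speed * dwell_time`` enters the arena with
    its leading edge at the boundary at t = 0 and sweeps across at constant
    speed, so every arena point is illuminated for exactly ``dwell_time``.
    A flash illuminates the whole arena for ``duration`` seconds starting
    at t = 0.
    """

    kind: str = "bar"                   # "bar" | "flash" | "masked"
    arena_width: float = 1000.0         # um
    dt: float = 1.0                     # ms
    speed: float = 0.5                  # mm/s (bars only)
    direction: int = 1                  # +1 left->right, -1 right->left
    dwell_time: float = 2.0             # s; bar length = speed * dwell_time
    bar_height: float = 1000.0          # um (bookkeeping only; 1-D model)
    intensity: float = 1.0
    duration: float = 0.0               # s (flashes; bars derive their own)
    mask_intervals: Optional[tuple] = None  # ((x0, x1), ...) held at background

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")
        if self.arena_width <= 0:
            raise ValueError("arena_width must be positive")
        if self.kind in ("bar", "masked"):
            if self.speed <= 0:
                raise ValueError("bar speed must be positive")
            if self.dwell_time <= 0:
                raise ValueError("dwell_time must be positive")
        elif self.kind == "flash":
            if self.duration <= 0:
                raise ValueError("flash duration must be positive")
        else:
            raise ValueError(f"unknown stimulus kind: {self.kind!r}")

    # ------------------------------------------------------------------ time
    @property
    def bar_length(self) -> float:
        """Physical bar length in um (speed [um/ms] x dwell [ms])."""
        return self.speed * self.dwell_time * 1000.0

    @property
    def total_duration_ms(self) -> float:
        """Time until the stimulus has fully left the arena."""
        if self.kind == "flash":
            return self.duration * 1000.0
        # leading edge crosses the arena, then the trailing edge follows
        return self.arena_width / self.speed + self.dwell_time * 1000.0

    @property
    def n_steps(self) -> int:
        return int(round(self.total_duration_ms / self.dt)) + 1

    # ------------------------------------------------------------- footprint
    def footprint(self, t: float) -> tuple:
        """Stimulated x-intervals ``((x0, x1), ...)`` at time t (ms).

        Mask intervals are removed from the footprint.  Empty tuple means
        no point of the arena is illuminated.
        """
        if self.kind == "flash":
            raw = ((0.0, self.arena_width),) if 0.0 <= t <= self.duration * 1000.0 else ()
        else:
            lead = self.speed * t  # distance travelled by the leading edge
            if self.direction >= 0:
                lo, hi = lead - self.bar_length, lead
            else:
                lo, hi = self.arena_width - lead, self.arena_width - lead + self.bar_length
            lo, hi = max(lo, 0.0), min(hi, self.arena_width)
            raw = ((lo, hi),) if hi > lo else ()
        if not self.mask_intervals:
            return raw
        return tuple(_subtract_masks(raw, self.mask_intervals))

    # ------------------------------------------------------------------- io
    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "StimulusSpec":
        d = json.loads(s)
        if d.get("mask_intervals"):
            d["mask_intervals"] = tuple(tuple(m) for m in d["mask_intervals"])
        return cls(**d)


def _subtract_masks(intervals, masks):
    out = list(intervals)
    for m0, m1 in masks:
        nxt = []
        for a, b in out:
            if m1 <= a or m0 >= b:
                nxt.append((a, b))
                continue
            if a < m0:
                nxt.append((a, m0))
            if m1 < b:
                nxt.append((m1, b))
        out = nxt
    return out


def make_bar_stimulus(speed: float, direction: int = 1, arena_width: float = 1000.0,
                      dwell_time: float = 2.0, dt: float = 1.0,
                      mask_intervals=None) -> StimulusSpec:
    """Moving-bar stimulus: leading edge enters at t=0 and sweeps the arena.

    Parameters
    ----------
    speed : mm/s.  The standard protocol uses 0.25, 0.5, 1, 2 and 4 mm/s.
    direction : +1 (left to right) or -1 (right to left).
    dwell_time : s each arena point stays illuminated (default 2 s).
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    kind = "masked" if mask_intervals else "bar"
    return StimulusSpec(kind=kind, speed=float(speed), direction=direction,
                        arena_width=float(arena_width), dwell_time=float(dwell_time),
                        dt=dt, mask_intervals=tuple(map(tuple, mask_intervals)) if mask_intervals else None)


def make_flash_stimulus(duration: float = 4.0, arena_width: float = 1000.0,
                        dt: float = 1.0) -> StimulusSpec:
    """Full-field flash covering the whole arena for ``duration`` seconds."""
    return StimulusSpec(kind="flash", duration=float(duration),
                        arena_width=float(arena_width), dt=dt)
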