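"""Voltage-clamp protocols as piecewise-constant sweep families.

A protocol is an ordered list of constant-voltage segments preceded by a
holding potential, plus exactly one *varying slot*: either one segment's
voltage or one segment's duration sweeps over a value list, producing one
sweep per value.  The five standard Nav1.5 protocols (activation,
deactivation, steady-state availability, two-pulse recovery, and
development of slow inactivation) are provided as builders; arbitrary
protocols round-trip through a YAML file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Segment",
    "SweepSpec",
    "VoltageProtocol",
    "activation_protocol",
    "deactivation_protocol",
    "availability_protocol",
    "recovery_protocol",
    "slow_inactivation_development_protocol",
]

#: default sampling interval, ms (upper end of 10-100 kHz digitization)
DEFAULT_DT = 0.01


@dataclass(frozen=True)
class Segment:
    """One constant-voltage command step.

    ``dt`` optionally overrides the protocol sampling interval for this
    segment — long conditioning or interpulse segments are typically
    recorded coarsely since only their endpoint occupancy matters.
    """

    duration: float  # ms
    voltage: float  # mV
    dt: float | None = None

    def __post_init__(self):
        if not (self.duration > 0):
            raise ValueError(f"segment duration must be > 0 ms, got {self.duration}")


@dataclass(frozen=True)
class SweepSpec:
    """Which slot varies across sweeps: segment index, field, value list."""

    segment: int
    vary: str  # "voltage" | "duration"
    values: tuple[float, ...]

    def __post_init__(self):
        if self.vary not in ("voltage", "duration"):
            raise ValueError(f"vary must be 'voltage' or 'duration', got {self.vary!r}")
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError("sweep value list must be non-empty")
        d = np.diff(vals)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("sweep values must be strictly monotone")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class VoltageProtocol:
    name: str
    holding: float  # mV
    segments: tuple[Segment, ...]
    sweep: SweepSpec
    dt: float = DEFAULT_DT

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if not (0 <= self.sweep.segment < len(self.segments)):
            raise ValueError("sweep segment index out of range")
        if not (self.dt > 0):
            raise ValueError("sampling interval dt must be > 0")
        if self.sweep.vary == "duration" and any(v <= 0 for v in self.sweep.values):
            raise ValueError("sweep durations must be > 0 ms")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep.values)

    def sweep_segments(self, i: int) -> tuple[Segment, ...]:
        """Concrete segment list for sweep ``i`` (varying slot filled in)."""
        value = self.sweep.values[i]
        segs = list(self.segments)
        segs[self.sweep.segment] = replace(segs[self.sweep.segment], **{self.sweep.vary: value})
        return tuple(segs)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "holding": self.holding,
            "dt": self.dt,
            "segments": [
                {"duration": s.duration, "voltage": s.voltage, **({"dt": s.dt} if s.dt else {})}
                for s in self.segments
            ],
            "sweep": {
                "segment": self.sweep.segment,
                "vary": self.sweep.vary,
                "values": [float(v) for v in self.sweep.values],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(
            name=d["name"],
            holding=float(d["holding"]),
            segments=tuple(
                Segment(duration=s["duration"], voltage=s["voltage"], dt=s.get("dt"))
                for s in d["segments"]
            ),
            sweep=SweepSpec(
                segment=d["sweep"]["segment"],
                vary=d["sweep"]["vary"],
                values=tuple(d["sweep"]["values"]),
            ),
            dt=float(d.get("dt", DEFAULT_DT)),
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "VoltageProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# standard Nav1.5 protocol builders
# ---------------------------------------------------------------------------


def activation_protocol(dt: float = DEFAULT_DT) -> VoltageProtocol:
    """20 ms steps from −90 to +60 mV in 5 mV increments, hold −120 mV."""
    return VoltageProtocol(
        name="activation",
        holding=-120.0,
        segments=(Segment(duration=20.0, voltage=0.0),),
        sweep=SweepSpec(segment=0, vary="voltage", values=tuple(np.arange(-90.0, 60.0 + 2.5, 5.0))),
        dt=dt,
    )


def deactivation_protocol(dt: float = DEFAULT_DT) -> VoltageProtocol:
    """0.25 ms pulse to −10 mV, then 20 ms tails −100…−30 mV (10 mV steps)."""
    return VoltageProtocol(
        name="deactivation",
        holding=-120.0,
        segments=(
            Segment(duration=0.25, voltage=-10.0),
            Segment(duration=20.0, voltage=0.0),
        ),
        sweep=SweepSpec(segment=1, vary="voltage", values=tuple(np.arange(-100.0, -30.0 + 5.0, 10.0))),
        dt=dt,
    )


def availability_protocol(dt: float = DEFAULT_DT) -> VoltageProtocol:
    """500 ms conditioning −120…0 mV (10 mV steps), 20 ms test at −10 mV."""
    return VoltageProtocol(
        name="availability",
        holding=-120.0,
        segments=(
            Segment(duration=500.0, voltage=0.0, dt=5.0),
            Segment(duration=20.0, voltage=-10.0),
        ),
        sweep=SweepSpec(segment=0, vary="voltage", values=tuple(np.arange(-120.0, 0.0 + 5.0, 10.0))),
        dt=dt,
    )


def _default_intervals(p1: float) -> tuple[float, ...]:
    # log-spaced grids covering both recovery components
    upper = 200.0 if p1 <= 100.0 else 5000.0
    return tuple(np.geomspace(0.5, upper, 30))


def recovery_protocol(
    P1: float = 30.0,
    recovery_V: float = -120.0,
    intervals=None,
    pulse_V: float = -20.0,
    dt: float = DEFAULT_DT,
) -> VoltageProtocol:
    """Two-pulse recovery: P1 prepulse, variable interval, 20 ms test P2.

    The prepulse/test voltage is not part of the protocol family definition
    (the interval segment is what varies); default −20 mV.
    """
    if intervals is None:
        intervals = _default_intervals(P1)
    intervals = tuple(sorted(float(t) for t in intervals))
    if not intervals:
        raise ValueError("recovery interval list must be non-empty")
    return VoltageProtocol(
        name=f"recovery_P1_{P1:g}ms_{recovery_V:g}mV",
        holding=-120.0,
        segments=(
            Segment(duration=P1, voltage=pulse_V, dt=min(0.05, dt * 5) if P1 > 100 else None),
            Segment(duration=1.0, voltage=recovery_V, dt=None),
            Segment(duration=20.0, voltage=pulse_V),
        ),
        sweep=SweepSpec(segment=1, vary="duration", values=intervals),
        dt=dt,
    )


def slow_inactivation_development_protocol(
    durations=None, dt: float = DEFAULT_DT
) -> VoltageProtocol:
    """−20 mV prepulse of varying duration, 30 ms interpulse at −120 mV
    (removes fast inactivation), 20 ms test at −20 mV."""
    if durations is None:
        durations = tuple(np.geomspace(10.0, 10_000.0, 25))
    durations = tuple(sorted(float(t) for t in durations))
    return VoltageProtocol(
        name="slow_inactivation_development",
        holding=-120.0,
        segments=(
            Segment(duration=1.0, voltage=-20.0, dt=None),
            Segment(duration=30.0, voltage=-120.0),
            Segment(duration=20.0, voltage=-20.0),
        ),
        sweep=SweepSpec(segment=0, vary="duration", values=durations),
        dt=dt,
    )
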