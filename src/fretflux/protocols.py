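"""Perfusion protocols: ordered bath interventions with onset times.

A protocol is the experiment's timeline: which drug or medium switch is
applied when.  Four presets cover the standard designs used for
transport-stop / trans-acceleration flux estimation in retinal slices:

``trans_acceleration``
    20 mM oxamate in the bath; trans-stimulated carrier export depletes
    intracellular lactate toward the zero-lactate floor.
``mct_block``
    5 uM AR-C155858 blocks MCT1/MCT2 lactate export; intracellular
    lactate then ramps up at the net production rate.
``glut_block_then_aglycemia``
    20 uM cytochalasin B blocks glucose import (intracellular glucose
    decays at the hexokinase rate), followed by a zero-glucose medium
    that anchors the trace at nominal zero glucose.
``aglycemia_only``
    Zero-glucose medium alone; starves glycolysis and empties both
    pools (the zero-analyte anchor experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

__all__ = ["EventKind", "ProtocolEvent", "Protocol", "get_protocol", "PROTOCOL_NAMES"]


class EventKind(str, Enum):
    BASELINE = "BASELINE"
    OXAMATE_ON = "OXAMATE_ON"
    ARC_ON = "ARC_ON"
    CYTB_ON = "CYTB_ON"
    AGLYCEMIA_ON = "AGLYCEMIA_ON"
    WASHOUT = "WASHOUT"


@dataclass(frozen=True)
class ProtocolEvent:
    """One bath intervention.

    ``dose`` is in mM for oxamate, uM for AR-C155858 / cytochalasin B,
    and unused for BASELINE / AGLYCEMIA_ON / WASHOUT.
    """

    kind: EventKind
    onset: float  # s
    dose: float = 0.0

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class Protocol:
    name: str
    events: tuple[ProtocolEvent, ...]
    duration: float  # s

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if not events:
            raise ValueError("protocol needs at least one event")
        if events[0].kind != EventKind.BASELINE or events[0].onset != 0.0:
            raise ValueError("first event must be BASELINE at t=0")
        onsets = [e.onset for e in events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if self.duration <= events[-1].onset:
            raise ValueError("duration must exceed the last onset")

    def __iter__(self) -> Iterator[ProtocolEvent]:
        return iter(self.events)

    @property
    def intervention_onsets(self) -> tuple[float, ...]:
        """Onsets of all non-baseline events."""
        return tuple(e.onset for e in self.events if e.kind != EventKind.BASELINE)

    def first_intervention(self) -> ProtocolEvent:
        for e in self.events:
            if e.kind != EventKind.BASELINE:
                return e
        raise ValueError(f"protocol {self.name!r} has no intervention")

    def segment_bounds(self) -> list[tuple[float, float]]:
        """[start, end) of each constant-bath segment, covering [0, duration]."""
        onsets = [e.onset for e in self.events] + [self.duration]
        return list(zip(onsets[:-1], onsets[1:]))


def _preset(name: str, events: Sequence[ProtocolEvent], duration: float) -> Protocol:
    return Protocol(name=name, events=tuple(events), duration=duration)


def get_protocol(name: str, *, onset: float = 120.0, duration: float | None = None) -> Protocol:
    """Return a named protocol preset.

    Parameters
    ----------
    name : str
        One of ``trans_acceleration``, ``mct_block``,
        ``glut_block_then_aglycemia``, ``aglycemia_only``.
    onset : float
        Time of the first intervention, s (baseline length).
    duration : float, optional
        Total length, s.  Defaults per preset.
    """
    base = ProtocolEvent(EventKind.BASELINE, 0.0)
    key = name.lower()
    if key == "trans_acceleration":
        dur = 600.0 if duration is None else duration
        return _preset(key, [base, ProtocolEvent(EventKind.OXAMATE_ON, onset, 20.0)], dur)
    if key == "mct_block":
        dur = 420.0 if duration is None else duration
        return _preset(key, [base, ProtocolEvent(EventKind.ARC_ON, onset, 5.0)], dur)
    if key == "glut_block_then_aglycemia":
        dur = 720.0 if duration is None else duration
        second = onset + 300.0
        if second >= dur:
            raise ValueError("duration too short for the aglycemia segment")
        return _preset(
            key,
            [
                base,
                ProtocolEvent(EventKind.CYTB_ON, onset, 20.0),
                ProtocolEvent(EventKind.AGLYCEMIA_ON, second, 0.0),
            ],
            dur,
        )
    if key == "aglycemia_only":
        dur = 600.0 if duration is None else duration
        return _preset(key, [base, ProtocolEvent(EventKind.AGLYCEMIA_ON, onset, 0.0)], dur)
    raise KeyError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")


PROTOCOL_NAMES = (
    "trans_acceleration",
    "mct_block",
    "glut_block_then_aglycemia",
    "aglycemia_only",
)
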