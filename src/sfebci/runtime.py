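"""Step D validity judgment and the asynchronous NC/IC control loop.

The interface idles in non-control (NC) mode: each accepted window runs
only the binary ON detector, and a validity-judged s-RB switches to
in-control (IC) mode.  In IC mode every accepted window is decoded 9-way;
a validity-judged s-RB switches back to NC, any other validity-judged sFE
emits its mapped stepping instruction, and NON holds on.  Validity
judgment is consistency checking over the latest n = 20 decoded labels:
the current label triggers iff at least x% of the buffer agrees with it
(boundary inclusive), with x per class from the criteria map.

Every processed window appends a time-log event, so a run can be replayed
and audited offline.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from .signal_core import (
    DECODING_BAND,
    NON_LABEL,
    SCREENING_BAND,
    SFE_CLASSES,
    WINDOW_SAMPLES,
    EEGRecording,
    bandpass_array,
)

#: Consistency-checking criteria for the robotic-arm task.
ARM_CRITERIA: dict[str, float] = {
    "s-RB": 0.95, "s-FB": 0.95, "s-LS": 0.45, "s-RS": 0.45,
    "s-OM": 0.45, "s-S": 0.95, "s-PM": 0.55, "s-DM": 0.80,
}

#: Consistency-checking criteria for the prosthetic-hand task
#: (disabled classes carry criterion 1.0 and no instruction mapping).
HAND_CRITERIA: dict[str, float] = {
    "s-RB": 0.95, "s-FB": 0.95, "s-LS": 0.35, "s-RS": 0.40,
    "s-OM": 1.0, "s-S": 0.95, "s-PM": 1.0, "s-DM": 1.0,
}

#: Robotic-arm instruction map: class -> (instruction, axis, stepping mm).
#: "Down" stepping depends on current height (see VirtualArm).
ARM_INSTRUCTIONS: dict[str, str] = {
    "s-FB": "Open", "s-LS": "Left", "s-RS": "Right", "s-OM": "Up",
    "s-S": "Down", "s-PM": "Backward", "s-DM": "Forward",
}

#: Prosthetic-hand instruction map (disabled classes absent).
HAND_INSTRUCTIONS: dict[str, str] = {
    "s-FB": "Open", "s-LS": "Extorsion", "s-RS": "Intorsion", "s-S": "Close",
}


@dataclass(frozen=True)
class CriteriaMap:
    """Per-class consistency fractions x in (0, 1]."""

    criteria: dict[str, float]

    def __post_init__(self) -> None:
        for lab, x in self.criteria.items():
            if not (0.0 < x <= 1.0):
                raise ValueError(f"criterion for {lab} must be in (0, 1], got {x}")

    def get(self, label: str) -> float:
        if label not in self.criteria:
            raise KeyError(f"no consistency criterion configured for {label!r}")
        return self.criteria[label]


def validity_judge(history, current: str, criteria: CriteriaMap,
                   n: int = 20) -> bool:
    """True iff the current label is valid: count(history == current)/n >=
    x(current).  NON never triggers; the current label is the nth entry of
    ``history``.
    """
    if current == NON_LABEL or current == "else":
        return False
    hist = list(history)
    if len(hist) < n:
        return False
    hist = hist[-n:]
    frac = sum(1 for l in hist if l == current) / n
    return frac >= criteria.get(current)


def theoretical_timespan(ts: float, n: int = 20) -> float:
    """Theoretical ms from data collection to instruction: Ts = 100 + n*ts."""
    if ts < 0 or n < 0:
        raise ValueError("ts and n must be non-negative")
    return 100.0 + n * ts


# ---------------------------------------------------------------------------
# Device adapters
# ---------------------------------------------------------------------------

class VirtualArm:
    """Virtual 6-DoF arm integrating the stepping instructions.

    Stepping magnitudes: Right +30/X, Left -2/X, Forward +20/Y, Backward
    -3/Y, Up +30/Z, Down -10/Z while above 21 mm else -3/Z, Open releases
    the gripper.  Positions in mm.
    """

    def __init__(self, x: float = 0.0, y: float = 0.0, z: float = 0.0):
        self.x, self.y, self.z = x, y, z
        self.gripper_open = False
        self.log: list[str] = []

    def send(self, instruction: str) -> dict:
        if instruction == "Right":
            self.x += 30.0
        elif instruction == "Left":
            self.x -= 2.0
        elif instruction == "Forward":
            self.y += 20.0
        elif instruction == "Backward":
            self.y -= 3.0
        elif instruction == "Up":
            self.z += 30.0
        elif instruction == "Down":
            self.z -= 10.0 if self.z > 21.0 else 3.0
        elif instruction == "Open":
            self.gripper_open = True
        else:
            raise ValueError(f"unknown arm instruction {instruction!r}")
        self.log.append(instruction)
        return {"ack": True, "x": self.x, "y": self.y, "z": self.z,
                "gripper_open": self.gripper_open}


class VirtualHand:
    """Virtual 2-DoF prosthetic hand: palm aperture (mm) and wrist angle (deg).

    Open +7.0 mm, Close -10.5 mm (aperture clamped to [0, 95]);
    Extorsion +11.0 deg, Intorsion -12.0 deg.
    """

    MAX_APERTURE = 95.0

    def __init__(self, aperture: float = 95.0, wrist: float = 0.0):
        self.aperture = aperture
        self.wrist = wrist
        self.log: list[str] = []

    def send(self, instruction: str) -> dict:
        if instruction == "Open":
            self.aperture = min(self.MAX_APERTURE, self.aperture + 7.0)
        elif instruction == "Close":
            self.aperture = max(0.0, self.aperture - 10.5)
        elif instruction == "Extorsion":
            self.wrist += 11.0
        elif instruction == "Intorsion":
            self.wrist -= 12.0
        else:
            raise ValueError(f"unknown hand instruction {instruction!r}")
        self.log.append(instruction)
        return {"ack": True, "aperture": self.aperture, "wrist": self.wrist}


def emit(instruction: str, device_adapter) -> dict:
    """Send one instruction to a device adapter; returns its acknowledgment."""
    return device_adapter.send(instruction)


# ---------------------------------------------------------------------------
# Streaming engine
# ---------------------------------------------------------------------------

@dataclass
class TimeLogEvent:
    """One processed window: timestamps, step outcomes, transition, emission."""

    timestamp_ms: float
    counter: int
    step_a: str                      # "accept" / "reject"
    step_b: str | None = None        # "ON" / "else"
    step_c: str | None = None        # decoded 9-way label
    mode: str = "NC"
    transition: str | None = None    # "NC->IC" / "IC->NC"
    instruction: str | None = None
    ack: dict | None = None

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        return json.dumps(d)


@dataclass
class DecoderState:
    """NC/IC mode flag plus the rolling label history feeding Step D."""

    mode: str = "NC"
    n: int = 20
    history: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        self.history = deque(self.history, maxlen=self.n)

    def push(self, label: str) -> None:
        self.history.append(label)

    def clear(self) -> None:
        self.history.clear()


class StepEngine:
    """Streaming four-step decoder over a recording.

    ``stride_samples`` defaults to 10 (90% window overlap at 1000 Hz).
    History is cleared on every mode transition and, by default, after each
    emitted instruction.
    """

    def __init__(self, threshold_bank, on_detector, net,
                 criteria: CriteriaMap | None = None,
                 instruction_map: dict[str, str] | None = None,
                 device=None, n: int = 20, stride_samples: int = 10,
                 reset_history_after_instruction: bool = True,
                 switch_debounce: bool = True):
        self.bank = threshold_bank
        self.on_detector = on_detector
        self.net = net
        self.criteria = criteria or CriteriaMap(ARM_CRITERIA)
        self.instruction_map = (ARM_INSTRUCTIONS if instruction_map is None
                                else instruction_map)
        self.device = device if device is not None else VirtualArm()
        self.n = n
        self.stride = stride_samples
        self.reset_after = reset_history_after_instruction
        self.switch_debounce = switch_debounce

    def run(self, rec: EEGRecording,
            length: int = WINDOW_SAMPLES) -> list[TimeLogEvent]:
        """Process every window of ``rec``; returns the full event log."""
        screen = bandpass_array(rec.data, SCREENING_BAND, rec.rate)
        decode = bandpass_array(rec.data, DECODING_BAND, rec.rate)
        state = DecoderState(n=self.n)
        events: list[TimeLogEvent] = []
        counter = 0
        # a state switch is a discrete brow-raise event: once it fires, the
        # run of s-RB labels that produced it cannot fire again until a
        # sustained stretch (10n windows, ~2 s at the default stride) of
        # mostly non-s-RB labels shows the expression has really ended;
        # transient decoder dips shorter than that do not re-arm the switch
        switch_armed = True
        from collections import deque as _deque
        rearm_hist: _deque = _deque(maxlen=10 * self.n)
        for s0 in range(0, rec.n_samples - length + 1, self.stride):
            counter += 1
            t_ms = (s0 + length) / rec.rate * 1000.0
            ev = TimeLogEvent(timestamp_ms=t_ms, counter=counter,
                              step_a="accept", mode=state.mode)
            w_screen = screen[:, s0:s0 + length]
            from .decoder import step_a_screen, step_c_decode
            if not step_a_screen(w_screen, self.bank):
                ev.step_a = "reject"
                state.push(NON_LABEL)
                rearm_hist.append(NON_LABEL)
                if not switch_armed and len(rearm_hist) == rearm_hist.maxlen \
                        and sum(1 for l in rearm_hist if l == "s-RB") \
                        / rearm_hist.maxlen < 0.25:
                    switch_armed = True
                events.append(ev)
                continue
            w_decode = decode[:, s0:s0 + length]
            if state.mode == "NC":
                label = self.on_detector.predict_window(w_decode)
                ev.step_b = label
                step_d_label = "s-RB" if label == "ON" else NON_LABEL
            else:
                step_d_label, _ = step_c_decode(self.net, w_decode)
                ev.step_c = step_d_label
            state.push(step_d_label)
            rearm_hist.append(step_d_label)
            if not switch_armed and len(rearm_hist) == rearm_hist.maxlen:
                frac_rb = sum(1 for l in rearm_hist if l == "s-RB") \
                    / rearm_hist.maxlen
                if frac_rb < 0.25:
                    switch_armed = True
            valid = validity_judge(state.history, step_d_label, self.criteria,
                                   n=self.n)
            if valid and step_d_label == "s-RB" and self.switch_debounce \
                    and not switch_armed:
                valid = False
            if valid:
                if step_d_label == "s-RB":
                    switch_armed = False
                    rearm_hist.clear()
                    if state.mode == "NC":
                        state.mode = "IC"
                        ev.transition = "NC->IC"
                    else:
                        state.mode = "NC"
                        ev.transition = "IC->NC"
                    state.clear()
                elif state.mode == "IC":
                    instr = self.instruction_map.get(step_d_label)
                    if instr is not None:
                        ev.instruction = instr
                        ev.ack = emit(instr, self.device)
                    if self.reset_after:
                        state.clear()
            ev.mode = state.mode
            events.append(ev)
        return events


def write_event_log(events: list[TimeLogEvent], path: str | Path) -> None:
    """Event log as JSON Lines, one event per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def summarize_events(events: list[TimeLogEvent]) -> dict:
    """Counts of transitions, instructions and step outcomes."""
    out = {
        "n_windows": len(events),
        "n_rejected": sum(1 for e in events if e.step_a == "reject"),
        "transitions": [e.transition for e in events if e.transition],
        "instructions": [e.instruction for e in events if e.instruction],
    }
    return out
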