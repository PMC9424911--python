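"""Step D consistency checking, the NC/IC engine and device adapters."""

import json

import numpy as np
import pytest

from sfebci import runtime as rt
from sfebci import signal_core as sc
from sfebci.decoder import ThresholdBank


class TestValidityJudge:
    ARM = rt.CriteriaMap(rt.ARM_CRITERIA)

    def test_unanimous_buffer_triggers(self):
        assert rt.validity_judge(["s-FB"] * 20, "s-FB", self.ARM)

    def test_eighteen_of_twenty_below_095_criterion(self):
        hist = ["s-FB"] * 18 + ["NON"] * 2
        assert not rt.validity_judge(hist, "s-FB", self.ARM)

    def test_boundary_criterion_inclusive(self):
        # 9/20 = 0.45 meets the s-LS criterion of 0.45 exactly
        hist = ["s-LS"] * 9 + ["NON"] * 11
        assert rt.validity_judge(hist, "s-LS", self.ARM)
        hist8 = ["s-LS"] * 8 + ["NON"] * 12
        assert not rt.validity_judge(hist8, "s-LS", self.ARM)

    def test_non_never_triggers(self):
        assert not rt.validity_judge(["NON"] * 20, "NON", self.ARM)

    def test_partial_history_never_triggers(self):
        assert not rt.validity_judge(["s-FB"] * 10, "s-FB", self.ARM)

    def test_missing_criterion_is_configuration_error(self):
        sparse = rt.CriteriaMap({"s-RB": 0.95})
        with pytest.raises(KeyError):
            rt.validity_judge(["s-FB"] * 20, "s-FB", sparse)

    def test_criteria_range_validated(self):
        with pytest.raises(ValueError):
            rt.CriteriaMap({"s-RB": 1.5})


class TestTheoreticalTimespan:
    @pytest.mark.parametrize("ts,n,expected", [
        (0.16, 20, 103.2),    # screening + ON detection per label
        (0.25, 20, 105.0),    # screening + 9-class decoding per label
        (0.0, 0, 100.0),
    ])
    def test_formula(self, ts, n, expected):
        assert rt.theoretical_timespan(ts, n) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rt.theoretical_timespan(-1.0)


class TestVirtualDevices:
    def test_arm_height_dependent_down_stepping(self):
        arm = rt.VirtualArm(z=30.0)
        arm.send("Down")
        assert arm.z == pytest.approx(20.0)    # 10 mm step above 21 mm
        arm.send("Down")
        assert arm.z == pytest.approx(17.0)    # 3 mm step at/below 21 mm

    def test_arm_axis_steppings(self):
        arm = rt.VirtualArm()
        for instr, attr, val in [("Right", "x", 30.0), ("Left", "x", 28.0),
                                 ("Forward", "y", 20.0),
                                 ("Backward", "y", 17.0),
                                 ("Up", "z", 30.0)]:
            ack = rt.emit(instr, arm)
            assert ack["ack"]
            assert getattr(arm, attr) == pytest.approx(val)
        arm.send("Open")
        assert arm.gripper_open

    def test_hand_aperture_clamped_at_maximum(self):
        hand = rt.VirtualHand(aperture=95.0)
        hand.send("Open")
        assert hand.aperture == 95.0
        hand.send("Close")
        assert hand.aperture == pytest.approx(84.5)
        hand.send("Extorsion")
        hand.send("Intorsion")
        assert hand.wrist == pytest.approx(-1.0)

    def test_unknown_instruction_rejected(self):
        with pytest.raises(ValueError):
            rt.VirtualArm().send("Fly")


class TestDecoderState:
    def test_history_ring_buffer_capped(self):
        state = rt.DecoderState(n=5)
        for i in range(9):
            state.push(f"l{i}")
        assert len(state.history) == 5
        assert list(state.history)[0] == "l4"


# ---------------------------------------------------------------------------
# Engine logic with stub models (no training needed)
# ---------------------------------------------------------------------------

def _accept_all_bank() -> ThresholdBank:
    return ThresholdBank(
        thresholds={c: 1e12 for c in sc.REFERENCE_CHANNELS},
        channels=list(sc.MONTAGE_30))


def _reject_all_bank() -> ThresholdBank:
    return ThresholdBank(
        thresholds={c: 1e-12 for c in sc.REFERENCE_CHANNELS},
        channels=list(sc.MONTAGE_30))


class _StubDetector:
    """Labels every accepted window ON (synthetic stand-in for Step B)."""

    def predict_window(self, window):
        return "ON"


class _StubNet:
    """Always decodes a fixed class (synthetic stand-in for the 9-class net)."""

    def __init__(self, label="s-OM"):
        self.idx = list(sc.ALL_LABELS).index(label)

    def predict_proba(self, windows):
        out = np.zeros((len(windows), 9))
        out[:, self.idx] = 1.0
        return out


def _noise_recording(seconds=3.0, seed=0) -> sc.EEGRecording:
    rng = np.random.default_rng(seed)
    return sc.EEGRecording(rng.normal(size=(30, int(seconds * 1000))),
                           1000.0, list(sc.MONTAGE_30))


class TestStepEngine:
    def test_all_rejected_stream_emits_nothing(self):
        engine = rt.StepEngine(_reject_all_bank(), _StubDetector(),
                               _StubNet(), device=rt.VirtualArm())
        events = engine.run(_noise_recording())
        summary = rt.summarize_events(events)
        assert summary["n_rejected"] == summary["n_windows"]
        assert summary["instructions"] == []
        assert summary["transitions"] == []

    def test_switch_then_instruction_cadence(self):
        engine = rt.StepEngine(_accept_all_bank(), _StubDetector(),
                               _StubNet("s-OM"), device=rt.VirtualArm())
        events = engine.run(_noise_recording())
        transitions = [e for e in events if e.transition]
        # detector always says ON: exactly one NC->IC switch (debounced)
        assert [e.transition for e in transitions] == ["NC->IC"]
        # switch happens at the n-th processed window
        assert transitions[0].counter == engine.n
        instr = [e for e in events if e.instruction]
        assert len(instr) > 0
        assert all(e.instruction == "Up" for e in instr)
        # first instruction after history refills (n windows post-switch);
        # thereafter one instruction per refilled buffer
        assert instr[0].counter == 2 * engine.n
        gaps = np.diff([e.counter for e in instr])
        assert (gaps == engine.n).all()

    def test_instruction_latency_matches_streaming_formula(self):
        engine = rt.StepEngine(_accept_all_bank(), _StubDetector(),
                               _StubNet(), device=rt.VirtualArm(),
                               stride_samples=10)
        events = engine.run(_noise_recording())
        first_instr = next(e for e in events if e.instruction)
        switch = next(e for e in events if e.transition)
        # the first window contributing to the instruction starts right
        # after the switch cleared the history; from that window's start to
        # the instruction the stream advances (n-1)*stride + window length
        first_window_start_ms = switch.counter * engine.stride
        latency = first_instr.timestamp_ms - first_window_start_ms
        assert latency == pytest.approx((engine.n - 1) * engine.stride + 100.0)

    def test_unmapped_class_emits_no_instruction(self):
        engine = rt.StepEngine(_accept_all_bank(), _StubDetector(),
                               _StubNet("s-OM"),
                               criteria=rt.CriteriaMap(rt.HAND_CRITERIA),
                               instruction_map=rt.HAND_INSTRUCTIONS,
                               device=rt.VirtualHand())
        events = engine.run(_noise_recording())
        # s-OM is disabled for the hand: criterion 1.0 is met by the stub's
        # unanimous labels, but no mapping exists -> nothing transmitted
        assert [e for e in events if e.instruction] == []

    def test_event_log_replay_is_deterministic(self, tmp_path):
        rec = _noise_recording(seconds=2.0, seed=5)
        engine = rt.StepEngine(_accept_all_bank(), _StubDetector(),
                               _StubNet(), device=rt.VirtualArm())
        ev1 = engine.run(rec)
        engine2 = rt.StepEngine(_accept_all_bank(), _StubDetector(),
                                _StubNet(), device=rt.VirtualArm())
        ev2 = engine2.run(rec)
        assert [e.to_json() for e in ev1] == [e.to_json() for e in ev2]
        path = tmp_path / "events.jsonl"
        rt.write_event_log(ev1, path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(ev1)
        first = json.loads(lines[0])
        assert first["counter"] == 1
        counters = [json.loads(l)["counter"] for l in lines]
        assert counters == list(range(1, len(lines) + 1))

    def test_timestamps_monotone(self):
        engine = rt.StepEngine(_accept_all_bank(), _StubDetector(),
                               _StubNet(), device=rt.VirtualArm())
        events = engine.run(_noise_recording(seconds=1.0))
        ts = [e.timestamp_ms for e in events]
        assert all(b > a for a, b in zip(ts, ts[1:]))
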