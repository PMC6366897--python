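"""Session configuration, orchestration, logging, and clock alignment.

A session runs entirely in-process on an accelerated virtual clock: the
control hub, the emulated stimulus client (connected over an in-memory
loopback channel carrying real wire frames), and a synthetic subject advance
in lockstep at the device sampling rate (1 kHz gaze for the structured
tasks, ~42 Hz video tracking for the avoidance task).  Every command any
module emits is recorded exactly once in the session backup log, which is
what the real rig writes: one record per sent/received frame and per event
code, plus the continuous streams.

The real-time constraint of the physical rig survives here as the
non-blocking transport contracts tested in the protocol and stimulus
modules; the virtual clock makes sessions fast and bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .control import (
    ArenaConfig,
    AvoidancePhase,
    AvoidanceState,
    Command,
    CursorSample,
    GazeSample,
    GazeWindows,
    TrialConfig,
    TrialMachine,
    TrialState,
    new_trial,
    open_gate,
    reset_trial,
    step_avoidance,
    step_trial,
)
from .protocol import EventRegistry, loopback_pair
from .stimulus import ClientState, FrameSchedule, _COMMAND_EFFECTS
from .subjects import (
    SubjectProfile,
    TTLSink,
    gen_fixation_trace,
    gen_rodent_session,
    gen_saccade,
)


class SessionError(Exception):
    pass


class AlignmentError(SessionError):
    pass


# ---------------------------------------------------------------------------
# Task presets
# ---------------------------------------------------------------------------

def app1_trial_config(**overrides) -> TrialConfig:
    """8-alternative tilt task: 11.5° targets every 45°, saccade report."""
    return TrialConfig(**overrides)


def app2_trial_config(**overrides) -> TrialConfig:
    """16-alternative tilt task: 6.5° targets every 22.5°, cursor report.

    The choice-window half-extent is 1.0° — the 22.5° spacing at 6.5°
    eccentricity puts adjacent target centers ~2.5° apart, so larger windows
    would overlap and fail construction-time validation.
    """
    defaults = dict(
        choice_radius=6.5,
        choice_angles=tuple(i * 22.5 for i in range(16)),
        choice_halfext=1.0,
        report_mode="cursor",
    )
    defaults.update(overrides)
    return TrialConfig(**defaults)


def app1_windows(**overrides) -> GazeWindows:
    return GazeWindows(**overrides)


def app2_windows(**overrides) -> GazeWindows:
    defaults = dict(version_halfext=3.0, vergence_halfext=2.0)
    defaults.update(overrides)
    return GazeWindows(**defaults)


#: Default avoidance-run schedule: three unarmed entering runs, then the
#: scrambler is armed; the first armed run ends in a shock and the animal
#: never enters again (censored at the session limit).
DEFAULT_APP3_RUNS: tuple[tuple[str, object], ...] = (
    ("unarmed", 5.0),
    ("unarmed", 4.0),
    ("unarmed", 3.0),
    ("armed", 4.0),
    ("armed", "never"),
    ("armed", "never"),
)


@dataclass
class SessionConfig:
    """Everything needed to reproduce a simulated session."""

    application: str = "app1_monkey"   # app1_monkey | app2_human | app3_mouse
    seed: int = 0
    n_trials: int = 20
    subject: SubjectProfile = field(default_factory=SubjectProfile)
    windows: GazeWindows | None = None
    trial: TrialConfig | None = None
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    schedule: FrameSchedule = field(default_factory=FrameSchedule)
    break_trials: tuple[int, ...] = ()     # trials with a scripted mid-stimulus break
    noncompliant_trials: tuple[int, ...] = ()
    client_clock_offset_ms: float = 0.0    # stimulus client clock minus hub clock
    app3_runs: tuple = DEFAULT_APP3_RUNS
    app3_pre_gate_s: float = 180.0

    def __post_init__(self):
        if self.application not in ("app1_monkey", "app2_human", "app3_mouse"):
            raise SessionError(f"unknown application {self.application!r}")
        if self.windows is None:
            self.windows = (app2_windows() if self.application == "app2_human"
                            else app1_windows())
        if self.trial is None:
            self.trial = (app2_trial_config() if self.application == "app2_human"
                          else app1_trial_config())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        for key, typ in (("subject", SubjectProfile), ("windows", GazeWindows),
                         ("trial", TrialConfig), ("arena", ArenaConfig),
                         ("schedule", FrameSchedule)):
            if isinstance(d.get(key), dict):
                sub = d[key]
                for k, v in list(sub.items()):
                    if isinstance(v, list):
                        sub[k] = tuple(tuple(x) if isinstance(x, list) else x
                                       for x in v)
                d[key] = typ(**sub)
        for key in ("break_trials", "noncompliant_trials"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "app3_runs" in d and d["app3_runs"] is not None:
            d["app3_runs"] = tuple(tuple(r) for r in d["app3_runs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Session log
# ---------------------------------------------------------------------------

@dataclass
class SessionLog:
    """The session backup file: every frame and event, plus streams."""

    events: list[dict] = field(default_factory=list)
    client_events: list[dict] = field(default_factory=list)
    streams: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    ttl: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def record(self, cmd: Command, source: str = "control",
               direction: str = "emitted") -> None:
        self.events.append({
            "t": cmd.t, "source": source, "direction": direction,
            "kind": cmd.kind, "event": cmd.label,
            "payload": list(cmd.payload),
        })

    def count(self, label: str, events: list[dict] | None = None) -> int:
        pool = self.events if events is None else events
        return sum(1 for e in pool if e["event"] == label)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "events.jsonl", "w") as fh:
            for rec in self.events:
                fh.write(json.dumps(rec) + "\n")
        with open(out / "client_events.jsonl", "w") as fh:
            for rec in self.client_events:
                fh.write(json.dumps(rec) + "\n")
        for name, df in self.streams.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        return out


# ---------------------------------------------------------------------------
# Emulated stimulus client (loopback side of the hub)
# ---------------------------------------------------------------------------

class _ClientSim:
    """Polls the loopback channel each tick and mirrors hub commands into
    placeholder render state, logging stimulus-related events edge-triggered
    on its own (offset) clock."""

    def __init__(self, channel, registry: EventRegistry, clock_offset_ms: float):
        self.channel = channel
        self.registry = registry
        self.offset = clock_offset_ms
        self.state = ClientState()
        self.log: list[dict] = []

    def tick(self, hub_t: float) -> None:
        for frame in self.channel.poll():
            decoded = self.registry.decode(frame)
            if decoded is None:
                continue
            ev, _stamp = decoded
            effect = _COMMAND_EFFECTS.get(ev.label)
            if effect is None:
                continue
            attr, value = effect
            if getattr(self.state, attr) != value:
                setattr(self.state, attr, value)
                self.log.append({"t": hub_t + self.offset, "source": "stimulus",
                                 "direction": "received", "kind": "event",
                                 "event": ev.label, "payload": []})


# ---------------------------------------------------------------------------
# Structured-task subject driver
# ---------------------------------------------------------------------------

class _TaskSubject:
    """Generates the per-tick behavioral sample for one structured trial."""

    def __init__(self, cfg: SessionConfig, trial_index: int, correct: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.correct = correct
        self.compliant = trial_index not in cfg.noncompliant_trials
        self.breaks = trial_index in cfg.break_trials
        self.sigma = cfg.subject.fixation_jitter_deg
        self.rng = rng
        self.saccade = None
        self.saccade_t0 = None
        self.cursor_t0 = None
        self.break_after_ms = 200.0   # scripted break: 200 ms into STIM_ON

    def gaze(self, t: float, machine: TrialMachine) -> GazeSample | CursorSample | None:
        st = machine.state
        if not self.compliant:
            # subject looks far off-target and never acquires
            return GazeSample(t, 15.0, 15.0, 15.0, 15.0)
        if st in (TrialState.IDLE, TrialState.ITI, TrialState.REWARD):
            return self._fix(t)
        if st in (TrialState.FIX_ACQUIRE, TrialState.FIX_HOLD, TrialState.STIM_ON):
            if (self.breaks and st is TrialState.STIM_ON
                    and t - machine.entered_at >= self.break_after_ms):
                return GazeSample(t, 12.0, 0.0, 12.0, 0.0)
            return self._fix(t)
        if st is TrialState.CHOICE:
            target = self.cfg.trial.choice_centers[self.correct]
            if self.cfg.trial.report_mode == "saccade":
                return self._saccade_sample(t, machine, target)
            return self._cursor_sample(t, machine, target)
        return None

    def _fix(self, t: float) -> GazeSample:
        n = self.rng.normal(0.0, self.sigma, 4) if self.sigma > 0 else np.zeros(4)
        return GazeSample(t, n[0], n[1], n[2], n[3])

    def _saccade_sample(self, t, machine, target):
        if self.saccade is None:
            self.saccade_t0 = machine.entered_at + self.cfg.subject.saccade_latency_ms
            self.saccade = gen_saccade(
                (0.0, 0.0), target,
                peak_velocity=self.cfg.subject.saccade_peak_velocity,
                pre_hold_ms=0.0, post_hold_ms=0.0, t0=self.saccade_t0,
            )
        if t < self.saccade_t0:
            return self._fix(t)
        i = int(round(t - self.saccade_t0))
        samples = self.saccade.samples
        s = samples[min(i, len(samples) - 1)]
        return GazeSample(t, s.lx, s.ly, s.rx, s.ry)

    def _cursor_sample(self, t, machine, target):
        move_ms, latency = 300.0, self.cfg.subject.saccade_latency_ms
        t0 = machine.entered_at + latency
        if t < t0:
            return CursorSample(t, 0.0, 0.0, False)
        frac = min((t - t0) / move_ms, 1.0)
        x, y = target[0] * frac, target[1] * frac
        clicked = frac >= 1.0 and (t - t0) >= move_ms + 50.0
        return CursorSample(t, x, y, clicked)


# ---------------------------------------------------------------------------
# Session runners
# ---------------------------------------------------------------------------

def run_session(cfg: SessionConfig) -> SessionLog:
    """Run one simulated session end-to-end and return its backup log."""
    if cfg.application == "app3_mouse":
        return _run_app3(cfg)
    return _run_structured(cfg)


def _tilt_to_choice(tilt: float, cfg: TrialConfig) -> int:
    angles = [a % 360.0 for a in cfg.choice_angles]
    return angles.index(tilt % 360.0)


def _run_structured(cfg: SessionConfig) -> SessionLog:
    log = SessionLog()
    registry = EventRegistry()
    hub_chan, client_chan = loopback_pair()
    client = _ClientSim(client_chan, registry, cfg.client_clock_offset_ms)
    sink = TTLSink()
    master = np.random.SeedSequence(cfg.seed)
    trial_seeds = master.spawn(cfg.n_trials + 1)
    cond_rng = np.random.default_rng(trial_seeds[-1])
    angles = cfg.trial.choice_angles

    clock = 0.0
    dt = 1.0  # ms, 1 kHz device tick
    gaze_rows = []
    summary = {"rewards": 0, "aborts": 0, "incorrect": 0, "no_choice": 0,
               "trials": cfg.n_trials}
    evaluated = 0

    for trial_index in range(cfg.n_trials):
        tilt = float(angles[cond_rng.integers(len(angles))])
        correct = _tilt_to_choice(tilt, cfg.trial)
        subject = _TaskSubject(cfg, trial_index, correct,
                               np.random.default_rng(trial_seeds[trial_index]))
        machine = new_trial(clock, correct, trial_index)
        deadline = clock + 20000.0  # per-trial safety cap, virtual ms

        while clock < deadline:
            sample = subject.gaze(clock, machine)
            if isinstance(sample, GazeSample):
                gaze_rows.append((clock, sample.lx, sample.ly, sample.rx, sample.ry))
                evaluated += 1
            machine, commands = step_trial(machine, sample, clock, cfg.trial,
                                           cfg.windows)
            for cmd in commands:
                log.record(cmd)
                if cmd.kind == "event" and cmd.label in registry:
                    hub_chan.send(registry.encode(cmd.label, cmd.t))
                if cmd.kind == "ttl":
                    sink.pulse(cmd.label, cmd.t, cmd.payload[0]
                               if cmd.payload else 100.0)
            client.tick(clock)
            if machine.state is TrialState.ABORT:
                summary["aborts"] += 1
                machine = reset_trial(machine, clock)
            clock += dt
            if machine.state is TrialState.IDLE and machine.trial_index > trial_index:
                break
        # classify outcome from this trial's end events
        # (counted from commands as they were logged)

    for e in log.events:
        if e["event"] == "reward_delivered":
            summary["rewards"] += 1
        elif e["event"] == "trial_end" and e["payload"][:1] == ["incorrect"]:
            summary["incorrect"] += 1
        elif e["event"] == "trial_end" and e["payload"][:1] == ["no_choice"]:
            summary["no_choice"] += 1
    summary["samples_evaluated"] = evaluated

    log.client_events = client.log
    log.ttl = sink.records
    stream_name = "gaze" if cfg.application == "app1_monkey" else "gaze_and_cursor"
    log.streams[stream_name] = pd.DataFrame(
        gaze_rows, columns=["t_ms", "lx", "ly", "rx", "ry"])
    log.summary = summary
    log.manifest = {"application": cfg.application, "seed": cfg.seed,
                    "config_hash": cfg.config_hash()}
    return log


def _run_app3(cfg: SessionConfig) -> SessionLog:
    log = SessionLog()
    sink = TTLSink()
    master = np.random.SeedSequence(cfg.seed)
    run_seeds = master.spawn(len(cfg.app3_runs))
    run_summaries = []
    clock_base = 0.0
    path_rows = []

    for run_index, (arm_mode, delay) in enumerate(cfg.app3_runs):
        armed = arm_mode == "armed"
        arena = dataclasses.replace(cfg.arena, armed=armed)
        ses = gen_rodent_session(
            arena=arena, entry_delay_s=delay,
            seed=int(run_seeds[run_index].generate_state(1)[0] % (2**31)),
            pre_gate_s=cfg.app3_pre_gate_s,
        )
        state = AvoidanceState()
        gate_done = False
        shocks = 0
        run_events_start = len(log.events)

        def _apply(commands):
            nonlocal shocks
            for cmd in commands:
                log.record(cmd, source="tracker" if cmd.label == "dark_entry"
                           else "control")
                if cmd.kind == "ttl" and cmd.payload and cmd.payload[0] > 0:
                    sink.pulse(cmd.label, cmd.t, arena.shock_s * 1000.0,
                               amplitude=cmd.payload[0])
                    shocks += 1

        clock = clock_base
        x = y = 0.0
        for t, x, y in zip(ses.t_ms, ses.x, ses.y):
            clock = clock_base + t
            path_rows.append((clock, run_index, x, y))
            if not gate_done and t >= ses.gate_open_ms:
                state, commands = open_gate(state, clock)
                gate_done = True
                _apply(commands)
            state, commands = step_avoidance(state, (x, y), clock, arena)
            _apply(commands)
            if state.phase is AvoidancePhase.DONE:
                break
        # the tracked path may end before the controller does: finish a
        # pending shock pulse, or close a no-entry run at the session limit
        if state.phase is AvoidancePhase.SHOCKING and state.shock_off_due is not None:
            clock = state.shock_off_due
            state, commands = step_avoidance(state, (x, y), clock, arena)
            _apply(commands)
        elif state.phase is AvoidancePhase.MONITOR:
            clock = clock_base + ses.gate_open_ms + arena.session_limit_s * 1000.0
            state, commands = step_avoidance(state, (x, y), clock, arena)
            _apply(commands)
        run_events = log.events[run_events_start:]
        latency = None
        gate_t = next((e["t"] for e in run_events if e["event"] == "gate_open"), None)
        entry_t = next((e["t"] for e in run_events if e["event"] == "dark_entry"), None)
        censored = entry_t is None
        if gate_t is not None:
            latency = (entry_t - gate_t) / 1000.0 if entry_t is not None \
                else arena.session_limit_s
        run_summaries.append({
            "run": run_index, "armed": armed, "entry_latency_s": latency,
            "censored": censored, "shocks": shocks,
        })
        clock_base = clock_base + float(ses.t_ms[-1]) + 10000.0

    log.ttl = sink.records
    log.streams["path"] = pd.DataFrame(
        path_rows, columns=["t_ms", "run", "x_px", "y_px"])
    log.summary = {"runs": run_summaries,
                   "total_shocks": sum(r["shocks"] for r in run_summaries)}
    log.manifest = {"application": cfg.application, "seed": cfg.seed,
                    "config_hash": cfg.config_hash()}
    return log


# ---------------------------------------------------------------------------
# Offline clock alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StreamAlignment:
    """Affine map from one log's clock onto the reference clock."""

    offset_ms: float
    drift: float | None        # None when only one shared event (offset-only)
    max_residual_ms: float
    n_shared: int

    def to_reference(self, t: float) -> float:
        drift = 1.0 if self.drift is None else self.drift
        return (t - self.offset_ms) / drift


def _event_times(log_events: Sequence[dict]) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for rec in log_events:
        label = rec.get("event") or rec.get("label")
        if label:
            out.setdefault(label, []).append(float(rec["t"]))
    return out


def align_streams(event_logs: Sequence[Sequence[dict]],
                  ref_index: int = 0) -> list[StreamAlignment]:
    """Re-reference a set of event logs onto one common clock.

    Shared event codes are paired occurrence-by-occurrence between the
    reference log and each other log, and the other clock is fit as
    ``t_other = offset + drift * t_ref`` by least squares.  One shared pair
    gives an offset-only alignment (drift indeterminate, reported as None);
    no shared codes raises :class:`AlignmentError`.
    """
    if not event_logs:
        raise AlignmentError("no logs to align")
    ref = _event_times(event_logs[ref_index])
    results: list[StreamAlignment] = []
    for i, log_events in enumerate(event_logs):
        if i == ref_index:
            results.append(StreamAlignment(0.0, 1.0, 0.0, sum(
                len(v) for v in ref.values())))
            continue
        other = _event_times(log_events)
        t_ref, t_other = [], []
        for label in sorted(set(ref) & set(other)):
            for a, b in zip(ref[label], other[label]):
                t_ref.append(a)
                t_other.append(b)
        if not t_ref:
            raise AlignmentError(f"log {i} shares no event codes with the reference")
        t_ref_a = np.asarray(t_ref)
        t_other_a = np.asarray(t_other)
        if len(t_ref) == 1 or np.ptp(t_ref_a) == 0:
            offset = float(t_other_a[0] - t_ref_a[0])
            results.append(StreamAlignment(offset, None, 0.0, len(t_ref)))
            continue
        drift, offset = np.polyfit(t_ref_a, t_other_a, 1)
        resid = t_other_a - (offset + drift * t_ref_a)
        results.append(StreamAlignment(float(offset), float(drift),
                                       float(np.max(np.abs(resid))), len(t_ref)))
    return results
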