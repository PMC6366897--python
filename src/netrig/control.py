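"""Experimental-control hub logic.

This module holds the real-time decision core of the framework, written as
pure functions over immutable state so every decision is replayable:

* binocular gaze geometry — version (conjugate mean of the two eyes) and
  vergence (left-minus-right horizontal position) — and the boundary-window
  tests that enforce fixation;
* the trial state machine for the structured tasks (8-alternative and
  16-alternative 3D tilt discrimination): fixation acquire/hold,
  gaze-contingent stimulus presentation, choice detection by saccade endpoint
  or cursor click, reward and abort paths;
* the continuous (trial-less) controller for the rodent passive-avoidance
  task: point-in-polygon room occupancy and a latched shock command on the
  first dark-room entry per gate-open epoch;
* the identifier -> variable parameter store updated by decoded frames.

All commands emitted by the step functions are plain :class:`Command` values;
transport and logging are layered on top by the session runner.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .protocol import decode_param

MAX_SHOCK_MA = 0.9  # hard ceiling on shock current, milliamps


class ControlError(Exception):
    """Base class for control-side errors."""


class IncompleteSampleError(ControlError):
    """A gaze sample is missing one eye."""


class InvalidConfigError(ControlError):
    """A task/arena configuration violates its own invariants."""


class InvalidTransitionError(ControlError):
    """A terminal machine state was stepped without a reset."""


class ConfigViolationError(ControlError):
    """An emitted command would exceed a configured safety ceiling."""


# ---------------------------------------------------------------------------
# Gaze samples and boundary windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeSample:
    """One binocular eye-position sample (degrees of visual angle)."""

    t: float          # ms on the tracker clock
    lx: float
    ly: float
    rx: float
    ry: float

    def _check(self) -> None:
        for v in (self.lx, self.ly, self.rx, self.ry):
            if v is None or not math.isfinite(v):
                raise IncompleteSampleError(f"non-finite eye coordinate in {self}")


@dataclass(frozen=True)
class CursorSample:
    """One mouse-cursor sample (degrees, screen-centered) plus click state."""

    t: float
    x: float
    y: float
    clicked: bool = False


def version_of(s: GazeSample) -> tuple[float, float]:
    """Conjugate gaze direction: component-wise mean of the two eyes."""
    s._check()
    return (0.5 * (s.lx + s.rx), 0.5 * (s.ly + s.ry))


def vergence_of(s: GazeSample) -> float:
    """Disconjugate (depth) component: left minus right horizontal position."""
    s._check()
    return s.lx - s.rx


@dataclass(frozen=True)
class GazeWindows:
    """Version and vergence boundary windows enforced in real time.

    Extents are half-extents: a sample passes the version test when it lies
    within ``version_halfext`` of the window center on each axis (rectangular)
    or in Euclidean distance (circular).  Defaults are the 8-alternative task
    values (±2° version, ±1° vergence); the 16-alternative psychophysics task
    uses ±3°/±2°.
    """

    version_center: tuple[float, float] = (0.0, 0.0)
    version_halfext: float = 2.0
    vergence_center: float = 0.0
    vergence_halfext: float = 1.0
    shape: str = "rectangular"  # or "circular" (version window only)

    def __post_init__(self):
        if self.version_halfext <= 0 or self.vergence_halfext <= 0:
            raise InvalidConfigError("window half-extents must be positive")
        if self.shape not in ("rectangular", "circular"):
            raise InvalidConfigError(f"unknown window shape {self.shape!r}")


def gaze_ok(s: GazeSample, w: GazeWindows) -> bool:
    """True iff version is inside the version window AND vergence is inside
    the vergence window."""
    vx, vy = version_of(s)
    dx, dy = vx - w.version_center[0], vy - w.version_center[1]
    if w.shape == "circular":
        version_in = math.hypot(dx, dy) <= w.version_halfext
    else:
        version_in = abs(dx) <= w.version_halfext and abs(dy) <= w.version_halfext
    vergence_in = abs(vergence_of(s) - w.vergence_center) <= w.vergence_halfext
    return version_in and vergence_in


# ---------------------------------------------------------------------------
# Trial configuration and choice geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialConfig:
    """Timing and choice-target geometry for the structured tasks.

    Defaults are the 8-alternative task: 300 ms fixation, 1000 ms stimulus,
    eight choice targets at 11.5° eccentricity every 45°, saccade report.
    The 16-alternative preset (16 targets at 6.5° every 22.5°, cursor-click
    report) is in :func:`netrig.session.app2_trial_config`.
    """

    fixation_ms: float = 300.0
    stimulus_ms: float = 1000.0
    choice_radius: float = 11.5
    choice_angles: tuple[float, ...] = tuple(float(a) for a in range(0, 360, 45))
    choice_halfext: float = 3.0
    choice_shape: str = "rectangular"
    report_mode: str = "saccade"            # or "cursor"
    reward_pulse_ms: float = 100.0
    iti_ms: float = 1000.0
    acquire_timeout_ms: float = 2000.0
    choice_timeout_ms: float = 3000.0
    break_tolerance: int = 1                # consecutive out-of-window samples to abort

    def __post_init__(self):
        if min(self.fixation_ms, self.stimulus_ms, self.reward_pulse_ms,
               self.iti_ms) <= 0:
            raise InvalidConfigError("durations must be positive")
        if self.report_mode not in ("saccade", "cursor"):
            raise InvalidConfigError(f"unknown report mode {self.report_mode!r}")
        angles = [a % 360.0 for a in self.choice_angles]
        if len(set(angles)) != len(angles):
            raise InvalidConfigError("choice angles must be distinct modulo 360")
        if self.break_tolerance < 1:
            raise InvalidConfigError("break tolerance must be >= 1")
        self._validate_no_overlap()

    @property
    def choice_centers(self) -> tuple[tuple[float, float], ...]:
        r = self.choice_radius
        return tuple(
            (r * math.cos(math.radians(a)), r * math.sin(math.radians(a)))
            for a in self.choice_angles
        )

    def _validate_no_overlap(self) -> None:
        centers = self.choice_centers
        h = self.choice_halfext
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                dx = abs(centers[i][0] - centers[j][0])
                dy = abs(centers[i][1] - centers[j][1])
                if self.choice_shape == "circular":
                    overlap = math.hypot(dx, dy) < 2 * h
                else:
                    overlap = dx < 2 * h and dy < 2 * h
                if overlap:
                    raise InvalidConfigError(
                        f"choice windows {i} and {j} overlap "
                        f"(half-extent {h}° at radius {self.choice_radius}°)"
                    )


def detect_choice(sample: GazeSample | CursorSample, cfg: TrialConfig) -> int | None:
    """Index of the choice window containing the probe point, else None.

    In saccade mode the probe is the version gaze position; in cursor mode the
    probe is the cursor position and a click must be registered.  Windows are
    validated non-overlapping at construction, so at most one can claim a
    point.
    """
    if isinstance(sample, GazeSample):
        px, py = version_of(sample)
        if cfg.report_mode == "cursor":
            return None
    else:
        px, py = sample.x, sample.y
        if cfg.report_mode == "cursor" and not sample.clicked:
            return None
    h = cfg.choice_halfext
    for k, (cx, cy) in enumerate(cfg.choice_centers):
        if cfg.choice_shape == "circular":
            inside = math.hypot(px - cx, py - cy) <= h
        else:
            inside = abs(px - cx) <= h and abs(py - cy) <= h
        if inside:
            return k
    return None


# ---------------------------------------------------------------------------
# Commands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Command:
    """A side-effect request emitted by a step function.

    kind is one of ``"event"`` (a registered event code), ``"param"`` (an
    identifier/value update for a client), or ``"ttl"`` (a digital pulse
    request such as reward or shock).
    """

    kind: str
    label: str
    t: float
    payload: tuple = ()


def _ev(label: str, t: float, *payload) -> Command:
    return Command("event", label, t, tuple(payload))


def _ttl(line: str, t: float, *payload) -> Command:
    return Command("ttl", line, t, tuple(payload))


# ---------------------------------------------------------------------------
# Trial state machine
# ---------------------------------------------------------------------------

class TrialState(enum.Enum):
    IDLE = "IDLE"
    FIX_ACQUIRE = "FIX_ACQUIRE"
    FIX_HOLD = "FIX_HOLD"
    STIM_ON = "STIM_ON"
    CHOICE = "CHOICE"
    REWARD = "REWARD"
    ABORT = "ABORT"
    ITI = "ITI"


#: States from which ABORT is reachable.
ABORTABLE = frozenset({TrialState.FIX_ACQUIRE, TrialState.FIX_HOLD, TrialState.STIM_ON})


@dataclass(frozen=True)
class TrialMachine:
    """Immutable trial-machine state; advanced only through step_trial."""

    state: TrialState = TrialState.IDLE
    entered_at: float = 0.0
    correct_choice: int = 0
    bad_streak: int = 0
    trial_index: int = 0


def new_trial(clock: float, correct_choice: int, trial_index: int = 0) -> TrialMachine:
    return TrialMachine(TrialState.IDLE, clock, correct_choice, 0, trial_index)


def reset_trial(m: TrialMachine, clock: float) -> TrialMachine:
    """Leave a terminal ABORT state and enter the inter-trial interval."""
    return replace(m, state=TrialState.ITI, entered_at=clock, bad_streak=0)


def step_trial(
    m: TrialMachine,
    sample: GazeSample | CursorSample | None,
    clock: float,
    cfg: TrialConfig,
    windows: GazeWindows,
) -> tuple[TrialMachine, tuple[Command, ...]]:
    """Advance the trial machine by one sample tick.

    Pure function of (state, input, clock, config): replaying a logged input
    stream reproduces the identical command log.  Emitted commands cover the
    stimulus-related path (fixation target / stimulus / choice targets on and
    off), the behavior-related path (acquired, broken, choice made, abort),
    and the reward TTL.
    """
    st, t0 = m.state, m.entered_at
    elapsed = clock - t0

    if st is TrialState.ABORT:
        raise InvalidTransitionError("ABORT is terminal; call reset_trial first")

    if st is TrialState.IDLE:
        return (
            replace(m, state=TrialState.FIX_ACQUIRE, entered_at=clock, bad_streak=0),
            (_ev("trial_start", clock, m.trial_index),
             _ev("fixation_target_on", clock)),
        )

    if st is TrialState.FIX_ACQUIRE:
        if isinstance(sample, GazeSample) and gaze_ok(sample, windows):
            return (
                replace(m, state=TrialState.FIX_HOLD, entered_at=clock, bad_streak=0),
                (_ev("fixation_acquired", clock),),
            )
        if elapsed >= cfg.acquire_timeout_ms:
            return (
                replace(m, state=TrialState.ABORT, entered_at=clock),
                (_ev("fixation_target_off", clock),
                 _ev("trial_abort", clock, "no_acquire")),
            )
        return m, ()

    if st in (TrialState.FIX_HOLD, TrialState.STIM_ON):
        ok = isinstance(sample, GazeSample) and gaze_ok(sample, windows)
        if not ok:
            streak = m.bad_streak + 1
            if streak >= cfg.break_tolerance:
                cmds = [_ev("fixation_broken", clock)]
                if st is TrialState.STIM_ON:
                    cmds.append(_ev("stimulus_off", clock))
                cmds.append(_ev("fixation_target_off", clock))
                cmds.append(_ev("trial_abort", clock, "fixation_broken"))
                return replace(m, state=TrialState.ABORT, entered_at=clock), tuple(cmds)
            return replace(m, bad_streak=streak), ()
        m = replace(m, bad_streak=0)
        if st is TrialState.FIX_HOLD and elapsed >= cfg.fixation_ms:
            return (
                replace(m, state=TrialState.STIM_ON, entered_at=clock),
                (_ev("stimulus_on", clock),),
            )
        if st is TrialState.STIM_ON and elapsed >= cfg.stimulus_ms:
            return (
                replace(m, state=TrialState.CHOICE, entered_at=clock),
                (_ev("stimulus_off", clock),
                 _ev("fixation_target_off", clock),
                 _ev("choice_targets_on", clock)),
            )
        return m, ()

    if st is TrialState.CHOICE:
        choice = None if sample is None else detect_choice(sample, cfg)
        if choice is not None:
            cmds = [_ev("choice_made", clock, choice),
                    _ev("choice_targets_off", clock)]
            if choice == m.correct_choice:
                cmds.append(_ttl("reward", clock, cfg.reward_pulse_ms))
                cmds.append(_ev("reward_delivered", clock))
                return replace(m, state=TrialState.REWARD, entered_at=clock), tuple(cmds)
            cmds.append(_ev("trial_end", clock, "incorrect"))
            return replace(m, state=TrialState.ITI, entered_at=clock), tuple(cmds)
        if elapsed >= cfg.choice_timeout_ms:
            return (
                replace(m, state=TrialState.ITI, entered_at=clock),
                (_ev("choice_targets_off", clock),
                 _ev("trial_end", clock, "no_choice")),
            )
        return m, ()

    if st is TrialState.REWARD:
        if elapsed >= cfg.reward_pulse_ms:
            return (
                replace(m, state=TrialState.ITI, entered_at=clock),
                (_ev("trial_end", clock, "correct"),),
            )
        return m, ()

    if st is TrialState.ITI:
        if elapsed >= cfg.iti_ms:
            return (
                replace(m, state=TrialState.IDLE, entered_at=clock,
                        trial_index=m.trial_index + 1),
                (),
            )
        return m, ()

    raise InvalidTransitionError(f"unhandled state {st}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Rodent arena: occupancy and avoidance controller
# ---------------------------------------------------------------------------

def _point_in_polygon(x: float, y: float, poly: Sequence[tuple[float, float]]) -> bool:
    """Crossing-number containment with a half-open edge rule.

    Each edge is treated as half-open in y (lower endpoint included, upper
    excluded), which deterministically assigns points on a shared boundary to
    exactly one of two edge-adjacent polygons.
    """
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 <= y) != (y2 <= y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def _polygon_area(poly: Sequence[tuple[float, float]]) -> float:
    n = len(poly)
    a = 0.0
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        a += x1 * y2 - x2 * y1
    return abs(a) / 2.0


@dataclass(frozen=True)
class ArenaConfig:
    """Shuttle-box geometry and shock safety limits for the avoidance task."""

    bright_poly: tuple[tuple[float, float], ...] = (
        (10.0, 10.0), (390.0, 10.0), (390.0, 140.0), (10.0, 140.0))
    dark_poly: tuple[tuple[float, float], ...] = (
        (10.0, 160.0), (390.0, 160.0), (390.0, 290.0), (10.0, 290.0))
    shock_ma: float = 0.5
    shock_s: float = 3.0
    session_limit_s: float = 180.0
    armed: bool = False

    def __post_init__(self):
        for name, poly in (("bright", self.bright_poly), ("dark", self.dark_poly)):
            if len(poly) < 3 or _polygon_area(poly) <= 0:
                raise InvalidConfigError(f"{name} polygon is degenerate")
        try:
            from shapely.geometry import Polygon
            if Polygon(self.bright_poly).intersects(Polygon(self.dark_poly)):
                raise InvalidConfigError("bright and dark polygons must be disjoint")
        except ImportError:  # pragma: no cover
            pass
        if not (0 < self.shock_ma < MAX_SHOCK_MA):
            raise InvalidConfigError(
                f"shock current must be in (0, {MAX_SHOCK_MA}) mA, got {self.shock_ma}")


def occupancy(p: tuple[float, float], a: ArenaConfig) -> str:
    """Classify a tracked position as 'bright', 'dark', or 'none'."""
    x, y = p
    if _point_in_polygon(x, y, a.bright_poly):
        return "bright"
    if _point_in_polygon(x, y, a.dark_poly):
        return "dark"
    return "none"


class AvoidancePhase(enum.Enum):
    WAIT_GATE = "WAIT_GATE"
    MONITOR = "MONITOR"
    SHOCKING = "SHOCKING"
    DONE = "DONE"


@dataclass(frozen=True)
class AvoidanceState:
    phase: AvoidancePhase = AvoidancePhase.WAIT_GATE
    gate_open_t: float | None = None
    shock_latched: bool = False
    shock_off_due: float | None = None
    entry_t: float | None = None


def open_gate(state: AvoidanceState, clock: float) -> tuple[AvoidanceState, tuple[Command, ...]]:
    """Operator action: open the gate and start scoring entries."""
    return (
        replace(state, phase=AvoidancePhase.MONITOR, gate_open_t=clock),
        (_ev("gate_open", clock),),
    )


def step_avoidance(
    state: AvoidanceState,
    p: tuple[float, float],
    clock: float,
    a: ArenaConfig,
) -> tuple[AvoidanceState, tuple[Command, ...]]:
    """Advance the continuous avoidance controller by one position sample.

    Entries are scored only after the gate-open event.  When the scrambler is
    armed, the first dark-room occupancy emits exactly one shock-on command
    (latched for the whole gate-open epoch), followed by a shock-off after the
    configured duration.  A session-end event is emitted at the session limit
    if the animal never enters.
    """
    ph = state.phase

    if ph in (AvoidancePhase.WAIT_GATE, AvoidancePhase.DONE):
        return state, ()

    if ph is AvoidancePhase.SHOCKING:
        if state.shock_off_due is not None and clock >= state.shock_off_due:
            return (
                replace(state, phase=AvoidancePhase.DONE, shock_off_due=None),
                (_ev("shock_off", clock), _ttl("shock", clock, 0.0)),
            )
        return state, ()

    # MONITOR
    assert state.gate_open_t is not None
    if clock - state.gate_open_t >= a.session_limit_s * 1000.0:
        return (
            replace(state, phase=AvoidancePhase.DONE),
            (_ev("session_end", clock, "no_entry"),),
        )
    if occupancy(p, a) == "dark":
        cmds = [_ev("dark_entry", clock)]
        new = replace(state, entry_t=clock)
        if a.armed and not state.shock_latched:
            if a.shock_ma >= MAX_SHOCK_MA:
                raise ConfigViolationError(
                    f"shock command at {a.shock_ma} mA exceeds the "
                    f"{MAX_SHOCK_MA} mA ceiling")
            cmds.append(_ev("shock_on", clock))
            cmds.append(_ttl("shock", clock, a.shock_ma))
            new = replace(new, phase=AvoidancePhase.SHOCKING, shock_latched=True,
                          shock_off_due=clock + a.shock_s * 1000.0)
        else:
            # Unarmed: the animal is removed shortly after entry; the epoch ends.
            new = replace(new, phase=AvoidancePhase.DONE)
        return new, tuple(cmds)
    return state, ()


# ---------------------------------------------------------------------------
# Parameter store
# ---------------------------------------------------------------------------

@dataclass
class ParamBinding:
    name: str
    value: object = None
    direction: str = "send"     # "send" (hub -> client) or "receive"
    caster: Callable[[str], object] = str


class ParameterStore:
    """Identifier -> named-variable mapping updated by decoded frames.

    Applying a frame with an unknown identifier leaves the store unchanged
    and returns a warning event; a value the binding's caster rejects returns
    an error event.  Every applied frame yields exactly one log command.
    """

    def __init__(self, bindings: dict[int, ParamBinding] | None = None):
        self._by_id: dict[int, ParamBinding] = dict(bindings or {})
        names = [b.name for b in self._by_id.values()]
        if len(set(names)) != len(names):
            raise InvalidConfigError("parameter names must be unique")

    def bind(self, identifier: int, name: str, value: object = None,
             direction: str = "send", caster: Callable[[str], object] = str) -> None:
        if identifier in self._by_id:
            raise InvalidConfigError(f"identifier {identifier} already bound")
        self._by_id[identifier] = ParamBinding(name, value, direction, caster)

    def get(self, name: str) -> object:
        for b in self._by_id.values():
            if b.name == name:
                return b.value
        raise KeyError(name)

    def identifiers(self) -> tuple[int, ...]:
        return tuple(self._by_id)

    def apply(self, frame: str, clock: float = 0.0) -> tuple[Command, ...]:
        """Decode and apply one frame; returns the acknowledgment/log events."""
        identifier, value = decode_param(frame)
        binding = self._by_id.get(identifier)
        if binding is None:
            return (_ev("param_unknown", clock, identifier, value),)
        try:
            coerced = binding.caster(value)
        except (ValueError, TypeError):
            return (_ev("param_rejected", clock, identifier, value),)
        binding.value = coerced
        return (_ev("param_applied", clock, identifier, binding.name, value),)


def default_store() -> ParameterStore:
    """Registry mirroring the worked examples: -106 'StimulusDuration' on the
    send side, 205 'TrialNum' on the receive side."""
    store = ParameterStore()
    store.bind(-106, "StimulusDuration", 1.0, "send", float)
    store.bind(-107, "FixationDuration", 0.3, "send", float)
    store.bind(-108, "VersionWindow", 2.0, "send", float)
    store.bind(-109, "VergenceWindow", 1.0, "send", float)
    store.bind(205, "TrialNum", 0, "receive", int)
    store.bind(206, "CorrectCount", 0, "receive", int)
    return store


class MonitorLoop:
    """The hub's monitoring role: evaluate every incoming gaze sample.

    Kept deliberately minimal so the per-sample evaluation cost is independent
    of the concurrent parameter-update role — applying frames between samples
    must not perturb the evaluation-latency distribution.
    """

    def __init__(self, windows: GazeWindows):
        self.windows = windows
        self.evaluated = 0

    def process(self, s: GazeSample) -> bool:
        self.evaluated += 1
        return gaze_ok(s, self.windows)
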