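"""Emulated stimulus client.

The real stimulus machine runs a while-loop that renders stereoscopic frames
at a fixed refresh rate (240 Hz display, alternating eyes, 120 Hz per eye)
while polling the control hub asynchronously, so the render loop never pauses
waiting for a packet.  Here rendering is placeholder bookkeeping — what is
under test is control timing, not graphics — but the contracts are real:

* :func:`simulate_flip` implements wait-for-next-refresh-cycle semantics: a
  flip requested mid-cycle takes effect at the next refresh boundary, and
  consecutive flips alternate eyes;
* :func:`run_client_loop` is the asynchronous polling loop: every iteration
  polls without blocking, applies any pending hub commands, advances frame
  state, and emits stimulus-related event codes edge-triggered on state
  changes (hub silence is not an error);
* :func:`synth_photo_traces` synthesizes the two-channel 30 kHz photosensor
  voltage record a phototransistor watching each eye's corner patch would
  produce — ideal, edge-jittered, or with dropped frames — which the offline
  analysis module verifies.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .protocol import Channel, EventRegistry


class StimulusError(Exception):
    pass


class InvalidGridError(StimulusError):
    pass


class InvalidDurationError(StimulusError):
    pass


# ---------------------------------------------------------------------------
# Stimulus conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusCondition:
    """One planar-surface condition of the 3D tilt-discrimination tasks.

    ``tilt`` is the direction of the surface's maximal depth gradient in
    degrees; ``slant`` its steepness.  A frontoparallel plane is slant 0 with
    tilt undefined (None).  Dot-field parameters describe the random dot
    stereogram (defaults: 250 dots of 0.3° within a 20° extent at 57 cm).
    """

    tilt: float | None
    slant: float
    dot_count: int = 250
    dot_size: float = 0.3
    extent: float = 20.0
    screen_distance: float = 57.0

    def __post_init__(self):
        if self.slant == 0 and self.tilt is not None:
            raise InvalidGridError("frontoparallel condition must have tilt=None")
        if self.slant != 0 and self.tilt is None:
            raise InvalidGridError("non-zero slant requires a defined tilt")


def make_condition_grid(
    tilt_start: float,
    tilt_stop: float,
    tilt_step: float,
    slants: Sequence[float],
    include_frontoparallel: bool = False,
    **dot_kwargs,
) -> list[StimulusCondition]:
    """Cartesian tilt x slant grid, slant-major, plus an optional
    frontoparallel condition appended last.

    ``tilt_stop`` is inclusive (the 8-alternative grid is 0..315 step 45; the
    16-alternative grid 0..337.5 step 22.5).
    """
    if tilt_step <= 0:
        raise InvalidGridError(f"tilt step must be positive, got {tilt_step}")
    if tilt_stop < tilt_start:
        raise InvalidGridError("tilt stop must be reachable from start")
    n = int(round((tilt_stop - tilt_start) / tilt_step)) + 1
    tilts = [tilt_start + k * tilt_step for k in range(n)]
    grid = [
        StimulusCondition(tilt=t, slant=float(s), **dot_kwargs)
        for s in slants
        for t in tilts
    ]
    if include_frontoparallel:
        grid.append(StimulusCondition(tilt=None, slant=0.0, **dot_kwargs))
    return grid


# ---------------------------------------------------------------------------
# Frame schedule and flips
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Alternating-eye presentation schedule (240 Hz display, 120 Hz/eye)."""

    display_hz: float = 240.0

    def __post_init__(self):
        if self.display_hz <= 0:
            raise StimulusError("display rate must be positive")

    @property
    def per_eye_hz(self) -> float:
        return self.display_hz / 2.0

    @property
    def interval_ms(self) -> float:
        return 1000.0 / self.display_hz

    def eye_of_frame(self, index: int) -> str:
        """Eye parity: even refresh cycles carry the right eye's half-image."""
        return "right" if index % 2 == 0 else "left"


@dataclass(frozen=True)
class FlipRecord:
    """A flip request and the refresh boundary at which it took effect."""

    command_time: float   # ms
    scheduled_onset: float  # ms, next refresh boundary >= command time
    eye: str


def simulate_flip(command_time: float, sched: FrameSchedule) -> FlipRecord:
    """Wait-for-next-cycle flip: the onset is the smallest refresh boundary at
    or after the command time, and the eye follows refresh-cycle parity."""
    dt = sched.interval_ms
    index = math.ceil(command_time / dt - 1e-9)
    onset = index * dt
    return FlipRecord(command_time, onset, sched.eye_of_frame(index))


# ---------------------------------------------------------------------------
# Asynchronous client loop
# ---------------------------------------------------------------------------

@dataclass
class ClientState:
    """Placeholder render state mirrored from hub commands."""

    fixation_target_visible: bool = False
    stimulus_visible: bool = False
    choice_targets_visible: bool = False
    frames_rendered: int = 0


#: hub event label -> (attribute, new value) applied by the client loop
_COMMAND_EFFECTS = {
    "fixation_target_on": ("fixation_target_visible", True),
    "fixation_target_off": ("fixation_target_visible", False),
    "stimulus_on": ("stimulus_visible", True),
    "stimulus_off": ("stimulus_visible", False),
    "fixation_broken": ("stimulus_visible", False),
    "choice_targets_on": ("choice_targets_visible", True),
    "choice_targets_off": ("choice_targets_visible", False),
}


def run_client_loop(
    channel: Channel | None,
    sched: FrameSchedule,
    n_iterations: int,
    registry: EventRegistry | None = None,
    loop_ms: float = 1.0,
) -> list[dict]:
    """Run the stimulus client's polling loop on a virtual clock.

    Each iteration: non-blocking poll of the hub channel (if any), apply
    pending commands, advance the frame counter past any refresh boundaries
    crossed, and log stimulus-related events edge-triggered on state changes.
    The loop runs to completion whether or not a hub is attached or
    responsive.
    """
    registry = registry or EventRegistry()
    state = ClientState()
    log: list[dict] = []
    next_boundary = 0.0
    for i in range(n_iterations):
        t = i * loop_ms
        frames = channel.poll() if channel is not None else []
        for frame in frames:
            decoded = registry.decode(frame)
            if decoded is None:
                continue
            ev, _stamp = decoded
            effect = _COMMAND_EFFECTS.get(ev.label)
            if effect is None:
                continue
            attr, value = effect
            if getattr(state, attr) != value:
                setattr(state, attr, value)
                log.append({"t": t, "event": ev.label, "source": "stimulus"})
        while next_boundary <= t:
            state.frames_rendered += 1
            next_boundary += sched.interval_ms
    log.append({"t": n_iterations * loop_ms, "event": "loop_done",
                "source": "stimulus", "frames": state.frames_rendered})
    return log


def measure_loop_periods(
    n_iterations: int,
    channel: Channel | None = None,
    work: Callable[[], None] | None = None,
) -> np.ndarray:
    """Wall-clock per-iteration periods of a minimal polling loop, in seconds.

    Used to verify the non-pausing contract: the period distribution must be
    invariant to whether a (silent) hub is attached to the polled channel.
    """
    stamps = np.empty(n_iterations + 1)
    perf = time.perf_counter
    for i in range(n_iterations + 1):
        stamps[i] = perf()
        if channel is not None:
            channel.poll()
        if work is not None:
            work()
    return np.diff(stamps)


def compare_loop_periods(
    n_iterations: int,
    channel_a: Channel | None,
    channel_b: Channel | None,
    work_s: float = 20e-6,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired wall-clock loop-period measurement for two channel conditions.

    Each iteration runs both conditions back-to-back in randomized order
    (seeded), and each condition's iteration consists of one non-blocking
    poll plus the loop's nominal workload (``work_s`` of deterministic
    busy-wait standing in for frame rendering).  The paired, order-randomized
    design makes environmental timing noise — scheduler bursts, clock-rate
    shifts — common to both samples, so a distributional difference between
    the returned period arrays reflects the channels themselves, which is
    exactly the non-pausing contract under test.
    """
    rng = np.random.default_rng(seed)
    order = rng.integers(0, 2, n_iterations)
    pa = np.empty(n_iterations)
    pb = np.empty(n_iterations)
    perf = time.perf_counter

    def one(ch: Channel | None, t_start: float) -> float:
        if ch is not None:
            ch.poll()
        end = t_start + work_s
        while perf() < end:
            pass
        return perf()

    for i in range(n_iterations):
        first, second = ((channel_a, channel_b) if order[i] == 0
                         else (channel_b, channel_a))
        t0 = perf()
        t1 = one(first, t0)
        t2 = one(second, t1)
        if order[i] == 0:
            pa[i], pb[i] = t1 - t0, t2 - t1
        else:
            pb[i], pa[i] = t1 - t0, t2 - t1
    return pa, pb


# ---------------------------------------------------------------------------
# Synthetic photosensor traces
# ---------------------------------------------------------------------------

@dataclass
class PhotoTrace:
    """Two-channel photosensor voltage record (default 30 kHz sampling).

    Each channel watches one eye's corner patch: 0 V dark, 1 V during that
    eye's refresh cycle, so each channel pulses at the per-eye rate with a
    50% duty cycle relative to its own period.
    """

    fs: float
    right: np.ndarray
    left: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        if len(self.right) != len(self.left):
            raise StimulusError("channel lengths must match")

    @property
    def t_ms(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.right)) / self.fs * 1000.0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"t_ms": self.t_ms, "right_v": self.right,
                             "left_v": self.left})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhotoTrace":
        import pandas as pd
        df = pd.read_csv(path)
        t = df["t_ms"].to_numpy()
        fs = 1000.0 / float(np.median(np.diff(t)))
        return cls(fs=fs, right=df["right_v"].to_numpy(),
                   left=df["left_v"].to_numpy(), t0=float(t[0]))


DEFAULT_ONSET_LATENCY_MS = 4.71
"""Default flip-command-to-photon delay, ms — a typical projector pipeline
latency of roughly one refresh cycle plus transport."""


def synth_photo_traces(
    sched: FrameSchedule,
    duration_s: float,
    onset_latency_ms: float = DEFAULT_ONSET_LATENCY_MS,
    jitter_sigma_ms: float = 0.0,
    dropped_frames: Iterable[int] = (),
    seed: int | None = None,
    fs: float = 30000.0,
) -> PhotoTrace:
    """Synthesize the two-channel photosensor record of an alternating-eye
    presentation lasting ``duration_s`` of stimulus time.

    Frame ``k`` (display-rate index; even = right eye) produces a rectangular
    1 V pulse on its eye's channel from ``onset_latency + k*interval`` lasting
    one display interval, so each channel pulses at the per-eye rate.  The
    trace is long enough to hold the entire schedule including the onset
    latency.  Gaussian jitter of ``jitter_sigma_ms`` is added independently
    to each rising and falling edge; frame indices listed in
    ``dropped_frames`` are omitted entirely (their channel stays dark for
    three nominal display intervals instead of one).  Deterministic under a
    fixed seed.
    """
    if duration_s <= 0:
        raise InvalidDurationError(f"duration must be positive, got {duration_s}")
    if fs <= 2 * sched.display_hz:
        raise StimulusError("sampling rate must exceed twice the display rate")
    if onset_latency_ms < 0:
        raise StimulusError("onset latency must be non-negative")
    rng = np.random.default_rng(seed)
    dropped = set(int(k) for k in dropped_frames)
    dt = sched.interval_ms
    n_frames = int(round(duration_s * 1000.0 / dt))
    pad_ms = 4.0 * jitter_sigma_ms
    n_samples = int(math.ceil(
        (onset_latency_ms + n_frames * dt + pad_ms) / 1000.0 * fs)) + 1
    right = np.zeros(n_samples)
    left = np.zeros(n_samples)
    for k in range(n_frames):
        # draw jitter unconditionally so dropping a frame does not reshuffle
        # the jitter of later frames (keeps drop/no-drop traces comparable)
        j_on, j_off = (rng.normal(0.0, jitter_sigma_ms, 2)
                       if jitter_sigma_ms > 0 else (0.0, 0.0))
        if k in dropped:
            continue
        on_ms = onset_latency_ms + k * dt + j_on
        off_ms = onset_latency_ms + (k + 1) * dt + j_off
        # epsilon guards against float drift in k*dt placing an edge one
        # sample off its exact 30 kHz grid position
        i0 = max(0, int(math.ceil(on_ms / 1000.0 * fs - 1e-6)))
        i1 = min(n_samples, int(math.ceil(off_ms / 1000.0 * fs - 1e-6)))
        if i1 <= i0:
            continue
        channel = right if sched.eye_of_frame(k) == "right" else left
        channel[i0:i1] = 1.0
    return PhotoTrace(fs=fs, right=right, left=left)
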