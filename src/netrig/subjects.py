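"""Synthetic subjects and device emulators.

Everything the real experiments got from hardware and animals is generated
here: 1 kHz binocular gaze streams (fixation jitter, minimum-jerk saccades
with an analytically known velocity-threshold crossing), cursor streams,
~42 Hz rodent trajectories inside the shuttle-box bright room with rendered
RGB video frames, the color-centroid tracker that recovers position from
those frames, and a TTL sink that records digital pulses.  All generators are
bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .control import ArenaConfig, GazeSample, occupancy


class SubjectError(Exception):
    pass


@dataclass(frozen=True)
class SubjectProfile:
    """Behavioral parameters of an emulated primate/human subject."""

    fixation_jitter_deg: float = 0.1
    saccade_peak_velocity: float = 400.0   # deg/s
    saccade_latency_ms: float = 200.0
    compliance: float = 1.0                # probability a trial is performed


# ---------------------------------------------------------------------------
# Gaze streams
# ---------------------------------------------------------------------------

def gen_fixation_trace(
    duration_ms: float,
    sigma_deg: float = 0.1,
    vergence_offset: float = 0.0,
    rate_hz: float = 1000.0,
    seed: int | None = None,
    center: tuple[float, float] = (0.0, 0.0),
    disconjugate_sigma: float = 0.0,
    t0: float = 0.0,
) -> list[GazeSample]:
    """Binocular fixation at ``center`` with Gaussian jitter.

    Fixational jitter is modeled as conjugate: both eyes share the same
    ``sigma_deg`` noise per axis (the eyes are yoked, so the version signal
    carries the jitter while vergence stays at ``vergence_offset``).  An
    optional independent ``disconjugate_sigma`` adds per-eye horizontal noise
    for emulating vergence instability or tracker noise.  A nonzero
    ``vergence_offset`` splits the horizontal positions symmetrically
    (left = +offset/2, right = -offset/2).
    """
    if duration_ms < 0:
        raise SubjectError("duration must be non-negative")
    if sigma_deg < 0 or disconjugate_sigma < 0:
        raise SubjectError("jitter sigma must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * rate_hz / 1000.0))
    dt = 1000.0 / rate_hz
    cx, cy = center
    conj = rng.normal(0.0, sigma_deg, (n, 2)) if sigma_deg > 0 else np.zeros((n, 2))
    disc = (rng.normal(0.0, disconjugate_sigma, (n, 2))
            if disconjugate_sigma > 0 else np.zeros((n, 2)))
    half = vergence_offset / 2.0
    return [
        GazeSample(
            t=t0 + i * dt,
            lx=cx + half + conj[i, 0] + disc[i, 0], ly=cy + conj[i, 1],
            rx=cx - half + conj[i, 0] + disc[i, 1], ry=cy + conj[i, 1],
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class SaccadeTrace:
    """A generated saccade with its analytic kinematic ground truth."""

    samples: tuple[GazeSample, ...]
    start: tuple[float, float]
    end: tuple[float, float]
    peak_velocity: float     # deg/s
    movement_start_ms: float  # time the displacement begins (after pre-hold)
    duration_ms: float       # movement duration

    def threshold_crossing(self, threshold: float) -> float | None:
        """Analytic first time the speed exceeds ``threshold`` (deg/s).

        The minimum-jerk speed profile is s(tau) = 30 (D/T) tau^2 (1-tau)^2
        with peak 1.875 D/T at tau = 1/2; the crossing solves a quadratic in
        tau(1-tau).  Returns None for subthreshold movements.
        """
        if threshold >= self.peak_velocity:
            return None
        if threshold <= 0:
            return self.movement_start_ms
        d = math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1])
        t_s = self.duration_ms / 1000.0
        u = math.sqrt(threshold * t_s / (30.0 * d))
        tau = (1.0 - math.sqrt(1.0 - 4.0 * u)) / 2.0
        return self.movement_start_ms + tau * self.duration_ms


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def gen_saccade(
    start: tuple[float, float],
    end: tuple[float, float],
    peak_velocity: float = 400.0,
    rate_hz: float = 1000.0,
    seed: int | None = None,
    noise_sigma: float = 0.0,
    pre_hold_ms: float = 50.0,
    post_hold_ms: float = 50.0,
    t0: float = 0.0,
) -> SaccadeTrace:
    """Conjugate minimum-jerk saccade from ``start`` to ``end``.

    The movement duration is set so the instantaneous speed peaks at
    ``peak_velocity`` (T = 1.875 D / v_peak); the trace holds at the start
    point for ``pre_hold_ms``, moves, then holds at the end point.  The
    analytic speed-threshold crossing time is available from the returned
    :class:`SaccadeTrace`, giving detectors a known ground truth.
    """
    if peak_velocity <= 0:
        raise SubjectError("peak velocity must be positive")
    d = math.hypot(end[0] - start[0], end[1] - start[1])
    if d == 0:
        raise SubjectError("zero-length movement")
    duration_ms = 1.875 * d / peak_velocity * 1000.0
    dt = 1000.0 / rate_hz
    total_ms = pre_hold_ms + duration_ms + post_hold_ms
    n = int(round(total_ms / dt)) + 1
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    tau = np.clip((t - pre_hold_ms) / duration_ms, 0.0, 1.0)
    s = _min_jerk(tau)
    x = start[0] + (end[0] - start[0]) * s
    y = start[1] + (end[1] - start[1]) * s
    if noise_sigma > 0:
        x = x + rng.normal(0, noise_sigma, n)
        y = y + rng.normal(0, noise_sigma, n)
    samples = tuple(
        GazeSample(t=t0 + t[i], lx=x[i], ly=y[i], rx=x[i], ry=y[i])
        for i in range(n)
    )
    return SaccadeTrace(samples, start, end, peak_velocity,
                        movement_start_ms=t0 + pre_hold_ms,
                        duration_ms=duration_ms)


# ---------------------------------------------------------------------------
# Rodent sessions
# ---------------------------------------------------------------------------

FRAME_HEIGHT, FRAME_WIDTH = 300, 400  # px, camera view of the arena


@dataclass(frozen=True)
class RodentSession:
    """A generated tracked trajectory and its scripted ground truth."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    gate_open_ms: float
    entry_truth_ms: float | None   # None = never entered

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _poly_bbox(poly) -> tuple[float, float, float, float]:
    xs = [p[0] for p in poly]
    ys = [p[1] for p in poly]
    return min(xs), min(ys), max(xs), max(ys)


def gen_rodent_session(
    arena: ArenaConfig | None = None,
    explore_frac: float = 0.7,
    entry_delay_s: float | str = 5.0,
    rate_hz: float = 42.0,
    seed: int | None = None,
    pre_gate_s: float = 180.0,
) -> RodentSession:
    """Bounded random walk in the bright room, then a dark-room entry.

    The animal wanders the bright room (an Ornstein-Uhlenbeck walk whose
    roaming extent scales with ``explore_frac`` of the room) for
    ``pre_gate_s`` before the gate opens, and for ``entry_delay_s`` after;
    it then heads for the dark room in a straight run.  ``entry_delay_s``
    may be the sentinel ``"never"`` (post-shock behavior): the walk continues
    until the session limit with no entry.
    """
    arena = arena or ArenaConfig()
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / rate_hz
    x0, y0, x1, y1 = _poly_bbox(arena.bright_poly)
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    half_w = (x1 - x0) / 2.0 * math.sqrt(max(min(explore_frac, 1.0), 0.01))
    half_h = (y1 - y0) / 2.0 * math.sqrt(max(min(explore_frac, 1.0), 0.01))
    never = isinstance(entry_delay_s, str)
    if never and entry_delay_s != "never":
        raise SubjectError(f"bad entry delay sentinel {entry_delay_s!r}")
    if not never and entry_delay_s < 0:
        raise SubjectError("entry delay must be non-negative")

    gate_open_ms = pre_gate_s * 1000.0
    wander_end_ms = (gate_open_ms + arena.session_limit_s * 1000.0 if never
                     else gate_open_ms + float(entry_delay_s) * 1000.0)

    ts: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    px, py = cx, cy
    step = max(half_w, half_h) * 0.15
    t = 0.0
    while t <= wander_end_ms:
        ts.append(t)
        xs.append(px)
        ys.append(py)
        # OU pull toward room center keeps the walk inside its roaming box
        px += 0.05 * (cx - px) + rng.normal(0, step)
        py += 0.05 * (cy - py) + rng.normal(0, step)
        px = min(max(px, cx - half_w), cx + half_w)
        py = min(max(py, cy - half_h), cy + half_h)
        t += dt_ms

    entry_truth: float | None = None
    if not never:
        # straight run from the last wander point into the dark room
        dbx0, dby0, dbx1, dby1 = _poly_bbox(arena.dark_poly)
        dark_cx, dark_cy = (dbx0 + dbx1) / 2.0, (dby0 + dby1) / 2.0
        run_ms = 1000.0
        n_run = int(round(run_ms / dt_ms))
        for i in range(1, n_run + 1):
            frac = i / n_run
            qx = px + (dark_cx - px) * frac
            qy = py + (dark_cy - py) * frac
            ts.append(t)
            xs.append(qx)
            ys.append(qy)
            if entry_truth is None and occupancy((qx, qy), arena) == "dark":
                entry_truth = t
            t += dt_ms

    return RodentSession(
        t_ms=np.asarray(ts), x=np.asarray(xs), y=np.asarray(ys),
        gate_open_ms=gate_open_ms, entry_truth_ms=entry_truth,
    )


# ---------------------------------------------------------------------------
# Video frames and the color-centroid tracker
# ---------------------------------------------------------------------------

DEFAULT_BLOB_COLOR = (200, 60, 60)
DEFAULT_BACKGROUND = (40, 40, 40)


def render_arena_frame(
    position: tuple[float, float],
    blob_radius: float = 8.0,
    blob_color: tuple[int, int, int] = DEFAULT_BLOB_COLOR,
    background: tuple[int, int, int] = DEFAULT_BACKGROUND,
    shape: tuple[int, int] = (FRAME_HEIGHT, FRAME_WIDTH),
) -> np.ndarray:
    """Render one RGB camera frame: uniform background plus a filled disc of
    ``blob_color`` centered at ``position`` (x, y in pixel coordinates)."""
    h, w = shape
    frame = np.empty((h, w, 3), dtype=np.uint8)
    frame[:, :] = background
    x0, y0 = position
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= blob_radius**2
    frame[mask] = blob_color
    return frame


def track_centroid(
    frame: np.ndarray,
    lo: tuple[int, int, int] = (120, 0, 0),
    hi: tuple[int, int, int] = (255, 119, 119),
) -> tuple[float, float] | None:
    """Color-segmentation tracker: binary mask of pixels whose RGB values lie
    within [lo, hi] per channel; position is the unweighted center of mass of
    the mask (x, y in pixels), or None when no pixel is in range.

    With multiple in-range blobs the centroid of their union is returned.
    """
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise SubjectError(f"expected an HxWx3 RGB frame, got shape {frame.shape}")
    lo_a = np.asarray(lo, dtype=frame.dtype)
    hi_a = np.asarray(hi, dtype=frame.dtype)
    mask = np.all((frame >= lo_a) & (frame <= hi_a), axis=2)
    if not mask.any():
        return None
    ys, xs = np.nonzero(mask)
    return float(xs.mean()), float(ys.mean())


# ---------------------------------------------------------------------------
# TTL sink
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTLRecord:
    line: str          # {"reward", "shock"}
    t_on: float        # ms
    t_off: float       # ms
    amplitude: float = 0.0  # mA for shock lines, 0 for logic-level lines

    def __post_init__(self):
        if self.t_off <= self.t_on:
            raise SubjectError("TTL pulse must have t_off > t_on")


@dataclass
class TTLSink:
    """Records digital pulse commands the hub would send to hardware."""

    records: list[TTLRecord] = field(default_factory=list)

    def pulse(self, line: str, t_on: float, width_ms: float,
              amplitude: float = 0.0) -> TTLRecord:
        rec = TTLRecord(line, t_on, t_on + width_ms, amplitude)
        self.records.append(rec)
        return rec

    def count(self, line: str) -> int:
        return sum(1 for r in self.records if r.line == line)
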