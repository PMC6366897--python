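"""Offline verification and alignment analyses.

These are the checks an experimenter runs after (or between) sessions to
verify that the rig did what the control code asked of it:

* photosensor edge detection and the frame-timing report — per-eye rates,
  right/left alternation differences, and the dropped-frame signature (an
  alternation difference of at least three nominal display intervals,
  12.5 ms at 240 Hz);
* saccade-onset detection by the 150 deg/s instantaneous-speed rule on the
  version signal;
* spike-train alignment to events, spike density functions by convolution
  with a unit-area double-exponential kernel, and condition-wise tuning
  curves;
* the round-trip-latency benchmark harness (echo-only vs busy-loop client),
  which reproduces the measurement procedure and the high-vs-low demand
  ordering — the printed magnitudes of any particular rig are
  hardware-specific;
* rodent behavioral metrics: percent of the bright room explored and the
  dark-room entry latency, censored at the session limit.
"""

from __future__ import annotations

import socket
import threading
import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .control import ArenaConfig, GazeSample, _point_in_polygon, version_of
from .stimulus import FrameSchedule, PhotoTrace


class AnalysisError(Exception):
    pass


class EmptyTraceError(AnalysisError):
    pass


class ResamplingRequiredError(AnalysisError):
    """Timestamps are too irregular for finite-difference velocity."""


# ---------------------------------------------------------------------------
# Photosensor edges and frame timing
# ---------------------------------------------------------------------------

def detect_edges(
    v: np.ndarray,
    fs: float,
    threshold: float = 0.5,
    t0: float = 0.0,
) -> np.ndarray:
    """Onset times (ms) of upward threshold crossings, linearly interpolated
    between the straddling samples.

    A trace that already starts above threshold contributes an onset at its
    first sample (the pulse was on when recording began).
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise EmptyTraceError("empty photosensor trace")
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    times = (idx + frac) / fs * 1000.0 + t0
    if v[0] >= threshold:
        times = np.concatenate([[t0], times])
    return times


@dataclass
class FrameReport:
    """Frame-timing verification summary for one presentation trace."""

    right_onsets: np.ndarray
    left_onsets: np.ndarray
    alternation_diffs: np.ndarray   # ms, onset -> next opposite-channel onset
    mean_diff: float
    sd_diff: float
    min_diff: float
    max_diff: float
    per_eye_rate_hz: dict
    dropped_flags: np.ndarray       # times (ms) whose diff >= 3x nominal
    onset_latency_ms: float | None
    alternation_ok: bool
    nominal_interval_ms: float

    def to_dict(self) -> dict:
        return {
            "n_right": int(len(self.right_onsets)),
            "n_left": int(len(self.left_onsets)),
            "mean_diff_ms": self.mean_diff,
            "sd_diff_ms": self.sd_diff,
            "min_diff_ms": self.min_diff,
            "max_diff_ms": self.max_diff,
            "per_eye_rate_hz": self.per_eye_rate_hz,
            "n_dropped_flags": int(len(self.dropped_flags)),
            "dropped_flag_times_ms": [float(t) for t in self.dropped_flags],
            "onset_latency_ms": self.onset_latency_ms,
            "alternation_ok": self.alternation_ok,
            "nominal_interval_ms": self.nominal_interval_ms,
        }


def _channel_rate_hz(onsets: np.ndarray) -> float:
    if len(onsets) < 2:
        return float("nan")
    span_ms = onsets[-1] - onsets[0]
    return (len(onsets) - 1) / span_ms * 1000.0


def frame_report(
    trace: PhotoTrace,
    sched: FrameSchedule,
    flip_commands: Sequence | None = None,
    threshold: float = 0.5,
    flag_tolerance_ms: float | None = None,
) -> FrameReport:
    """Verify an alternating-eye presentation against its schedule.

    The alternation-difference series holds, for each detected onset, the
    time to the next onset on the *opposite* channel; on an ideal trace every
    entry equals the nominal display interval.  A dropped frame leaves its
    channel dark for an extra per-eye period, so the preceding opposite-
    channel onset's difference grows to three nominal intervals — the flag
    threshold.  Because edge jitter spreads a real three-interval gap
    symmetrically around its nominal value, the flag criterion allows a
    margin below it (default half a display interval; normal differences sit
    at one interval, a drop at three, so the separation stays unambiguous).
    Non-interleaved channels are reported (``alternation_ok``), not raised.
    """
    right = detect_edges(trace.right, trace.fs, threshold, trace.t0)
    left = detect_edges(trace.left, trace.fs, threshold, trace.t0)
    if len(right) < 2 or len(left) < 2:
        raise AnalysisError("need at least two pulses per channel")

    onsets = np.concatenate([right, left])
    labels = np.concatenate([np.zeros(len(right), int), np.ones(len(left), int)])
    order = np.argsort(onsets, kind="stable")
    onsets, labels = onsets[order], labels[order]

    diffs = []
    diff_times = []
    for i in range(len(onsets)):
        j = i + 1
        while j < len(onsets) and labels[j] == labels[i]:
            j += 1
        if j < len(onsets):
            diffs.append(onsets[j] - onsets[i])
            diff_times.append(onsets[i])
    diffs = np.asarray(diffs)
    diff_times = np.asarray(diff_times)

    nominal = sched.interval_ms
    if flag_tolerance_ms is None:
        flag_tolerance_ms = nominal / 2.0
    flag_mask = diffs >= 3.0 * nominal - flag_tolerance_ms
    alternation_ok = bool(np.all(labels[1:] != labels[:-1]))

    latency = None
    if flip_commands:
        first_cmd = min(
            getattr(f, "command_time", f) for f in flip_commands)
        latency = float(onsets[0] - first_cmd)

    return FrameReport(
        right_onsets=right,
        left_onsets=left,
        alternation_diffs=diffs,
        mean_diff=float(diffs.mean()),
        sd_diff=float(diffs.std()),
        min_diff=float(diffs.min()),
        max_diff=float(diffs.max()),
        per_eye_rate_hz={"right": _channel_rate_hz(right),
                         "left": _channel_rate_hz(left)},
        dropped_flags=diff_times[flag_mask],
        onset_latency_ms=latency,
        alternation_ok=alternation_ok,
        nominal_interval_ms=nominal,
    )


# ---------------------------------------------------------------------------
# Saccade onset
# ---------------------------------------------------------------------------

def saccade_onset(
    samples: Sequence[GazeSample],
    threshold: float = 150.0,
    smooth: int | None = None,
    dt_tolerance: float = 0.1,
) -> float | None:
    """First time (ms) the version-signal speed exceeds ``threshold`` deg/s.

    Speed is estimated by central finite differences on the version position;
    ``smooth`` applies an odd-length boxcar to the speed first.  Returns None
    if the threshold is never exceeded.  Requires near-regular sampling.
    """
    if len(samples) < 3:
        raise AnalysisError("need at least 3 samples for central differences")
    t = np.array([s.t for s in samples])
    pos = np.array([version_of(s) for s in samples])
    dts = np.diff(t)
    if np.any(np.abs(dts - np.median(dts)) > dt_tolerance * np.median(dts)):
        raise ResamplingRequiredError("irregular timestamps; resample first")
    # central difference, deg per ms -> deg/s
    vel = (pos[2:] - pos[:-2]) / (t[2:] - t[:-2])[:, None] * 1000.0
    speed = np.hypot(vel[:, 0], vel[:, 1])
    if smooth and smooth > 1:
        k = int(smooth) | 1
        speed = np.convolve(speed, np.ones(k) / k, mode="same")
    if threshold <= 0:
        hits = np.nonzero(speed > 0)[0]
    else:
        hits = np.nonzero(speed > threshold)[0]
    if hits.size == 0:
        return None
    return float(t[hits[0] + 1])  # +1: speed[i] sits at sample i+1


# ---------------------------------------------------------------------------
# Spike alignment, SDF, tuning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDFKernel:
    """Causal double-exponential smoothing kernel, unit area per spike.

    k(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / (tau_decay - tau_rise)
    for t >= 0.  Defaults: 1 ms rise, 20 ms decay.
    """

    rise_ms: float = 1.0
    decay_ms: float = 20.0

    def __post_init__(self):
        if not (0 < self.rise_ms < self.decay_ms):
            raise AnalysisError("need 0 < rise < decay")

    def sample(self, dt_ms: float, support_decays: float = 10.0) -> np.ndarray:
        """Kernel evaluated on a dt grid, discretely normalized so that
        sum(k) * dt == 1 (mass conservation holds exactly in the discrete
        convolution)."""
        t = np.arange(0.0, self.decay_ms * support_decays, dt_ms)
        k = np.exp(-t / self.decay_ms) - np.exp(-t / self.rise_ms)
        k = np.clip(k, 0.0, None)
        return k / (k.sum() * dt_ms)


def align_spikes(
    spikes: np.ndarray,
    events: np.ndarray,
    window: tuple[float, float] = (-0.2, 1.2),
) -> list[np.ndarray]:
    """Raster rows: for each event, the spike times (s) falling inside
    [event + pre, event + post], re-referenced to the event."""
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise AnalysisError("no alignment events")
    pre, post = window
    if pre >= post:
        raise AnalysisError("window pre must be < post")
    spikes = np.sort(np.asarray(spikes, dtype=float))
    rows = []
    for e in events:
        lo = np.searchsorted(spikes, e + pre, side="left")
        hi = np.searchsorted(spikes, e + post, side="right")
        rows.append(spikes[lo:hi] - e)
    return rows


def sdf(
    rows: Sequence[np.ndarray],
    kernel: SDFKernel | None = None,
    dt_ms: float = 1.0,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged spike density function in spikes/s.

    Spike times (seconds, event-referenced raster rows) are binned at
    ``dt_ms`` and convolved with the discretely-normalized kernel; the
    returned grid extends past the window by the kernel support so the full
    smoothed mass of every in-window spike is present (the integral of
    SDF x n_trials recovers the total spike count).
    """
    kernel = kernel or SDFKernel()
    if not rows:
        raise AnalysisError("no raster rows")
    all_ms = np.concatenate([np.asarray(r) * 1000.0 for r in rows]) if rows else np.array([])
    if window is None:
        lo = float(all_ms.min()) if all_ms.size else 0.0
        hi = float(all_ms.max()) if all_ms.size else dt_ms
    else:
        lo, hi = window[0] * 1000.0, window[1] * 1000.0
    k = kernel.sample(dt_ms)
    edges = np.arange(lo, hi + dt_ms, dt_ms)
    counts, _ = np.histogram(all_ms, bins=edges)
    conv = np.convolve(counts, k, mode="full")  # length n_bins + len(k) - 1
    n_trials = len(rows)
    rate = conv / n_trials * 1000.0  # spikes/ms per trial -> spikes/s
    # bin centers, extended past the window by the kernel support
    t = lo + (np.arange(conv.size) + 0.5) * dt_ms
    return t, rate


def sdf_mass(t_ms: np.ndarray, rate: np.ndarray, n_trials: int) -> float:
    """Integral of SDF x trials over the returned grid, in spikes."""
    dt_s = float(np.median(np.diff(t_ms))) / 1000.0
    return float(rate.sum() * dt_s * n_trials)


def tuning_curve(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean firing rate per (slant, tilt) condition cell.

    ``trials`` needs columns tilt (NaN for frontoparallel), slant,
    spike_count, duration_s.  Cells are ordered slant-major then tilt, with
    the frontoparallel cell last; empty cells are simply absent.
    """
    required = {"tilt", "slant", "spike_count", "duration_s"}
    missing = required - set(trials.columns)
    if missing:
        raise AnalysisError(f"trial table missing columns {sorted(missing)}")
    df = trials.copy()
    df["rate_hz"] = df["spike_count"] / df["duration_s"]
    grouped = (
        df.groupby(["slant", "tilt"], dropna=False)["rate_hz"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_rate_hz", "count": "n_trials"})
    )
    fronto = grouped["tilt"].isna()
    grouped = pd.concat([
        grouped[~fronto].sort_values(["slant", "tilt"]),
        grouped[fronto],
    ], ignore_index=True)
    return grouped


# ---------------------------------------------------------------------------
# Latency statistics and the RTT benchmark harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatencyStats:
    samples_ms: tuple[float, ...]
    mean: float
    sd: float
    n: int
    losses: int = 0

    def to_dict(self) -> dict:
        return {"mean_ms": self.mean, "sd_ms": self.sd, "n": self.n,
                "losses": self.losses}


def rtt_stats(samples_ms: Sequence[float], losses: int = 0) -> LatencyStats:
    arr = np.asarray(list(samples_ms), dtype=float)
    if arr.size == 0:
        raise AnalysisError("no latency samples")
    return LatencyStats(tuple(arr.tolist()), float(arr.mean()),
                        float(arr.std()), int(arr.size), losses)


def _echo_server(sock: socket.socket, busy_ms: float, stop: threading.Event) -> None:
    sock.setblocking(False)
    perf = time.perf_counter
    while not stop.is_set():
        try:
            data, addr = sock.recvfrom(8192)
        except BlockingIOError:
            data = None
        if data:
            if data == b"__STOP__":
                break
            sock.sendto(data, addr)
        if busy_ms > 0:
            # artificial render workload between polls (high-demand mode)
            end = perf() + busy_ms / 1000.0
            while perf() < end:
                pass


def run_rtt_benchmark(
    n: int = 500,
    mode: str = "echo",
    busy_ms: float = 1.0,
    timeout_s: float = 1.0,
    payload_bytes: int = 1024,
) -> LatencyStats:
    """Measure UDP round-trip latency hub -> client -> hub on loopback.

    In ``"echo"`` mode the client thread only polls and echoes; in
    ``"busy"`` mode it additionally runs a fixed busy-wait workload between
    polls, emulating a demanding render loop.  A round trip not answered
    within ``timeout_s`` counts as a loss and is excluded from the
    statistics.  All times are read on one clock (the hub's), so no
    cross-clock alignment is involved.
    """
    if n < 1:
        raise AnalysisError("need n >= 1")
    if mode not in ("echo", "busy"):
        raise AnalysisError(f"unknown mode {mode!r}")
    busy = busy_ms if mode == "busy" else 0.0

    server_sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
    server_sock.bind(("127.0.0.1", 0))
    server_addr = server_sock.getsockname()
    stop = threading.Event()
    thread = threading.Thread(target=_echo_server,
                              args=(server_sock, busy, stop), daemon=True)
    thread.start()

    client = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
    client.bind(("127.0.0.1", 0))
    client.settimeout(timeout_s)
    payload = b"x" * payload_bytes
    samples: list[float] = []
    losses = 0
    perf = time.perf_counter
    try:
        for i in range(n):
            msg = i.to_bytes(4, "big") + payload
            t0 = perf()
            client.sendto(msg, server_addr)
            try:
                while True:
                    data, _ = client.recvfrom(8192)
                    if data[:4] == msg[:4]:
                        break
                samples.append((perf() - t0) * 1000.0)
            except socket.timeout:
                losses += 1
    finally:
        stop.set()
        try:
            client.sendto(b"__STOP__", server_addr)
        except OSError:
            pass
        thread.join(timeout=2.0)
        client.close()
        server_sock.close()
    if not samples:
        raise AnalysisError(f"all {n} round trips lost")
    return rtt_stats(samples, losses)


# ---------------------------------------------------------------------------
# Rodent behavioral metrics
# ---------------------------------------------------------------------------

def exploration_pct(
    positions: np.ndarray,
    polygon: Sequence[tuple[float, float]],
    cell_px: float = 10.0,
) -> float:
    """Percent of the room's grid cells visited by the trajectory.

    The room is tiled with ``cell_px`` squares; a cell belongs to the room if
    its center is inside the polygon, and is visited if any sample falls in
    it.  Percent = visited / total room cells x 100.
    """
    xs = [p[0] for p in polygon]
    ys = [p[1] for p in polygon]
    x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
    if x1 <= x0 or y1 <= y0:
        raise AnalysisError("zero-area polygon")
    nx = int(np.ceil((x1 - x0) / cell_px))
    ny = int(np.ceil((y1 - y0) / cell_px))
    room_cells = set()
    for i in range(nx):
        for j in range(ny):
            cx = x0 + (i + 0.5) * cell_px
            cy = y0 + (j + 0.5) * cell_px
            if _point_in_polygon(cx, cy, polygon):
                room_cells.add((i, j))
    if not room_cells:
        raise AnalysisError("polygon contains no grid cells at this cell size")
    pos = np.asarray(positions, dtype=float)
    ii = np.floor((pos[:, 0] - x0) / cell_px).astype(int)
    jj = np.floor((pos[:, 1] - y0) / cell_px).astype(int)
    visited = set(zip(ii.tolist(), jj.tolist())) & room_cells
    return len(visited) / len(room_cells) * 100.0


@dataclass(frozen=True)
class EntryLatency:
    seconds: float
    censored: bool


def entry_latency(
    events: Iterable[dict],
    session_limit_s: float = 180.0,
) -> EntryLatency:
    """Dark-room entry latency from a session event log.

    Latency is the first ``dark_entry`` after ``gate_open``; with no entry
    the value is censored at the session limit.
    """
    gate_t = None
    for rec in events:
        label = rec.get("event") or rec.get("label")
        if label == "gate_open" and gate_t is None:
            gate_t = rec["t"]
        elif label == "dark_entry" and gate_t is not None:
            return EntryLatency((rec["t"] - gate_t) / 1000.0, censored=False)
    return EntryLatency(session_limit_s, censored=True)
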