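# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `netrig`, and what the synthetic-data generators do and do
not emulate.

## Wire protocol

A parameter frame is `"<identifier> <value> "` followed by a maximal run of
`q` padding and a terminating `/`, exactly 1024 characters (7-bit text, so
characters equal bytes).  The grammar is deliberately minimal: tokens are
separated by single spaces, the padding is always a distinct final token
(at least one `q` is inserted), and decoding splits on whitespace, parses
the first token as the integer identifier, requires the last token to match
`q+/`, and rejoins the middle tokens as the value.  Consequences worth
knowing:

* values consisting only of `q` characters are legal — the terminator is the
  *last* token, never part of the value;
* encodable values are single-spaced printable text without leading/trailing
  whitespace; anything else cannot survive the round trip and is rejected at
  encode time rather than corrupted silently;
* the `/` is counted inside the 1024 characters;
* the largest legal value alongside identifier −106 is 1016 characters
  (identifier + two separators + minimal `q/` terminator).

Event codes share the frame format on a reserved identifier band
(|code| ≥ 900; negative codes are stimulus-related commands, positive codes
behavior-related status events), leaving the small-identifier space for
parameters such as −106 `StimulusDuration` or 205 `TrialNum`.  Each process
timestamps with its own clock; streams are re-aligned offline through shared
event codes (below).

Transports: UDP datagrams (unordered, unreliable, one frame per datagram)
and TCP streams (ordered, reliable, frames recovered as fixed-size slices),
both polled non-blockingly; plus an in-memory loopback channel used by the
deterministic simulated sessions.

## Gaze geometry and windows

Version is the component-wise binocular mean; vergence is left-minus-right
horizontal position (vertical vergence is ignored).  "Window" sizes are
half-extents: a ±2° version window spans 4°.  Windows are rectangular by
default (independent x/y bounds) with a circular option for the version
test; the vergence test is always a 1-D interval.  Task defaults: ±2°
version / ±1° vergence for the 8-alternative task, ±3°/±2° for the
16-alternative task.

Choice windows default to ±3° around each target center.  For the
16-alternative geometry (6.5° eccentricity, 22.5° spacing) adjacent target
centers are only ~2.5° apart, so that preset uses ±1.0°; window overlap is
rejected at construction time, which is what guarantees `detect_choice`
returns at most one index.

## Trial state machine

States: IDLE, FIX_ACQUIRE, FIX_HOLD, STIM_ON, CHOICE, REWARD, ABORT, ITI.
Timing defaults: 300 ms fixation hold, 1000 ms stimulus, 2000 ms acquisition
timeout, 3000 ms choice timeout, 100 ms reward pulse, 1000 ms inter-trial
interval.  ABORT is reachable only from FIX_ACQUIRE/FIX_HOLD/STIM_ON and is
terminal until an explicit reset; an abort during STIM_ON emits the
stimulus-off command before the abort event.  A single out-of-window sample
aborts by default; `break_tolerance` makes the detector require N
consecutive bad samples (debouncing) without changing the strict default.
The function is pure — all timing comes from the caller's clock — which is
what makes session replay exact.

## Avoidance controller

Occupancy uses a crossing-number point-in-polygon test with a half-open edge
rule (each edge includes its lower-y endpoint and excludes its upper one),
so a point exactly on a boundary shared by two rooms belongs to exactly one
of them, deterministically.  The shock command is latched per gate-open
epoch: at most one shock-on regardless of re-entries; the configured current
must be strictly below the 0.9 mA ceiling (validated at configuration and
again at emission).  Gate opening is an operator-scripted event; entries
before it are not scored.  Sessions end at 180 s without an entry.

## Stimulus client and photosensor synthesis

Rendering is placeholder bookkeeping (frame counters and visibility flags):
the contribution under test is control timing, not graphics.  Flips follow
wait-for-next-cycle semantics — the effective onset is the first refresh
boundary at or after the command — and eye assignment follows refresh-cycle
parity (even cycles right).  Hub commands are applied within one loop
iteration; state-change events are edge-triggered, not per-frame.

Synthetic photosensor traces sample at 30 kHz.  Each undropped frame k puts
a 1 V rectangular pulse on its eye's channel for one display interval
starting at `latency + k·interval`, giving each channel a 50% duty cycle at
the per-eye rate; threshold 0.5 V defines onsets.  The default onset latency
is 4.71 ms (a typical projector pipeline delay of roughly one refresh cycle
plus transport); a strictly positive latency also keeps the first pulse's
rising edge inside the record.  Edge jitter is Gaussian per edge; dropped
frames are omitted entirely, which leaves their channel dark for three
nominal display intervals instead of one.  Jitter draws are made whether or
not a frame is dropped so that drop/no-drop traces differ only at the drop.

## Frame-timing report

Onsets are upward threshold crossings, linearly interpolated between the
straddling samples (a trace already high at its first sample counts an onset
there).  The alternation-difference series pairs each onset with the next
onset on the *opposite* channel; on an ideal trace every entry equals the
display interval (4.1667 ms at 240 Hz) with zero spread, and a dropped frame
produces exactly one three-interval (12.5 ms) entry.  The dropped-frame flag
fires at 3× nominal minus a tolerance of half an interval: edge jitter
spreads a true 3× gap symmetrically about 12.5 ms, while normal differences
sit at 1×, so the margin preserves exact reporting on clean traces and keeps
sensitivity and specificity at 1.0 up to ~0.1 ms jitter.  Per-eye rate is
(onset count − 1) / span.  Non-interleaved channels are reported as an
alternation violation, not an exception.

## Subjects

Fixational jitter is conjugate: both eyes share the same Gaussian
displacement per axis, so the jitter appears in version while vergence stays
at its configured offset (an optional disconjugate term adds per-eye
horizontal noise).  With the default σ = 0.1° the ±2°/±1° windows are ≥ 10σ
away and violations are negligible.

Saccades follow a minimum-jerk displacement profile
x(τ) = x₀ + D·(10τ³ − 15τ⁴ + 6τ⁵), whose speed peaks at 1.875·D/T; the
duration is chosen so the peak equals the requested velocity, and the first
crossing of any speed threshold has a closed-form time (quadratic in
τ(1−τ)), which the generators report as ground truth for the onset
detector.  The saccade-onset detector estimates speed by central differences
on the 1 kHz version signal (optional boxcar smoothing) and returns the
first sample above 150°/s; against the analytic truth it is accurate to
≤ 2 samples across peak velocities 200–800°/s.

Rodent sessions wander the bright room with an Ornstein–Uhlenbeck walk whose
roaming box scales with the exploration fraction, then run straight into the
dark room after the scripted post-gate delay (or never, for the post-shock
profile).  Defaults follow the task as run: gate opens after 180 s, sessions
censored 180 s after the gate.  The tracker renders a uniform disc on a
uniform background and recovers position as the unweighted centroid of the
RGB-in-range mask — the round trip is accurate to well under half a pixel.
Multiple in-range blobs yield the centroid of their union.

What the generators do **not** emulate: microsaccades and drift structure in
fixation, saccade curvature and variability, camera optics or illumination
gradients, competing colored objects, and any learning dynamics — passing
tests show the control and analysis chain is correct against known ground
truth, not that it is robust to every artifact of real data.

## Spike density and tuning

The SDF kernel is a causal double exponential
k(t) ∝ e^(−t/τ_d) − e^(−t/τ_r), defaults τ_r = 1 ms, τ_d = 20 ms
(conventional rise/decay constants; configurable).  The kernel is evaluated
on the analysis grid and normalized *discretely* (Σk·Δt = 1) so that the
discrete convolution conserves spike mass exactly: the returned grid extends
past the window by the kernel support (10 decay constants), and the integral
of SDF × trial count equals the in-window spike count to float precision.
Rates are reported in spikes/s.  Tuning curves are arithmetic means of
count/duration per (slant, tilt) cell, slant-major ordered, frontoparallel
last; empty cells are absent rather than imputed.

## Latency benchmarking and the non-pausing contract

The round-trip benchmark sends UDP frames to an echo client on loopback and
times the round trip on one clock; "busy" mode inserts a fixed busy-wait
workload between the client's polls, emulating a demanding render loop.  The
reported magnitudes are properties of the host, not of the framework; the
meaningful result is the ordering (busy > echo) and zero loss on loopback.

The non-pausing contract is measured with a paired, order-randomized design:
each iteration runs both conditions (e.g. hub endpoint present-but-silent vs
absent) back-to-back in seeded random order, each consisting of one
non-blocking poll plus the loop's nominal ~20 µs workload.  Sequential
bulk measurements are useless here — two consecutive 10⁴-sample runs of the
*identical* condition fail a KS comparison because of clock nonstationarity
and timer quantization — whereas the paired design shares that noise between
conditions, so a distributional difference reflects the channels themselves.

## Sessions, logging, alignment

Sessions run in-process on a virtual clock (1 ms ticks for the structured
tasks, ~23.8 ms for the tracker), with hub and stimulus client exchanging
real wire frames over the loopback channel.  Every emitted command is logged
exactly once (JSONL events; CSV streams; a manifest with the config hash and
seed), and identical config+seed reproduces the logs bit-for-bit.  The
default avoidance schedule is three unarmed entering runs, then three armed
runs of which the first ends in a single shock and the rest use the
never-enter profile.

Offline alignment pairs shared event codes occurrence-by-occurrence between
logs and fits t_other = offset + drift·t_ref by least squares; a single
shared event yields an offset-only alignment with drift reported as
indeterminate, and disjoint logs are an error.  A constant injected offset
is recovered exactly; a 10 ppm drift over 60 s leaves sub-millisecond
residuals.

## Problem sizes

Default test and demonstration sizes: 1 s photosensor traces (≈30 k samples
per channel), 60 s of 1 kHz gaze monitoring, 20-trial sessions, 6-run
avoidance schedules, 500-round-trip latency benchmarks, and 10⁴-iteration
loop-period comparisons — large enough for the statistics they support while
keeping any run interactive.

## Known limitations

* No real rendering, no multi-view stereo geometry, no graphical monitoring
  panels; the stimulus client is bookkeeping plus event codes.
* Single-host loopback stands in for the multi-switch topology of a physical
  rig; multi-NIC routing is out of scope.
* The virtual clock removes genuine concurrency hazards (preemption,
  interrupt jitter) from session runs; the real-time claims tested are the
  transport-level non-blocking contracts, measured on the wall clock.
* The KS-based loop-period criterion is a hypothesis test and retains its
  nominal false-alarm probability by construction.
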