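# netrig

A headless, fully simulatable implementation of a **network-parallel
behavioral-rig control framework** for real-time neuroscience experiments,
together with the offline analyses used to verify that such a rig did what it
was asked to do.

## Who this is for

Labs that run closed-loop behavioral experiments — gaze-contingent visual
psychophysics and electrophysiology in primates and humans, automated
behavioral training in rodents — split their rig across machines: an
experimental-control hub that monitors behavior and enforces contingencies in
real time, a stimulus machine that renders frames on a strict refresh
schedule, and device processes (eye tracker, video tracker, data
acquisition).  The machines coordinate over the network with small text
messages and time-stamped event codes, and every stream is re-aligned
offline.  `netrig` reproduces that whole architecture in software: every
device and subject is emulated, sessions run on an accelerated virtual clock,
and all contracts that matter on real hardware (non-blocking transport,
fixed-length frames, pure replayable state machines, latched safety commands)
are kept and tested.

## The model

**Wire protocol.** Parameters and event codes travel as fixed-length
1024-character text frames: `"<identifier> <value> qqq…q/"` — an integer
identifier, the value text, and a `q…/` terminator pad.  Example: identifier
−106 with value `one` renders as `-106 one qqq…q/`.  Transport is either
unordered/unreliable (UDP) or ordered/reliable (TCP), and **every poll is
non-blocking**: a control loop never pauses waiting for a remote peer.

**Gaze contingencies.** From a binocular sample (x<sub>L</sub>, y<sub>L</sub>,
x<sub>R</sub>, y<sub>R</sub>), version is the conjugate mean
((x<sub>L</sub>+x<sub>R</sub>)/2, (y<sub>L</sub>+y<sub>R</sub>)/2) and
vergence is x<sub>L</sub> − x<sub>R</sub>.  Fixation requires version within
±2° and vergence within ±1° of the target (±3°/±2° for the human task).

**Trial state machine.** IDLE → FIX_ACQUIRE → FIX_HOLD (300 ms) → STIM_ON
(1000 ms) → CHOICE → REWARD/ITI, with ABORT on any fixation break before the
choice targets appear.  `step_trial` is a pure function of (state, sample,
clock, config), so replaying a logged input stream reproduces the identical
command log.  Choices are reported by saccade endpoint (8 targets at 11.5°
eccentricity every 45°) or cursor click (16 targets at 6.5° every 22.5°).

**Continuous control.** The rodent passive-avoidance task has no trial
structure: a color-centroid tracker estimates position at ~42 Hz in a
300×400 px camera view, room occupancy is a deterministic point-in-polygon
test, and the first dark-room entry per gate-open epoch triggers exactly one
latched shock command (< 0.9 mA ceiling, ~3 s), with sessions censored at
180 s.

**Verification analyses.** Photosensor traces (30 kHz, one channel per eye)
are reduced to onset times by threshold crossing; the alternation-difference
series (each onset to the next opposite-eye onset) should sit at the display
interval (4.17 ms at 240 Hz), and a dropped frame appears as a ≥ 12.5 ms
(3×) gap.  Saccade onsets are the first time the version speed exceeds
150°/s.  Spike trains are aligned to events and smoothed into a spike
density function by convolution with a unit-area double-exponential kernel;
tuning curves are mean rates per (slant, tilt) condition.  Round-trip UDP
latency is benchmarked with echo-only vs busy-loop clients.

## Worked example

Run a 20-trial simulated session of the 8-alternative tilt-discrimination
task and verify an ideal photosensor trace:

```bash
$ netrig run --app app1 --trials 20 --seed 42 --out demo
session complete: {"rewards": 20, "aborts": 0, "incorrect": 0,
                   "no_choice": 0, "trials": 20, "samples_evaluated": 52700}

$ netrig make-fixtures --seed 7 --out fx
$ netrig verify-frames --trace fx/photo_ideal.csv --out vf
```

`vf/frame_report.json` then contains

```
mean_diff_ms     4.1667      # right/left alternation = display interval
sd_diff_ms       ~4e-14      # jitter-free trace: zero spread
per_eye_rate_hz  {right: 120.0, left: 120.0}
n_dropped_flags  0
```

i.e. the emulated 240 Hz alternating-eye schedule presents each eye at
exactly 120 Hz with no dropped frames; every one of the 52,700 generated
1 kHz gaze samples was evaluated by the hub (no sample loss); and all 20
compliant trials ended in a reward with zero aborts.  Running the same
command again reproduces the logs bit-for-bit.

The same toolkit runs the human cursor-report task (`--app app2`), the
mouse avoidance task (`--app app3` followed by `netrig analyze-arena`),
spike alignment (`netrig analyze-spikes`), and the loopback latency
benchmark (`netrig benchmark-rtt`).

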