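"""Gaze geometry, trial state machine, arena controller, parameter store."""

import math

import numpy as np
import pytest

from netrig.control import (
    ArenaConfig,
    AvoidancePhase,
    AvoidanceState,
    ConfigViolationError,
    CursorSample,
    GazeSample,
    GazeWindows,
    IncompleteSampleError,
    InvalidConfigError,
    InvalidTransitionError,
    TrialConfig,
    TrialState,
    _point_in_polygon,
    default_store,
    detect_choice,
    gaze_ok,
    new_trial,
    occupancy,
    open_gate,
    reset_trial,
    step_avoidance,
    step_trial,
    vergence_of,
    version_of,
)
from netrig.protocol import encode_param


def gs(lx, ly, rx, ry, t=0.0):
    return GazeSample(t, lx, ly, rx, ry)


class TestGazeGeometry:
    @pytest.mark.parametrize(
        "eyes, version, vergence",
        [
            ((1, 0, -1, 0), (0.0, 0.0), 2.0),
            ((3, 2, 3, 2), (3.0, 2.0), 0.0),
            ((2.0, 1.0, 1.0, -1.0), (1.5, 0.0), 1.0),
        ],
    )
    def test_version_and_vergence(self, eyes, version, vergence):
        s = gs(*eyes)
        assert version_of(s) == pytest.approx(version)
        assert vergence_of(s) == pytest.approx(vergence)

    def test_missing_eye_raises(self):
        with pytest.raises(IncompleteSampleError):
            version_of(gs(float("nan"), 0, 0, 0))

    def test_gaze_ok_is_conjunction_of_subtests(self, windows):
        # exhaustive truth table over (version in/out) x (vergence in/out)
        cases = {
            (True, True): gs(0.1, 0.0, -0.1, 0.0),       # version 0, vergence 0.2
            (True, False): gs(0.6, 0.0, -0.6, 0.0),      # vergence 1.2 > 1
            (False, True): gs(2.1, 0.0, 2.1, 0.0),       # version x 2.1 > 2
            (False, False): gs(3.0, 0.0, 1.5, 0.0),      # version 2.25, verg 1.5
        }
        for (v_in, g_in), s in cases.items():
            assert gaze_ok(s, windows) is (v_in and g_in)

    def test_circular_window_uses_euclidean_distance(self):
        w = GazeWindows(version_halfext=2.0, shape="circular")
        corner = gs(1.8, 1.8, 1.8, 1.8)  # |v| = 2.55 > 2 but inside the square
        assert not gaze_ok(corner, w)
        assert gaze_ok(corner, GazeWindows(version_halfext=2.0))

    def test_bad_window_config(self):
        with pytest.raises(InvalidConfigError):
            GazeWindows(version_halfext=0.0)


class TestChoiceDetection:
    def test_probe_at_each_target_center(self, trial_cfg):
        # polar-geometry oracle: the probe placed exactly at the window center
        for k, angle in enumerate(trial_cfg.choice_angles):
            x = 11.5 * math.cos(math.radians(angle))
            y = 11.5 * math.sin(math.radians(angle))
            assert detect_choice(gs(x, y, x, y), trial_cfg) == k

    def test_origin_in_no_window(self, trial_cfg):
        assert detect_choice(gs(0, 0, 0, 0), trial_cfg) is None

    def test_cursor_requires_click(self):
        from netrig.session import app2_trial_config
        cfg = app2_trial_config()
        cx, cy = cfg.choice_centers[3]
        assert detect_choice(CursorSample(0.0, cx, cy, clicked=False), cfg) is None
        assert detect_choice(CursorSample(0.0, cx, cy, clicked=True), cfg) == 3

    def test_overlapping_windows_rejected_at_construction(self):
        with pytest.raises(InvalidConfigError):
            TrialConfig(choice_radius=6.5,
                        choice_angles=tuple(i * 22.5 for i in range(16)),
                        choice_halfext=3.0)


def run_compliant_trial(cfg, windows, break_at_ms=None):
    """Drive a trial at 1 kHz with a scripted subject; return the command log."""
    m = new_trial(0.0, correct_choice=2)
    target = cfg.choice_centers[2]
    log = []
    clock = 0.0
    while clock < 10000.0:
        if m.state is TrialState.CHOICE and clock - m.entered_at > 150.0:
            s = gs(target[0], target[1], target[0], target[1], clock)
        elif break_at_ms is not None and clock >= break_at_ms:
            s = gs(10.0, 0.0, 10.0, 0.0, clock)
        else:
            s = gs(0.0, 0.0, 0.0, 0.0, clock)
        m, cmds = step_trial(m, s, clock, cfg, windows)
        log.extend(cmds)
        if m.state is TrialState.ABORT:
            return m, log
        if m.state is TrialState.ITI:
            return m, log
        clock += 1.0
    raise AssertionError("trial did not finish")


class TestTrialMachine:
    def test_fixation_held_reaches_stimulus_after_fix_duration(self, trial_cfg, windows):
        m = new_trial(0.0, 0)
        m, cmds = step_trial(m, None, 0.0, trial_cfg, windows)  # IDLE -> acquire
        assert m.state is TrialState.FIX_ACQUIRE
        assert [c.label for c in cmds] == ["trial_start", "fixation_target_on"]
        clock = 1.0
        m, _ = step_trial(m, gs(0, 0, 0, 0, clock), clock, trial_cfg, windows)
        assert m.state is TrialState.FIX_HOLD
        hold_start = clock
        while m.state is TrialState.FIX_HOLD:
            clock += 1.0
            m, cmds = step_trial(m, gs(0, 0, 0, 0, clock), clock, trial_cfg, windows)
        assert m.state is TrialState.STIM_ON
        assert clock - hold_start == pytest.approx(trial_cfg.fixation_ms)
        assert [c.label for c in cmds] == ["stimulus_on"]

    def test_break_during_stimulus_aborts_with_stimulus_off(self, trial_cfg, windows):
        m, log = run_compliant_trial(trial_cfg, windows, break_at_ms=600.0)
        assert m.state is TrialState.ABORT
        labels = [c.label for c in log]
        assert "trial_abort" in labels
        assert labels.index("stimulus_off") < labels.index("trial_abort")

    def test_correct_choice_yields_one_reward_ttl(self, trial_cfg, windows):
        m, log = run_compliant_trial(trial_cfg, windows)
        ttl = [c for c in log if c.kind == "ttl"]
        assert len(ttl) == 1 and ttl[0].label == "reward"
        assert sum(1 for c in log if c.label == "reward_delivered") == 1

    def test_stimulus_duration_respected(self, trial_cfg, windows):
        _, log = run_compliant_trial(trial_cfg, windows)
        t_on = next(c.t for c in log if c.label == "stimulus_on")
        t_off = next(c.t for c in log if c.label == "stimulus_off")
        assert t_off - t_on == pytest.approx(trial_cfg.stimulus_ms)

    def test_terminal_abort_requires_reset(self, trial_cfg, windows):
        m, _ = run_compliant_trial(trial_cfg, windows, break_at_ms=600.0)
        with pytest.raises(InvalidTransitionError):
            step_trial(m, None, 9999.0, trial_cfg, windows)
        m2 = reset_trial(m, 9999.0)
        assert m2.state is TrialState.ITI

    def test_step_is_pure_replay(self, trial_cfg, windows):
        logs = [run_compliant_trial(trial_cfg, windows, break_at_ms=600.0)[1]
                for _ in range(2)]
        assert logs[0] == logs[1]

    def test_break_tolerance_debounces_single_bad_sample(self, windows):
        cfg = TrialConfig(break_tolerance=3)
        m = new_trial(0.0, 0)
        m, _ = step_trial(m, None, 0.0, cfg, windows)
        m, _ = step_trial(m, gs(0, 0, 0, 0, 1.0), 1.0, cfg, windows)
        assert m.state is TrialState.FIX_HOLD
        m, _ = step_trial(m, gs(9, 0, 9, 0, 2.0), 2.0, cfg, windows)
        m, _ = step_trial(m, gs(9, 0, 9, 0, 3.0), 3.0, cfg, windows)
        assert m.state is TrialState.FIX_HOLD  # 2 bad < tolerance 3
        m, _ = step_trial(m, gs(0, 0, 0, 0, 4.0), 4.0, cfg, windows)
        assert m.bad_streak == 0


class TestOccupancy:
    def test_room_centroids(self, arena):
        assert occupancy((200.0, 75.0), arena) == "bright"
        assert occupancy((200.0, 225.0), arena) == "dark"
        assert occupancy((200.0, 150.0), arena) == "none"

    def test_interior_matches_shapely_oracle(self, arena, rng):
        from shapely.geometry import Point, Polygon
        bright = Polygon(arena.bright_poly)
        dark = Polygon(arena.dark_poly)
        pts = np.column_stack([rng.uniform(0, 400, 500), rng.uniform(0, 300, 500)])
        for x, y in pts:
            expected = ("bright" if bright.contains(Point(x, y))
                        else "dark" if dark.contains(Point(x, y)) else "none")
            # half-open rule only matters exactly on edges, which have
            # measure zero for these uniform draws
            if bright.boundary.distance(Point(x, y)) > 1e-9 and \
                    dark.boundary.distance(Point(x, y)) > 1e-9:
                assert occupancy((x, y), arena) == expected

    def test_half_open_edge_rule_is_deterministic(self):
        # two rectangles sharing the edge y=100: a point on the shared edge
        # belongs to exactly one of them under the half-open rule
        lower = ((0.0, 0.0), (10.0, 0.0), (10.0, 100.0), (0.0, 100.0))
        upper = ((0.0, 100.0), (10.0, 100.0), (10.0, 200.0), (0.0, 200.0))
        on_edge = (5.0, 100.0)
        in_lower = _point_in_polygon(*on_edge, lower)
        in_upper = _point_in_polygon(*on_edge, upper)
        assert in_lower != in_upper

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(InvalidConfigError):
            ArenaConfig(bright_poly=((0, 0), (1, 1), (2, 2)))

    def test_excessive_shock_current_rejected(self):
        with pytest.raises(InvalidConfigError):
            ArenaConfig(shock_ma=0.9)


class TestAvoidance:
    def drive(self, arena, path, gate_at=0.0):
        state = AvoidanceState()
        log = []
        state, cmds = open_gate(state, gate_at)
        log.extend(cmds)
        for t, x, y in path:
            state, cmds = step_avoidance(state, (x, y), t, arena)
            log.extend(cmds)
        return state, log

    def test_armed_first_entry_emits_one_latched_shock(self):
        arena = ArenaConfig(armed=True)
        # enter dark, wander inside, leave, re-enter: still one shock
        path = [(t, 200.0, 225.0) for t in np.arange(10.0, 8000.0, 24.0)]
        state, log = self.drive(arena, path)
        assert sum(1 for c in log if c.label == "shock_on") == 1
        assert sum(1 for c in log if c.label == "shock_off") == 1
        t_on = next(c.t for c in log if c.label == "shock_on")
        t_off = next(c.t for c in log if c.label == "shock_off")
        assert t_off - t_on >= arena.shock_s * 1000.0

    def test_unarmed_entry_logs_but_does_not_shock(self):
        arena = ArenaConfig(armed=False)
        path = [(10.0, 200.0, 225.0)]
        _, log = self.drive(arena, path)
        labels = [c.label for c in log]
        assert "dark_entry" in labels
        assert "shock_on" not in labels

    def test_no_entry_session_ends_at_limit(self):
        arena = ArenaConfig(armed=True, session_limit_s=180.0)
        path = [(t, 200.0, 75.0) for t in (1000.0, 100000.0, 180000.0)]
        _, log = self.drive(arena, path)
        labels = [c.label for c in log]
        assert "session_end" in labels
        assert "shock_on" not in labels

    def test_entries_before_gate_open_not_scored(self):
        arena = ArenaConfig(armed=True)
        state = AvoidanceState()
        state, cmds = step_avoidance(state, (200.0, 225.0), 5.0, arena)
        assert cmds == () and state.phase is AvoidancePhase.WAIT_GATE


class TestParameterStore:
    def test_worked_example_updates_stimulus_duration(self):
        store = default_store()
        cmds = store.apply(encode_param(-106, "1"), clock=10.0)
        assert store.get("StimulusDuration") == 1.0
        assert cmds[0].label == "param_applied"

    def test_unknown_identifier_is_logged_noop(self):
        store = default_store()
        before = {i: store._by_id[i].value for i in store.identifiers()}
        cmds = store.apply(encode_param(999, "5"))
        assert cmds[0].label == "param_unknown"
        assert {i: store._by_id[i].value for i in store.identifiers()} == before

    def test_receive_direction_trial_number(self):
        store = default_store()
        store.apply(encode_param(205, "12"))
        assert store.get("TrialNum") == 12

    def test_uncoercible_value_rejected(self):
        store = default_store()
        cmds = store.apply(encode_param(-106, "abc"))
        assert cmds[0].label == "param_rejected"
        assert store.get("StimulusDuration") == 1.0
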