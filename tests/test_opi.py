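"""OPI engine: geometry oracles, metric identities, invariance properties."""

import math

import numpy as np
import pytest

from opikin.ontology import build_step_windows
from opikin.opi import (
    bimanual_dexterity,
    clip_stream,
    compute_step_opis,
    console_sensitivity,
    derive_hand_activity,
    flag_sensitivity_outliers,
    instrument_speed,
    normalize_workspace,
    path_length,
    pct_active,
    workspace_volume,
)
from opikin.records import ActivityInterval, Trajectory
from opikin.simulate import simulate_case
from conftest import small_config


def _traj(xyz, t=None, hand="dominant", seg=None):
    xyz = np.asarray(xyz, dtype=float)
    if t is None:
        t = np.arange(len(xyz), dtype=float)
    return Trajectory("op", hand, "instrument_tip", t, xyz, segment_id=seg)


class TestPathLength:
    def test_3_4_5_triangle(self):
        assert path_length(_traj([(0, 0, 0), (3, 4, 0)])) == pytest.approx(5.0)

    def test_single_sample_is_zero(self):
        assert path_length(_traj([(1, 2, 3)])) == 0.0

    def test_discontinuity_not_accumulated(self):
        t = _traj([(0, 0, 0), (1, 0, 0), (100, 0, 0)], seg=[0, 0, 1])
        assert path_length(t) == pytest.approx(1.0)

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            xyz = rng.normal(size=(1000, 3))
            got = path_length(_traj(xyz))
            brute = sum(
                math.dist(tuple(xyz[i]), tuple(xyz[i + 1])) for i in range(len(xyz) - 1)
            )
            assert got == pytest.approx(brute, abs=1e-9)


class TestClipStream:
    def test_full_window_is_identity(self):
        xyz = np.random.default_rng(0).normal(size=(100, 3))
        t = np.linspace(0, 10, 100, endpoint=False)
        out = clip_stream(_traj(xyz, t), [(0, 10)])
        assert out.n == 100
        np.testing.assert_array_equal(out.xyz_cm, xyz)

    def test_window_beyond_stream_is_empty(self):
        out = clip_stream(_traj(np.zeros((50, 3)), np.arange(50.0)), [(100, 200)])
        assert out.n == 0

    def test_two_windows_marked_discontinuous(self):
        xyz = np.column_stack([np.arange(100.0), np.zeros(100), np.zeros(100)])
        t = np.arange(100.0)
        out = clip_stream(_traj(xyz, t), [(0, 10), (50, 60)])
        assert out.n == 20
        assert len(np.unique(out.segment_id)) == 2
        # unit steps within each window only: 9 + 9 pairs
        assert path_length(out) == pytest.approx(18.0)


class TestScalarMetrics:
    def test_pct_active(self):
        assert pct_active(50, 100) == pytest.approx(50.0)
        assert pct_active(0, 100) == 0.0
        assert pct_active(100, 100) == 100.0
        assert pct_active(10, 0) is None

    def test_instrument_speed(self):
        assert instrument_speed(100, 25) == pytest.approx(4.0)
        assert instrument_speed(0, 10) == 0.0
        assert instrument_speed(5, 0) is None

    def test_bimanual_dexterity(self):
        assert bimanual_dexterity(10, 10) == pytest.approx(1.0)
        assert bimanual_dexterity(20, 10) == pytest.approx(2.0)
        assert bimanual_dexterity(5, 0) is None

    def test_normalize_workspace(self):
        assert normalize_workspace(100, 20, 50) == (pytest.approx(5.0), pytest.approx(2.0))
        assert normalize_workspace(0, 20, 50) == (0.0, 0.0)
        r1, _ = normalize_workspace(100, 20, 50)
        r2, _ = normalize_workspace(100, 40, 50)
        assert r2 == pytest.approx(r1 / 2)

    def test_console_sensitivity(self):
        assert console_sensitivity(30, 10) == pytest.approx(3.0)
        assert console_sensitivity(10, 10) == pytest.approx(1.0)
        assert console_sensitivity(10, 0) is None

    def test_sensitivity_outlier_flags(self):
        flags = flag_sensitivity_outliers([1.8, 1.82, 1.79, 2.5, None])
        assert flags == [False, False, False, True, False]


class TestWorkspaceVolume:
    def test_unit_cube_corners(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        assert workspace_volume(corners) == pytest.approx(1.0)

    def test_degenerate_clouds_are_zero(self):
        assert workspace_volume(np.zeros((3, 3))) == 0.0
        coplanar = np.column_stack([np.random.default_rng(1).normal(size=(50, 2)), np.zeros(50)])
        assert workspace_volume(coplanar) == 0.0

    def test_monte_carlo_inclusion_oracle(self):
        """Hull volume agrees with uniform point-in-hull sampling."""
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(11)
        for _ in range(5):
            pts = rng.uniform(-2, 2, size=(500, 3))
            vol = workspace_volume(pts)
            tri = Delaunay(pts)
            lo, hi = pts.min(axis=0), pts.max(axis=0)
            draws = rng.uniform(lo, hi, size=(200_000, 3))
            frac = np.mean(tri.find_simplex(draws) >= 0)
            box = float(np.prod(hi - lo))
            assert vol == pytest.approx(frac * box, rel=0.02)


class TestDerivedHandActivity:
    def test_moving_then_still_controller(self):
        t = np.arange(0, 20, 0.05)
        xyz = np.zeros((len(t), 3))
        moving = t < 10
        xyz[moving, 0] = t[moving] * 2.0  # 2 cm/s then frozen
        traj = Trajectory("op", "dominant", "controller_wrist", t, xyz)
        ivs = derive_hand_activity(traj, [(0.0, 20.0)])
        total = sum(e - s for s, e in ivs)
        assert total == pytest.approx(10.0, abs=0.5)


def _rigid_transform(case, R, shift):
    for tr in case.trajectories:
        tr.xyz_cm = tr.xyz_cm @ R.T + shift
    return case


def _match(got, expected, **approx_kw):
    """Metric equality where ``None`` (undefined) must map to ``None``."""
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, **approx_kw)


class TestComputeStepOPIs:
    def test_simulated_speeds_recovered(self):
        cfg = small_config(seed=5, speed_dom_cm_s=4.0, speed_nondom_cm_s=3.0)
        case = simulate_case(cfg, "solo", 0)
        opis = compute_step_opis(case, build_step_windows(case))
        assert len(opis) == 2
        for o in opis:
            truth_dom = 4.0  # dominance_scale 1, but case-level jitter applies
            assert o.speed_dom_cm_s == pytest.approx(truth_dom, rel=0.35)
            assert 0 <= o.pct_active_console <= 100

    def test_speed_times_active_time_equals_pathlength(self, small_case):
        opis = compute_step_opis(small_case, build_step_windows(small_case))
        for o in opis:
            if o.speed_dom_cm_s is not None and o.active_time_dom_s > 0:
                assert o.speed_dom_cm_s * o.active_time_dom_s == pytest.approx(
                    o.pathlength_dom_cm, abs=1e-9
                )
            if o.speed_nondom_cm_s is not None and o.active_time_nondom_s > 0:
                assert o.speed_nondom_cm_s * o.active_time_nondom_s == pytest.approx(
                    o.pathlength_nondom_cm, abs=1e-9
                )

    def test_idle_step_has_zero_activity_and_undefined_speed(self):
        cfg = small_config(seed=2, duty_cycle_dom=0.0, duty_cycle_nondom=0.0)
        case = simulate_case(cfg, "solo", 0)
        opis = compute_step_opis(case, build_step_windows(case))
        for o in opis:
            assert o.pct_active_console == 0.0
            assert o.speed_dom_cm_s is None
            assert o.pathlength_dom_cm == 0.0

    def test_two_operators_give_two_rows(self, small_case):
        import copy

        from opikin.records import OperatorInfo, StepSegment

        case = copy.deepcopy(small_case)
        # clone the operator's streams under a second identity operating later
        case.roster["surg2"] = OperatorInfo("resident", 10)
        t_shift = max(s.end_s for s in case.segments) + 5.0
        extra_segs = []
        for tr in list(case.trajectories):
            case.trajectories.append(
                Trajectory(
                    "surg2", tr.hand, tr.source, tr.time_s + t_shift, tr.xyz_cm.copy()
                )
            )
        for a in list(case.activity):
            case.activity.append(
                ActivityInterval("surg2", a.scope, a.start_s + t_shift, a.end_s + t_shift)
            )
        for s in case.segments:
            if s.raw_label == "Dissection":
                extra_segs.append(
                    StepSegment("dissection", "surg2", "resident", s.start_s + t_shift, s.end_s + t_shift)
                )
        case.segments.extend(extra_segs)
        opis = compute_step_opis(case, build_step_windows(case))
        dissection_rows = [o for o in opis if o.step.value == "dissection"]
        assert {o.operator_id for o in dissection_rows} == {"surg1", "surg2"}

    def test_rigid_transform_leaves_opis_unchanged(self, small_case):
        import copy

        from scipy.stats import special_ortho_group

        base = compute_step_opis(small_case, build_step_windows(small_case))
        case = _rigid_transform(
            copy.deepcopy(small_case),
            special_ortho_group.rvs(3, random_state=4),
            np.array([10.0, -5.0, 3.0]),
        )
        moved = compute_step_opis(case, build_step_windows(case))
        for a, b in zip(base, moved):
            for f in (
                "pathlength_dom_cm", "pathlength_nondom_cm", "speed_dom_cm_s",
                "speed_nondom_cm_s", "bimanual_dexterity", "workspace_volume_cm3",
                "workspace_rate_cm3_s",
            ):
                _match(getattr(b, f), getattr(a, f), rel=1e-9, abs=1e-9)

    def test_coordinate_scaling_equivariance(self, small_case):
        import copy

        k = 2.5
        base = compute_step_opis(small_case, build_step_windows(small_case))
        case = copy.deepcopy(small_case)
        for tr in case.trajectories:
            tr.xyz_cm = tr.xyz_cm * k
        scaled = compute_step_opis(case, build_step_windows(case))
        for a, b in zip(base, scaled):
            _match(b.pathlength_dom_cm, k * a.pathlength_dom_cm, rel=1e-9)
            _match(
                b.workspace_volume_cm3,
                None if a.workspace_volume_cm3 is None else k**3 * a.workspace_volume_cm3,
                rel=1e-9,
            )
            _match(b.bimanual_dexterity, a.bimanual_dexterity, rel=1e-9)
            _match(b.pct_active_console, a.pct_active_console, rel=1e-12)

    def test_hand_swap_maps_dexterity_to_reciprocal(self, small_case):
        import copy

        base = compute_step_opis(small_case, build_step_windows(small_case))
        case = copy.deepcopy(small_case)
        swap = {"dominant": "nondominant", "nondominant": "dominant"}
        for tr in case.trajectories:
            tr.hand = swap[tr.hand]
        for a in case.activity:
            if a.scope == "dominant_hand":
                a.scope = "nondominant_hand"
            elif a.scope == "nondominant_hand":
                a.scope = "dominant_hand"
        swapped = compute_step_opis(case, build_step_windows(case))
        for a, b in zip(base, swapped):
            _match(
                b.bimanual_dexterity,
                None if a.bimanual_dexterity is None else 1.0 / a.bimanual_dexterity,
                rel=1e-9,
            )
            _match(b.pathlength_dom_cm, a.pathlength_nondom_cm, rel=1e-12)
            _match(b.speed_nondom_cm_s, a.speed_dom_cm_s, rel=1e-12)
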