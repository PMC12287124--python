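"""Generator: determinism, programmed-parameter realization, preset structure."""

import numpy as np
import pytest

from opikin import intervals as iv
from opikin.ontology import Step, build_step_windows
from opikin.opi import compute_step_opis
from opikin.simulate import (
    PRESET_EFFECTS,
    StepProfile,
    null_config,
    preset_study_effects,
    simulate_bouts,
    simulate_case,
    simulate_cohorts,
    simulate_trajectory,
    wrist_from_tip,
)
from conftest import small_config


class TestBouts:
    def test_duty_extremes(self):
        rng = np.random.default_rng(0)
        assert simulate_bouts(rng, 100.0, 0.0, 8.0) == []
        assert simulate_bouts(rng, 100.0, 1.0, 8.0) == [(0.0, 100.0)]

    def test_long_run_duty_fraction(self):
        fracs = [
            iv.total(simulate_bouts(np.random.default_rng(s), 5000.0, 0.6, 8.0)) / 5000.0
            for s in range(5)
        ]
        assert np.mean(fracs) == pytest.approx(0.6, abs=0.03)

    def test_bouts_disjoint_and_inside_duration(self):
        bouts = simulate_bouts(np.random.default_rng(3), 120.0, 0.5, 8.0)
        for (s1, e1), (s2, e2) in zip(bouts, bouts[1:]):
            assert e1 < s2
        assert all(0 <= s < e <= 120.0 for s, e in bouts)


class TestTrajectory:
    def test_realized_active_speed_matches_target(self):
        prof = StepProfile(duration_median_s=60.0)
        rng = np.random.default_rng(1)
        traj = simulate_trajectory(
            prof, "nondominant", 60.0, [(0.0, 60.0)], rng,
            sample_rate_hz=50.0, target_speed_cm_s=4.0, workspace_sigma_cm=2.0,
        )
        d = np.linalg.norm(np.diff(traj.xyz_cm, axis=0), axis=1)
        assert d.sum() / 60.0 == pytest.approx(4.0, rel=0.01)

    def test_frozen_outside_active_intervals(self):
        prof = StepProfile()
        traj = simulate_trajectory(
            prof, "dominant", 30.0, [(0.0, 10.0)], np.random.default_rng(2),
            sample_rate_hz=25.0, target_speed_cm_s=3.0, workspace_sigma_cm=2.0,
        )
        idle = traj.time_s >= 10.0
        idle_pos = traj.xyz_cm[idle]
        assert np.all(idle_pos == idle_pos[0])

    def test_no_active_time_means_no_travel(self):
        traj = simulate_trajectory(
            StepProfile(), "dominant", 20.0, [], np.random.default_rng(3),
            sample_rate_hz=25.0,
        )
        assert np.all(traj.xyz_cm == traj.xyz_cm[0])

    def test_same_seed_reproduces_samples(self):
        kw = dict(sample_rate_hz=25.0, target_speed_cm_s=3.0, workspace_sigma_cm=1.5)
        t1 = simulate_trajectory(StepProfile(), "dominant", 30.0, [(0, 30)], np.random.default_rng(7), **kw)
        t2 = simulate_trajectory(StepProfile(), "dominant", 30.0, [(0, 30)], np.random.default_rng(7), **kw)
        np.testing.assert_array_equal(t1.xyz_cm, t2.xyz_cm)

    def test_workspace_spread_tracks_sigma(self):
        spreads = []
        for sigma in (1.0, 3.0):
            traj = simulate_trajectory(
                StepProfile(), "dominant", 300.0, [(0, 300)], np.random.default_rng(5),
                sample_rate_hz=25.0, target_speed_cm_s=4.0, workspace_sigma_cm=sigma,
            )
            spreads.append(traj.xyz_cm.std(axis=0).mean())
        assert spreads[1] > 2.0 * spreads[0]

    def test_wrist_is_tip_scaled_about_centroid(self):
        tip = simulate_trajectory(
            StepProfile(), "dominant", 30.0, [(0, 30)], np.random.default_rng(6),
            sample_rate_hz=25.0, target_speed_cm_s=4.0, workspace_sigma_cm=2.0,
        )
        wrist = wrist_from_tip(tip, 2.0)
        tip_pl = np.linalg.norm(np.diff(tip.xyz_cm, axis=0), axis=1).sum()
        wrist_pl = np.linalg.norm(np.diff(wrist.xyz_cm, axis=0), axis=1).sum()
        assert tip_pl / wrist_pl == pytest.approx(2.0, rel=1e-12)


class TestCaseGeneration:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = small_config(seed=4)
        simulate_cohorts(cfg, out_dir=tmp_path / "a")
        simulate_cohorts(cfg, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                g = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == g.read_bytes(), f.name
        with pytest.raises(FileExistsError):
            simulate_cohorts(cfg, out_dir=tmp_path / "a")

    def test_single_step_config_yields_single_step_bundle(self):
        cfg = small_config(seed=5, steps=[Step.MEASUREMENT])
        case = simulate_case(cfg, "solo", 0)
        assert {s.raw_label for s in case.segments} == {"Limb measurement"}
        sets = build_step_windows(case)
        assert [s.step for s in sets] == [Step.MEASUREMENT]

    def test_adding_cases_does_not_perturb_existing_ones(self):
        cfg = small_config(seed=6)
        cfg.cohorts[0].n_cases = 1
        a = simulate_case(cfg, "solo", 0)
        cfg.cohorts[0].n_cases = 3
        b = simulate_case(cfg, "solo", 0)
        assert a.equals(b)

    def test_dexterity_direction_recovered_from_dominance_parameter(self):
        hits = 0
        for seed in range(20):
            cfg = small_config(
                seed=100 + seed, steps=[Step.DISSECTION], dominance_scale=1.5,
                duty_cycle_dom=0.9, duty_cycle_nondom=0.9, duration_median_s=40.0,
            )
            case = simulate_case(cfg, "solo", 0)
            opis = compute_step_opis(case, build_step_windows(case))
            if opis and opis[0].bimanual_dexterity is not None and opis[0].bimanual_dexterity > 1:
                hits += 1
        assert hits >= 19


class TestPreset:
    def test_effect_directions_encoded_in_profiles(self):
        cfg = preset_study_effects(4, 4, seed=0)
        att = cfg.cohort("attending").profiles
        trn = cfg.cohort("trainee").profiles
        assert att[Step.DISSECTION].dominance_scale > trn[Step.DISSECTION].dominance_scale
        assert att[Step.DISSECTION].speed_nondom_cm_s > trn[Step.DISSECTION].speed_nondom_cm_s
        p = Step.CREATION_OF_GASTRIC_POUCH
        assert att[p].speed_nondom_cm_s < trn[p].speed_nondom_cm_s
        assert att[p].duty_cycle_dom > trn[p].duty_cycle_dom
        h = Step.HAND_SEWN_ANASTOMOSIS
        assert att[h].duty_cycle_dom > trn[h].duty_cycle_dom
        assert att[h].workspace_sigma_cm < trn[h].workspace_sigma_cm

    def test_null_steps_have_identical_profiles(self):
        from opikin.simulate import PRESET_NULL_STEPS

        cfg = preset_study_effects(4, 4, seed=0)
        att = cfg.cohort("attending").profiles
        trn = cfg.cohort("trainee").profiles
        for s in PRESET_NULL_STEPS:
            assert att[s] == trn[s]

    def test_study_shaped_roster(self):
        cfg = preset_study_effects(14, 17, seed=0)
        ds = simulate_cohorts(cfg)
        assert len(ds.cases) == 31
        roster = {}
        for c in ds.cases:
            roster.update({k: v.role for k, v in c.roster.items()})
        roles = sorted(roster.values())
        assert roles.count("attending") == 2
        assert roles.count("resident") + roles.count("fellow") == 6
        assert all(
            info.handedness == "right" for c in ds.cases for info in c.roster.values()
        )

    def test_null_config_equalizes_profiles(self):
        cfg = null_config(3, 3, seed=0)
        a, b = cfg.cohorts
        for s, p in a.profiles.items():
            assert b.profiles[s] == p

    def test_truth_manifest_covers_all_case_steps(self):
        cfg = preset_study_effects(2, 2, seed=1, duration_median_s=20.0)
        ds = simulate_cohorts(cfg)
        assert set(ds.truth.columns) >= {"case_id", "step", "speed_dom_cm_s", "duty_dom"}
        assert len(ds.truth) == 4 * 8
        assert set(t[0].value for t in PRESET_EFFECTS) <= set(ds.truth.step)
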