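"""Trial geometry, kinematics, training-set sampling and task batteries."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remapnet.protocol import (TrainingSet, TrialSpec, battery_from_json,
                               battery_to_json, build_task_battery,
                               enumerate_feasible_pairs, eye_position_trace,
                               kinematics, make_training_trial,
                               pair_is_feasible, retinal_stimulus_trace,
                               sample_multidirection_pairs,
                               sample_training_set, time_grid)

DT = 2.0


def trial(h=None, s=None, t_on=0.0, t_off=0.0, t_sacc=None, dur=900.0, **kw):
    return TrialSpec(h=h, s=s, t_stim_on=t_on, t_stim_off=t_off,
                     t_sacc=t_sacc, duration=dur, **kw)


class TestTrialSpec:
    @pytest.mark.parametrize("kw", [
        dict(h=50.0, t_on=0, t_off=100),            # stimulus off the grid
        dict(s=35.0, t_sacc=100.0),                 # saccade off the grid
        dict(h=0.0, t_on=200, t_off=100),           # inverted window
        dict(h=0.0, t_on=0, t_off=1000),            # window past trial end
        dict(s=10.0, t_sacc=None),                  # saccade without onset
        dict(h=40.0, s=-10.0, t_on=0, t_off=100, t_sacc=100.0),  # post=50
    ])
    def test_invalid_geometry_rejected(self, kw):
        with pytest.raises(ValueError):
            trial(**kw)

    def test_strict_false_allows_offgrid_postsaccadic_location(self):
        t = trial(h=40.0, s=-10.0, t_on=0, t_off=100, t_sacc=100.0,
                  strict=False)
        assert t.h - t.s == 50.0

    def test_roundtrip_dict(self):
        t = trial(h=-5.0, s=15.0, t_on=100, t_off=200, t_sacc=600.0)
        assert TrialSpec.from_dict(t.to_dict()) == t


class TestKinematics:
    def test_15deg_saccade_completes_in_50ms(self):
        t = trial(h=-5.0, s=15.0, t_on=0, t_off=700, t_sacc=200.0, dur=700)
        eye = eye_position_trace(t, DT)
        grid = time_grid(700, DT)
        assert eye[grid <= 200].max() == 0.0
        assert eye[np.searchsorted(grid, 250)] == pytest.approx(15.0)
        assert np.all(eye[grid >= 250] == 15.0)

    def test_minus30_saccade_completes_in_100ms(self):
        t = trial(s=-30.0, t_sacc=100.0)
        eye = eye_position_trace(t, DT)
        grid = time_grid(900, DT)
        assert eye[np.searchsorted(grid, 200)] == pytest.approx(-30.0)
        assert eye[np.searchsorted(grid, 198)] > -30.0

    def test_no_saccade_eye_stays_at_zero(self):
        assert not eye_position_trace(trial(h=0.0, t_on=0, t_off=100),
                                      DT).any()

    def test_retinal_location_shifts_by_saccade(self):
        t = trial(h=-5.0, s=15.0, t_on=0, t_off=700, t_sacc=200.0, dur=700)
        kin = kinematics(t, DT)
        assert kin.retinal_stim[0] == -5.0
        assert kin.retinal_stim[-2] == pytest.approx(-20.0)

    def test_fixation_trial_retinal_equals_head_location(self):
        t = trial(h=32.0, t_on=100, t_off=200)
        kin = kinematics(t, DT)
        vis = ~np.isnan(kin.retinal_stim)
        assert np.all(kin.retinal_stim[vis] == 32.0)
        assert np.isnan(kin.retinal_stim[kin.times >= 200]).all()
        assert np.isnan(kin.retinal_stim[kin.times < 100]).all()

    @settings(max_examples=30, deadline=None)
    @given(st.sampled_from(enumerate_feasible_pairs()),
           st.integers(0, 300))
    def test_head_centered_constancy(self, pair, t_sacc):
        """h - e(t) - psi(t) == 0 at every visible sample, saccade or not."""
        h, s = pair
        t = trial(h=float(h), s=float(s), t_on=0, t_off=900,
                  t_sacc=float(t_sacc))
        eye = eye_position_trace(t, DT)
        psi = retinal_stimulus_trace(t, eye, DT)
        vis = ~np.isnan(psi)
        np.testing.assert_allclose(h - eye[vis] - psi[vis], 0.0, atol=1e-12)


class TestTrainingSet:
    def test_constraints_and_determinism(self):
        ts1 = sample_training_set(50, seed=3)
        ts2 = sample_training_set(50, seed=3)
        assert ts1.pairs == ts2.pairs
        for h, s in ts1.pairs:
            assert abs(s) >= 10 and -45 <= h - s <= 45
            assert h == int(h) and s == int(s)

    def test_sampling_matches_enumeration_oracle(self):
        """Empirical frequencies over the feasible integer set agree with
        the uniform enumeration within multinomial error."""
        feasible = enumerate_feasible_pairs()
        n = 100_000
        ts = sample_training_set(n, seed=11)
        counts = {}
        for pr in ts.pairs:
            counts[pr] = counts.get(pr, 0) + 1
        assert set(counts) <= set(feasible)
        expect = n / len(feasible)
        freqs = np.array([counts.get(pr, 0) for pr in feasible])
        # ~5 sigma multinomial bound on each cell
        assert np.abs(freqs - expect).max() < 5 * np.sqrt(expect) + 1

    def test_distinct_posts_option(self):
        ts = sample_training_set(40, seed=5, distinct_posts=True)
        posts = ts.post_saccadic_locations()
        assert len(set(posts)) == len(posts)

    def test_infeasible_pair_rejected(self):
        with pytest.raises(ValueError):
            TrainingSet(((40, -10),), seed=0)

    def test_multidirection_pairs(self):
        ts = sample_multidirection_pairs([-20, 0, 30], per_target=4, seed=2)
        assert ts.M == 12
        for k, r in enumerate([-20, 0, 30]):
            group = ts.pairs[4 * k:4 * (k + 1)]
            assert len(set(group)) == 4
            assert all(h - s == r for h, s in group)


class TestTrainingTrial:
    def test_fig_2a_template(self):
        t = make_training_trial(-5, 15)
        assert t.duration == 700.0
        assert t.t_sacc == 200.0
        assert (t.t_stim_on, t.t_stim_off) == (0.0, 700.0)

    def test_post_saccadic_location_follows_geometry(self):
        t = make_training_trial(0, 10)
        assert t.h - t.s == -10

    def test_infeasible_pair_rejected_with_reason(self):
        with pytest.raises(ValueError, match="training constraints"):
            make_training_trial(40, -10)

    def test_duration_snaps_up_to_grid(self):
        t = make_training_trial(0, 10)          # saccade lasts 33.33 ms
        assert t.duration % 2.0 == 0.0
        assert 683.0 <= t.duration <= 684.5


class TestBatteries:
    def test_cardinalities(self):
        ts = sample_training_set(17, seed=1)
        assert len(build_task_battery("stimulus_control")) == 91
        assert len(build_task_battery("saccade_control")) == 61
        assert len(build_task_battery("probe")) == 5551
        assert len(build_task_battery("single_step", ts)) == 17
        assert len(build_task_battery("delayed_flash", ts)) == 26 * 17

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            build_task_battery("double_step")

    def test_single_step_template(self):
        ts = TrainingSet(((-5, 15),), seed=0)
        (t,) = build_task_battery("single_step", ts)
        assert (t.t_stim_on, t.t_stim_off) == (100.0, 200.0)
        assert t.t_sacc == 600.0 and t.duration == 900.0
        assert t.saccade_end() == 650.0

    def test_delayed_flash_families(self):
        ts = TrainingSet(((-5, 15),), seed=0)
        batt = build_task_battery("delayed_flash", ts)
        fams = {}
        for t in batt:
            fams.setdefault(t.tag["family"], []).append(t)
        assert set(fams) == {"current_RF", "future_RF"}
        for fam, trials in fams.items():
            assert len(trials) == 13
            onsets = sorted(t.tag["onset"] for t in trials)
            assert onsets == [100.0 + 50.0 * k for k in range(13)]
        # current RF sits at the pre-saccadic RF head-centered location
        assert all(t.h == -20.0 for t in fams["current_RF"])
        assert all(t.h == -5.0 for t in fams["future_RF"])

    def test_every_generated_trial_is_valid(self):
        ts = sample_training_set(8, seed=9)
        for kind in ("stimulus_control", "saccade_control", "single_step"):
            for t in build_task_battery(kind, ts):
                assert isinstance(t, TrialSpec)  # constructor validated

    def test_json_roundtrip(self, tmp_path):
        batt = build_task_battery("saccade_control")
        path = tmp_path / "batt.json"
        battery_to_json(batt, path)
        assert battery_from_json(path) == batt
        # serialization is plain JSON objects
        raw = json.loads(path.read_text())
        assert raw[0]["s"] == -30


def test_feasibility_oracle_consistency():
    for h, s in enumerate_feasible_pairs():
        assert pair_is_feasible(h, s)
    assert not pair_is_feasible(40, -10)
    assert not pair_is_feasible(0, 5)
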