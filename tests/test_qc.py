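"""Trial rejection criteria, participant inclusion, and analysis-table
assembly."""

import numpy as np
import pandas as pd
import pytest

import popgaze as pg
from popgaze.gaze import aoi_set_for_trial, process_gaze_trial
from popgaze.qc import (ValidityFlags, apply_trial_criteria,
                        assemble_trial_table, include_participant)
from popgaze.schedule import POSITIONS
from popgaze.simulate import draw_infants, simulate_trial

FS = 600.0
SO, VO, VOFF = 0.75, 1.0, 4.0
T = np.arange(0, 4.5, 1 / FS)
AOIS = aoi_set_for_trial({"face": "UL", "manmade": "UR",
                          "natural": "LL", "shape": "LR"}, POSITIONS)


def build_trial(center_until=None, saccade_at=0.4, target=(-12.0, 6.0),
                offscreen_spans=(), missing_spans=(), pre_center_frac=1.0):
    """Construct gaze for one trial: centre dwell, saccade to `target`
    `saccade_at` seconds after visual onset, optional corruption."""
    x = np.zeros(T.size)
    y = np.zeros(T.size)
    i_sac = np.searchsorted(T, VO + saccade_at)
    x[i_sac:] = target[0]
    y[i_sac:] = target[1]
    if pre_center_frac < 1.0:
        # push part of the pre-sound window out of the central area
        w1 = np.flatnonzero((T >= SO - 0.5) & (T < SO))
        k = int(round((1 - pre_center_frac) * w1.size))
        x[w1[:k]] = 10.0
    for s, e in offscreen_spans:
        m = (T >= s) & (T < e)
        x[m] = 30.0
    series = pg.EyeSampleSeries(
        t=T, lx=x, ly=y, rx=x.copy(), ry=y.copy(),
        lp=np.full(T.size, 4.0), rp=np.full(T.size, 4.0),
        sound_onset_s=SO, visual_onset_s=VO, visual_offset_s=VOFF)
    for s, e in missing_spans:
        m = (series.t >= s) & (series.t < e)
        for chan in ("lx", "ly", "rx", "ry"):
            getattr(series, chan)[m] = np.nan
    return series


def flags_for(series, **kw):
    gaze_res, _interp, x, y = process_gaze_trial(series, AOIS)
    return apply_trial_criteria(gaze_res, series, x, y, AOIS, **kw), gaze_res


class TestCriteria:
    def test_clean_trial_passes_all(self):
        flags, _ = flags_for(build_trial())
        assert flags.valid
        assert flags.reject_reason is None

    def test_c1_low_center_occupancy_before_sound(self):
        flags, _ = flags_for(build_trial(pre_center_frac=0.30))
        assert flags.c1
        flags, _ = flags_for(build_trial(pre_center_frac=0.50))
        assert not flags.c1

    def test_c2_no_central_sample_before_visual(self):
        flags, _ = flags_for(build_trial(offscreen_spans=[(VO - 0.2, VO)]))
        assert flags.c2

    def test_c3_any_bad_sample_in_first_half_second(self):
        # a 50 ms off-screen excursion: a single bad sample in the first
        # 500 ms trips the strict (default) reading
        flags, _ = flags_for(build_trial(offscreen_spans=[(VO + 0.2, VO + 0.25)]))
        assert flags.c3
        # short *missing* gaps are interpolated away first and do not trip it
        flags, _ = flags_for(build_trial(missing_spans=[(VO + 0.2, VO + 0.21)]))
        assert not flags.c3
        # an uninterpolable (>= 150 ms) gap does
        flags, _ = flags_for(build_trial(missing_spans=[(VO + 0.2, VO + 0.4)]))
        assert flags.c3

    def test_c3_second_clause_quarter_threshold(self):
        """30% off-screen in [vo+0.5, vo+1.0) rejects; 20% does not."""
        f30, _ = flags_for(build_trial(
            offscreen_spans=[(VO + 0.6, VO + 0.75)]))   # 150 ms / 500 ms
        f20, _ = flags_for(build_trial(
            offscreen_spans=[(VO + 0.6, VO + 0.7)]))    # 100 ms / 500 ms
        assert f30.c3
        assert not f20.c3

    def test_c3_mode_variants(self):
        series = build_trial(offscreen_spans=[(VO + 0.1, VO + 0.2)])
        any_mode, _ = flags_for(series, c3_mode="any")
        prop_mode, _ = flags_for(series, c3_mode="proportion")
        all_mode, _ = flags_for(series, c3_mode="all")
        assert any_mode.c3            # 100 ms excursion trips the strict reading
        assert not prop_mode.c3       # 20% < 25%
        assert not all_mode.c3

    def test_c4_no_aoi_entry(self):
        # gaze stays at centre for the whole presentation
        flags, gaze_res = flags_for(build_trial(saccade_at=10.0))
        assert np.isnan(gaze_res.latency_s)
        assert flags.c4

    def test_c5_latency_bounds(self):
        fast, _ = flags_for(build_trial(saccade_at=0.15))
        slow, _ = flags_for(build_trial(saccade_at=1.2))
        ok, _ = flags_for(build_trial(saccade_at=0.5))
        assert fast.c5 and slow.c5
        assert not ok.c5

    def test_validity_is_conjunction(self):
        f = ValidityFlags(c3=True)
        assert not f.valid
        assert f.reject_reason == "c3_missing_after_visual"
        assert ValidityFlags().valid


class TestCorruptionMonotonicity:
    def test_adding_missing_samples_never_rescues_a_trial(self, rng):
        """Rejection is monotone in corruption: masking extra samples of a
        trial never turns an invalid trial valid."""
        params = pg.SimulationParams(n_infants_per_age=1)
        infant = draw_infants(params, rng)[0]
        sched = pg.generate_schedule(3)
        for tr in sched.trials[:6]:
            series, _ = simulate_trial(tr, infant, params, rng)
            gaze_res, _i, x, y = process_gaze_trial(series, AOIS)
            before = apply_trial_criteria(gaze_res, series, x, y, AOIS).valid
            corrupted = series.copy()
            start = rng.uniform(0, series.t[-1] - 0.3)
            m = (corrupted.t >= start) & (corrupted.t < start + 0.3)
            for chan in ("lx", "ly", "rx", "ry", "lp", "rp"):
                getattr(corrupted, chan)[m] = np.nan
            gaze_res2, _i2, x2, y2 = process_gaze_trial(corrupted, AOIS)
            after = apply_trial_criteria(gaze_res2, corrupted, x2, y2, AOIS).valid
            if not before:
                assert not after


class TestIncludeParticipant:
    @pytest.mark.parametrize("n_valid,expected", [(50, True), (40, True),
                                                  (39, False), (0, False)])
    def test_seventy_percent_rule(self, n_valid, expected):
        flags = [ValidityFlags() for _ in range(n_valid)]
        flags += [ValidityFlags(c4=True) for _ in range(56 - n_valid)]
        included, summary = include_participant(flags)
        assert included is expected
        assert summary["n_valid"] == n_valid
        assert summary["n_trials"] == 56


class TestAssembleTrialTable:
    def _inputs(self, n_infants=2, n_trials=56, invalid=()):
        rows, frows = [], []
        for i in range(n_infants):
            iid = f"p{i}"
            for t in range(1, n_trials + 1):
                rows.append({"infant_id": iid, "trial_index": t,
                             "first_aoi": "face" if t % 2 else "manmade",
                             "order_in_pair": "first" if t % 2 else "second",
                             "dilation_mm": 0.1, "latency_s": 0.4})
                valid = (iid, t) not in invalid
                frows.append({"infant_id": iid, "trial_index": t,
                              "valid": valid})
        participants = pd.DataFrame(
            [{"infant_id": f"p{i}", "age_months": 5 if i % 2 else 10,
              "sex": "f"} for i in range(n_infants)])
        return pd.DataFrame(rows), pd.DataFrame(frows), participants

    def test_all_valid_gives_full_table(self):
        feats, flags, parts = self._inputs()
        table = assemble_trial_table(feats, flags, parts)
        assert len(table) == 112
        assert set(table["first_look_face"].unique()) == {0, 1}
        assert (table.loc[table["first_aoi"] == "face",
                          "first_look_face"] == 1).all()

    def test_row_count_matches_valid_tally(self):
        invalid = {("p0", 3), ("p0", 10), ("p1", 56)}
        feats, flags, parts = self._inputs(invalid=invalid)
        table = assemble_trial_table(feats, flags, parts)
        assert len(table) == 112 - len(invalid)
        assert table["n_valid_trials"].min() == 54

    def test_below_threshold_participant_dropped(self):
        invalid = {("p0", t) for t in range(1, 19)}   # 38/56 valid = 0.679
        feats, flags, parts = self._inputs(invalid=invalid)
        table = assemble_trial_table(feats, flags, parts)
        assert set(table["infant_id"]) == {"p1"}

    def test_id_mismatch_raises(self):
        feats, flags, parts = self._inputs()
        with pytest.raises(ValueError, match="missing infants"):
            assemble_trial_table(feats, flags, parts[parts.infant_id == "p0"])

    def test_global_standardization(self):
        feats, flags, parts = self._inputs()
        feats["dilation_mm"] = np.random.default_rng(0).normal(0.1, 0.2,
                                                               len(feats))
        table = assemble_trial_table(feats, flags, parts, standardize="global")
        assert table["dilation_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table["dilation_z"].std() == pytest.approx(1.0, rel=1e-9)


def test_zero_corruption_cohort_has_no_rejections(clean_params):
    from popgaze.pipeline import analyze_simulated_cohort
    table, summary = analyze_simulated_cohort(clean_params, seed=2)
    assert summary["n_valid"] == summary["n_trials"] == 112
    assert len(table) == 112
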