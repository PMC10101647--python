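"""Branch tracking, the persistence rule, events, rates and windows."""

import itertools

import numpy as np
import pandas as pd
import pytest

import arbordyn as ad
from arbordyn.dynamics import BRANCH_TABLE_COLUMNS
from arbordyn.errors import InconsistencyError, ScheduleError, UndefinedStatisticError
from arbordyn.simulate import GrowthSimConfig, make_y_tree, simulate_series


def make_series(rows, n_timepoints=7, schedule=None):
    """Minimal series: static Y arbors + a hand-written branch table."""
    schedule = schedule or ad.EpochSchedule.das(20.0, 20.0, 20.0)
    times = [10.0 * k for k in range(n_timepoints)]
    table = pd.DataFrame(rows, columns=BRANCH_TABLE_COLUMNS)
    return ad.AxonTimeSeries(
        "test", [make_y_tree() for _ in times], times, schedule, table
    )


def row(t, bid, length, bp=(1, 0, 0), tp=(2, 0, 0)):
    return [t, bid, length, *bp, *tp]


class TestTrackBranches:
    def test_persistent_branch_has_no_birth_or_death(self):
        series = make_series([row(t, 1, 4.0) for t in range(7)])
        (tr,) = ad.track_branches(series)
        assert tr.birth_interval is None and tr.death_interval is None
        assert tr.included and tr.max_length == 4.0

    def test_short_branch_excluded_by_persistence_rule(self):
        series = make_series([row(t, 1, 1.2) for t in range(3, 6)])
        (tr,) = ad.track_branches(series)
        assert tr.birth_interval == 3 and tr.death_interval == 6
        assert not tr.included

    def test_exactly_threshold_included(self):
        series = make_series([row(2, 1, 1.5)])
        assert ad.track_branches(series)[0].included

    def test_duplicate_rows_rejected(self):
        series = make_series([row(1, 7, 2.0), row(1, 7, 2.5)])
        with pytest.raises(InconsistencyError, match="branch 7"):
            ad.track_branches(series)


class TestDetectEvents:
    def test_birth_in_async_epoch(self):
        # schedule: dark (0,20], async (20,40], sync (40,60]
        series = make_series([row(t, 1, 3.0) for t in range(3, 7)])
        tracks = ad.track_branches(series)
        events = ad.detect_events(tracks, series.schedule, series.times_min)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "addition" and ev.epoch == "async"
        assert ev.interval_index == 3

    def test_single_timepoint_branch_is_transient_pair(self):
        series = make_series([row(3, 1, 2.0)])
        tracks = ad.track_branches(series)
        events = ad.detect_events(tracks, series.schedule, series.times_min)
        assert [e.kind for e in events] == ["addition", "elimination"]
        assert events[0].interval_index == 3
        assert events[1].interval_index == 4
        assert ad.classify_fate(tracks[0], (1, 6)) == "transient"

    def test_event_coordinates_come_from_event_timepoint(self):
        rows = [row(2, 1, 2.0, bp=(1, 1, 1), tp=(9, 9, 9)),
                row(3, 1, 2.5, bp=(1, 1, 1), tp=(7, 7, 7))]
        series = make_series(rows)
        events = ad.detect_events(
            ad.track_branches(series), series.schedule, series.times_min
        )
        add = next(e for e in events if e.kind == "addition")
        elim = next(e for e in events if e.kind == "elimination")
        assert add.coords == (1, 1, 1)  # branch point at birth time point
        assert elim.coords == (7, 7, 7)  # terminal point at last presence

    def test_event_outside_schedule_raises_when_strict(self):
        series = make_series([row(t, 1, 3.0) for t in range(5, 7)],
                             schedule=ad.EpochSchedule.das(10.0, 10.0, 10.0))
        tracks = ad.track_branches(series)
        with pytest.raises(ScheduleError):
            ad.detect_events(tracks, series.schedule, series.times_min)
        assert ad.detect_events(tracks, series.schedule, series.times_min,
                                strict=False) == []


class TestClassifyFate:
    def test_enumerated_truth_table(self):
        window = (2, 4)
        for birth, death in itertools.product([None, 1, 3, 5], repeat=2):
            if birth is not None and death is not None and death < birth:
                continue
            tr = ad.BranchTrack(1, 0, 0, birth, death, 2.0, {}, {}, True)
            got = ad.classify_fate(tr, window)
            b_in = birth is not None and 2 <= birth <= 4
            d_in = death is not None and 2 <= death <= 4
            expected = (
                "transient" if b_in and d_in
                else "added" if b_in
                else "lost" if d_in
                else "stable"
            )
            assert got == expected, (birth, death)


def _events(counts_by_interval, kind="addition", schedule=None, times=None):
    schedule = schedule or ad.EpochSchedule.das()
    times = times or [10.0 * k for k in range(int(schedule.end_min / 10) + 1)]
    evs = []
    bid = 1
    for ival, n in counts_by_interval.items():
        for _ in range(n):
            epoch = schedule.epoch_of(times[ival])
            evs.append(ad.RemodelingEvent(kind, (0, 0, 0), ival, epoch, bid))
            bid += 1
    return evs, schedule, times


class TestRateSeries:
    def test_darkness_normalization_arithmetic(self):
        counts = {i: 2 for i in range(1, 7)}  # darkness: 2 per interval
        counts[7] = 4  # async interval
        evs, schedule, times = _events(counts)
        rates = ad.rate_series(evs, schedule, times)
        assert rates.normalized["addition"][6] == pytest.approx(2.0)
        dark = [rates.normalized["addition"][i] for i in range(6)]
        assert np.mean(dark) == pytest.approx(1.0)

    def test_zero_darkness_flagged_not_divided(self):
        evs, schedule, times = _events({8: 3})
        rates = ad.rate_series(evs, schedule, times)
        assert not rates.normalization_defined["addition"]
        assert rates.normalized["addition"] is None
        with pytest.raises(UndefinedStatisticError):
            rates.twenty_min_bins("addition")

    def test_twenty_min_bins_average_pairs(self):
        counts = {i: 1 for i in range(1, 7)}
        counts[7], counts[8] = 2, 4
        evs, schedule, times = _events(counts)
        rates = ad.rate_series(evs, schedule, times)
        bins = rates.twenty_min_bins("addition")
        b = bins[bins["bin_start_min"] == 60.0]["rate"].iloc[0]
        assert b == pytest.approx(3.0)  # mean of normalized 2 and 4

    def test_darkness_mean_is_one_on_simulation(self):
        series, _ = simulate_series(GrowthSimConfig(seed=17))
        al = series.align_to_first()
        evs = ad.detect_events(ad.track_branches(al), al.schedule, al.times_min)
        rates = ad.rate_series(evs, al.schedule, al.times_min)
        for kind in ("addition", "elimination"):
            if rates.normalization_defined[kind]:
                dark = [
                    v for v, e in zip(rates.normalized[kind], rates.epoch)
                    if e == "dark"
                ]
                assert np.mean(dark) == pytest.approx(1.0)


class TestWindowMeans:
    def test_constant_rate_first_hour(self):
        counts = {i: 2 for i in range(1, 7)}
        for i in range(7, 13):  # first hour of async: normalized 1.5
            counts[i] = 3
        evs, schedule, times = _events(counts)
        wm = ad.window_means(ad.rate_series(evs, schedule, times), schedule)
        r = wm[(wm.epoch == "async") & (wm.kind == "addition")]
        assert r["mean_normalized_rate"].iloc[0] == pytest.approx(1.5)

    def test_async_sync_ratio(self):
        counts = {i: 2 for i in range(1, 7)}
        counts.update({i: 4 for i in range(7, 19)})  # async ×2
        counts.update({i: 2 for i in range(19, 31)})  # sync ×1
        evs, schedule, times = _events(counts)
        wm = ad.window_means(ad.rate_series(evs, schedule, times), schedule)
        ratio = wm[(wm.epoch == "async/sync") & (wm.kind == "addition")]
        assert ratio["mean_normalized_rate"].iloc[0] == pytest.approx(2.0)

    def test_90min_epoch_uses_last_40min_loss_window(self):
        schedule = ad.EpochSchedule.das(60.0, 90.0, 90.0)
        times = [10.0 * k for k in range(25)]
        evs, schedule, times = _events(
            {i: 1 for i in range(1, 25)}, kind="elimination",
            schedule=schedule, times=times,
        )
        wm = ad.window_means(ad.rate_series(evs, schedule, times), schedule)
        r = wm[(wm.epoch == "async") & (wm.kind == "elimination")].iloc[0]
        assert r["window_end_min"] - r["window_start_min"] == pytest.approx(40.0)
        # the window covers exactly the last 4 intervals of the 1.5 h epoch
        covered = [
            t for t in times
            if r["window_start_min"] < t <= r["window_end_min"]
        ]
        assert len(covered) == 4


class TestConservation:
    @pytest.mark.parametrize("seed", [51, 52, 53])
    def test_net_branch_change_equals_additions_minus_eliminations(self, seed):
        series, _ = simulate_series(
            GrowthSimConfig(seed=seed, missing_timepoint_prob=0.0)
        )
        al = series.align_to_first()
        tracks = [t for t in ad.track_branches(al) if t.included]
        evs = ad.detect_events(tracks, al.schedule, al.times_min)
        n_add = sum(e.kind == "addition" for e in evs)
        n_elim = sum(e.kind == "elimination" for e in evs)
        first = sum(t.present_at(0) for t in tracks)
        last = sum(t.present_at(al.n_timepoints - 1) for t in tracks)
        assert n_add - n_elim == last - first
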