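"""Tests for effort computation, suspect-tag filtering, monthly residency,
and observation-history assembly, on hand-built calendar-dated fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolhmm import preprocess as prep
from poolhmm.preprocess import (
    Calendar,
    build_histories,
    compute_effort,
    filter_suspect_tags,
    monthly_residency,
    residency_table,
)


def receivers_df(rows):
    return pd.DataFrame(
        rows,
        columns=["receiver_id", "pool", "river_km", "deploy_date", "retrieve_date",
                 "at_lock"],
    )


APRIL = Calendar(start="2013-04-01", n_months=1, mode="calendar")


class TestComputeEffort:
    def test_single_receiver_full_month(self):
        rec = receivers_df([("r1", 1, 5.0, "2013-04-01", "2013-05-01", False)])
        x = compute_effort(rec, APRIL, n_pools=2)
        assert x[0, 0] == pytest.approx(1.0)
        assert x[1, 0] == 0.0

    def test_half_month_second_receiver(self):
        # one full 30-day month + one covering 15 of 30 days -> 45/30 = 1.5
        rec = receivers_df(
            [
                ("r1", 1, 5.0, "2013-04-01", "2013-05-01", False),
                ("r2", 1, 8.0, "2013-04-01", "2013-04-16", False),
            ]
        )
        x = compute_effort(rec, APRIL, n_pools=1)
        assert x[0, 0] == pytest.approx(1.5)

    def test_half_open_intervals_do_not_double_count_handover(self):
        # swap on the 16th: [1st,16th) + [16th,1st) covers April exactly once
        rec = receivers_df(
            [
                ("r1", 1, 5.0, "2013-04-01", "2013-04-16", False),
                ("r2", 1, 5.0, "2013-04-16", "2013-05-01", False),
            ]
        )
        x = compute_effort(rec, APRIL, n_pools=1)
        assert x[0, 0] == pytest.approx(1.0)

    def test_calendar_month_lengths_used(self):
        cal = Calendar(start="2013-01-01", n_months=2, mode="calendar")
        rec = receivers_df([("r1", 1, 5.0, "2013-01-01", "2013-03-01", False)])
        x = compute_effort(rec, cal, n_pools=1)
        assert np.allclose(x[0], [1.0, 1.0])  # 31/31 and 28/28

    def test_out_of_range_clipped_with_warning(self, caplog):
        rec = receivers_df([("r1", 1, 5.0, "2013-03-15", "2013-06-01", False)])
        with caplog.at_level("WARNING"):
            x = compute_effort(rec, APRIL, n_pools=1)
        assert x[0, 0] == pytest.approx(1.0)
        assert "clipped" in caplog.text

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(split=st.integers(min_value=1, max_value=29))
    def test_invariant_under_interval_splitting(self, split):
        cal = Calendar(start="2013-04-01", n_months=1, mode="calendar")
        whole = receivers_df([("r1", 1, 5.0, "2013-04-01", "2013-05-01", False)])
        mid = pd.Timestamp("2013-04-01") + pd.Timedelta(days=split)
        parts = receivers_df(
            [
                ("r1", 1, 5.0, "2013-04-01", str(mid.date()), False),
                ("r1", 1, 5.0, str(mid.date()), "2013-05-01", False),
            ]
        )
        assert compute_effort(whole, cal, 1)[0, 0] == pytest.approx(
            compute_effort(parts, cal, 1)[0, 0]
        )


RECEIVERS = receivers_df(
    [
        ("a1", 1, 5.0, "2013-01-01", "2014-01-01", False),
        ("a2", 1, 5.3, "2013-01-01", "2014-01-01", False),  # 300 m from a1
        ("a3", 1, 15.0, "2013-01-01", "2014-01-01", False),  # 10 km from a1
        ("b1", 2, 25.0, "2013-01-01", "2014-01-01", False),
        ("lock1", 2, 20.0, "2013-01-01", "2014-01-01", True),
    ]
)

TAG = pd.DataFrame(
    [
        {
            "fish_id": "f1",
            "species": "silver",
            "tag_code": "t1",
            "release_date": "2013-01-05",
            "release_pool": 1,
            "expire_date": "2013-12-01",
        }
    ]
)


def det(times, receiver="a1", code="t1"):
    return pd.DataFrame(
        {
            "tag_code": code,
            "receiver_id": receiver if isinstance(receiver, list) else
            [receiver] * len(times),
            "timestamp": pd.to_datetime(times),
        }
    )


class TestFilterSuspectTags:
    def test_only_first30_detections_removed(self):
        d = det(["2013-01-08", "2013-01-20", "2013-02-02"])  # days 3, 15, 28
        rep = filter_suspect_tags(d, TAG, RECEIVERS)
        assert rep.loc[0, "reason"] == "first30"

    def test_continuous_single_receiver_release_pool_removed(self):
        times = pd.date_range("2013-02-01", periods=40, freq="2D")
        rep = filter_suspect_tags(det(times), TAG, RECEIVERS)
        assert rep.loc[0, "reason"] == "stationary"

    def test_proximal_receiver_pair_counts_as_stationary(self):
        # alternating a1/a2 (300 m apart): continuous proximal event +
        # max distance < 1,000 m -> two conditions met even though the fish
        # was tagged elsewhere (condition 3 false)
        tag2 = TAG.assign(release_pool=2)
        times = pd.date_range("2013-02-01", periods=40, freq="2D")
        recs = ["a1", "a2"] * 20
        rep = filter_suspect_tags(det(list(times), receiver=recs), tag2, RECEIVERS)
        assert rep.loc[0, "reason"] == "stationary"

    def test_multi_pool_long_span_kept(self):
        d = pd.concat(
            [
                det(["2013-02-01", "2013-03-01"], receiver="a1"),
                det(["2013-06-01", "2013-07-01"], receiver="b1"),
            ]
        )
        rep = filter_suspect_tags(d, TAG, RECEIVERS)
        assert rep.loc[0, "reason"] == "kept"

    def test_never_detected_is_kept(self):
        rep = filter_suspect_tags(det([]), TAG, RECEIVERS)
        assert rep.loc[0, "reason"] == "kept"
        assert rep.loc[0, "n_detections"] == 0

    def test_single_late_ping_kept(self):
        # one lone detection is neither "continuously detected" nor a
        # measurable receiver spread: only the release-pool condition holds
        rep = filter_suspect_tags(det(["2013-05-10"]), TAG, RECEIVERS)
        assert rep.loc[0, "reason"] == "kept"

    def test_distant_receivers_break_stationary(self):
        # a1 and a3 are 10 km apart: continuous event fails (not proximal),
        # distance fails; only release-pool-only holds -> kept
        times = pd.date_range("2013-02-01", periods=40, freq="2D")
        recs = ["a1", "a3"] * 20
        rep = filter_suspect_tags(det(list(times), receiver=recs), TAG, RECEIVERS)
        assert rep.loc[0, "reason"] == "kept"


class TestMonthlyResidency:
    def test_majority_of_detection_days(self):
        d = pd.concat(
            [
                det([f"2013-03-{day:02d}" for day in range(1, 11)], receiver="a1"),
                det([f"2013-03-{day:02d}" for day in range(20, 25)], receiver="b1"),
            ]
        )
        assert monthly_residency(d, RECEIVERS) == 1

    def test_tie_broken_by_event_count(self):
        days_a = [f"2013-03-{d:02d} 0{h}:00" for d in (1, 2, 3, 4, 5) for h in range(8)]
        days_b = [f"2013-03-{d:02d} 01:00" for d in (10, 11, 12, 13, 14)]
        d = pd.concat([det(days_a, receiver="a1"), det(days_b, receiver="b1")])
        assert monthly_residency(d, RECEIVERS) == 1  # 40 vs 5 events on 5 days each

    def test_double_tie_prefers_previous_pool(self):
        d = pd.concat(
            [det(["2013-03-01"], receiver="a1"), det(["2013-03-02"], receiver="b1")]
        )
        assert monthly_residency(d, RECEIVERS, prev_pool=2) == 2
        assert monthly_residency(d, RECEIVERS, prev_pool=None) == 1  # lowest index

    def test_lock_receivers_excluded(self):
        d = det(["2013-03-01", "2013-03-02"], receiver="lock1")
        assert monthly_residency(d, RECEIVERS) is None

    def test_invariant_to_record_order(self, rng):
        d = pd.concat(
            [
                det([f"2013-03-{day:02d}" for day in range(1, 9)], receiver="a1"),
                det([f"2013-03-{day:02d}" for day in range(5, 12)], receiver="b1"),
            ]
        ).reset_index(drop=True)
        expected = monthly_residency(d, RECEIVERS)
        for _ in range(5):
            shuffled = d.sample(frac=1.0, random_state=int(rng.integers(1 << 31)))
            assert monthly_residency(shuffled, RECEIVERS) == expected


class TestBuildHistories:
    CAL = Calendar(start="2013-01-01", n_months=8, mode="calendar")

    def test_direct_construction(self):
        # released month 0 pool 2, detected months 0-2 in pool 2, expires month 4
        tags = pd.DataFrame(
            [
                {
                    "fish_id": "f1",
                    "tag_code": "t1",
                    "release_date": "2013-01-05",
                    "release_pool": 2,
                    "expire_date": "2013-05-10",
                }
            ]
        )
        res = pd.DataFrame(
            {"fish_id": "f1", "month": [0, 1, 2], "pool": [2, 2, 2]}
        )
        (h,) = build_histories(tags, res, self.CAL, n_pools=6)
        # symbols: pool2 -> 1, not-detected -> 6, expired -> 7
        assert list(h.obs) == [1, 1, 1, 6, 7, 7, 7, 7]
        assert h.release_month == 0 and h.expire_month == 4

    def test_never_redetected(self):
        tags = pd.DataFrame(
            [
                {
                    "fish_id": "f1",
                    "tag_code": "t1",
                    "release_date": "2013-02-01",
                    "release_pool": 4,
                    "expire_date": "2013-07-15",
                }
            ]
        )
        res = pd.DataFrame({"fish_id": ["f1"], "month": [1], "pool": [4]})
        (h,) = build_histories(tags, res, self.CAL, n_pools=6)
        assert list(h.obs) == [3, 6, 6, 6, 6, 7, 7]

    def test_residency_before_release_rejected(self):
        tags = pd.DataFrame(
            [
                {
                    "fish_id": "f1",
                    "tag_code": "t1",
                    "release_date": "2013-03-01",
                    "release_pool": 1,
                    "expire_date": "2014-01-01",
                }
            ]
        )
        res = pd.DataFrame({"fish_id": ["f1"], "month": [0], "pool": [1]})
        with pytest.raises(ValueError, match="precedes release"):
            build_histories(tags, res, self.CAL, n_pools=6)

    def test_detections_after_expiration_dropped(self):
        tags = pd.DataFrame(
            [
                {
                    "fish_id": "f1",
                    "tag_code": "t1",
                    "release_date": "2013-01-05",
                    "release_pool": 1,
                    "expire_date": "2013-04-10",
                }
            ]
        )
        d = det(["2013-02-10", "2013-05-20"])  # second is past expiration
        res = residency_table(d, tags, RECEIVERS, self.CAL)
        months = set(res["month"])
        assert months == {0, 1}  # release month + February; May dropped
        (h,) = build_histories(tags, res, self.CAL, n_pools=6)
        assert list(h.obs) == [0, 0, 6, 7, 7, 7, 7, 7]

    def test_history_spans_release_to_calendar_end(self, default_preprocessed):
        cal_months = 36
        for h in default_preprocessed.histories:
            assert h.release_month + len(h.obs) == cal_months
            if h.expire_month is not None:
                k = h.expire_month - h.release_month
                assert np.all(h.obs[k:] == 7)
                assert np.all(h.obs[1:k] != 7)


class TestRoundTrips:
    def test_histories_frame_round_trip(self, default_preprocessed):
        df = prep.histories_to_frame(default_preprocessed.histories, 6)
        packed = prep.frame_to_packed(df, 36, 6)
        assert np.array_equal(packed.obs, default_preprocessed.packed.obs)
        assert np.array_equal(
            packed.release_month, default_preprocessed.packed.release_month
        )

    def test_effort_frame_round_trip(self, default_preprocessed):
        x = default_preprocessed.effort
        back = prep.frame_to_effort(prep.effort_to_frame(x))
        assert np.allclose(x, back)
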