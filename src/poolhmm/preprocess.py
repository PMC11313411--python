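"""Turn raw telemetry streams into model-ready inputs.

Three delimited-text streams drive everything downstream:

* ``receivers``:  receiver_id, pool, river_km, deploy_date, retrieve_date,
  at_lock — one row per continuous deployment interval.
* ``tags``:       fish_id, species, tag_code, release_date, release_pool,
  expire_date — one row per tagged fish.
* ``detections``: tag_code, receiver_id, timestamp — one row per decoded
  detection.

This module computes the monthly receiver-effort covariate (mean receivers
deployed per day, per pool per month), removes fish suspected to have died or
shed their tag shortly after release, reduces detections to a monthly pool
residency, and assembles per-fish monthly observation sequences anchored at
the release month and the projected battery-expiration month.

Months can be calendar months ("calendar" mode) or fixed 30-day blocks from
the calendar start ("block30" mode, used by the synthetic generator where the
monthly model is indifferent to day counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MonthlyHistory, PackedHistories

__all__ = [
    "Calendar",
    "compute_effort",
    "effort_to_frame",
    "frame_to_effort",
    "filter_suspect_tags",
    "monthly_residency",
    "residency_table",
    "build_histories",
    "histories_to_frame",
    "frame_to_packed",
    "preprocess",
    "PreprocessResult",
]

log = logging.getLogger(__name__)

REASON_KEPT = "kept"
REASON_FIRST30 = "first30"
REASON_STATIONARY = "stationary"


@dataclass(frozen=True)
class Calendar:
    """Maps timestamps to 0-based month indices.

    ``mode="calendar"`` uses real calendar months; ``mode="block30"`` uses
    consecutive 30-day blocks starting at ``start`` (midnight).  ``start``
    should be the first day of a month in calendar mode.
    """

    start: pd.Timestamp
    n_months: int
    mode: str = "calendar"

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start).normalize())
        if self.mode not in ("calendar", "block30"):
            raise ValueError(f"unknown calendar mode {self.mode!r}")

    def month_of(self, timestamps) -> np.ndarray:
        ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
        if self.mode == "block30":
            days = (ts - self.start) // pd.Timedelta(days=1)
            return np.asarray(days // 30, dtype=int)
        return np.asarray(
            (ts.year - self.start.year) * 12 + ts.month - self.start.month, dtype=int
        )

    def month_start(self, m: int) -> pd.Timestamp:
        if self.mode == "block30":
            return self.start + pd.Timedelta(days=30 * m)
        return self.start + pd.DateOffset(months=m)

    def days_in_month(self, m: int) -> int:
        return int(
            (self.month_start(m + 1) - self.month_start(m)) // pd.Timedelta(days=1)
        )

    @property
    def end(self) -> pd.Timestamp:
        return self.month_start(self.n_months)


def validate_deployments(receivers: pd.DataFrame) -> None:
    """Reject malformed or overlapping deployment intervals per receiver."""
    dep = pd.to_datetime(receivers["deploy_date"])
    ret = pd.to_datetime(receivers["retrieve_date"])
    bad = dep > ret
    if bad.any():
        raise ValueError(
            f"deploy after retrieve for receivers: "
            f"{sorted(receivers.loc[bad, 'receiver_id'].unique())}"
        )
    df = receivers.assign(_dep=dep, _ret=ret).sort_values(["receiver_id", "_dep"])
    for rid, grp in df.groupby("receiver_id", sort=False):
        prev_end = None
        for _, row in grp.iterrows():
            if prev_end is not None and row["_dep"] < prev_end:
                raise ValueError(
                    f"overlapping deployment intervals for receiver {rid}"
                )
            prev_end = row["_ret"]


def compute_effort(
    receivers: pd.DataFrame, calendar: Calendar, n_pools: int
) -> np.ndarray:
    """Mean receivers deployed per day: array x[pool, month] (0-based).

    Deployment intervals are half-open [deploy, retrieve) in whole days, so a
    receiver swapped out on the day another is dropped in is not counted
    twice.  Intervals extending outside the calendar range are clipped (with
    a warning); pool-months with no overlapping deployments get exactly 0.
    """
    validate_deployments(receivers)
    x = np.zeros((n_pools, calendar.n_months))
    cal_start, cal_end = calendar.start, calendar.end
    clipped = 0
    for _, row in receivers.iterrows():
        dep = pd.Timestamp(row["deploy_date"]).normalize()
        ret = pd.Timestamp(row["retrieve_date"]).normalize()
        if dep < cal_start or ret > cal_end:
            clipped += 1
        dep, ret = max(dep, cal_start), min(ret, cal_end)
        if ret <= dep:
            continue
        pool = int(row["pool"]) - 1
        if not (0 <= pool < n_pools):
            raise ValueError(f"pool {row['pool']} outside 1..{n_pools}")
        m0 = int(calendar.month_of([dep])[0])
        m1 = int(calendar.month_of([ret - pd.Timedelta(days=1)])[0])
        for m in range(m0, m1 + 1):
            lo = max(dep, calendar.month_start(m))
            hi = min(ret, calendar.month_start(m + 1))
            days = (hi - lo) // pd.Timedelta(days=1)
            if days > 0:
                x[pool, m] += int(days) / calendar.days_in_month(m)
    if clipped:
        log.warning("%d deployment intervals clipped to the calendar range", clipped)
    return x


def effort_to_frame(x: np.ndarray) -> pd.DataFrame:
    """Long-format effort table with 1-based pool and month indices."""
    P, T = x.shape
    pools, months = np.meshgrid(np.arange(1, P + 1), np.arange(1, T + 1), indexing="ij")
    return pd.DataFrame(
        {"pool": pools.ravel(), "month": months.ravel(), "x": x.ravel()}
    )


def frame_to_effort(df: pd.DataFrame) -> np.ndarray:
    P = int(df["pool"].max())
    T = int(df["month"].max())
    x = np.zeros((P, T))
    x[df["pool"].to_numpy() - 1, df["month"].to_numpy() - 1] = df["x"].to_numpy()
    return x


# ---------------------------------------------------------------------------
# suspect-tag filtering
# ---------------------------------------------------------------------------


def _continuous_single_event(
    det: pd.DataFrame, proximity_m: float, max_gap_days: float
) -> bool:
    """Whole history = one continuous event on one receiver / a proximal set.

    "Continuously detected" requires at least two detections; consecutive
    detections may be at most ``max_gap_days`` apart; and all receivers
    involved must lie within ``proximity_m`` of each other (river distance),
    which is trivially true for a single receiver.
    """
    if len(det) < 2:
        return False
    km = det["river_km"].to_numpy(dtype=float)
    if (km.max() - km.min()) * 1000.0 > proximity_m:
        return False
    ts = det["timestamp"].sort_values().to_numpy()
    gaps = np.diff(ts) / np.timedelta64(1, "D")
    return bool((gaps <= max_gap_days).all())


def _stationary_conditions(
    det: pd.DataFrame,
    release_pool: int,
    proximity_m: float,
    max_gap_days: float,
) -> tuple[bool, bool, bool]:
    """The three stationary-tag conditions, in fixed evaluation order.

    1. the totality of detections is a single continuous event on one
       receiver or on simultaneously-heard receivers in proximity;
    2. the maximum river distance between all receivers with detections
       (at least two distinct receivers) is under ``proximity_m``;
    3. the only pool of detection is the release pool.

    Condition 2 is defined over receiver pairs: a single-receiver history is
    the business of condition 1, and letting one receiver satisfy both would
    make the two-of-three rule vacuous for any single-receiver event.
    """
    c1 = _continuous_single_event(det, proximity_m, max_gap_days)
    km = det["river_km"].to_numpy(dtype=float)
    n_receivers = det["receiver_id"].nunique()
    c2 = bool(n_receivers >= 2 and (km.max() - km.min()) * 1000.0 < proximity_m)
    pools = set(det["pool"].astype(int))
    c3 = bool(pools == {int(release_pool)})
    return bool(c1), c2, c3


def filter_suspect_tags(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    receivers: pd.DataFrame,
    first_days: int = 30,
    proximity_m: float = 1000.0,
    max_gap_days: float = 7.0,
) -> pd.DataFrame:
    """Classify each fish as kept / first30 / stationary.

    A fish is removed if its only detections fall within ``first_days`` of
    release ("first30": likely died or shed the tag right after tagging), or
    if the tag kept transmitting but was stationary (at least two of the
    three conditions in :func:`_stationary_conditions`).  Fish with zero
    detections are retained — never being detected is not evidence of a
    suspect tag.  Lock receivers are excluded before any rule is evaluated.

    Returns a frame (fish_id, reason, n_detections).
    """
    rec = receivers.drop_duplicates("receiver_id")[
        ["receiver_id", "pool", "river_km", "at_lock"]
    ]
    det = detections.merge(
        tags[["fish_id", "tag_code", "release_date", "release_pool"]],
        on="tag_code",
        how="inner",
    ).merge(rec, on="receiver_id", how="left")
    if det["pool"].isna().any():
        missing = det.loc[det["pool"].isna(), "receiver_id"].unique()
        raise ValueError(f"detections on unknown receivers: {sorted(missing)}")
    det = det[~det["at_lock"].astype(bool)].copy()
    det["timestamp"] = pd.to_datetime(det["timestamp"])
    det["release_date"] = pd.to_datetime(det["release_date"])

    rows = []
    groups = dict(iter(det.groupby("fish_id", sort=False)))
    for _, tag_row in tags.iterrows():
        fid = tag_row["fish_id"]
        d = groups.get(fid)
        if d is None or len(d) == 0:
            rows.append({"fish_id": fid, "reason": REASON_KEPT, "n_detections": 0})
            continue
        age_days = (d["timestamp"] - d["release_date"]).dt.total_seconds() / 86400.0
        if (age_days <= first_days).all():
            reason = REASON_FIRST30
        else:
            c1, c2, c3 = _stationary_conditions(
                d, int(tag_row["release_pool"]), proximity_m, max_gap_days
            )
            n_met = int(c1) + int(c2) + int(c3)
            reason = REASON_STATIONARY if n_met >= 2 else REASON_KEPT
        rows.append({"fish_id": fid, "reason": reason, "n_detections": len(d)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# monthly residency and observation histories
# ---------------------------------------------------------------------------


def monthly_residency(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    prev_pool: int | None = None,
) -> int | None:
    """Residency pool for one fish-month, or None if no usable detections.

    The residence pool is the one with the most distinct detection-days; ties
    go to the pool with more detection events; a double tie goes to the
    previous month's residence pool if it is among the tied pools, else to
    the lowest pool index (logged).  Lock receivers are excluded before
    counting.
    """
    rec = receivers.drop_duplicates("receiver_id")[["receiver_id", "pool", "at_lock"]]
    det = detections.merge(rec, on="receiver_id", how="left")
    det = det[~det["at_lock"].astype(bool)]
    if len(det) == 0:
        return None
    det = det.assign(day=pd.to_datetime(det["timestamp"]).dt.normalize())
    per_pool = det.groupby("pool").agg(days=("day", "nunique"), n=("timestamp", "size"))
    best = per_pool[per_pool["days"] == per_pool["days"].max()]
    if len(best) > 1:
        best = best[best["n"] == best["n"].max()]
    if len(best) > 1:
        tied = sorted(int(p) for p in best.index)
        if prev_pool is not None and prev_pool in tied:
            log.debug("double tie resolved to previous pool %d", prev_pool)
            return prev_pool
        log.debug("double tie resolved to lowest pool %d", tied[0])
        return tied[0]
    return int(best.index[0])


def residency_table(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    receivers: pd.DataFrame,
    calendar: Calendar,
) -> pd.DataFrame:
    """Monthly residency for every fish: frame (fish_id, month, pool), 0-based
    months, 1-based pools.  Detections after a fish's projected expiration
    date or outside the calendar are dropped; the release month is asserted
    at the release pool regardless of detections.  Months are processed in
    order so the double-tie rule can see the previous month's pool.
    """
    det = detections.merge(
        tags[["fish_id", "tag_code", "expire_date"]], on="tag_code", how="inner"
    )
    det["timestamp"] = pd.to_datetime(det["timestamp"])
    n_before = len(det)
    det = det[det["timestamp"] < pd.to_datetime(det["expire_date"])]
    if len(det) < n_before:
        log.info("dropped %d detections after projected expiration", n_before - len(det))
    det = det[
        (det["timestamp"] >= calendar.start) & (det["timestamp"] < calendar.end)
    ].copy()
    det["month"] = calendar.month_of(det["timestamp"])

    release_month = dict(
        zip(tags["fish_id"], calendar.month_of(pd.to_datetime(tags["release_date"])))
    )
    release_pool = dict(zip(tags["fish_id"], tags["release_pool"].astype(int)))

    # lock receivers never count toward residency
    rec = receivers.drop_duplicates("receiver_id")[["receiver_id", "pool", "at_lock"]]
    det = det.merge(rec, on="receiver_id", how="left")
    det = det[~det["at_lock"].astype(bool)].copy()
    det["day"] = det["timestamp"].dt.normalize()
    # release-month detections are overridden by the asserted release pool
    rel = det["fish_id"].map(release_month)
    det = det[det["month"] > rel]

    counts = (
        det.groupby(["fish_id", "month", "pool"])
        .agg(days=("day", "nunique"), n=("timestamp", "size"))
        .reset_index()
    )
    # majority of detection-days, then most events, then (rare) double tie
    counts = counts.sort_values(
        ["fish_id", "month", "days", "n", "pool"],
        ascending=[True, True, False, False, True],
    )
    top = counts.drop_duplicates(["fish_id", "month"]).copy()
    tied = (
        counts.merge(
            top[["fish_id", "month", "days", "n"]],
            on=["fish_id", "month", "days", "n"],
        )
        .groupby(["fish_id", "month"])
        .size()
    )
    double_tied = set(tied[tied > 1].index)

    rows = [
        {"fish_id": fid, "month": int(release_month[fid]), "pool": release_pool[fid]}
        for fid in tags["fish_id"]
    ]
    for fid, d in top.groupby("fish_id", sort=False):
        prev = release_pool[fid]
        d = d.sort_values("month")
        tied_months = {m for (f, m) in double_tied if f == fid}
        if tied_months:
            # re-resolve this fish sequentially so the previous month's pool
            # can break double ties
            sub = counts[counts["fish_id"] == fid]
            for m in sorted(d["month"]):
                dm = sub[sub["month"] == m]
                best = dm[(dm["days"] == dm["days"].max())]
                best = best[best["n"] == best["n"].max()]
                pools = sorted(int(p) for p in best["pool"])
                if len(pools) > 1:
                    pool = prev if prev in pools else pools[0]
                    log.debug("double tie for %s month %d -> pool %d", fid, m, pool)
                else:
                    pool = pools[0]
                rows.append({"fish_id": fid, "month": int(m), "pool": pool})
                prev = pool
        else:
            for _, rr in d.iterrows():
                rows.append(
                    {"fish_id": fid, "month": int(rr["month"]), "pool": int(rr["pool"])}
                )
    return pd.DataFrame(rows).sort_values(["fish_id", "month"]).reset_index(drop=True)


def build_histories(
    tags: pd.DataFrame,
    residencies: pd.DataFrame,
    calendar: Calendar,
    n_pools: int,
) -> list[MonthlyHistory]:
    """Assemble per-fish monthly observation sequences.

    Observation for month t: detected-in-pool-k if a residency exists,
    battery-expired from the calendar month containing the projected
    expiration date onward, else not-detected.  The sequence starts at the
    release month (asserted at the release pool) and ends at the calendar
    end.  Residency records before the release month are rejected.
    """
    res_by_fish = dict(iter(residencies.groupby("fish_id", sort=False)))
    histories = []
    for _, row in tags.iterrows():
        fid = row["fish_id"]
        r = int(calendar.month_of([pd.to_datetime(row["release_date"])])[0])
        if r < 0 or r >= calendar.n_months:
            log.warning("fish %s released outside the calendar range; skipped", fid)
            continue
        e = int(calendar.month_of([pd.to_datetime(row["expire_date"])])[0])
        obs = np.full(calendar.n_months - r, n_pools, dtype=int)  # not-detected
        res = res_by_fish.get(fid)
        if res is not None:
            for _, rr in res.iterrows():
                m = int(rr["month"])
                if m < r:
                    raise ValueError(
                        f"fish {fid}: residency in month {m} precedes release month {r}"
                    )
                if m < calendar.n_months and m < e:
                    obs[m - r] = int(rr["pool"]) - 1
        obs[0] = int(row["release_pool"]) - 1  # asserted release observation
        if e < calendar.n_months:
            if e <= r:
                log.warning("fish %s expires in its release month", fid)
                obs[1:] = n_pools + 1
            else:
                obs[e - r :] = n_pools + 1
        histories.append(
            MonthlyHistory(
                fish_id=fid,
                release_month=r,
                release_pool=int(row["release_pool"]) - 1,
                obs=obs,
                expire_month=e if e < calendar.n_months else None,
            )
        )
    return histories


def histories_to_frame(histories: list[MonthlyHistory], n_pools: int) -> pd.DataFrame:
    """Long-format obs table (fish_id, month 1-based, obs symbol string)."""
    rows = []
    for h in histories:
        for k, o in enumerate(h.obs):
            if o < n_pools:
                sym = f"pool{o + 1}"
            elif o == n_pools:
                sym = "nd"
            else:
                sym = "exp"
            rows.append(
                {"fish_id": h.fish_id, "month": h.release_month + k + 1, "obs": sym}
            )
    return pd.DataFrame(rows)


def frame_to_packed(df: pd.DataFrame, n_months: int, n_pools: int) -> PackedHistories:
    """Rebuild packed histories from the long-format obs table."""

    def decode(sym: str) -> int:
        if sym.startswith("pool"):
            return int(sym[4:]) - 1
        return n_pools if sym == "nd" else n_pools + 1

    histories = []
    for fid, grp in df.groupby("fish_id", sort=False):
        grp = grp.sort_values("month")
        obs = np.array([decode(s) for s in grp["obs"]], dtype=int)
        r = int(grp["month"].iloc[0]) - 1
        histories.append(
            MonthlyHistory(
                fish_id=str(fid), release_month=r, release_pool=int(obs[0]), obs=obs
            )
        )
    return PackedHistories(histories, n_months, n_pools)


@dataclass
class PreprocessResult:
    effort: np.ndarray
    histories: list[MonthlyHistory]
    packed: PackedHistories
    filter_report: pd.DataFrame
    residencies: pd.DataFrame
    n_dropped_out_of_window: int


def preprocess(
    receivers: pd.DataFrame,
    tags: pd.DataFrame,
    detections: pd.DataFrame,
    calendar: Calendar,
    n_pools: int,
    first_days: int = 30,
    proximity_m: float = 1000.0,
    max_gap_days: float = 7.0,
) -> PreprocessResult:
    """Full preprocessing chain: validate, filter, reduce, assemble.

    Detections outside their receiver's deployment interval are logged and
    dropped before anything else (they indicate clock or join errors).
    """
    receivers = receivers.copy()
    if "at_lock" not in receivers:
        receivers["at_lock"] = False
    detections = detections.copy()
    detections["timestamp"] = pd.to_datetime(detections["timestamp"])

    dep = receivers.drop_duplicates("receiver_id").set_index("receiver_id")
    joined = detections.join(
        dep[["deploy_date", "retrieve_date"]], on="receiver_id", how="left"
    )
    in_window = (joined["timestamp"] >= pd.to_datetime(joined["deploy_date"])) & (
        joined["timestamp"] < pd.to_datetime(joined["retrieve_date"])
    )
    n_dropped = int((~in_window).sum())
    if n_dropped:
        log.warning(
            "dropped %d detections outside receiver deployment windows", n_dropped
        )
    detections = detections[in_window.to_numpy()]

    report = filter_suspect_tags(
        detections,
        tags,
        receivers,
        first_days=first_days,
        proximity_m=proximity_m,
        max_gap_days=max_gap_days,
    )
    kept_ids = set(report.loc[report["reason"] == REASON_KEPT, "fish_id"])
    tags_kept = tags[tags["fish_id"].isin(kept_ids)].reset_index(drop=True)
    log.info(
        "suspect-tag filter: %d kept, %d removed (%s)",
        len(tags_kept),
        len(tags) - len(tags_kept),
        report[report["reason"] != REASON_KEPT]["reason"].value_counts().to_dict(),
    )

    effort = compute_effort(receivers, calendar, n_pools)
    residencies = residency_table(detections, tags_kept, receivers, calendar)
    histories = build_histories(tags_kept, residencies, calendar, n_pools)
    packed = PackedHistories(histories, calendar.n_months, n_pools)
    return PreprocessResult(
        effort=effort,
        histories=histories,
        packed=packed,
        filter_report=report,
        residencies=residencies,
        n_dropped_out_of_window=n_dropped,
    )
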