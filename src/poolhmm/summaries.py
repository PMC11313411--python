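"""Descriptive movement and receiver-array performance summaries.

Covers the three table-style reductions of the study design: classifying
each fish's movement history as none / downstream-only / upstream-only /
both (on the full detection record or on the monthly residency sequence),
per-fish detection frequency and detection-period metrics, and reductions of
a destination-by-origin monthly movement-probability matrix (diagonal stay
probabilities, total upstream/downstream probability per origin pool, and
cross-pool means and ranges).

Pool index increases upstream: pool 1 is the most downstream pool.  In a
movement matrix ``m[i, j]`` (destination row i, origin column j), entries
above the diagonal (i < j) are therefore downstream movements and entries
below it are upstream movements.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "classify_movement",
    "movement_classes",
    "tabulate_movement_classes",
    "detection_frequency",
    "detection_period",
    "summarize_movement_matrix",
    "load_reference_matrix",
]

CLASSES = ("none", "downstream", "upstream", "both")


def classify_movement(pools) -> str:
    """Classify an ordered pool sequence (gaps already removed).

    ``none`` if the fish never changes pool (or the sequence is empty),
    ``downstream`` if every change decreases the pool index, ``upstream`` if
    every change increases it, ``both`` otherwise.
    """
    seq = [int(p) for p in pools]
    if len(seq) == 0:
        return "none"
    steps = np.diff(seq)
    down = bool((steps < 0).any())
    up = bool((steps > 0).any())
    if down and up:
        return "both"
    if down:
        return "downstream"
    if up:
        return "upstream"
    return "none"


def _pool_sequence_all_detections(det: pd.DataFrame) -> list[int]:
    d = det.sort_values("timestamp")
    return list(d["pool"].astype(int))


def movement_classes(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    receivers: pd.DataFrame,
    residencies: pd.DataFrame,
) -> pd.DataFrame:
    """Per-fish movement class on both bases: frame (fish_id, basis, class).

    The "all-detections" basis uses the time-ordered pool sequence of every
    non-lock detection (anchored at the release pool); the "monthly" basis
    uses the monthly residency sequence.  Both bases cover the same fish set:
    fish without detections are class "none".
    """
    rec = receivers.drop_duplicates("receiver_id")[["receiver_id", "pool", "at_lock"]]
    det = detections.merge(
        tags[["fish_id", "tag_code", "release_pool"]], on="tag_code", how="inner"
    ).merge(rec, on="receiver_id", how="left")
    det = det[~det["at_lock"].astype(bool)]
    rows = []
    det_by_fish = dict(iter(det.groupby("fish_id", sort=False)))
    res_by_fish = dict(iter(residencies.groupby("fish_id", sort=False)))
    for _, trow in tags.iterrows():
        fid = trow["fish_id"]
        rel = int(trow["release_pool"])
        d = det_by_fish.get(fid)
        seq = [rel] + (_pool_sequence_all_detections(d) if d is not None else [])
        rows.append(
            {"fish_id": fid, "basis": "all", "class": classify_movement(seq)}
        )
        r = res_by_fish.get(fid)
        mseq = (
            list(r.sort_values("month")["pool"].astype(int)) if r is not None else [rel]
        )
        rows.append(
            {"fish_id": fid, "basis": "monthly", "class": classify_movement(mseq)}
        )
    return pd.DataFrame(rows)


def tabulate_movement_classes(classes: pd.DataFrame, basis: str) -> pd.DataFrame:
    """Counts and percentages per movement class for one basis."""
    sub = classes[classes["basis"] == basis]
    n = len(sub)
    rows = []
    for cls in CLASSES:
        count = int((sub["class"] == cls).sum())
        rows.append(
            {
                "class": cls,
                "count": count,
                "percent": 100.0 * count / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def detection_frequency(detections: pd.DataFrame) -> int:
    """Number of distinct days with at least one detection for one fish."""
    if len(detections) == 0:
        return 0
    return int(pd.to_datetime(detections["timestamp"]).dt.normalize().nunique())


def detection_period(detections: pd.DataFrame, expire_date=None) -> float:
    """Days between first and last detection, last capped at tag expiration."""
    if len(detections) == 0:
        return 0.0
    ts = pd.to_datetime(detections["timestamp"])
    first, last = ts.min(), ts.max()
    if expire_date is not None:
        last = min(last, pd.Timestamp(expire_date))
    return max((last - first).total_seconds() / 86400.0, 0.0)


@dataclass
class MovementMatrixSummary:
    """Reductions of a 6x6 destination-by-origin movement matrix."""

    stay: np.ndarray  # diagonal, by origin pool
    total_down: np.ndarray  # NaN for the most downstream origin
    total_up: np.ndarray  # NaN for the most upstream origin
    mean_stay: float
    mean_down: float  # over origins that have a downstream pool
    mean_up: float  # over origins that have an upstream pool
    stay_range: tuple[float, float]
    down_range: tuple[float, float]
    up_range: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        P = len(self.stay)
        return pd.DataFrame(
            {
                "origin": np.arange(1, P + 1),
                "stay": self.stay,
                "total_down": self.total_down,
                "total_up": self.total_up,
            }
        )


def summarize_movement_matrix(m: np.ndarray) -> MovementMatrixSummary:
    """Stay/upstream/downstream reductions of a movement matrix.

    ``m[i, j]`` is the monthly probability of moving to pool i from pool j
    (destination rows, origin columns, pool index increasing upstream).  For
    each origin j: stay = m[j, j]; total downstream = sum of entries above
    the diagonal in column j; total upstream = sum below the diagonal.
    Cross-pool means average stay over all origins, total downstream over
    origins 2..P (those with a pool below them), and total upstream over
    origins 1..P-1.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != 6:
        raise ValueError(f"expected a 6x6 movement matrix, got {m.shape}")
    P = m.shape[0]
    stay = np.diag(m).astype(float)
    total_down = np.full(P, np.nan)
    total_up = np.full(P, np.nan)
    for j in range(P):
        if j > 0:
            total_down[j] = m[:j, j].sum()
        if j < P - 1:
            total_up[j] = m[j + 1 :, j].sum()
    down = total_down[1:]
    up = total_up[:-1]
    return MovementMatrixSummary(
        stay=stay,
        total_down=total_down,
        total_up=total_up,
        mean_stay=float(stay.mean()),
        mean_down=float(down.mean()),
        mean_up=float(up.mean()),
        stay_range=(float(stay.min()), float(stay.max())),
        down_range=(float(down.min()), float(down.max())),
        up_range=(float(up.min()), float(up.max())),
    )


def load_reference_matrix(species: str) -> np.ndarray:
    """Published posterior-mean movement matrix for one species.

    Reference estimates (silver or bighead carp) from the six-pool Illinois
    Waterway telemetry study that motivates this package; used to validate
    the matrix reductions, never as model input.
    """
    name = f"movement_{species}.csv"
    with resources.files("poolhmm.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, comment="#", index_col=0)
    return df.to_numpy(dtype=float)
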