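#!/usr/bin/env python
"""Descriptive movement summaries before any model fitting.

Classifies each retained fish's movements as none / downstream-only /
upstream-only / both, on the full detection record and again after the
monthly residency reduction — the monthly timestep typically collapses
within-month excursions, shrinking the "both directions" class.  Also
tabulates per-fish detection frequency (days with a detection) and
detection period (first-to-last span), the raw metrics of receiver-array
performance.  Tables land in results/summaries/.
"""

from pathlib import Path

import pandas as pd

from poolhmm.summaries import (
    detection_frequency,
    detection_period,
    movement_classes,
    tabulate_movement_classes,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "summaries"


def main() -> None:
    streams = ROOT / "streams"
    receivers = pd.read_csv(streams / "receivers.csv")
    tags = pd.read_csv(streams / "tags.csv")
    detections = pd.read_csv(streams / "detections.csv")
    report = pd.read_csv(ROOT / "prep" / "filter_report.csv")
    residencies = pd.read_csv(ROOT / "prep" / "residencies.csv")

    kept = set(report.loc[report["reason"] == "kept", "fish_id"])
    tags_kept = tags[tags["fish_id"].isin(kept)]

    classes = movement_classes(detections, tags_kept, receivers, residencies)
    OUT.mkdir(parents=True, exist_ok=True)
    tabs = []
    for basis in ("all", "monthly"):
        tab = tabulate_movement_classes(classes, basis).assign(basis=basis)
        tabs.append(tab)
    table = pd.concat(tabs, ignore_index=True)
    table.to_csv(OUT / "movement_classes.csv", index=False)
    print("movement classes (counts and % of retained fish):")
    print(table.to_string(index=False))

    det = detections.merge(tags_kept[["fish_id", "tag_code", "expire_date"]],
                           on="tag_code")
    rows = []
    for fid, d in det.groupby("fish_id"):
        rows.append(
            {
                "fish_id": fid,
                "detection_frequency_days": detection_frequency(d),
                "detection_period_days": detection_period(
                    d, d["expire_date"].iloc[0]
                ),
            }
        )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(OUT / "detection_metrics.csv", index=False)
    print(f"\ndetection frequency: median "
          f"{metrics['detection_frequency_days'].median():.0f} days; "
          f"detection period: median "
          f"{metrics['detection_period_days'].median():.0f} days "
          f"(n={len(metrics)} fish)")


if __name__ == "__main__":
    main()
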