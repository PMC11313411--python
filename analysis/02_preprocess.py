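#!/usr/bin/env python
"""Clean and reduce the raw telemetry streams.

Validates detections against receiver deployment windows, removes suspect
tags (fish only detected in their first 30 days, or stationary tags), and
reduces the remainder to monthly pool residencies, observation histories
and the receiver-effort covariate.  Outputs land in results/prep/.
"""

from pathlib import Path

import pandas as pd

from poolhmm import preprocess as prep
from poolhmm.synthetic import ScenarioConfig

ROOT = Path(__file__).resolve().parents[1] / "results"
STREAMS = ROOT / "streams"
OUT = ROOT / "prep"


def main() -> None:
    scenario = ScenarioConfig.from_yaml(STREAMS / "scenario.yaml")
    result = prep.preprocess(
        pd.read_csv(STREAMS / "receivers.csv"),
        pd.read_csv(STREAMS / "tags.csv"),
        pd.read_csv(STREAMS / "detections.csv"),
        scenario.calendar,
        scenario.n_pools,
    )
    OUT.mkdir(parents=True, exist_ok=True)
    prep.effort_to_frame(result.effort).to_csv(OUT / "effort.csv", index=False)
    prep.histories_to_frame(result.histories, scenario.n_pools).to_csv(
        OUT / "histories.csv", index=False
    )
    result.filter_report.to_csv(OUT / "filter_report.csv", index=False)
    result.residencies.to_csv(OUT / "residencies.csv", index=False)

    removed = result.filter_report[result.filter_report["reason"] != "kept"]
    truth = pd.read_csv(STREAMS / "artifacts.csv")
    planted = set(truth.loc[truth["kind"] != "mobile", "fish_id"])
    caught = planted & set(removed["fish_id"])
    print(f"removed {len(removed)} of {len(result.filter_report)} fish "
          f"({removed['reason'].value_counts().to_dict()})")
    print(f"planted artifacts caught: {len(caught)}/{len(planted)}")
    print(f"histories built: {len(result.histories)}; "
          f"mean effort {result.effort.mean():.2f} receivers/day")


if __name__ == "__main__":
    main()
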