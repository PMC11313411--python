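"""End-to-end pipeline: simulate -> preprocess -> fit -> report.

Stages communicate through plain CSV files so any stage can also be run
standalone from the command line.  Every run writes a manifest listing each
output file with its SHA-256 checksum; deterministic stages are byte-stable
under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import preprocess as prep
from . import synthetic
from .sampler import MCMCConfig, fit_mcmc, derive_outputs
from .summaries import movement_classes, tabulate_movement_classes

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one input source: either ``scenario`` (a synthetic scenario to
    simulate) or ``input_dir`` (a directory holding receivers.csv, tags.csv,
    detections.csv).  ``n_months``/``origin``/``calendar_mode`` describe the
    study calendar when reading real exports; for a scenario they come from
    the scenario itself.
    """

    out_dir: Path
    scenario: synthetic.ScenarioConfig | None = None
    input_dir: Path | None = None
    n_pools: int = 6
    n_months: int | None = None
    origin: str | None = None
    calendar_mode: str = "calendar"
    mcmc: MCMCConfig | None = None
    seed: int = 0
    with_artifacts: bool = True

    def validate(self) -> None:
        if (self.scenario is None) == (self.input_dir is None):
            raise ValueError(
                "provide exactly one input source: a scenario config or an "
                "input directory with the three raw streams"
            )
        if self.input_dir is not None and (
            self.n_months is None or self.origin is None
        ):
            raise ValueError("real inputs need the calendar: origin and n_months")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    manifest[str(path.name)] = _sha256(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    counts: dict[str, object] = {}

    # --- stage 1: obtain the three raw streams -----------------------------
    if config.scenario is not None:
        scenario = config.scenario
        data = synthetic.simulate_scenario(
            scenario, with_artifacts=config.with_artifacts
        )
        for name, p in synthetic.write_streams(data, out / "streams").items():
            manifest[name] = _sha256(Path(p))
        receivers, tags, detections = data.receivers, data.tags, data.detections
        calendar = scenario.calendar
        n_pools = scenario.n_pools
    else:
        indir = Path(config.input_dir)
        receivers = pd.read_csv(indir / "receivers.csv")
        tags = pd.read_csv(indir / "tags.csv")
        detections = pd.read_csv(indir / "detections.csv")
        calendar = prep.Calendar(
            start=pd.Timestamp(config.origin),
            n_months=int(config.n_months),
            mode=config.calendar_mode,
        )
        n_pools = config.n_pools
    counts["fish_tagged"] = int(len(tags))
    log.info("stage simulate/load done: %d fish, %d detections", len(tags), len(detections))

    # --- stage 2: preprocess ------------------------------------------------
    try:
        result = prep.preprocess(receivers, tags, detections, calendar, n_pools)
    except Exception as exc:  # pragma: no cover - stage labelling
        raise RuntimeError(f"preprocess stage failed: {exc}") from exc
    removed = result.filter_report[result.filter_report["reason"] != "kept"]
    counts["fish_removed"] = removed["reason"].value_counts().to_dict()
    counts["histories_built"] = len(result.histories)
    _write(prep.effort_to_frame(result.effort), out / "effort.csv", manifest)
    _write(
        prep.histories_to_frame(result.histories, n_pools),
        out / "histories.csv",
        manifest,
    )
    _write(result.filter_report, out / "filter_report.csv", manifest)

    classes = movement_classes(detections, tags, receivers, result.residencies)
    kept = set(
        result.filter_report.loc[result.filter_report["reason"] == "kept", "fish_id"]
    )
    classes = classes[classes["fish_id"].isin(kept)]
    tab = pd.concat(
        [
            tabulate_movement_classes(classes, basis).assign(basis=basis)
            for basis in ("all", "monthly")
        ],
        ignore_index=True,
    )
    _write(tab, out / "movement_classes.csv", manifest)

    # --- stage 3: fit -------------------------------------------------------
    mcmc = config.mcmc or MCMCConfig(seed=config.seed)
    try:
        sample = fit_mcmc(result.packed, result.effort, mcmc)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"fit stage failed: {exc}") from exc
    summary = sample.summary().reset_index()
    counts["max_top_level_rhat"] = float(sample.max_top_level_rhat())
    _write(summary, out / "params_summary.csv", manifest)
    draws_long = posterior_to_frame(sample)
    _write(draws_long, out / "draws.csv", manifest)

    # --- stage 4: report ----------------------------------------------------
    derived = derive_outputs(sample, result.effort)
    _write(
        movement_matrix_table(derived["movement_matrix"]),
        out / "movement_matrix.csv",
        manifest,
    )
    _write(derived["detection_curves"], out / "detection_curves.csv", manifest)
    _write(derived["detection_series"], out / "detection_series.csv", manifest)
    render_figures(result.effort, derived, out / "figures")
    for p in sorted((out / "figures").glob("*.svg")):
        manifest[p.name] = _sha256(p)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "counts.json").write_text(json.dumps(counts, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", json.dumps(counts))
    return manifest


def posterior_to_frame(sample) -> pd.DataFrame:
    """Draws in plain columnar format (parameter, chain, iteration, value)."""
    frames = []
    for name in sample.param_names:
        arr = sample.draws[name]
        C, D = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "parameter": name,
                    "chain": np.repeat(np.arange(C), D),
                    "iteration": np.tile(np.arange(D), C),
                    "value": arr.reshape(-1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def movement_matrix_table(m: np.ndarray) -> pd.DataFrame:
    """Movement matrix with Total downstream / Total upstream rows appended."""
    from .summaries import summarize_movement_matrix

    P = m.shape[0]
    cols = [f"pool{j + 1}" for j in range(P)]
    df = pd.DataFrame(m, columns=cols)
    df.insert(0, "destination", [f"pool{i + 1}" for i in range(P)])
    if P == 6:
        s = summarize_movement_matrix(m)
        down = ["total_downstream"] + [
            "" if np.isnan(v) else round(v, 6) for v in s.total_down
        ]
        up = ["total_upstream"] + [
            "" if np.isnan(v) else round(v, 6) for v in s.total_up
        ]
        df = pd.concat(
            [df, pd.DataFrame([down, up], columns=["destination"] + cols)],
            ignore_index=True,
        )
    return df


def render_figures(effort: np.ndarray, derived: dict, fig_dir: Path) -> None:
    """Effort time series, detection curves, and detection time series."""
    fig_dir = Path(fig_dir)
    fig_dir.mkdir(parents=True, exist_ok=True)
    # deterministic SVG output (no embedded dates or per-process hash ids)
    plt.rcParams["svg.hashsalt"] = "poolhmm"
    _savefig_kw = {"metadata": {"Date": None}}
    P, T = effort.shape

    fig, axes = plt.subplots(P, 1, figsize=(7, 1.6 * P), sharex=True)
    for j, ax in enumerate(np.atleast_1d(axes)):
        ax.bar(np.arange(1, T + 1), effort[j], color="steelblue")
        ax.set_ylabel(f"pool {j + 1}")
    np.atleast_1d(axes)[-1].set_xlabel("month")
    fig.suptitle("Mean receivers deployed per day")
    fig.tight_layout()
    fig.savefig(fig_dir / "effort.svg", **_savefig_kw)
    plt.close(fig)

    curves = derived["detection_curves"]
    fig, axes = plt.subplots(2, (P + 1) // 2, figsize=(9, 5), sharey=True)
    for j, ax in enumerate(np.ravel(axes)[:P]):
        c = curves[curves["pool"] == j + 1]
        ax.plot(c["x"], c["median"], color="firebrick")
        ax.fill_between(c["x"], c["lo"], c["hi"], alpha=0.3, color="firebrick")
        ax.set_title(f"pool {j + 1}")
        ax.set_xlabel("mean receivers/day")
    np.ravel(axes)[0].set_ylabel("detection probability")
    fig.suptitle("Detection probability vs receiver effort (median, 95% CI)")
    fig.tight_layout()
    fig.savefig(fig_dir / "detection_curves.svg", **_savefig_kw)
    plt.close(fig)

    series = derived["detection_series"]
    fig, axes = plt.subplots(2, (P + 1) // 2, figsize=(9, 5), sharey=True)
    for j, ax in enumerate(np.ravel(axes)[:P]):
        s = series[series["pool"] == j + 1]
        ax.plot(s["month"], s["median"], color="darkgreen")
        ax.fill_between(s["month"], s["lo"], s["hi"], alpha=0.3, color="darkgreen")
        ax.set_title(f"pool {j + 1}")
        ax.set_xlabel("month")
    np.ravel(axes)[0].set_ylabel("detection probability")
    fig.suptitle("Detection probability at observed effort")
    fig.tight_layout()
    fig.savefig(fig_dir / "detection_series.svg", **_savefig_kw)
    plt.close(fig)


def render_tables(posterior_dir: Path, out_dir: Path | None = None) -> dict:
    """Re-render summary tables and figures from a fitted pipeline directory."""
    posterior_dir = Path(posterior_dir)
    out_dir = Path(out_dir) if out_dir is not None else posterior_dir
    needed = ["draws.csv", "effort.csv", "detection_curves.csv"]
    missing = [n for n in needed if not (posterior_dir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"posterior directory {posterior_dir} is missing {missing}; "
            "run the fit stage first"
        )
    effort = prep.frame_to_effort(pd.read_csv(posterior_dir / "effort.csv"))
    curves = pd.read_csv(posterior_dir / "detection_curves.csv")
    series_path = posterior_dir / "detection_series.csv"
    series = pd.read_csv(series_path) if series_path.exists() else curves
    render_figures(
        effort,
        {"detection_curves": curves, "detection_series": series},
        out_dir / "figures",
    )
    return {"figures": str(out_dir / "figures")}
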