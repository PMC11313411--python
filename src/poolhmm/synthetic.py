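"""Synthetic acoustic-telemetry generator.

Emulates the three raw data streams of a six-pool river telemetry study —
receiver deployments, tag deployments, and detection events — from the exact
generative structure the movement model assumes: Markovian monthly pool
transitions (``psi``), constant monthly survival (``phi``) and battery
retention (``delta``), and per-pool logistic detection driven by mean
receiver-days.  It also plants labelled dead-fish / dropped-tag artifacts so
the preprocessing filters can be tested against ground truth.

Months are fixed 30-day blocks for raw-event generation (the monthly model is
indifferent to day counts; calendar-month arithmetic is exercised separately
in the preprocessing tests).  Within a detected fish-month, raw detections
are placed at uniformly random timestamps, with a shifted-geometric event
count whose mean is ``daily_detection_rate * 30``; multi-detection months are
scattered across at least two receiver stations, reflecting a live fish
roaming its pool — genuinely stationary signatures are the business of the
artifact injector, never of clean fish.

Battery lifetimes: the model treats the projected tag-expiration date as
exact, so by default each fish's true lifetime is drawn from the battery
process itself (geometric with monthly retention ``delta``) and reported as
the projected expiration date.  A tagging-plan entry may instead pin a fixed
lifetime in months.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .model import ModelParams, detection_prob
from .preprocess import Calendar, compute_effort

__all__ = [
    "ReceiverSite",
    "TagCohort",
    "ScenarioConfig",
    "SimulatedData",
    "LatentTrajectory",
    "default_true_params",
    "default_scenario",
    "generate_effort",
    "simulate_cohort",
    "plant_artifacts",
    "simulate_scenario",
    "write_streams",
    "clean_fish_ids",
]

ORIGIN = pd.Timestamp("2012-01-01")


@dataclass
class ReceiverSite:
    pool: int  # 1-based
    river_km: float
    deploy_month: int  # 1-based, inclusive
    retrieve_month: int  # 1-based, inclusive (retrieved at end of this month)
    at_lock: bool = False


@dataclass
class TagCohort:
    release_month: int  # 1-based
    release_pool: int  # 1-based
    n_fish: int
    species: str = "silver"
    tag_life_months: int | None = None  # None: drawn from the battery process


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic telemetry scenario."""

    n_pools: int
    n_months: int
    pool_lengths_km: list[float]
    receiver_plan: list[ReceiverSite]
    tagging_plan: list[TagCohort]
    true_params: ModelParams
    seed: int = 0
    daily_detection_rate: float = 1.0
    origin: pd.Timestamp = ORIGIN

    def validate(self) -> None:
        self.true_params.validate()
        if len(self.pool_lengths_km) != self.n_pools:
            raise ValueError("pool_lengths_km must have one entry per pool")
        for site in self.receiver_plan:
            if not (1 <= site.pool <= self.n_pools):
                raise ValueError(f"receiver pool {site.pool} outside 1..{self.n_pools}")
            if not (1 <= site.deploy_month <= site.retrieve_month <= self.n_months):
                raise ValueError("receiver deploy/retrieve months out of range")
        for cohort in self.tagging_plan:
            if not (1 <= cohort.release_pool <= self.n_pools):
                raise ValueError("release pool out of range")
            if not (1 <= cohort.release_month <= self.n_months):
                raise ValueError("release month out of range")
            if cohort.n_fish < 0:
                raise ValueError("n_fish must be non-negative")
            if cohort.tag_life_months is not None and cohort.tag_life_months < 1:
                raise ValueError("tag lifetime must be at least one month")

    @property
    def calendar(self) -> Calendar:
        return Calendar(start=self.origin, n_months=self.n_months, mode="block30")

    def pool_bounds_km(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.pool_lengths_km)])

    def to_yaml(self, path) -> None:
        d = {
            "n_pools": self.n_pools,
            "n_months": self.n_months,
            "pool_lengths_km": [float(v) for v in self.pool_lengths_km],
            "seed": self.seed,
            "daily_detection_rate": self.daily_detection_rate,
            "origin": str(self.origin.date()),
            "receiver_plan": [asdict(s) for s in self.receiver_plan],
            "tagging_plan": [asdict(c) for c in self.tagging_plan],
            "true_params": {
                "phi": self.true_params.phi,
                "delta": self.true_params.delta,
                "psi": self.true_params.psi.tolist(),
                "beta": self.true_params.beta.tolist(),
                "theta": self.true_params.theta,
                "sigma": self.true_params.sigma,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        tp = d["true_params"]
        return ScenarioConfig(
            n_pools=d["n_pools"],
            n_months=d["n_months"],
            pool_lengths_km=d["pool_lengths_km"],
            receiver_plan=[ReceiverSite(**s) for s in d["receiver_plan"]],
            tagging_plan=[TagCohort(**c) for c in d["tagging_plan"]],
            true_params=ModelParams(
                phi=tp["phi"],
                delta=tp["delta"],
                psi=np.array(tp["psi"]),
                beta=np.array(tp["beta"]),
                theta=tp.get("theta", 0.0),
                sigma=tp.get("sigma", 1.0),
            ),
            seed=d.get("seed", 0),
            daily_detection_rate=d.get("daily_detection_rate", 1.0),
            origin=pd.Timestamp(d.get("origin", ORIGIN)),
        )


@dataclass
class LatentTrajectory:
    """Ground-truth monthly states of one simulated fish.

    ``states[k]`` is the latent state in month ``release_month + k`` using
    the model's coding (0..P-1 = alive/operable in pool, P = dead/operable,
    P+1 = alive/expired, P+2 = dead/expired).
    """

    fish_id: str
    release_month: int  # 0-based
    expire_month: int  # 0-based; may be >= n_months (censored)
    states: np.ndarray


@dataclass
class SimulatedData:
    receivers: pd.DataFrame
    tags: pd.DataFrame
    detections: pd.DataFrame
    trajectories: list[LatentTrajectory]
    artifacts: pd.DataFrame
    effort: np.ndarray
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------


def default_true_params() -> ModelParams:
    """Generating parameters of the default scenario.

    Diagonally dominant pool transitions (stay ~0.80) with downstream
    movement more likely than upstream, monthly survival 0.96, monthly
    battery retention 0.97, and pool detection effects spanning 0.3-3 on an
    even grid (hyper-mean 1.65, hyper-SD 1).
    """
    psi = np.array(
        [  # destination rows (pool 1 most downstream), origin columns
            [0.82, 0.10, 0.03, 0.02, 0.02, 0.02],
            [0.12, 0.80, 0.10, 0.04, 0.02, 0.02],
            [0.03, 0.06, 0.80, 0.08, 0.04, 0.03],
            [0.015, 0.02, 0.05, 0.80, 0.08, 0.04],
            [0.01, 0.012, 0.012, 0.04, 0.80, 0.09],
            [0.005, 0.008, 0.008, 0.02, 0.04, 0.80],
        ]
    )
    beta = np.array([0.3, 0.84, 1.38, 1.92, 2.46, 3.0])
    return ModelParams(
        phi=0.96, delta=0.97, psi=psi, beta=beta, theta=float(beta.mean()), sigma=1.0
    )


def default_scenario(seed: int = 0, n_months: int = 36) -> ScenarioConfig:
    """Default six-pool study: 200 fish, 36 months, 33 receiver stations.

    Receiver counts per pool (20, 7, 4, 3, 3, 2) are paired against the
    ascending detection-effect grid so every pool is informatively monitored
    (monthly detection probability ~0.6-0.9, counts within the realistic
    0-21 receivers-per-pool range); a couple of stations have partial
    deployments so the effort covariate is not flat in time.
    """
    pool_lengths = [130.0, 125.0, 120.0, 30.0, 40.0, 25.0]
    counts = [20, 7, 4, 3, 3, 2]
    bounds = np.concatenate([[0.0], np.cumsum(pool_lengths)])
    plan: list[ReceiverSite] = []
    for pool0, c in enumerate(counts):
        lo, hi = bounds[pool0], bounds[pool0 + 1]
        positions = lo + (hi - lo) * (np.arange(1, c + 1)) / (c + 1)
        for k, km in enumerate(positions):
            deploy, retrieve = 1, n_months
            if pool0 == 0 and k == 0:
                retrieve = max(1, n_months // 2)  # pulled early
            if pool0 == 2 and k == 0:
                deploy = min(n_months, 7)  # added late
            plan.append(
                ReceiverSite(
                    pool=pool0 + 1,
                    river_km=float(km),
                    deploy_month=deploy,
                    retrieve_month=retrieve,
                )
            )
    tagging = [
        TagCohort(release_month=1, release_pool=1, n_fish=34),
        TagCohort(release_month=1, release_pool=2, n_fish=34),
        TagCohort(release_month=2, release_pool=3, n_fish=33),
        TagCohort(release_month=2, release_pool=4, n_fish=33),
        TagCohort(release_month=3, release_pool=5, n_fish=33),
        TagCohort(release_month=3, release_pool=6, n_fish=33),
    ]
    return ScenarioConfig(
        n_pools=6,
        n_months=n_months,
        pool_lengths_km=pool_lengths,
        receiver_plan=plan,
        tagging_plan=tagging,
        true_params=default_true_params(),
        seed=seed,
        daily_detection_rate=1.0,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def receivers_frame(config: ScenarioConfig) -> pd.DataFrame:
    cal = config.calendar
    rows = []
    for k, site in enumerate(config.receiver_plan):
        rows.append(
            {
                "receiver_id": f"R{k + 1:03d}",
                "pool": site.pool,
                "river_km": site.river_km,
                "deploy_date": cal.month_start(site.deploy_month - 1),
                "retrieve_date": cal.month_start(site.retrieve_month),
                "at_lock": site.at_lock,
            }
        )
    return pd.DataFrame(rows)


def generate_effort(config: ScenarioConfig) -> np.ndarray:
    """Mean receivers per day, per pool per month, implied by the plan.

    Shares the exact day-count arithmetic with the preprocessing module, so
    the covariate used to *generate* detections is identical to the one the
    model will be fed.
    """
    config.validate()
    return compute_effort(receivers_frame(config), config.calendar, config.n_pools)


def _draw_event_times(
    rng: np.random.Generator, month_start: pd.Timestamp, k: int
) -> pd.DatetimeIndex:
    secs = rng.integers(0, 30 * 86400, size=k)
    return pd.DatetimeIndex(sorted(month_start + pd.to_timedelta(secs, unit="s")))


def simulate_cohort(config: ScenarioConfig, rng: np.random.Generator | None = None):
    """Draw latent trajectories and raw detection events.

    Returns (trajectories, detections, tags, receivers).  Fully determined
    by ``config.seed`` when ``rng`` is not supplied.  A fish's monthly
    detection in pool j happens with probability rho[j, t] from the logistic
    effort curve whenever it is alive with an operable battery; dead,
    expired, and pre-release fish-months yield no events.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.true_params
    P = config.n_pools
    cal = config.calendar
    receivers = receivers_frame(config)
    effort = compute_effort(receivers, cal, P)
    rho = detection_prob(p.beta[:, None], effort, p.intercept)  # (P, T)
    mean_events = max(config.daily_detection_rate * 30.0, 1.0)

    # receivers available per pool-month (non-lock), for event placement
    active_sites: list[list[list[str]]] = []
    for j in range(P):
        by_month = []
        sub = receivers[(receivers["pool"] == j + 1) & (~receivers["at_lock"])]
        for t in range(config.n_months):
            ms, me = cal.month_start(t), cal.month_start(t + 1)
            ok = sub[(sub["deploy_date"] <= ms) & (sub["retrieve_date"] >= me)]
            by_month.append(list(ok["receiver_id"]))
        active_sites.append(by_month)

    trajectories: list[LatentTrajectory] = []
    tag_rows = []
    det_rows = []
    fish_no = 0
    for cohort in config.tagging_plan:
        r = cohort.release_month - 1
        pool0 = cohort.release_pool - 1
        for _ in range(cohort.n_fish):
            fish_no += 1
            fid = f"F{fish_no:04d}"
            code = f"T{10_000 + fish_no}"
            if cohort.tag_life_months is not None:
                life = int(cohort.tag_life_months)
            elif p.delta >= 1.0:
                life = config.n_months + 1  # battery never expires
            else:
                life = int(rng.geometric(1.0 - p.delta))
            expire_month = r + life
            release_date = cal.month_start(r) + pd.Timedelta(
                days=int(rng.integers(0, 10))
            )
            expire_date = release_date + pd.Timedelta(days=30 * life)
            tag_rows.append(
                {
                    "fish_id": fid,
                    "species": cohort.species,
                    "tag_code": code,
                    "release_date": release_date,
                    "release_pool": cohort.release_pool,
                    "expire_date": expire_date,
                }
            )

            n_rel = config.n_months - r
            states = np.empty(n_rel, dtype=int)
            alive = True
            pool = pool0
            for k, t in enumerate(range(r, config.n_months)):
                if k > 0:
                    operable_prev = t - 1 < expire_month
                    if alive:
                        alive = rng.random() < p.phi
                    if alive and operable_prev and t < expire_month:
                        pool = int(rng.choice(P, p=p.psi[:, pool]))
                operable = t < expire_month
                if operable:
                    states[k] = pool if alive else P
                else:
                    states[k] = P + 1 if alive else P + 2
                # raw detections for alive/operable fish-months
                if states[k] < P and rng.random() < rho[pool, t]:
                    sites = active_sites[pool][t]
                    if not sites:
                        continue
                    k_events = int(rng.geometric(1.0 / mean_events))
                    times = _draw_event_times(rng, cal.month_start(t), k_events)
                    chosen = [str(s) for s in rng.choice(sites, size=k_events)]
                    if k_events >= 2 and len(sites) >= 2:
                        two = rng.choice(len(sites), size=2, replace=False)
                        chosen[0] = sites[two[0]]
                        chosen[1] = sites[two[1]]
                    for ts, rid in zip(times, chosen):
                        det_rows.append(
                            {"tag_code": code, "receiver_id": rid, "timestamp": ts}
                        )
            trajectories.append(
                LatentTrajectory(
                    fish_id=fid,
                    release_month=r,
                    expire_month=expire_month,
                    states=states,
                )
            )
    tags = pd.DataFrame(tag_rows)
    detections = (
        pd.DataFrame(det_rows)
        .sort_values(["timestamp", "tag_code"])
        .reset_index(drop=True)
        if det_rows
        else pd.DataFrame(columns=["tag_code", "receiver_id", "timestamp"])
    )
    return trajectories, detections, tags, receivers


def plant_artifacts(
    data: SimulatedData,
    n_first30: int = 20,
    n_stationary: int = 20,
    n_mobile: int = 5,
    rng: np.random.Generator | None = None,
) -> SimulatedData:
    """Inject labelled suspect-tag artifact fish into the raw streams.

    * ``first30``: fish whose only detections fall within 30 days of tagging
      (died or shed the tag immediately).
    * ``stationary``: a dropped tag continuously detected on one receiver in
      the release pool for months (gap <= 3 days).
    * ``mobile``: control fish detected in two pools over several months —
      must pass every filter.

    Artifact labels go to a side truth table only; the event stream itself
    carries no marker, so the filter has to rediscover them.
    """
    if rng is None:
        rng = np.random.default_rng(data.config.seed + 777_001)
    cfg = data.config
    cal = cfg.calendar
    receivers = data.receivers
    next_no = len(data.tags) + len(data.artifacts) + 1

    tag_rows, det_rows, art_rows = [], [], []

    def new_fish(kind: str, pool: int, release_month0: int, life: int):
        nonlocal next_no
        fid = f"A{next_no:04d}"
        code = f"T{80_000 + next_no}"
        next_no += 1
        release_date = cal.month_start(release_month0) + pd.Timedelta(
            days=int(rng.integers(0, 5))
        )
        tag_rows.append(
            {
                "fish_id": fid,
                "species": "silver",
                "tag_code": code,
                "release_date": release_date,
                "release_pool": pool + 1,
                "expire_date": release_date + pd.Timedelta(days=30 * life),
            }
        )
        art_rows.append({"fish_id": fid, "kind": kind})
        return fid, code, release_date

    def pool_sites(pool: int) -> pd.DataFrame:
        # restrict to stations deployed across the whole study so planted
        # detections always fall inside a deployment window
        full = (receivers["deploy_date"] == cal.month_start(0)) & (
            receivers["retrieve_date"] == cal.month_start(cfg.n_months)
        )
        return receivers[(receivers["pool"] == pool + 1) & (~receivers["at_lock"]) & full]

    max_release = max(1, cfg.n_months - 12)
    for _ in range(n_first30):
        pool = int(rng.integers(0, cfg.n_pools))
        r = int(rng.integers(0, max_release))
        _, code, release_date = new_fish("first30", pool, r, 30)
        sites = pool_sites(pool)
        k = int(rng.integers(5, 15))
        for _ in range(k):
            day = float(rng.uniform(1.0, 25.0))
            rid = str(sites["receiver_id"].iloc[int(rng.integers(0, len(sites)))])
            det_rows.append(
                {
                    "tag_code": code,
                    "receiver_id": rid,
                    "timestamp": release_date + pd.Timedelta(days=day),
                }
            )

    for _ in range(n_stationary):
        pool = int(rng.integers(0, cfg.n_pools))
        r = int(rng.integers(0, max_release))
        _, code, release_date = new_fish("stationary", pool, r, 30)
        sites = pool_sites(pool)
        rid = str(sites["receiver_id"].iloc[int(rng.integers(0, len(sites)))])
        span_days = int(rng.integers(120, 240))
        day = float(rng.uniform(0.5, 3.0))
        while day < span_days:
            det_rows.append(
                {
                    "tag_code": code,
                    "receiver_id": rid,
                    "timestamp": release_date + pd.Timedelta(days=day),
                }
            )
            day += float(rng.uniform(0.5, 3.0))

    for _ in range(n_mobile):
        pool = int(rng.integers(0, cfg.n_pools - 1))
        r = int(rng.integers(0, max_release))
        _, code, release_date = new_fish("mobile", pool, r, 30)
        for m, pl in [(0, pool), (2, pool + 1), (5, pool)]:
            sites = pool_sites(pl)
            for _ in range(4):
                rid = str(sites["receiver_id"].iloc[int(rng.integers(0, len(sites)))])
                det_rows.append(
                    {
                        "tag_code": code,
                        "receiver_id": rid,
                        "timestamp": release_date
                        + pd.Timedelta(days=30 * m + float(rng.uniform(1, 28))),
                    }
                )

    detections = (
        pd.concat([data.detections, pd.DataFrame(det_rows)], ignore_index=True)
        .sort_values(["timestamp", "tag_code"])
        .reset_index(drop=True)
    )
    tags = pd.concat([data.tags, pd.DataFrame(tag_rows)], ignore_index=True)
    artifacts = pd.concat(
        [data.artifacts, pd.DataFrame(art_rows)], ignore_index=True
    )
    return SimulatedData(
        receivers=data.receivers,
        tags=tags,
        detections=detections,
        trajectories=data.trajectories,
        artifacts=artifacts,
        effort=data.effort,
        config=data.config,
    )


def simulate_scenario(
    config: ScenarioConfig,
    with_artifacts: bool = True,
    n_first30: int = 20,
    n_stationary: int = 20,
    n_mobile: int = 5,
) -> SimulatedData:
    """Convenience wrapper: cohort simulation plus (optionally) artifacts."""
    trajectories, detections, tags, receivers = simulate_cohort(config)
    data = SimulatedData(
        receivers=receivers,
        tags=tags,
        detections=detections,
        trajectories=trajectories,
        artifacts=pd.DataFrame(columns=["fish_id", "kind"]),
        effort=generate_effort(config),
        config=config,
    )
    if with_artifacts:
        data = plant_artifacts(
            data, n_first30=n_first30, n_stationary=n_stationary, n_mobile=n_mobile
        )
    return data


def trajectories_frame(trajectories: list[LatentTrajectory], n_pools: int):
    from .model import state_labels

    labels = state_labels(n_pools)
    rows = []
    for tr in trajectories:
        for k, s in enumerate(tr.states):
            rows.append(
                {
                    "fish_id": tr.fish_id,
                    "month": tr.release_month + k + 1,
                    "state": labels[s],
                }
            )
    return pd.DataFrame(rows)


def write_streams(data: SimulatedData, out_dir) -> dict[str, str]:
    """Write the three raw streams plus truth tables as CSV; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {
        "receivers.csv": data.receivers,
        "tags.csv": data.tags,
        "detections.csv": data.detections,
        "trajectories.csv": trajectories_frame(data.trajectories, data.config.n_pools),
        "artifacts.csv": data.artifacts,
    }
    for name, df in frames.items():
        path = out / name
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths


def clean_fish_ids(data: SimulatedData, first_days: int = 30) -> set[str]:
    """Fish the suspect-tag filter must keep.

    Clean = not a planted artifact and detected at least once more than
    ``first_days`` after release.  A non-artifact fish whose only detections
    fall inside the first month is observationally identical to an immediate
    tagging death, which is precisely what the first-30-day rule removes, so
    such fish belong to neither truth class.
    """
    det = data.detections.merge(
        data.tags[["fish_id", "tag_code", "release_date"]], on="tag_code"
    )
    age = (
        pd.to_datetime(det["timestamp"]) - pd.to_datetime(det["release_date"])
    ).dt.total_seconds() / 86400.0
    late = set(det.loc[age > first_days, "fish_id"])
    mobile = set(
        data.artifacts.loc[data.artifacts["kind"] == "mobile", "fish_id"]
    )
    planted = set(data.artifacts["fish_id"]) - mobile
    return (late - planted) | (mobile & late)
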