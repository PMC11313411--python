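"""Tests of the synthetic telemetry generator: effort arithmetic, latent-state
legality, seed reproducibility, and convergence of empirical rates to the
generating parameters."""

import numpy as np
import pandas as pd
import pytest

from poolhmm import synthetic
from poolhmm.model import ModelParams, detection_prob
from poolhmm.synthetic import ReceiverSite, ScenarioConfig, TagCohort


def small_config(**kw):
    defaults = dict(
        n_pools=2,
        n_months=6,
        pool_lengths_km=[40.0, 40.0],
        receiver_plan=[
            ReceiverSite(pool=1, river_km=10.0, deploy_month=1, retrieve_month=6),
            ReceiverSite(pool=1, river_km=30.0, deploy_month=1, retrieve_month=6),
            ReceiverSite(pool=2, river_km=50.0, deploy_month=1, retrieve_month=6),
            ReceiverSite(pool=2, river_km=70.0, deploy_month=1, retrieve_month=6),
        ],
        tagging_plan=[TagCohort(release_month=1, release_pool=1, n_fish=10)],
        true_params=ModelParams(
            phi=0.95,
            delta=0.95,
            psi=np.array([[0.8, 0.3], [0.2, 0.7]]),
            beta=np.array([2.0, 2.5]),
        ),
        seed=42,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestGenerateEffort:
    def test_full_month_single_receiver_is_one(self):
        cfg = small_config(
            receiver_plan=[
                ReceiverSite(pool=1, river_km=10.0, deploy_month=1, retrieve_month=6)
            ]
        )
        x = synthetic.generate_effort(cfg)
        assert np.allclose(x[0], 1.0)
        assert np.allclose(x[1], 0.0)  # no receivers in pool 2 at all

    def test_partial_deployment_months(self):
        cfg = small_config(
            receiver_plan=[
                ReceiverSite(pool=1, river_km=10.0, deploy_month=2, retrieve_month=3)
            ]
        )
        x = synthetic.generate_effort(cfg)
        assert np.allclose(x[0], [0, 1, 1, 0, 0, 0])

    def test_study_maximum_receiver_count(self):
        plan = [
            ReceiverSite(pool=1, river_km=1.0 + k, deploy_month=1, retrieve_month=6)
            for k in range(21)
        ]
        cfg = small_config(receiver_plan=plan)
        x = synthetic.generate_effort(cfg)
        assert np.allclose(x[0], 21.0)

    def test_overlapping_deployments_rejected(self):
        cfg = small_config()
        data = synthetic.simulate_scenario(cfg, with_artifacts=False)
        rec = data.receivers
        dup = rec.iloc[[0]].copy()  # same receiver id, overlapping interval
        bad = pd.concat([rec, dup], ignore_index=True)
        from poolhmm.preprocess import validate_deployments

        with pytest.raises(ValueError, match="overlapping"):
            validate_deployments(bad)


class TestTrajectoryLegality:
    def test_no_revival_or_unexpiry(self, default_data):
        P = default_data.config.n_pools
        for tr in default_data.trajectories:
            s = tr.states
            dead = (s == P) | (s == P + 2)
            expired = s >= P + 1
            assert not np.any(~dead[1:] & dead[:-1]), "a dead fish revived"
            assert not np.any(~expired[1:] & expired[:-1]), "a battery recovered"

    def test_expired_status_from_projected_month(self, default_data):
        P = default_data.config.n_pools
        for tr in default_data.trajectories:
            for k, s in enumerate(tr.states):
                month = tr.release_month + k
                if month >= tr.expire_month:
                    assert s >= P + 1

    def test_dead_or_expired_fish_produce_no_detections(self, default_data):
        P = default_data.config.n_pools
        cal = default_data.config.calendar
        det = default_data.detections.merge(
            default_data.tags[["fish_id", "tag_code"]], on="tag_code"
        )
        det = det[det["fish_id"].str.startswith("F")]  # exclude artifacts
        det["month"] = cal.month_of(det["timestamp"])
        by_fish = {t.fish_id: t for t in default_data.trajectories}
        for (fid, month), _ in det.groupby(["fish_id", "month"]):
            tr = by_fish[fid]
            state = tr.states[month - tr.release_month]
            assert state < P, f"{fid} detected while in state {state}"


class TestReproducibility:
    def test_same_seed_bitwise_identical(self):
        cfg = small_config()
        a = synthetic.simulate_scenario(cfg)
        b = synthetic.simulate_scenario(cfg)
        pd.testing.assert_frame_equal(a.detections, b.detections)
        pd.testing.assert_frame_equal(a.tags, b.tags)
        pd.testing.assert_frame_equal(a.artifacts, b.artifacts)
        for x, y in zip(a.trajectories, b.trajectories):
            assert np.array_equal(x.states, y.states)

    def test_different_seed_differs(self):
        a = synthetic.simulate_scenario(small_config(seed=1))
        b = synthetic.simulate_scenario(small_config(seed=2))
        assert not a.detections.equals(b.detections)


@pytest.fixture(scope="module")
def big_cohort():
    params = synthetic.default_true_params()
    cfg = ScenarioConfig(
        n_pools=6,
        n_months=8,
        pool_lengths_km=[50.0] * 6,
        receiver_plan=[
            ReceiverSite(pool=j + 1, river_km=50.0 * j + 10 + 20 * k,
                         deploy_month=1, retrieve_month=8)
            for j in range(6)
            for k in range(2)
        ],
        tagging_plan=[
            TagCohort(release_month=1, release_pool=j + 1, n_fish=334)
            for j in range(6)
        ],
        true_params=params,
        seed=99,
        daily_detection_rate=0.2,
    )
    return cfg, synthetic.simulate_scenario(cfg, with_artifacts=False)


class TestEmpiricalRates:
    """Monte-Carlo convergence of empirical frequencies to the generating
    parameters, checked at n=2,000 fish within Monte-Carlo error."""

    def test_pool_transition_frequencies_match_psi(self):
        # no mortality/expiry so every monthly move is observable
        psi = synthetic.default_true_params().psi
        params = ModelParams(phi=1.0, delta=1.0, psi=psi, beta=np.full(6, 1.0))
        cfg = ScenarioConfig(
            n_pools=6,
            n_months=5,
            pool_lengths_km=[50.0] * 6,
            receiver_plan=[
                ReceiverSite(pool=j + 1, river_km=50.0 * j + 25,
                             deploy_month=1, retrieve_month=5)
                for j in range(6)
            ],
            tagging_plan=[
                TagCohort(release_month=1, release_pool=j + 1, n_fish=334,
                          tag_life_months=12)
                for j in range(6)
            ],
            true_params=params,
            seed=7,
            daily_detection_rate=0.1,
        )
        data = synthetic.simulate_scenario(cfg, with_artifacts=False)
        counts = np.zeros((6, 6))
        for tr in data.trajectories:
            s = tr.states
            for a, b in zip(s[:-1], s[1:]):
                counts[b, a] += 1
        from scipy.stats import chisquare

        for j in range(6):
            n = counts[:, j].sum()
            res = chisquare(counts[:, j], n * psi[:, j])
            assert res.pvalue > 1e-4, (
                f"column {j}: freq {counts[:, j] / n} vs psi {psi[:, j]} "
                f"(chi-square p={res.pvalue:.2e})"
            )

    def test_survival_and_battery_retention_rates(self, big_cohort):
        cfg, data = big_cohort
        P = cfg.n_pools
        phi, delta = cfg.true_params.phi, cfg.true_params.delta
        alive_pairs = dead_after_alive = 0
        operable_pairs = expired_after_operable = 0
        for tr in data.trajectories:
            s = tr.states
            alive = (s < P) | (s == P + 1)
            operable = s <= P
            for k in range(len(s) - 1):
                if alive[k]:
                    alive_pairs += 1
                    dead_after_alive += not alive[k + 1]
                if operable[k]:
                    operable_pairs += 1
                    expired_after_operable += not operable[k + 1]
        surv = 1 - dead_after_alive / alive_pairs
        se = np.sqrt(phi * (1 - phi) / alive_pairs)
        assert abs(surv - phi) <= 3 * se
        reten = 1 - expired_after_operable / operable_pairs
        se = np.sqrt(delta * (1 - delta) / operable_pairs)
        assert abs(reten - delta) <= 3 * se

    def test_detection_fraction_matches_rho(self, big_cohort):
        cfg, data = big_cohort
        P = cfg.n_pools
        cal = cfg.calendar
        rho = detection_prob(cfg.true_params.beta[:, None], data.effort)
        det = data.detections.merge(
            data.tags[["fish_id", "tag_code"]], on="tag_code"
        )
        det["month"] = cal.month_of(det["timestamp"])
        detected = {(f, m) for f, m in zip(det["fish_id"], det["month"])}
        for j in range(P):
            hits = trials = 0
            expect = []
            for tr in data.trajectories:
                for k, s in enumerate(tr.states):
                    if s == j:
                        t = tr.release_month + k
                        trials += 1
                        expect.append(rho[j, t])
                        hits += (tr.fish_id, t) in detected
            p = float(np.mean(expect))
            se = np.sqrt(p * (1 - p) / trials)
            assert abs(hits / trials - p) <= 3 * se + 1e-9


class TestArtifacts:
    def test_labels_only_in_side_table(self, default_data):
        art_ids = set(default_data.artifacts["fish_id"])
        assert art_ids
        assert "kind" not in default_data.detections.columns
        assert art_ids <= set(default_data.tags["fish_id"])
        traj_ids = {t.fish_id for t in default_data.trajectories}
        assert not (art_ids & traj_ids)

    def test_artifact_kinds_present(self, default_data):
        kinds = set(default_data.artifacts["kind"])
        assert kinds == {"first30", "stationary", "mobile"}

    def test_streams_round_trip_through_csv(self, default_data, tmp_path):
        paths = synthetic.write_streams(default_data, tmp_path)
        det = pd.read_csv(paths["detections.csv"], parse_dates=["timestamp"])
        assert len(det) == len(default_data.detections)
        rec = pd.read_csv(paths["receivers.csv"])
        assert set(rec.columns) >= {
            "receiver_id", "pool", "river_km", "deploy_date", "retrieve_date",
        }

    def test_scenario_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "s.yaml")
        back = ScenarioConfig.from_yaml(tmp_path / "s.yaml")
        assert back.n_pools == cfg.n_pools
        assert np.allclose(back.true_params.psi, cfg.true_params.psi)
        assert back.tagging_plan == cfg.tagging_plan
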