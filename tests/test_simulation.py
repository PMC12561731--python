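"""Tests for the agent-based community simulator."""

import numpy as np
import pytest
from scipy import stats

import trailmap.simulation as sim
from trailmap import (
    SimulationConfig,
    TrailTable,
    build_population,
    run_simulation,
    sample_rating,
    schedule_requests,
)
from trailmap.simulation import (
    HelperAgent,
    SeekerAgent,
    available_helpers,
    route_request,
)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SimulationConfig().validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(seeker_proportion=0.3),  # proportions no longer sum to 1
            dict(n_agents=1001),  # non-integral seeker count
            dict(duration_hours=10.5),  # not a multiple of the hourly grid
            dict(condition="greedy"),
            dict(request_rate_per_seeker_per_day=0.0),
            dict(interaction_duration_mean_min=-3.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()


class TestBuildPopulation:
    def test_default_split_200_800(self, rng):
        seekers, helpers, table = build_population(SimulationConfig(), rng)
        assert len(seekers) == 200
        assert len(helpers) == 800
        assert len(table) == 800

    def test_ids_disjoint_and_trails_zero(self, rng):
        seekers, helpers, table = build_population(SimulationConfig(), rng)
        s_ids = {s.id for s in seekers}
        h_ids = {h.id for h in helpers}
        assert not (s_ids & h_ids)
        assert np.all(table.values == 0.0)

    def test_latent_helpfulness_beta_mean(self, rng):
        # Beta(2, 5) mean is a/(a+b) = 2/7; 800 draws, 4-standard-error band
        _, helpers, _ = build_population(SimulationConfig(), rng)
        h = np.array([x.h_latent for x in helpers])
        se = np.sqrt((2 * 5) / ((2 + 5) ** 2 * 8) / 800)  # Beta variance / n
        assert abs(h.mean() - 2 / 7) < 4 * se
        assert np.all((h > 0) & (h < 1))


class TestSampleRating:
    def test_noiseless_extremes(self, rng):
        assert sample_rating(0.9999, 0.0, rng) == 5
        assert sample_rating(0.5, 0.0, rng) == 3
        assert sample_rating(0.0001, 0.0, rng) == 1

    def test_mean_matches_monte_carlo_oracle(self):
        # independent vectorised oracle of the same recipe
        h, sigma, n = 0.75, 0.7, 100_000
        oracle_rng = np.random.default_rng(99)
        mu = 1 + 4 * h
        oracle = np.clip(np.round(mu + oracle_rng.normal(0, sigma, n)), 1, 5)
        rng = np.random.default_rng(7)
        draws = np.array([sample_rating(h, sigma, rng) for _ in range(20_000)])
        se = oracle.std() * np.sqrt(1 / 20_000 + 1 / n)
        assert abs(draws.mean() - oracle.mean()) < 4 * se

    def test_support_is_1_to_5(self, rng):
        draws = {sample_rating(0.5, 2.0, rng) for _ in range(2000)}
        assert draws <= {1, 2, 3, 4, 5}
        assert {1, 5} <= draws  # heavy noise reaches both clamps

    def test_latent_outside_unit_interval_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_rating(1.5, 0.1, rng)


class TestScheduleRequests:
    def test_poisson_count(self, rng):
        seekers = [SeekerAgent(id=i) for i in range(200)]
        horizon = 30 * 24 * 60.0
        stream = schedule_requests(seekers, 1.0, horizon, rng)
        expected = 200 * 30
        assert abs(len(stream) - expected) < 4 * np.sqrt(expected)
        times = [t for _, t in stream]
        assert times == sorted(times)
        assert all(0 <= t < horizon for t in times)

    def test_vanishing_rate_empty_stream(self, rng):
        seekers = [SeekerAgent(id=0)]
        assert schedule_requests(seekers, 1e-9, 1440.0, rng) == []

    def test_deterministic_for_fixed_seed(self):
        seekers = [SeekerAgent(id=i) for i in range(5)]
        a = schedule_requests(seekers, 2.0, 7200.0, np.random.default_rng(3))
        b = schedule_requests(seekers, 2.0, 7200.0, np.random.default_rng(3))
        assert a == b


class TestAvailability:
    def test_busy_window(self):
        helpers = [
            HelperAgent(id=1, h_latent=0.5),
            HelperAgent(id=2, h_latent=0.5, busy_until=110.0),
        ]
        assert available_helpers(helpers, 100.0) == [1]
        assert available_helpers(helpers, 110.0) == [1, 2]
        helpers[0].busy_until = 200.0
        assert available_helpers(helpers, 100.0) == []


class TestRouteRequest:
    def params(self):
        from trailmap import RoutingParams

        return RoutingParams()

    def test_single_available_helper(self, rng):
        table = TrailTable([1, 2, 3])
        for cond in ("trailmap", "random"):
            assert route_request(table, [2], cond, self.params(), rng) == 2

    def test_empty_availability_queues(self, rng):
        with pytest.raises(ValueError):
            route_request(TrailTable([1]), [], "random", self.params(), rng)

    def test_random_condition_uniform_chi_square(self, rng):
        table = TrailTable(range(5))
        counts = np.zeros(5)
        for _ in range(10_000):
            counts[route_request(table, list(range(5)), "random", self.params(), rng)] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_zero_trails_match_random_in_distribution(self, rng):
        # all-zero trails: the adaptive rule degenerates to uniform choice
        table = TrailTable(range(5))
        counts = np.zeros(5)
        for _ in range(10_000):
            counts[
                route_request(table, list(range(5)), "trailmap", self.params(), rng)
            ] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.001


class TestRunSimulation:
    def test_bit_reproducible_event_log(self, small_config):
        import json

        log1, m1 = run_simulation(small_config)
        log2, m2 = run_simulation(small_config)
        assert json.dumps(log1.records) == json.dumps(log2.records)
        assert m1 == m2

    def test_request_conservation(self, small_config):
        log, m = run_simulation(small_config)
        created = sum(1 for r in log if r["event"] == "request_created")
        assert created == m.n_resolved + m.n_unresolved

    def test_evaporation_on_hourly_grid(self, small_config):
        log, _ = run_simulation(small_config)
        evap = [r for r in log if r["event"] == "trail_evaporated"]
        assert len(evap) == int(small_config.duration_hours)
        times = [r["t_min"] for r in evap]
        assert times == [60.0 * (k + 1) for k in range(len(evap))]

    def test_timestamps_non_decreasing(self, small_config):
        log, _ = run_simulation(small_config)
        times = [r["t_min"] for r in log]
        assert all(b >= a for a, b in zip(times, times[1:]))

    def test_no_overlapping_interactions(self, small_config):
        log, _ = run_simulation(small_config)
        starts = {}  # (request_id, helper_id) -> start stack
        intervals = {}
        for r in log:
            if r["event"] == "routed":
                starts.setdefault((r["request_id"], r["helper_id"]), []).append(
                    r["t_min"]
                )
            elif r["event"] == "interaction_completed":
                key = (r["request_id"], r["helper_id"])
                t0 = starts[key].pop(0)
                intervals.setdefault(r["helper_id"], []).append((t0, r["t_min"]))
        for helper, ivs in intervals.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2, f"helper {helper} overlaps: {(s1, e1)} {(s2, e2)}"

    def test_resolved_requests_trace_to_helpful_rating(self, small_config):
        log, m = run_simulation(small_config)
        helpful = {
            r["request_id"]
            for r in log
            if r["event"] == "interaction_completed" and r["rating"] >= 4
        }
        assert len(helpful) == m.n_resolved

    def test_random_loads_exchangeable_wrt_latent_helpfulness(self, small_config):
        """Attempts served under random routing carry no signal about
        intrinsic helpfulness (Spearman test, pooled over seeds)."""
        from trailmap.metrics import helper_loads

        pooled_h, pooled_loads = [], []
        for seed in (1, 2, 3):
            cfg = small_config.with_(condition="random", seed=seed)
            log, _ = run_simulation(cfg)
            rng = np.random.default_rng(cfg.seed)
            _, helpers, _ = build_population(cfg, rng)  # same draws as the run
            pooled_h.extend(h.h_latent for h in helpers)
            pooled_loads.extend(helper_loads(log, basis="attempts"))
        rho, p = stats.spearmanr(pooled_h, pooled_loads)
        assert p > 0.01

    def test_adaptive_routing_raises_delivered_rating(self, small_config):
        """Paired over seeds: the adaptive condition's mean delivered rating
        beats random routing's."""
        diffs = []
        for seed in range(1, 11):
            _, m_t = run_simulation(small_config.with_(condition="trailmap", seed=seed))
            _, m_r = run_simulation(small_config.with_(condition="random", seed=seed))
            diffs.append(m_t.mean_rating - m_r.mean_rating)
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 9

    def test_alpha_zero_no_signal_matches_random(self, small_config):
        """With alpha = 0 the adaptive weights are uniform, so the load
        distribution is indistinguishable from random routing's."""
        from dataclasses import replace

        from trailmap.metrics import helper_loads

        loads_a, loads_r = [], []
        for seed in (1, 2, 3):
            cfg_a = small_config.with_(
                seed=seed,
                condition="trailmap",
                routing=replace(small_config.routing, alpha=0.0),
            )
            log_a, _ = run_simulation(cfg_a)
            loads_a.extend(helper_loads(log_a, basis="attempts"))
            log_r, _ = run_simulation(small_config.with_(seed=seed, condition="random"))
            loads_r.extend(helper_loads(log_r, basis="attempts"))
        _, p = stats.ks_2samp(loads_a, loads_r)
        assert p > 0.001

    def test_learning_curve_on_toy_community(self, monkeypatch):
        """With one clearly good helper and two bad ones (no rating noise),
        the adaptive condition's routing share to the good helper is
        non-decreasing across successive 5-day windows."""
        cfg = SimulationConfig(
            n_agents=4,
            seeker_proportion=0.25,
            helper_proportion=0.75,
            duration_hours=720.0,
            request_rate_per_seeker_per_day=3.0,
            interaction_duration_mean_min=6.0,
            rating_noise_sd=0.0,
            condition="trailmap",
            seed=2,
        )
        h_latents = [0.9, 0.2, 0.2]  # mu = 4.6, 1.8, 1.8

        def toy_population(config, rng):
            rng.beta(2, 5, 3)  # keep the stream layout of the real builder
            seekers = [SeekerAgent(id=0)]
            helpers = [
                HelperAgent(id=1 + j, h_latent=h) for j, h in enumerate(h_latents)
            ]
            return seekers, helpers, TrailTable(h.id for h in helpers)

        monkeypatch.setattr(sim, "build_population", toy_population)
        log, _ = run_simulation(cfg)
        window_min = 5 * 24 * 60.0
        shares = []
        routed = [r for r in log if r["event"] == "routed"]
        for w in range(6):
            in_w = [
                r for r in routed if w * window_min <= r["t_min"] < (w + 1) * window_min
            ]
            shares.append(
                sum(1 for r in in_w if r["helper_id"] == 1) / len(in_w)
            )
        assert all(b >= a - 1e-12 for a, b in zip(shares, shares[1:])), shares
        assert shares[-1] > 0.9
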