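import math

import numpy as np
import pandas as pd
import pytest

from rrlogistic import (
    DemographyParams,
    DispersalSpec,
    Domain,
    KernelSpec,
    MovementParams,
    PopulationState,
    SimConfig,
    death_rate,
    gillespie_step,
    initialize_population,
    run,
)
from rrlogistic import _engine
from rrlogistic.geometry_kernels import n_kernel_images
from rrlogistic.simulator import all_death_rates

from conftest import make_config


def random_state(n, rng, domain=None, spread=1.0):
    domain = domain or Domain()
    centres = domain.L * rng.random((n, 2))
    positions = centres + spread * 0.01 * rng.standard_normal((n, 2))
    return PopulationState(
        ids=np.arange(n), centres=centres, positions=np.mod(positions, domain.L),
        t=0.0, domain=domain,
    )


def engine_rates(state, demog, domain):
    """Death rates straight from the jitted kernels (cell list or all-pairs)."""
    N = state.N
    L = domain.L
    kern = demog.kernel
    rcut = kern.trunc_radius
    m_img = n_kernel_images(kern, domain)
    s2 = kern.sigma_q**2
    norm = 1.0 / (2 * math.pi * s2)
    px = np.ascontiguousarray(state.positions[:, 0])
    py = np.ascontiguousarray(state.positions[:, 1])
    out = np.zeros(N)
    ncell = min(int(L / rcut), 64) if rcut < L / 2 else 0
    if m_img == 0 and ncell >= 3:
        nc2 = ncell * ncell
        _engine._rates_cells(
            px, py, N, L, ncell, demog.d0, demog.gamma, s2, norm, rcut * rcut,
            np.zeros(N), np.zeros(N), np.zeros(N, dtype=np.int64),
            np.zeros(N, dtype=np.int64), np.zeros(nc2 + 1, dtype=np.int64),
            np.zeros(nc2, dtype=np.int64), np.zeros(N, dtype=np.int64), out,
        )
    else:
        _engine._rates_bruteforce(
            px, py, N, L, demog.d0, demog.gamma, s2, norm, rcut * rcut, m_img, out
        )
    return out


class TestDeathRate:
    def test_isolated_organism_feels_baseline_rate(self, domain):
        cfg = make_config()
        state = PopulationState(
            ids=[0], centres=[[0.5, 0.5]], positions=[[0.5, 0.5]], t=0.0, domain=domain
        )
        assert death_rate(0, state, cfg.demography) == pytest.approx(0.1)

    def test_coincident_pair_rate(self, domain):
        cfg = make_config()
        state = PopulationState(
            ids=[0, 1],
            centres=[[0.5, 0.5], [0.5, 0.5]],
            positions=[[0.5, 0.5], [0.5, 0.5]],
            t=0.0,
            domain=domain,
        )
        expected = 0.1 + 0.002 / (2 * math.pi * 1e-4)
        assert death_rate(0, state, cfg.demography) == pytest.approx(expected)
        assert expected == pytest.approx(3.2831, abs=1e-4)

    def test_competition_off_gives_baseline(self, domain, rng):
        cfg = make_config(gamma=0.0)
        state = random_state(40, rng)
        rates = all_death_rates(state, cfg.demography)
        assert np.allclose(rates, 0.1)

    @pytest.mark.parametrize("sigma_q", [0.01, 0.1, 0.8], ids=["cells", "coarse", "image-sum"])
    def test_engine_rates_match_bruteforce_reference(self, sigma_q, domain, rng):
        cfg = make_config(sigma_q=sigma_q)
        state = random_state(150, rng, spread=5.0)
        expected = all_death_rates(state, cfg.demography)
        got = engine_rates(state, cfg.demography, domain)
        assert np.allclose(got, expected, rtol=1e-12, atol=1e-12)


class TestInitialization:
    def test_initial_state_in_box(self, rng):
        cfg = make_config(n0=700)
        state = initialize_population(cfg, rng)
        assert state.N == 700
        assert np.all((state.centres >= 0) & (state.centres < 1))
        assert np.array_equal(state.positions, state.centres)  # sessile rule

    def test_empty_population_is_valid(self, rng):
        state = initialize_population(make_config(n0=0), rng)
        assert state.N == 0 and state.n == 0.0

    def test_centres_are_csr(self):
        from scipy import stats

        passes = 0
        for seed in range(100):
            state = initialize_population(make_config(n0=700), np.random.default_rng(seed))
            counts, _, _ = np.histogram2d(
                state.centres[:, 0], state.centres[:, 1], bins=10, range=[[0, 1], [0, 1]]
            )
            if stats.chisquare(counts.ravel()).pvalue > 0.01:
                passes += 1
        assert passes >= 97


class TestGillespieStep:
    def test_single_step_bookkeeping(self, domain, rng):
        cfg = make_config()
        state = random_state(30, rng)
        new, rec = gillespie_step(state, cfg.demography, cfg.movement, domain, rng)
        assert abs(new.N - state.N) == 1
        assert rec["event"] in ("birth", "death")
        assert new.t > state.t

    def test_no_birth_channel_population_never_grows(self, domain, rng):
        cfg = make_config(b=0.0, n0=20)
        state = random_state(20, rng)
        sizes = [state.N]
        for _ in range(15):
            if state.N == 0:
                break
            state, _ = gillespie_step(state, cfg.demography, cfg.movement, domain, rng)
            sizes.append(state.N)
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_extinct_state_rejected(self, domain, rng):
        cfg = make_config(n0=0)
        state = initialize_population(cfg, rng)
        with pytest.raises(ValueError):
            gillespie_step(state, cfg.demography, cfg.movement, domain, rng)

    def test_waiting_time_mean_for_lone_organism(self, domain):
        # N=1: total rate b + d0 = 1.6, mean waiting time 0.625
        cfg = make_config(n0=1)
        rng = np.random.default_rng(7)
        base = PopulationState(
            ids=[0], centres=[[0.5, 0.5]], positions=[[0.5, 0.5]], t=0.0, domain=domain
        )
        dts = []
        for _ in range(10_000):
            _, rec = gillespie_step(base, cfg.demography, cfg.movement, domain, rng)
            dts.append(rec["dt"])
        dts = np.asarray(dts)
        target = 1.0 / (1.5 + 0.1)
        se = dts.std(ddof=1) / math.sqrt(len(dts))
        assert abs(dts.mean() - target) < 4 * se

    def test_event_first_order_also_steps(self, domain, rng):
        cfg = make_config()
        state = random_state(25, rng)
        new, rec = gillespie_step(
            state, cfg.demography, cfg.movement, domain, rng, order="event_first"
        )
        assert abs(new.N - state.N) == 1


class TestRun:
    def test_same_seed_is_bit_identical(self):
        cfg = make_config(n0=60, events=2_000)
        a = run(cfg, seed=5)
        b = run(cfg, seed=5)
        assert a.abundance.equals(b.abundance)
        assert np.array_equal(a.final_state.positions, b.final_state.positions)
        assert np.array_equal(a.final_state.ids, b.final_state.ids)

    def test_event_count_conservation(self):
        cfg = make_config(n0=80, events=3_000)
        res = run(cfg, seed=2)
        births = int((res.abundance["event"] == 1).sum())
        deaths = int((res.abundance["event"] == -1).sum())
        assert births - deaths == res.final_state.N - cfg.n0
        assert np.all(np.abs(np.diff(res.abundance["N"])) == 1)
        assert res.abundance["N"].iloc[0] in (cfg.n0 - 1, cfg.n0 + 1)

    @pytest.mark.parametrize(
        "mode,kwargs,events",
        [
            ("SESSILE", {}, 400),
            ("OU", {"tau": 0.05, "sigma_r2": 0.002}, 200),
            ("BM", {"D": 0.5}, 200),
        ],
        ids=["SESSILE", "OU", "BM"],
    )
    def test_engine_matches_reference_path(self, mode, kwargs, events):
        # the jitted engine and the NumPy reference consume one RNG stream:
        # identical event sequences, waiting times equal to rounding
        cfg = make_config(mode=mode, n0=40, events=events, **kwargs)
        fast = run(cfg, seed=13)
        ref = run(cfg, seed=13, method="reference")
        assert np.array_equal(fast.abundance["event"], ref.abundance["event"])
        assert np.allclose(fast.abundance["t"], ref.abundance["t"], rtol=1e-9)
        assert sorted(fast.final_state.ids) == sorted(ref.final_state.ids)

    def test_gamma_dispersal_variant_runs(self):
        cfg = make_config(n0=60, events=1_500, dispersal_family="gamma_distance")
        fast = run(cfg, seed=3)
        ref = run(cfg, seed=3, method="reference")
        assert np.array_equal(fast.abundance["event"], ref.abundance["event"])

    def test_sessile_positions_are_bit_invariant(self):
        # D = 0: an organism's position never changes after establishment
        cfg = make_config(n0=80, events=2_000)
        rng = np.random.default_rng(21)
        initial = initialize_population(cfg, rng)
        res = run(cfg, seed=21)
        final = res.final_state
        surviving = np.isin(final.ids, initial.ids)
        for idx in np.flatnonzero(surviving):
            orig = int(final.ids[idx])
            assert np.array_equal(final.positions[idx], initial.positions[orig])
            assert np.array_equal(final.centres[idx], initial.centres[orig])

    def test_short_range_dispersal_collapses_population(self):
        cfg = make_config(sigma_q=1e-3, sigma_d=1e-3, events=100_000)
        res = run(cfg, seed=0)
        assert res.extinct or res.final_state.N < 100

    def test_capacity_growth_resumes_transparently(self):
        # pure birth process quadruples past the initial allocation
        cfg = make_config(n0=300, gamma=0.0, d0=0.0, events=1_300)
        res = run(cfg, seed=1)
        assert res.final_state.N == 300 + 1_300
        assert np.all(res.abundance["event"] == 1)

    def test_record_stride_thins_series_keeping_endpoint(self):
        import dataclasses

        full_cfg = make_config(n0=60, events=1_000)
        thin_cfg = dataclasses.replace(full_cfg, record_stride=7)
        full = run(full_cfg, seed=8)
        thin = run(thin_cfg, seed=8)
        assert len(thin.abundance) == math.ceil(1_000 / 7)
        assert thin.abundance["t"].iloc[-1] == full.abundance["t"].iloc[-1]
        assert thin.abundance["N"].iloc[-1] == full.abundance["N"].iloc[-1]
        assert np.array_equal(thin.final_state.positions, full.final_state.positions)

    def test_extinction_terminates_run(self):
        cfg = make_config(b=0.0, n0=10, events=100_000)
        res = run(cfg, seed=4)
        assert res.extinct
        assert res.events_run < cfg.events
        assert res.abundance["N"].iloc[-1] == 0


class TestMeanFieldLimit:
    def test_flat_kernel_recovers_nonspatial_logistic(self):
        # sigma_q comparable to the box makes the image-summed kernel 1/A:
        # death rates depend on N only and the chain obeys the exact
        # quasistationary identity E[N^2]/E[N] = (b-d0)/gamma + 1
        cfg = make_config(sigma_q=0.8, gamma=0.02, n0=70, events=50_000)
        ratios = []
        for seed in range(4):
            res = run(cfg, seed=seed)
            ab = res.abundance
            frm = len(ab) // 2
            t = ab["t"].to_numpy()[frm:]
            n = ab["N"].to_numpy()[frm:].astype(float)
            w = np.diff(t)
            ratios.append(np.sum(n[:-1] ** 2 * w) / np.sum(n[:-1] * w))
        ratios = np.asarray(ratios)
        target = (1.5 - 0.1) / 0.02 + 1.0
        se = ratios.std(ddof=1) / math.sqrt(len(ratios))
        assert abs(ratios.mean() - target) < 3 * se
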