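"""Brownian single-file channel: dynamics, reservoirs, flux estimators."""

import math
from dataclasses import replace

import numpy as np
import pytest

from singlefile import channel_sim as cs
from singlefile._kernels import SCHEME_METROPOLIS
from singlefile.errors import DomainError


def block_mean_se(blocks):
    return float(np.mean(blocks)), float(np.std(blocks, ddof=1) / math.sqrt(len(blocks)))


class TestConfig:
    def test_resolution_condition_enforced(self):
        with pytest.raises(DomainError, match="resolution"):
            cs.ChannelConfig(dt=1.0)  # sqrt(2*1*1) = 1.41 > a/4

    def test_boundary_zone_minimum(self):
        with pytest.raises(DomainError, match="boundary_zone"):
            cs.ChannelConfig(boundary_zone=0.2)

    def test_defaults_derived_from_geometry(self):
        cfg = cs.ChannelConfig(L=12.0)
        assert cfg.t_burn == pytest.approx(5 * 12.0 ** 2)
        assert cfg.boundary_zone == cfg.a

    def test_reservoir_density_from_activity(self):
        # ideal reservoir activity equals rho; channel at phi has
        # activity (phi/a) exp(mu_ex)
        rho = cs.reservoir_density_for_occupancy(0.5, a=2.0)
        assert rho == pytest.approx(0.25 * math.exp(1 + math.log(2)))
        assert cs.reservoir_density_for_occupancy(0.0) == 0.0


class TestStep:
    def test_order_preserved_and_gaps_enforced(self, rng):
        cfg = cs.ChannelConfig(L=10.0)
        state = cs.new_state([2.0, 3.2, 4.4, 6.0, 8.0], [1, 0, 1, 0, 0])
        for _ in range(500):
            state = cs.step(state, cfg, rng)
            assert np.all(np.diff(state.positions) >= cfg.a - 1e-12)

    def test_single_rod_free_diffusion_msd(self, rng):
        """A lone rod far from the boundaries obeys <dx^2> = 2*D0*t."""
        cfg = cs.ChannelConfig(L=2000.0, t_run=1.0)
        disps = []
        for _ in range(400):
            state = cs.new_state([1000.0])
            for _ in range(25):
                state = cs.step(state, cfg, rng)
            disps.append(state.positions[0] - 1000.0)
        msd = np.mean(np.square(disps))
        expect = 2 * cfg.D0 * 25 * cfg.dt
        se = expect * math.sqrt(2 / len(disps))
        assert abs(msd - expect) < 3 * se

    def test_absorption_counted(self, rng):
        cfg = cs.ChannelConfig(L=10.0)
        rec = cs.FluxRecord()
        state = cs.new_state([0.01, 9.99], [1, 0])
        for _ in range(200):
            state = cs.step(state, cfg, rng, rec)
        assert state.n + rec.crossings_left + rec.crossings_right == 2

    def test_metropolis_never_overlaps(self, rng):
        cfg = cs.ChannelConfig(L=10.0, scheme=SCHEME_METROPOLIS)
        state = cs.new_state([2.0, 3.05, 4.1, 5.15], [0, 0, 0, 0])
        for _ in range(500):
            state = cs.step(state, cfg, rng)
            assert np.all(np.diff(state.positions) >= cfg.a)


class TestReservoirExchange:
    def test_empty_reservoirs_drain_channel(self):
        cfg = cs.ChannelConfig(rho_left=0.0, rho_right=0.0, t_run=2000.0, seed=1)
        data = cs.simulate_blocks(cfg)
        assert data.phi_hat == 0.0

    def test_insertions_labelled_by_origin(self, rng):
        cfg = cs.ChannelConfig(rho_left=50.0, rho_right=0.0)
        state = cs.new_state([])
        rec = cs.FluxRecord()
        for _ in range(200):
            state = cs.exchange_with_reservoirs(state, cfg, rng, rec)
            state = cs.step(state, cfg, rng, rec)
        assert rec.insertions_left > 0 and rec.insertions_right == 0
        assert np.all(state.labels == 1)

    def test_particle_conservation_exact(self, rng):
        cfg = cs.ChannelConfig(rho_left=20.0, rho_right=20.0)
        state = cs.new_state([])
        rec = cs.FluxRecord()
        for _ in range(2000):
            state = cs.step(state, cfg, rng, rec)
            state = cs.exchange_with_reservoirs(state, cfg, rng, rec)
        inserted = rec.insertions_left + rec.insertions_right
        removed = rec.crossings_left + rec.crossings_right
        assert state.n == inserted - removed


@pytest.fixture(scope="module")
def eq_data():
    rho = cs.calibrate_reservoir_density(0.3, seed=5)
    cfg = cs.ChannelConfig(
        rho_left=rho, rho_right=rho, t_run=2.0e6, seed=5, n_bins=20
    )
    return cs.simulate_blocks(cfg)


class TestEquilibrium:
    def test_zero_net_flux(self, eq_data):
        mean, se = block_mean_se(eq_data.block_net_flux() / eq_data.cfg.rho_left)
        assert abs(mean) < 3 * se

    def test_interior_profile_flat(self, eq_data):
        """Away from the boundary zones the steady profile has no gradient."""
        h = eq_data.hist.astype(float)
        hn = h / h.sum(axis=1, keepdims=True)
        interior = slice(6, 14)  # exclude 3a next to each boundary
        mean = hn.mean(axis=0)[interior]
        se = hn.std(axis=0, ddof=1)[interior] / math.sqrt(len(hn))
        z = (mean - mean.mean()) / se
        assert np.max(np.abs(z)) < 3.0

    def test_occupancy_near_target(self, eq_data):
        assert eq_data.phi_hat == pytest.approx(0.3, abs=0.03)


class TestSchemeEquivalence:
    def test_sort_and_metropolis_profiles_agree(self):
        """The two standard single-file updates share the stationary profile."""
        rho = cs.calibrate_reservoir_density(0.3, seed=6)
        profiles = []
        for scheme in (cs.SCHEME_SORT, SCHEME_METROPOLIS):
            cfg = cs.ChannelConfig(
                rho_left=rho, rho_right=rho, t_run=2.0e6, seed=6,
                n_bins=20, scheme=scheme,
            )
            data = cs.simulate_blocks(cfg)
            h = data.hist.astype(float)
            profiles.append(h / h.sum(axis=1, keepdims=True))
        interior = slice(4, 16)
        za, zb = profiles
        diff = za.mean(axis=0)[interior] - zb.mean(axis=0)[interior]
        se = np.sqrt(
            za.std(axis=0, ddof=1)[interior] ** 2 / za.shape[0]
            + zb.std(axis=0, ddof=1)[interior] ** 2 / zb.shape[0]
        )
        assert np.max(np.abs(diff / se)) < 4.0


class TestFluxMeasurement:
    def test_pd_requires_equal_reservoirs(self):
        cfg = cs.ChannelConfig(rho_left=0.3, rho_right=0.2)
        with pytest.raises(DomainError):
            cs.measure_pd(cfg)

    def test_pf_requires_drive(self):
        cfg = cs.ChannelConfig(rho_left=0.3, rho_right=0.3)
        with pytest.raises(DomainError):
            cs.measure_pf(cfg)

    def test_flux_antisymmetric_under_reservoir_swap(self):
        cfg = cs.ChannelConfig(
            rho_left=0.40, rho_right=0.36, t_run=1.0e6, seed=21
        )
        fwd = cs.simulate_blocks(cfg)
        rev = cs.simulate_blocks(
            replace(cfg, rho_left=cfg.rho_right, rho_right=cfg.rho_left, seed=22)
        )
        jf, sf = block_mean_se(fwd.block_net_flux())
        jr, sr = block_mean_se(rev.block_net_flux())
        assert jf > 0 > jr
        assert abs(jf + jr) < 3 * math.hypot(sf, sr)

    def test_se_shrinks_with_run_length(self):
        rho = cs.reservoir_density_for_occupancy(0.2)
        short = cs.measure_pd(
            cs.ChannelConfig(rho_left=rho, rho_right=rho, t_run=4.0e5, seed=31)
        )
        long = cs.measure_pd(
            cs.ChannelConfig(rho_left=rho, rho_right=rho, t_run=1.6e6, seed=31)
        )
        # four times the data should halve the standard error, roughly
        assert 0.25 < long.se / short.se < 0.85

    def test_insufficient_statistics_flagged(self):
        cfg = cs.ChannelConfig(rho_left=0.02, rho_right=0.02, t_run=2e3, seed=41)
        est = cs.measure_pd(cfg)
        assert est.insufficient

    def test_linear_response_through_origin(self):
        """Net flux is linear in the density difference for small drives."""
        rho = cs.calibrate_reservoir_density(0.3, L=8.0, seed=42)
        drives = [0.02, 0.05, 0.1]
        J = []
        for i, d in enumerate(drives):
            cfg = cs.ChannelConfig(
                L=8.0, rho_left=rho * (1 + d / 2), rho_right=rho * (1 - d / 2),
                t_run=2.4e7, seed=100 + i,
            )
            J.append(float(np.mean(cs.simulate_blocks(cfg).block_net_flux())))
        J = np.array(J)
        x = rho * np.array(drives)
        slope = float(np.sum(x * J) / np.sum(x * x))
        r2 = 1.0 - np.sum((J - slope * x) ** 2) / np.sum((J - J.mean()) ** 2)
        assert r2 > 0.99

    def test_oversized_drive_warns(self):
        cfg = cs.ChannelConfig(rho_left=0.5, rho_right=0.3, t_run=2e4, seed=51)
        with pytest.warns(cs.LinearResponseWarning):
            est = cs.measure_pf(cfg)
        assert "linear-response" in est.flags


class TestEmpiricalRatio:
    def test_paired_measurement_structure(self):
        cfg = cs.ChannelConfig.for_occupancy(0.25, drive=0.1, t_run=2.0e5, seed=61)
        rr = cs.empirical_ratio(cfg)
        assert rr.pf.value > 0 and rr.pd.value > 0
        assert rr.ratio == pytest.approx(rr.pf.value / rr.pd.value)
        assert rr.predicted_ratio > 1.0
        assert math.isfinite(rr.discrepancy_se)

    def test_needs_drive(self):
        cfg = cs.ChannelConfig(rho_left=0.3, rho_right=0.3)
        with pytest.raises(DomainError):
            cs.empirical_ratio(cfg)


class TestTracerMsd:
    def test_diffusive_scaling(self):
        t, msd = cs.tracer_msd(n_steps=20_000, every=20, n_reps=100, seed=2)
        slope = cs.fit_msd_slope(t, msd)
        assert slope == pytest.approx(2.0, rel=0.05)
        exponent = np.polyfit(np.log(t[:40]), np.log(msd[:40]), 1)[0]
        assert exponent == pytest.approx(1.0, abs=0.1)
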