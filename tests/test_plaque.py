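"""Radial grid, finite-volume diffusion, and plaque integration."""

import numpy as np
import pytest
from dataclasses import replace

from linphage.fixtures import gaussian_profile, heat_kernel_2d
from linphage.plaque import (
    PlaqueParams,
    RadialGrid,
    initial_plaque_state,
    radial_diffusion,
    simulate_plaque,
)
from scipy.integrate import solve_ivp

#: Reduced-size domain for tests that integrate but do not measure radii.
SMALL = dict(R_max=3000.0, dr=20.0, t_end=120.0)


class TestRadialGrid:
    def test_areas_tile_the_disc(self):
        g = RadialGrid(dr=20.0, M=500)
        assert g.areas.sum() == pytest.approx(np.pi * g.R_max**2, rel=1e-12)

    def test_first_centre_off_origin(self):
        g = RadialGrid(dr=20.0, M=10)
        assert g.r[0] == pytest.approx(10.0)


class TestRadialDiffusion:
    def test_uniform_field_has_zero_rate(self):
        g = RadialGrid(dr=20.0, M=100)
        rate = radial_diffusion(np.full(100, 3.7), 240.0, g)
        assert np.allclose(rate, 0.0, atol=1e-18)

    def test_exact_conservation(self):
        g = RadialGrid(dr=20.0, M=200)
        rng = np.random.default_rng(42)
        field = rng.random(200)
        rate = radial_diffusion(field, 240.0, g)
        assert abs(np.sum(g.areas * rate)) < 1e-9 * np.abs(g.areas * rate).max()

    def test_negative_diffusivity_rejected(self):
        g = RadialGrid(dr=20.0, M=10)
        with pytest.raises(ValueError):
            radial_diffusion(np.zeros(10), -1.0, g)

    def test_gaussian_matches_heat_kernel(self):
        """Free spreading of a Gaussian follows the 2-D heat kernel to
        within 2% of the peak at dr = 20 µm."""
        D, sigma0, t_end = 240.0, 300.0, 200.0
        g = RadialGrid(dr=20.0, M=300)  # boundary far beyond the pulse
        y0 = gaussian_profile(g, sigma=sigma0)
        sol = solve_ivp(
            lambda t, y: radial_diffusion(y, D, g),
            (0.0, t_end),
            y0,
            method="LSODA",
            rtol=1e-8,
            atol=1e-14,
        )
        exact = heat_kernel_2d(g.r, t_end, D, sigma0)
        err = np.abs(sol.y[:, -1] - exact).max() / exact.max()
        assert err < 0.02


class TestInitialState:
    def test_single_seeded_cell(self):
        p = PlaqueParams.default("r_mutant")
        f = initial_plaque_state(p)
        assert np.sum(f.grid.areas * f.I[0]) == pytest.approx(1.0, rel=1e-12)
        assert not f.I[1:].any()

    def test_uniform_lawn_and_nutrient_totals(self):
        p = PlaqueParams.default("lin_phage")
        f = initial_plaque_state(p)
        area = np.pi * p.R_max**2
        assert np.sum(f.grid.areas * f.B) == pytest.approx(p.B0 * area, rel=1e-12)
        assert np.sum(f.grid.areas * f.n) == pytest.approx(p.n0 * area, rel=1e-12)
        assert not f.phage.any()
        assert f.L is not None and not f.L.any()


class TestSimulatePlaque:
    def test_uniform_limit_equals_batch_growth(self):
        """Without a seeded infection the lawn grows uniformly, converting
        nutrient to cells exactly as the batch model does."""
        p = PlaqueParams.default("r_mutant", **SMALL)
        init = initial_plaque_state(p)
        init.I[:] = 0.0
        res = simulate_plaque(p, sample_times=[0.0, 120.0], init=init)
        f = res.fields[-1]
        assert np.ptp(f.B) / f.B.max() < 1e-9  # stays uniform
        assert not f.phage.any()
        # uniform field obeys dB/dt = g(n)B, dn/dt = -g(n)B
        expected_total = p.B0 + p.n0
        assert f.B[0] + f.n[0] == pytest.approx(expected_total, rel=1e-6)
        assert f.B[0] > p.B0 * np.exp(0.030 * 120.0 / 2)  # grew substantially

    def test_nutrient_total_nonincreasing(self, mp0_result):
        g = mp0_result.params.grid
        totals = [np.sum(g.areas * f.n) for f in mp0_result.fields]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(totals, totals[1:]))

    def test_fields_nonnegative(self, mp1_result):
        for f in mp1_result.fields:
            for arr in (f.B, f.n, f.phage, f.I, f.L):
                assert arr.min() >= 0.0

    def test_cell_bookkeeping(self, mp0_result):
        """Total intact cells change only through division (bounded by
        nutrient use) and lysis: B_tot never exceeds B0 + n0 consumed."""
        p = mp0_result.params
        g = p.grid
        for f in mp0_result.fields:
            cells = np.sum(g.areas * f.B_tot)
            nutrient_used = np.sum(g.areas * (p.n0 - f.n))
            # lawn + the one seeded infected cell + cells built from nutrient
            budget = np.sum(g.areas) * p.B0 + 1.0 + nutrient_used
            assert cells <= budget * (1 + 1e-9)

    def test_lin_reduces_to_r_mutant_without_secondary_adsorption(self):
        """MP1 with f_tau = f_beta = 1 and the secondary-adsorption terms
        switched off is MP0 in different clothing."""
        p0 = PlaqueParams.default("r_mutant", **SMALL)
        p1 = PlaqueParams.default("lin_phage", **SMALL)
        p1 = replace(p1, secondary_adsorption=False)
        r0 = simulate_plaque(p0, sample_times=[0.0, 60.0, 120.0])
        r1 = simulate_plaque(p1, sample_times=[0.0, 60.0, 120.0])
        for f0, f1 in zip(r0.fields, r1.fields):
            for a, b in ((f0.B, f1.B), (f0.n, f1.n), (f0.phage, f1.phage)):
                scale = max(np.abs(a).max(), 1e-30)
                assert np.abs(a - b).max() / scale < 1e-5
            # the lysis-inhibited chain stays empty up to integrator noise
            assert np.abs(f1.L).max() < 1e-12

    def test_grid_refinement_converges(self):
        """Halving dr moves the visible-plaque radius by < 2%."""
        from linphage.metrics import front_radii

        radii = {}
        for dr in (20.0, 10.0):
            p = PlaqueParams.default("r_mutant", R_max=4000.0, dr=dr, t_end=150.0)
            res = simulate_plaque(p, sample_times=[0.0, 150.0])
            radii[dr] = front_radii(res.fields[-1], p.B0).r_half
        assert radii[10.0] == pytest.approx(radii[20.0], rel=0.02)

    def test_sample_times_beyond_t_end_rejected(self):
        p = PlaqueParams.default("r_mutant", **SMALL)
        with pytest.raises(ValueError):
            simulate_plaque(p, sample_times=[0.0, 500.0])
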