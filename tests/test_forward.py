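"""Three-stream forward model: closed forms, residuals, oracle, diagnostics."""

import numpy as np
import pytest

import tristream as ts
from tristream.errors import DegenerateProfileError, InvalidInputError
from tristream.forward import residuals
from conftest import random_geometry, random_physical_iops


def _one_band_grid():
    return ts.WavelengthGrid((490.0,))


def _bc(grid, e_dir=0.7, e_dif=0.3):
    n = len(grid)
    return ts.SurfaceBoundary(
        grid, e_dir * np.ones(n), e_dif * np.ones(n), par=500.0, sun_zenith=30.0
    )


class TestAnalyticProfile:
    def test_direct_beam_attenuation_closed_form(self):
        grid = _one_band_grid()
        iops = ts.BulkIOP(grid, np.array([0.1]), np.array([0.2]), np.array([0.0]))
        geom = ts.GeometryParams(cos_theta_d=0.8)
        sol = ts.analytic_profile(iops, geom, _bc(grid))
        assert sol.c_dir[0] == pytest.approx(0.375, abs=1e-15)

    def test_pure_absorber_streams_decouple(self):
        grid = _one_band_grid()
        a = 0.25
        iops = ts.BulkIOP(grid, np.array([a]), np.array([0.0]), np.array([0.0]))
        geom = ts.GeometryParams(cos_theta_d=0.9, v_dif=0.83)
        sol = ts.analytic_profile(iops, geom, _bc(grid))
        z = np.array([0.0, 2.0, 10.0])
        e_dir, e_dif, e_u = sol.evaluate(z)
        np.testing.assert_allclose(e_dir.ravel(), 0.7 * np.exp(-a * z / 0.9), rtol=1e-14)
        np.testing.assert_allclose(e_dif.ravel(), 0.3 * np.exp(-a * z / 0.83), rtol=1e-14)
        np.testing.assert_allclose(e_u.ravel(), 0.0, atol=1e-18)

    def test_residuals_vanish_for_reference_case(self, ref_cfg, geom, boundary):
        x = ts.ConstituentVector(1.0, 20.0, 10.0)
        iops = ts.bulk_iops(x, 500.0, ref_cfg)
        sol = ts.analytic_profile(iops, geom, boundary)
        res = residuals(sol, iops, geom, [0.0, 1.0, 5.0, 20.0, 50.0])
        assert res.max() <= 1e-8

    def test_residual_invariant_random_draws(self, ref_cfg):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            iops = random_physical_iops(rng, ref_cfg.grid)
            g = random_geometry(rng)
            sol = ts.analytic_profile(iops, g, _bc(ref_cfg.grid))
            z = rng.uniform(0.0, 80.0, 20)
            assert residuals(sol, iops, g, z).max() <= 1e-8

    def test_positivity_and_decay(self, ref_cfg):
        rng = np.random.default_rng(7)
        for _ in range(50):
            iops = random_physical_iops(rng, ref_cfg.grid)
            g = random_geometry(rng)
            sol = ts.analytic_profile(iops, g, _bc(ref_cfg.grid))
            z_deep = 40.0 / sol.k_plus.min()
            z = np.linspace(0.0, z_deep, 200)
            e_dir, e_dif, e_u = sol.evaluate(z)
            surface_total = float((e_dir + e_dif + e_u)[0].sum())
            for stream in (e_dir, e_dif, e_u):
                assert np.all(stream >= -1e-12)
                # all streams vanish at depth
                assert np.all(stream[-1] <= 1e-12 * surface_total)

    def test_nonpositive_absorption_rejected(self, geom):
        grid = _one_band_grid()
        with pytest.raises(InvalidInputError):
            iops = ts.BulkIOP(grid, np.array([0.0]), np.array([0.1]), np.array([0.01]))
            ts.analytic_profile(iops, geom, _bc(grid))


class TestNumericOracle:
    def test_pure_absorber_matches_closed_form(self):
        grid = _one_band_grid()
        a = 0.2
        iops = ts.BulkIOP(grid, np.array([a]), np.array([0.0]), np.array([0.0]))
        geom = ts.GeometryParams(cos_theta_d=1.0, v_dif=0.83)
        z, e_dir, e_dif, e_u = ts.numeric_oracle(iops, geom, _bc(grid), z_max=150.0)
        np.testing.assert_allclose(
            e_dif[:, 0], 0.3 * np.exp(-a * z / 0.83), atol=1e-8
        )
        np.testing.assert_allclose(e_u[:, 0], 0.0, atol=1e-8)

    def test_agreement_with_analytic_reference_case(self, ref_cfg, geom, boundary):
        x = ts.ConstituentVector(1.0, 20.0, 10.0)
        iops = ts.bulk_iops(x, 500.0, ref_cfg)
        sol = ts.analytic_profile(iops, geom, boundary)
        z_ck = np.array([0.0, 1.0, 5.0, 20.0, 50.0])
        z, e_dir_n, e_dif_n, e_u_n = ts.numeric_oracle(iops, geom, boundary, z_max=400.0)
        e_dir_a, e_dif_a, e_u_a = sol.evaluate(z)
        scale = (e_dir_a + e_dif_a + e_u_a).max()
        assert np.max(np.abs(e_dif_a - e_dif_n)) / scale <= 1e-6
        assert np.max(np.abs(e_u_a - e_u_n)) / scale <= 1e-6
        # Kd from the analytic profile matches the oracle's ln-slope
        kd = ts.kd_between_depths(sol, 4.0, 9.0)
        i4, i9 = np.argmin(np.abs(z - 4)), np.argmin(np.abs(z - 9))
        ed_n = e_dir_n + e_dif_n
        kd_num = np.log(ed_n[i4] / ed_n[i9]) / (z[i9] - z[i4])
        np.testing.assert_allclose(kd, kd_num, atol=1e-6)

    def test_agreement_random_draws(self, ref_cfg):
        import warnings as _warnings

        grid = _one_band_grid()
        rng = np.random.default_rng(99)
        for _ in range(10):
            iops = random_physical_iops(rng, grid)
            g = random_geometry(rng)
            bc = _bc(grid)
            sol = ts.analytic_profile(iops, g, bc)
            # 35 e-foldings of the true decaying mode suffice; the oracle's
            # own screen uses the conservative a/v_dif bound and may warn
            z_max = 35.0 / sol.k_plus[0]
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                z, _, e_dif_n, e_u_n = ts.numeric_oracle(iops, g, bc, z_max=z_max)
            e_dir_a, e_dif_a, e_u_a = sol.evaluate(z)
            scale = (e_dir_a + e_dif_a + e_u_a).max()
            assert np.max(np.abs(e_dif_a - e_dif_n.ravel())) / scale <= 1e-6
            assert np.max(np.abs(e_u_a - e_u_n.ravel())) / scale <= 1e-6

    def test_shallow_domain_warns(self, ref_cfg, geom, boundary):
        iops = ts.bulk_iops(ts.ConstituentVector(0.1, 1, 1), 500.0, ref_cfg)
        with pytest.warns(UserWarning, match="too shallow"):
            ts.numeric_oracle(iops, geom, boundary, z_max=5.0)


class TestSurfaceTransfer:
    def test_zero_upwelling_gives_zero_rrs(self):
        grid = _one_band_grid()
        iops = ts.BulkIOP(grid, np.array([0.3]), np.array([0.0]), np.array([0.0]))
        geom = ts.GeometryParams()
        sol = ts.analytic_profile(iops, geom, _bc(grid))
        for mode in ("interface", "identity"):
            assert ts.surface_transfer(sol, geom, mode=mode) == pytest.approx(0.0)

    def test_interface_transfer_hand_value(self, ref_cfg, geom, boundary):
        # subsurface ratio 0.04/Q with Q=4 -> r=0.01 -> 0.0052/(1-0.017)
        x = ts.ConstituentVector(1.0, 20.0, 10.0)
        iops = ts.bulk_iops(x, 500.0, ref_cfg)
        sol = ts.analytic_profile(iops, geom, boundary)
        identity = ts.surface_transfer(sol, geom, mode="identity")
        interface = ts.surface_transfer(sol, geom, mode="interface")
        np.testing.assert_allclose(
            interface, 0.52 * identity / (1 - 1.7 * identity), rtol=1e-14
        )
        # frozen hand evaluation of the transfer formula at r = 0.01
        r = 0.01
        assert 0.52 * r / (1 - 1.7 * r) == pytest.approx(0.005290, abs=5e-7)

    def test_raman_hook_multiplies(self, ref_cfg, geom, boundary):
        iops = ts.bulk_iops(ts.ConstituentVector(1, 2, 3), 500.0, ref_cfg)
        sol = ts.analytic_profile(iops, geom, boundary)
        base = ts.surface_transfer(sol, geom)
        doubled = ts.surface_transfer(sol, geom, raman_factor=lambda lam: 2.0)
        np.testing.assert_allclose(doubled, 2 * base)

    def test_dark_band_raises_listing_wavelengths(self, ref_cfg, geom):
        n = len(ref_cfg.grid)
        e = np.ones(n)
        e_dark = e.copy()
        e_dark[0] = 0.0
        bc = ts.SurfaceBoundary(ref_cfg.grid, 0.0 * e, e_dark, 500.0, 30.0)
        iops = ts.bulk_iops(ts.ConstituentVector(1, 2, 3), 500.0, ref_cfg)
        sol = ts.analytic_profile(iops, geom, bc)
        with pytest.raises(DegenerateProfileError, match="412.5"):
            ts.surface_transfer(sol, geom)

    def test_rrs_monotone_in_backscatter_and_absorption(self, ref_cfg, geom, boundary):
        x = ts.ConstituentVector(0.5, 1.0, 2.0)
        iops = ts.bulk_iops(x, 500.0, ref_cfg)

        def rrs_of(iops_):
            sol = ts.analytic_profile(iops_, geom, boundary)
            return ts.surface_transfer(sol, geom)

        base = rrs_of(iops)
        more_bb = ts.BulkIOP(iops.grid, iops.a, iops.b, 2.0 * iops.b_b)
        more_a = ts.BulkIOP(iops.grid, 1.2 * iops.a, iops.b, iops.b_b)
        assert np.all(rrs_of(more_bb) > base)
        assert np.all(rrs_of(more_a) < base)


class TestKd:
    def test_direct_only_limit(self):
        grid = _one_band_grid()
        iops = ts.BulkIOP(grid, np.array([0.1]), np.array([0.0]), np.array([0.0]))
        geom = ts.GeometryParams(cos_theta_d=1.0)
        sol = ts.analytic_profile(iops, geom, _bc(grid, e_dir=1.0, e_dif=0.0))
        assert ts.kd_between_depths(sol, 4.0, 9.0)[0] == pytest.approx(0.1, abs=1e-14)
        assert ts.kd_between_depths(sol, 0.0, 30.0)[0] == pytest.approx(0.1, abs=1e-14)

    def test_diffuse_only_limit(self):
        grid = _one_band_grid()
        iops = ts.BulkIOP(grid, np.array([0.083]), np.array([0.0]), np.array([0.0]))
        geom = ts.GeometryParams(v_dif=0.83)
        sol = ts.analytic_profile(iops, geom, _bc(grid, e_dir=0.0, e_dif=1.0))
        assert ts.kd_between_depths(sol, 4.0, 9.0)[0] == pytest.approx(0.1, abs=1e-14)

    def test_absorption_only_kd_between_the_two_stream_limits(self):
        grid = _one_band_grid()
        a, cos_d, v_dif = 0.2, 0.95, 0.80
        iops = ts.BulkIOP(grid, np.array([a]), np.array([0.0]), np.array([0.0]))
        geom = ts.GeometryParams(cos_theta_d=cos_d, v_dif=v_dif)
        sol = ts.analytic_profile(iops, geom, _bc(grid))
        kd = ts.kd_between_depths(sol, 2.0, 7.0)[0]
        assert a / cos_d <= kd <= a / v_dif

    def test_bad_depth_order_rejected(self, ref_cfg, geom, boundary):
        iops = ts.bulk_iops(ts.ConstituentVector(1, 2, 3), 500.0, ref_cfg)
        sol = ts.analytic_profile(iops, geom, boundary)
        with pytest.raises(InvalidInputError):
            ts.kd_between_depths(sol, 9.0, 4.0)


class TestBbp:
    def test_cdom_only_gives_zero(self, ref_cfg):
        np.testing.assert_allclose(
            ts.bbp_model(ts.ConstituentVector(0, 7.3, 0), 500.0, ref_cfg), 0.0
        )

    def test_unit_chlorophyll_value(self, ref_cfg):
        bbp = ts.bbp_model(ts.ConstituentVector(1, 0, 0), 500.0, ref_cfg)
        assert bbp[1] == pytest.approx(5.18e-5 * 50, rel=1e-9)

    def test_nap_only_550nm_power_law(self):
        cfg_550 = _cfg_with_550()
        bbp = ts.bbp_model(ts.ConstituentVector(0, 0, 10), 500.0, cfg_550)
        assert bbp[-1] == pytest.approx(10 * 1.4375e-4, rel=1e-9)


def _cfg_with_550():
    """REF-like configuration on a grid that includes 550 nm exactly."""
    ref = ts.BioOpticalConfig.ref()
    grid = ts.WavelengthGrid((412.5, 550.0))
    take = np.array([0, 4])  # reuse 412.5 and (approximately) 555 rows
    water = ts.WaterIOP(
        grid, ref.water.a_w[take], ref.water.b_w[take], ref.water.b_bw[take]
    )
    phyto = ts.PhytoOpticalParams(
        grid,
        ref.phyto.a_star_ph[take],
        ref.phyto.b_star_ph[take],
        ref.phyto.b_star_bph[take],
    )
    return ts.BioOpticalConfig(grid=grid, water=water, phyto=phyto)
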