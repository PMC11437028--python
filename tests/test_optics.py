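"""Bio-optical parameterisations: spectral laws, photoacclimation, bulk IOPs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tristream as ts
from tristream.errors import ConfigError, InvalidInputError
from tristream.optics import perturb_phyto_optics


class TestSpectralLaws:
    @pytest.mark.parametrize(
        "lam, expected",
        [
            (450.0, 0.015),          # reference wavelength value
            (412.5, 0.028376184),    # hand evaluation of the exponential law
            (555.0, 0.0025169559),
        ],
    )
    def test_cdom_specific_absorption(self, lam, expected):
        assert ts.cdom_specific_absorption(lam) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize(
        "lam, expected",
        [
            (440.0, 0.0013),
            (412.5, 0.0018586757),
            (555.0, 0.00029152319),
        ],
    )
    def test_nap_specific_absorption(self, lam, expected):
        assert ts.nap_specific_absorption(lam) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize(
        "lam, b_exp, bb_exp",
        [
            (550.0, 0.02875, 1.4375e-4),
            (412.5, 0.033197640, 1.6598820e-4),
        ],
    )
    def test_nap_specific_scattering(self, lam, b_exp, bb_exp):
        b, bb = ts.nap_specific_scattering(lam)
        assert b == pytest.approx(b_exp, rel=1e-6)
        assert bb == pytest.approx(bb_exp, rel=1e-6)

    def test_nap_scattering_flat_for_zero_exponent(self):
        p = ts.NAPParams(f_nap=1e-12)  # effectively flat law
        b1, _ = ts.nap_specific_scattering(412.5, p)
        b2, _ = ts.nap_specific_scattering(700.0, p)
        assert b1 == pytest.approx(0.02875, rel=1e-9)
        assert b2 == pytest.approx(0.02875, rel=1e-9)

    def test_invalid_wavelengths_rejected(self):
        with pytest.raises(InvalidInputError):
            ts.cdom_specific_absorption(np.nan)
        with pytest.raises(InvalidInputError):
            ts.nap_specific_scattering(-1.0)

    @given(
        slope=st.floats(0.005, 0.03),
        lam1=st.floats(310, 780),
        delta=st.floats(1.0, 20.0),
    )
    def test_absorption_spectra_strictly_decreasing(self, slope, lam1, delta):
        lam2 = min(lam1 + delta, 800.0)
        cd = ts.CDOMParams(s_cdom=slope)
        na = ts.NAPParams(s_nap=slope)
        assert ts.cdom_specific_absorption(lam2, cd) < ts.cdom_specific_absorption(lam1, cd)
        assert ts.nap_specific_absorption(lam2, na) < ts.nap_specific_absorption(lam1, na)


class TestPhotoacclimation:
    def test_inflection_value(self):
        # at PAR = beta the sigmoid is exactly 1/2
        assert ts.theta_chl(500.0) == pytest.approx(0.03 / 2 + 0.005, abs=1e-15)

    def test_saturating_light_floor(self):
        assert ts.theta_chl(5000.0) == pytest.approx(0.005, abs=1e-15)

    def test_dark_limit(self):
        assert ts.theta_chl(0.0) == pytest.approx(0.035, abs=1e-6)

    @given(par=st.floats(0, 800), delta=st.floats(0.5, 100))
    def test_strictly_decreasing_and_bounded(self, par, delta):
        # strict decrease checked where the sigmoid term is representable;
        # far beyond the inflection it saturates at theta_min to machine eps
        p = ts.PhotoacclimationParams()
        t1, t2 = ts.theta_chl(par, p), ts.theta_chl(par + delta, p)
        assert t2 < t1
        assert p.theta_min < t2 < t1 < p.theta_min + p.theta0

    def test_overflow_safe_far_below_inflection(self):
        p = ts.PhotoacclimationParams(sigma=1e-3)
        assert np.isfinite(ts.theta_chl(0.0, p))


class TestBulkIOPs:
    def test_empty_water_identity(self, ref_cfg):
        iops = ts.bulk_iops(ts.ConstituentVector(0, 0, 0), 500.0, ref_cfg)
        np.testing.assert_allclose(iops.a, ref_cfg.water.a_w)
        np.testing.assert_allclose(iops.b, ref_cfg.water.b_w)
        np.testing.assert_allclose(iops.b_b, ref_cfg.water.b_bw)

    def test_unit_chlorophyll_sum(self, ref_cfg):
        # chl=1, PAR=500 -> theta=0.02 -> C=50 mg C m^-3
        iops = ts.bulk_iops(ts.ConstituentVector(1, 0, 0), 500.0, ref_cfg)
        assert iops.a[1] == pytest.approx(0.04742, abs=1e-8)
        assert iops.b[1] == pytest.approx(1.01537, abs=1e-8)
        assert iops.b_b[1] == pytest.approx(0.004774, abs=1e-9)

    def test_cdom_absorbs_but_does_not_scatter(self, ref_cfg):
        iops = ts.bulk_iops(ts.ConstituentVector(0, 10, 0), 500.0, ref_cfg)
        assert iops.a[0] == pytest.approx(0.288561840, rel=1e-8)
        np.testing.assert_array_equal(iops.b, ref_cfg.water.b_w)
        np.testing.assert_array_equal(iops.b_b, ref_cfg.water.b_bw)

    @given(
        chl=st.floats(0.01, 30),
        cdom=st.floats(0.01, 500),
        nap=st.floats(0.01, 500),
        alpha=st.floats(0.1, 5),
        par=st.floats(0, 3000),
    )
    def test_linearity_in_constituents(self, ref_cfg, chl, cdom, nap, alpha, par):
        water = ts.bulk_iops(ts.ConstituentVector(0, 0, 0), par, ref_cfg)
        one = ts.bulk_iops(ts.ConstituentVector(chl, cdom, nap), par, ref_cfg)
        scaled = ts.bulk_iops(
            ts.ConstituentVector(alpha * chl, alpha * cdom, alpha * nap), par, ref_cfg
        )
        for attr in ("a", "b", "b_b"):
            lhs = getattr(scaled, attr) - getattr(water, attr)
            rhs = alpha * (getattr(one, attr) - getattr(water, attr))
            np.testing.assert_allclose(lhs, rhs, rtol=1e-9)

    @given(
        chl=st.floats(0, 50),
        cdom=st.floats(0, 1000),
        nap=st.floats(0, 1000),
        par=st.floats(0, 3000),
    )
    def test_backscatter_never_exceeds_scatter(self, ref_cfg, chl, cdom, nap, par):
        iops = ts.bulk_iops(ts.ConstituentVector(chl, cdom, nap), par, ref_cfg)
        assert np.all(iops.b_b <= iops.b)


class TestPerturbPhytoOptics:
    def test_identity_triple_reproduces_reference(self, ref_cfg):
        ref = ref_cfg.phyto
        ratio = ref.b_star_ph[0] / ref.b_star_ph[-1]
        bb = float(np.mean(ref.b_star_bph / ref.b_star_ph))
        out = perturb_phyto_optics(ref, 1.0, ratio, bb)
        np.testing.assert_allclose(out.a_star_ph, ref.a_star_ph, rtol=1e-12)
        np.testing.assert_allclose(out.b_star_ph, ref.b_star_ph, rtol=1e-12)
        np.testing.assert_allclose(out.b_star_bph, ref.b_star_bph, rtol=0.02)

    def test_maximum_amplification_blue_absorption(self, ref_cfg):
        out = perturb_phyto_optics(ref_cfg.phyto, 1.95, 1.1, 2.56e-3)
        assert out.a_star_ph[0] == pytest.approx(0.0663, abs=1e-4)
        low = perturb_phyto_optics(ref_cfg.phyto, 0.05, 1.1, 2.56e-3)
        assert low.a_star_ph[0] == pytest.approx(0.0017, abs=1e-4)

    def test_slope_perturbation_hits_requested_ratio_and_anchor(self, ref_cfg):
        out = perturb_phyto_optics(ref_cfg.phyto, 1.0, 22.0, 2.56e-3)
        eta = np.log(22.0) / np.log(555.0 / 412.5)
        assert eta == pytest.approx(10.417, abs=1e-2)
        assert out.b_star_ph[-1] == pytest.approx(0.01907, rel=1e-12)
        assert out.b_star_ph[0] / out.b_star_ph[-1] == pytest.approx(22.0, rel=1e-9)

    def test_backscatter_ratio_is_flat(self, ref_cfg):
        out = perturb_phyto_optics(ref_cfg.phyto, 1.0, 2.0, 1.3e-4)
        np.testing.assert_allclose(out.b_star_bph / out.b_star_ph, 1.3e-4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"aph_factor": 2.5, "bph_slope_ratio": 1.0, "bb_ratio": 1e-3},
            {"aph_factor": 1.0, "bph_slope_ratio": 30.0, "bb_ratio": 1e-3},
            {"aph_factor": 1.0, "bph_slope_ratio": 1.0, "bb_ratio": 1e-5},
        ],
    )
    def test_out_of_range_rejected(self, ref_cfg, kwargs):
        with pytest.raises(ConfigError):
            perturb_phyto_optics(ref_cfg.phyto, **kwargs)

    def test_tilt_mode_anchors_green_end(self, ref_cfg):
        out = perturb_phyto_optics(
            ref_cfg.phyto, 1.95, 1.1, 2.56e-3, aph_mode="tilt"
        )
        assert out.a_star_ph[0] == pytest.approx(1.95 * 0.034, rel=1e-12)
        assert out.a_star_ph[-1] == pytest.approx(0.009, rel=1e-12)


class TestDomainTypes:
    def test_wavelength_grid_validation(self):
        with pytest.raises(ConfigError):
            ts.WavelengthGrid((500.0, 400.0))
        with pytest.raises(ConfigError):
            ts.WavelengthGrid((200.0, 400.0))

    def test_water_backscatter_ratio_is_half(self, ref_cfg):
        ratio = ref_cfg.water.b_bw / ref_cfg.water.b_w
        np.testing.assert_allclose(ratio, 0.5, rtol=2e-3)  # printed-table rounding

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            ts.ConstituentVector(-0.1, 0, 0)
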