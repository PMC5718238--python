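import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iplsim.tissue import (GeometryConfig, OpticsConfig, ScatteringLaw,
                           TissueClass, build_grid)
from iplsim.transport import (Photon, deposit_weight, hg_phase,
                              propagate_photon, run_transport, sample_azimuth,
                              sample_deflection, sample_path_length,
                              surface_fresnel)

G_TISSUE = 0.789


class TestHGPhase:
    def test_isotropic_limit(self):
        for theta in (0.0, 1.0, np.pi):
            assert hg_phase(theta, 0.0) == pytest.approx(1.0)

    def test_forward_value_at_tissue_g(self):
        g = G_TISSUE
        expected = (1 - g ** 2) / ((1 + g ** 2 - 2 * g) ** 1.5)
        assert hg_phase(0.0, g) == pytest.approx(expected)

    def test_even_in_theta(self):
        th = np.linspace(0, np.pi, 20)
        np.testing.assert_allclose(hg_phase(th, 0.6), hg_phase(-th, 0.6))

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            hg_phase(0.1, 1.0)


class TestDeflectionSampler:
    def test_limits(self):
        assert sample_deflection(G_TISSUE, 1.0) == pytest.approx(1.0)
        assert sample_deflection(G_TISSUE, 0.0) == pytest.approx(-1.0)

    def test_midpoint_value(self):
        assert sample_deflection(G_TISSUE, 0.5) == pytest.approx(0.9379, abs=1e-4)

    def test_isotropic_case(self):
        assert sample_deflection(0.0, 0.75) == pytest.approx(0.5)

    @pytest.mark.parametrize("g", [0.1, 0.5, G_TISSUE])
    def test_mean_cosine_equals_g(self, g):
        """First moment of the HG distribution is the anisotropy factor."""
        rng = np.random.default_rng(123)
        n = 1_000_000
        c = sample_deflection(g, rng.random(n))
        se = c.std(ddof=1) / np.sqrt(n)
        assert abs(c.mean() - g) < 5 * se

    @pytest.mark.parametrize("g", [0.3, G_TISSUE])
    def test_matches_numerical_cdf_inversion(self, g):
        """Sampler agrees with brute-force inversion of the phase-function CDF."""
        # CDF of cos(theta): integrate p(c) = 0.5*(1-g^2)/(1+g^2-2gc)^{3/2}
        c_grid = np.linspace(-1.0, 1.0, 400_001)
        pdf = 0.5 * (1 - g ** 2) / (1 + g ** 2 - 2 * g * c_grid) ** 1.5
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5
                                               * np.diff(c_grid))])
        cdf /= cdf[-1]
        for R in np.arange(0.01, 1.0, 0.07):
            c_ref = np.interp(R, cdf, c_grid)
            assert sample_deflection(g, R) == pytest.approx(c_ref, abs=1e-6)


class TestAzimuthAndPath:
    def test_azimuth_endpoints(self):
        assert sample_azimuth(0.0) == 0.0
        assert sample_azimuth(0.5) == pytest.approx(np.pi)

    def test_azimuth_mean(self):
        rng = np.random.default_rng(5)
        n = 1_000_000
        phi = sample_azimuth(rng.random(n))
        se = phi.std(ddof=1) / np.sqrt(n)
        assert abs(phi.mean() - np.pi) < 5 * se

    def test_path_length_identity(self):
        assert sample_path_length(100.0, 1.0 / np.e) == pytest.approx(0.01)

    def test_path_length_mean(self):
        rng = np.random.default_rng(11)
        n = 1_000_000
        s = sample_path_length(100.0, rng.random(n) + 1e-12)
        se = s.std(ddof=1) / np.sqrt(n)
        assert abs(s.mean() - 0.01) < 5 * se

    @given(R=st.floats(1e-6, 1.0), mu=st.floats(1.0, 1e5))
    @settings(max_examples=100, deadline=None)
    def test_path_scaling(self, R, mu):
        assert sample_path_length(2 * mu, R) == pytest.approx(
            sample_path_length(mu, R) / 2, rel=1e-12)


class TestWeightDeposition:
    def test_symmetric_case(self):
        p = Photon(position=(0, 0), weight=1.0)
        assert deposit_weight(p, 50.0, 50.0) == pytest.approx(0.5)
        assert p.weight == pytest.approx(0.5)

    def test_tabulated_albedo(self):
        p = Photon(position=(0, 0), weight=1.0)
        assert deposit_weight(p, 30.0, 270.0) == pytest.approx(0.1)

    def test_no_absorption_no_deposit(self):
        p = Photon(position=(0, 0), weight=0.7)
        assert deposit_weight(p, 0.0, 100.0) == 0.0
        assert p.weight == 0.7


class TestFresnel:
    def test_matched_index(self):
        assert surface_fresnel(1.0, 0.0) == pytest.approx(0.0)

    def test_epidermis_normal_incidence(self):
        assert surface_fresnel(1.34, 0.0) == pytest.approx((0.34 / 2.34) ** 2, rel=1e-6)

    def test_grazing_limit(self):
        assert surface_fresnel(1.34, np.pi / 2 - 1e-6) > 0.99


def _absorbing_slab_grid():
    """Homogeneous pure-absorber block: melanin-rich, zero scattering."""
    geo = GeometryConfig(domain_width=500e-6, domain_depth=1000e-6,
                         epidermis_thickness=0.0, follicle_top_depth=0.0,
                         follicle_diameter=500e-6, follicle_length=1000e-6)
    zero = {t: 0.0 for t in (TissueClass.EPIDERMIS, TissueClass.DERMIS,
                             TissueClass.HAIR)}
    optics = OpticsConfig(
        water_fraction=zero, blood_fraction=zero,
        scattering={t: ScatteringLaw(0.0, 0.7, 0.0) for t in zero})
    grid = build_grid(geo, optics)  # follicle fills the whole block
    assert np.all(grid.class_map == int(TissueClass.HAIR))
    return grid


class TestPropagation:
    def test_beer_lambert_straight_line(self):
        """With zero scattering, deposition depth is exponential (mu_a)."""
        grid = _absorbing_slab_grid()
        wl = 700.0
        props = grid.optics_at(TissueClass.HAIR, wl)
        mu_a = props.mu_a
        assert props.mu_s == 0.0
        n = 30_000
        from iplsim.spectrum import EmissionSpectrum, N_BINS
        w = np.zeros(N_BINS)
        w[int(wl - 500)] = 1.0
        spec = EmissionSpectrum(weights=w)
        ab, tally = run_transport(grid, spec, n, seed=99)
        depth_profile = ab.deposited.sum(axis=1)
        z = (np.arange(len(depth_profile)) + 0.5) * grid.geometry.cell_size
        # pure absorber: all non-reflected weight deposits; profile ~ exp(-mu_a z)
        expected = np.exp(-mu_a * z)
        expected /= expected.sum()
        got = depth_profile / depth_profile.sum()
        # compare where statistics are decent
        sel = expected > 1e-4
        np.testing.assert_allclose(got[sel], expected[sel], rtol=0.2, atol=3e-4)
        assert tally.diffuse_reflected == 0.0

    def test_low_weight_terminates_immediately(self):
        grid = _absorbing_slab_grid()
        p = Photon(position=(250e-6, 10e-6), weight=0.005, wavelength_nm=700.0)
        res = propagate_photon(p, grid, seed=1)
        assert res.status == "terminated"
        # below the 1/100 threshold: the whole weight is the residual of the
        # first interaction's remainder
        assert res.absorbed_weight + res.residual_weight == pytest.approx(0.005)

    def test_fixed_seed_reproducible(self):
        grid = _absorbing_slab_grid()
        out = []
        for _ in range(2):
            p = Photon(position=(250e-6, 0.0), wavelength_nm=700.0)
            A = np.zeros(grid.shape)
            res = propagate_photon(p, grid, seed=42, absorption=A)
            out.append((res, A.copy()))
        assert out[0][0] == out[1][0]
        np.testing.assert_array_equal(out[0][1], out[1][1])


class TestBulkTransport:
    def test_zero_photons_rejected(self, tiny_grid, tiny_spectrum):
        with pytest.raises(ValueError):
            run_transport(tiny_grid, tiny_spectrum, 0, seed=1)

    def test_energy_conservation(self, tiny_transport):
        _, tally = tiny_transport
        assert tally.total == pytest.approx(1.0, abs=1e-9)

    def test_bit_identical_repeat(self, tiny_grid, tiny_spectrum, tiny_transport):
        ab1, tally1 = tiny_transport
        ab2, tally2 = run_transport(tiny_grid, tiny_spectrum, ab1.n_photons,
                                    ab1.rng_seed)
        np.testing.assert_array_equal(ab1.deposited, ab2.deposited)
        assert tally1 == tally2

    def test_deposition_nonnegative(self, tiny_transport):
        ab, _ = tiny_transport
        assert np.all(ab.deposited >= 0)

    def test_follicle_hotter_than_same_depth_dermis(self, tiny_grid, tiny_transport):
        """Melanin-rich follicle cells accumulate more energy density than
        dermis at the same depth."""
        ab, _ = tiny_transport
        cmap = tiny_grid.class_map
        for iz in (35, 45, 55):  # inside the tiny follicle span
            hair = ab.deposited[iz][cmap[iz] == int(TissueClass.HAIR)]
            dermis = ab.deposited[iz][cmap[iz] == int(TissueClass.DERMIS)]
            assert hair.mean() > dermis.mean()

    def test_literal_discard_mode_reports_residual(self, tiny_grid, tiny_spectrum):
        ab, tally = run_transport(tiny_grid, tiny_spectrum, 5000, seed=3,
                                  deposit_residual=False)
        assert tally.terminated_residual > 0
        assert tally.total == pytest.approx(1.0, abs=1e-9)
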