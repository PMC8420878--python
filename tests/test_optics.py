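import numpy as np
import pytest

from hsicurve.optics import (
    PHANTOM_CONFIG,
    PhantomParams,
    SkinParams,
    SphereDistribution,
    build_slab,
    dermis_mua,
    distribution_scattering,
    epidermis_mua,
    melanin_mua,
    phantom_masses,
    phantom_mua,
    siliglass_refractive_index,
    skin_mus_prime,
    skin_refractive_index,
)


class TestPhantomMasses:
    def test_zero_concentrations(self):
        assert phantom_masses(0.0, 0.0, 50.0) == (0.0, 0.0, 50.0)

    def test_absorber_mass_aa(self):
        mabs, _, _ = phantom_masses(0.037, 0.0, 50.0)
        assert mabs == pytest.approx(2 * 0.037 * 50 / (1 - 2 * 0.037))
        assert mabs == pytest.approx(3.9957, abs=1e-3)

    def test_scatterer_and_part_b(self):
        _, msc, mB = phantom_masses(0.0, 0.016, 50.0)
        assert msc == pytest.approx(1.6)
        assert mB == pytest.approx(48.4)

    def test_wall_loss_adjustment(self):
        _, msc, mB = phantom_masses(0.0, 0.016, 50.0, wall_loss=True)
        assert mB == pytest.approx(49.4)
        assert msc > 1.6  # rescaled for the extra material

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            phantom_masses(0.5, 0.0, 50.0)


class TestSiliglassIndex:
    def test_reference_wavelength(self):
        assert siliglass_refractive_index(436.4) == pytest.approx(1.41779, abs=1e-5)

    def test_long_wavelength_limit(self):
        assert siliglass_refractive_index(1e9) == pytest.approx(np.sqrt(1.95007197), rel=1e-9)
        assert siliglass_refractive_index(1e9) == pytest.approx(1.39645, abs=1e-5)

    def test_normal_dispersion(self):
        lam = np.linspace(440, 1000, 200)
        n = siliglass_refractive_index(lam)
        assert np.all(np.diff(n) < 0)

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(ValueError):
            siliglass_refractive_index(0.0)


class TestPhantomAbsorption:
    def test_zero_absorber_gives_medium_only(self, tables, grid):
        mua = phantom_mua(PhantomParams(0.0, 1.6), tables, grid)
        assert np.allclose(mua, tables("AB", grid))

    def test_dilution_denominator_cancels(self, tables, grid):
        # at Cabs equal to the dilution constant the pigment term reduces to
        # the measured pigment curve
        cabs_pct = PHANTOM_CONFIG["dilution_denominator"] * 100
        mua = phantom_mua(PhantomParams(cabs_pct, 0.0), tables, grid)
        expected = (1 - cabs_pct / 100) * tables("AB", grid) + tables("abs", grid)
        assert np.allclose(mua, expected)

    def test_linear_in_concentration(self, tables, grid):
        m0 = phantom_mua(PhantomParams(0.0, 1.6), tables, grid)
        m1 = phantom_mua(PhantomParams(10.0, 1.6), tables, grid)
        m2 = phantom_mua(PhantomParams(20.0, 1.6), tables, grid)
        assert np.allclose(m2 - m1, m1 - m0, rtol=1e-9)

    def test_out_of_coverage_raises(self, tables):
        with pytest.raises(ValueError, match="coverage"):
            phantom_mua(PhantomParams(1.0, 1.0), tables, np.array([2000.0]))


class TestDistributionScattering:
    def test_single_radius_reduces_to_monodisperse(self, grid):
        from hsicurve.mie import mie_sphere

        dist = SphereDistribution(radii=np.array([7.0]), volume_fraction=np.array([1.0]))
        mus, g = distribution_scattering(dist, 1.0, grid[:3])
        n_med = siliglass_refractive_index(grid[:3])
        for k, lam in enumerate(grid[:3]):
            qsca, g1 = mie_sphere(7.0, lam, PHANTOM_CONFIG["sphere_index"], n_med[k])
            assert mus[k] == pytest.approx(3 * qsca / (4 * 7e-4), rel=1e-9)
            assert g[k] == pytest.approx(g1, rel=1e-9)

    def test_doubling_fractions_doubles_mus_not_g(self, grid):
        dist = SphereDistribution(radii=np.array([2.0, 7.0]), volume_fraction=np.array([0.3, 0.7]))
        dist2 = SphereDistribution(radii=dist.radii, volume_fraction=2 * dist.volume_fraction)
        mus1, g1 = distribution_scattering(dist, 1.0, grid[:4])
        mus2, g2 = distribution_scattering(dist2, 1.0, grid[:4])
        assert np.allclose(mus2, 2 * mus1, rtol=1e-12)
        assert np.allclose(g2, g1, rtol=1e-12)

    def test_peak_radius_forward_scattering(self, grid):
        dist = SphereDistribution(radii=np.array([7.0]), volume_fraction=np.array([1.0]))
        mus, g = distribution_scattering(dist, 0.016, grid[:5])
        assert np.all(np.isfinite(mus)) and np.all(mus > 0)
        assert np.all((g > 0.9) & (g < 1.0))

    def test_weighted_g_within_single_sphere_range(self, grid):
        sub = grid[:3]
        dist = SphereDistribution(radii=np.array([1.0, 4.0, 10.0]), volume_fraction=np.array([0.2, 0.5, 0.3]))
        _, g = distribution_scattering(dist, 1.0, sub)
        gs = []
        from hsicurve.mie import mie_sphere

        n_med = siliglass_refractive_index(sub)
        for r in dist.radii:
            gs.append([mie_sphere(r, lam, PHANTOM_CONFIG["sphere_index"], nm)[1] for lam, nm in zip(sub, n_med)])
        gs = np.array(gs)
        assert np.all(g >= gs.min(axis=0) - 1e-12)
        assert np.all(g <= gs.max(axis=0) + 1e-12)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            SphereDistribution(radii=np.array([]), volume_fraction=np.array([]))

    def test_default_distribution_reaches_stated_scattering_regime(self, grid):
        dist = SphereDistribution.load_default()
        mus_lo, g_lo = distribution_scattering(dist, 0.016, grid)
        mus_hi, g_hi = distribution_scattering(dist, 0.065, grid)
        musp_lo = mus_lo * (1 - g_lo)
        musp_hi = mus_hi * (1 - g_hi)
        assert musp_lo.min() > 6.0 and musp_hi.max() < 45.0


class TestSkinModel:
    def test_epidermis_baseline_only(self, grid):
        assert np.allclose(epidermis_mua(0.0, grid), 0.25)

    def test_melanin_power_law_at_500(self):
        assert melanin_mua(500.0) == pytest.approx(6.6e11 * 500.0**-3.33, rel=1e-12)
        assert melanin_mua(500.0) == pytest.approx(678.0, abs=2.0)

    def test_melanin_strictly_decreasing(self, grid):
        assert np.all(np.diff(melanin_mua(grid)) < 0)

    def test_dermis_baseline_with_no_absorbers(self, tables, grid):
        p = SkinParams(fmel=0, fHb=0, fHbO2=0, fCytO=0, fCytOO2=0, a=30.0, fbil=0.0)
        assert np.allclose(dermis_mua(p, tables, grid), 0.25)

    def test_dermis_single_term_proportional(self, tables, grid):
        p = SkinParams(fmel=0, fHb=2.0, fHbO2=0, fCytO=0, fCytOO2=0, a=30.0)
        mua = dermis_mua(p, tables, grid)
        assert np.allclose(mua, 0.02 * tables("Hb", grid) + 0.25)

    def test_isosbestic_wavelengths_swap_invariant(self, tables, grid):
        diff = tables("Hb", grid) - tables("HbO2", grid)
        sign_change = np.nonzero(np.diff(np.sign(diff)))[0]
        assert sign_change.size > 0, "bundled Hb/HbO2 tables must cross"
        k = sign_change[0]
        lam_iso = grid[k] - diff[k] * (grid[k + 1] - grid[k]) / (diff[k + 1] - diff[k])
        p_hb = SkinParams(fmel=0, fHb=1.0, fHbO2=0, fCytO=0, fCytOO2=0, a=30.0)
        p_ox = SkinParams(fmel=0, fHb=0, fHbO2=1.0, fCytO=0, fCytOO2=0, a=30.0)
        lam = np.array([lam_iso])
        assert dermis_mua(p_hb, tables, lam) == pytest.approx(dermis_mua(p_ox, tables, lam), rel=1e-3)

    def test_dermis_linear_superposition(self, tables, grid):
        base = SkinParams(fmel=0, fHb=0, fHbO2=0, fCytO=0, fCytOO2=0, a=30.0)
        pa = SkinParams(fmel=0, fHb=3.0, fHbO2=0, fCytO=0, fCytOO2=0, a=30.0)
        pb = SkinParams(fmel=0, fHb=0, fHbO2=0, fCytO=0.7, fCytOO2=0, a=30.0)
        pab = SkinParams(fmel=0, fHb=3.0, fHbO2=0, fCytO=0.7, fCytOO2=0, a=30.0)
        m0 = dermis_mua(base, tables, grid)
        assert np.allclose(
            dermis_mua(pab, tables, grid) - m0,
            (dermis_mua(pa, tables, grid) - m0) + (dermis_mua(pb, tables, grid) - m0),
            rtol=1e-12,
        )

    def test_mus_prime_pivot_and_similarity(self, grid):
        assert skin_mus_prime(33.0, 1.27, np.array([500.0]))[0] == pytest.approx(33.0)
        musp = skin_mus_prime(30.0, 1.27, np.array([650.0]))[0]
        assert musp == pytest.approx(30.0 * 1.3**-1.27, rel=1e-12)
        assert 21.4 < musp < 21.6
        # similarity: mus = musp / (1 - g) with g = 0.82
        slab = build_slab("skin", SkinParams(a=30.0), grid)
        assert np.allclose(np.asarray(slab[0].mus) * 0.18, skin_mus_prime(30.0, 1.27, grid))

    def test_skin_refractive_index_plausible(self, grid):
        n = skin_refractive_index(grid)
        assert np.all((n > 1.3) & (n < 1.6))
        assert np.all(np.diff(n) < 0)  # normal dispersion


class TestBuildSlab:
    def test_layer_counts(self, grid):
        assert len(build_slab("phantom", PhantomParams(3.7, 1.6), grid)) == 1
        assert len(build_slab("skin", SkinParams(), grid)) == 2

    def test_phantom_thicknesses_and_index(self, grid):
        lay = build_slab("phantom", PhantomParams(3.7, 1.6), grid)[0]
        assert lay.thickness == pytest.approx(2.0)
        assert np.allclose(np.asarray(lay.n), siliglass_refractive_index(grid))

    def test_skin_layer_geometry(self, grid):
        epi, derm = build_slab("skin", SkinParams(), grid)
        assert epi.thickness == pytest.approx(0.01)
        assert derm.thickness == pytest.approx(1.0)
        assert np.allclose(np.asarray(epi.g), 0.82)

    def test_phantom_absorption_band(self, grid):
        # lowest-absorber recipe sits at the bottom of the documented
        # 0.1-1.1 cm^-1 band, the highest near its top
        lo = build_slab("phantom", PhantomParams(3.7, 1.6), grid)[0]
        hi = build_slab("phantom", PhantomParams(37.0, 1.6), grid)[0]
        assert np.all(np.asarray(lo.mua) >= 0.1)
        assert np.all(np.asarray(hi.mua) <= 1.15)

    def test_properties_finite_nonnegative_inside_bounds(self, grid, rng):
        for _ in range(5):
            p = PhantomParams(rng.uniform(0.1, 45), rng.uniform(0.1, 10))
            lay = build_slab("phantom", p, grid)[0]
            assert np.all(np.isfinite(lay.mua)) and np.all(np.asarray(lay.mua) >= 0)
            assert np.all(np.isfinite(lay.mus)) and np.all(np.asarray(lay.mus) >= 0)
        for _ in range(5):
            vals = [rng.uniform(*SkinParams.BOUNDS[k]) for k in SkinParams.FREE]
            for lay in build_slab("skin", SkinParams.from_free_values(vals), grid):
                assert np.all(np.isfinite(lay.mua)) and np.all(np.asarray(lay.mua) >= 0)
                assert np.all(np.isfinite(lay.mus)) and np.all(np.asarray(lay.mus) >= 0)

    def test_wrong_params_type_rejected(self, grid):
        with pytest.raises(TypeError):
            build_slab("phantom", SkinParams(), grid)
        with pytest.raises(ValueError):
            build_slab("bone", PhantomParams(1, 1), grid)
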