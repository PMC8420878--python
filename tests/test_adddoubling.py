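import numpy as np
import pytest

from hsicurve.adddoubling import (
    QuadratureScheme,
    add_boundaries_and_layers,
    forward_spectrum,
    hg_redistribution,
    layer_rt,
)
from hsicurve.optics import LayerOpticalProperties, PhantomParams, build_slab


@pytest.fixture(scope="module")
def radau20():
    return QuadratureScheme.radau(20)


@pytest.fixture(scope="module")
def split20():
    return QuadratureScheme.split(20, 1.4)


class TestQuadrature:
    @pytest.mark.parametrize("maker", [QuadratureScheme.radau, lambda M: QuadratureScheme.split(M, 1.4)])
    def test_integrates_polynomials(self, maker):
        s = maker(20)
        for p in range(6):
            assert np.sum(s.w * s.mu**p) == pytest.approx(1.0 / (p + 1), abs=1e-12)

    def test_normal_cone_is_a_node(self, radau20, split20):
        assert radau20.mu[radau20.normal_index] == pytest.approx(1.0)
        assert split20.mu[split20.normal_index] == pytest.approx(1.0)

    def test_split_places_node_panel_at_critical_cosine(self):
        n = 1.4
        mu_c = np.sqrt(1 - 1 / n**2)
        s = QuadratureScheme.split(20, n)
        assert np.sum(s.mu < mu_c) == 10

    def test_matched_index_falls_back_to_radau(self):
        a = QuadratureScheme.split(20, 1.0)
        b = QuadratureScheme.radau(20)
        assert np.allclose(a.mu, b.mu)


class TestRedistribution:
    def test_isotropic_is_uniform(self, radau20):
        hp, hm = hg_redistribution(0.0, radau20)
        assert np.allclose(hp, 0.5)
        assert np.allclose(hm, 0.5)

    def test_column_sums_normalized(self, radau20):
        for g in (0.0, 0.5, 0.82, 0.99):
            hp, hm = hg_redistribution(g, radau20)
            sums = radau20.w @ (hp[0] + hm[0])
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_forward_peaked_for_large_g(self, radau20):
        hp, _ = hg_redistribution(0.82, radau20)
        # same-direction redistribution dominates the isotropic level
        diag = np.diag(hp[0])
        assert np.all(diag > 0.5)

    def test_invalid_g_rejected(self, radau20):
        with pytest.raises(ValueError):
            hg_redistribution(1.0, radau20)
        with pytest.raises(ValueError):
            hg_redistribution(-0.1, radau20)


class TestLayerOperators:
    def test_no_scattering_is_beer_lambert(self, radau20):
        lay = LayerOpticalProperties(mua=1.3, mus=0.0, g=0.0, n=1.0, thickness=1.0)
        S, T = layer_rt(lay, radau20)
        assert np.abs(S).max() == 0.0
        assert np.allclose(np.diag(T[0]), np.exp(-1.3 / radau20.mu), rtol=1e-9)

    def test_empty_layer_is_identity(self, radau20):
        lay = LayerOpticalProperties(mua=0.0, mus=0.0, g=0.0, n=1.0, thickness=1e-9)
        S, T = layer_rt(lay, radau20)
        assert np.allclose(T[0], np.eye(radau20.M), atol=1e-8)
        assert np.abs(S).max() < 1e-8

    def test_conservative_layer_conserves_energy(self, radau20):
        lay = LayerOpticalProperties(mua=0.0, mus=10.0, g=0.0, n=1.0, thickness=1.0)
        S, T = layer_rt(lay, radau20)
        col = (S[0] + T[0]).sum(axis=0)
        assert np.allclose(col, 1.0, atol=1e-9)

    def test_layer_reciprocity(self, radau20):
        # the radiance kernel S_ij / (mu_i w_i) is symmetric up to the small
        # energy renormalization of the starting layer
        lay = LayerOpticalProperties(mua=0.3, mus=20.0, g=0.82, n=1.0, thickness=0.5)
        S, _ = layer_rt(lay, radau20)
        K = S[0] / (radau20.mu[:, None] * radau20.w[:, None])
        assert np.abs(K - K.T).max() < 1e-4 * np.abs(K).max()
        rel = np.abs(K - K.T) / np.maximum(np.abs(K), 1e-12)
        assert rel.max() < 5e-3


class TestSlabAssembly:
    def test_vacuum_slab(self, radau20):
        lay = LayerOpticalProperties(mua=0.0, mus=0.0, g=0.0, n=1.0, thickness=1.0)
        res = add_boundaries_and_layers([lay], 1.0, radau20)
        assert res.R_total[0] == pytest.approx(0.0, abs=1e-12)
        assert res.T_total[0] == pytest.approx(1.0, abs=1e-12)

    def test_conservative_slab_unit_energy(self, radau20):
        lay = LayerOpticalProperties(mua=0.0, mus=10.0, g=0.0, n=1.0, thickness=1.0)
        res = add_boundaries_and_layers([lay], 1.0, radau20)
        assert res.R_total[0] + res.T_total[0] == pytest.approx(1.0, abs=1e-6)

    def test_semi_infinite_conservative_reflects_everything(self, radau20):
        lay = LayerOpticalProperties(mua=0.0, mus=100.0, g=0.0, n=1.0, thickness=50.0)
        res = add_boundaries_and_layers([lay], 1.0, radau20)
        assert res.R_total[0] > 0.99

    def test_energy_closure_with_mismatched_boundaries(self, split20):
        lay = LayerOpticalProperties(mua=0.0, mus=10.0, g=0.8, n=1.4, thickness=2.0)
        res = add_boundaries_and_layers([lay], 1.0, split20)
        total = res.R_total[0] + res.T_total[0] + res.R_specular[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_specular_component_is_fresnel_normal(self, split20):
        lay = LayerOpticalProperties(mua=1.0, mus=10.0, g=0.5, n=1.4, thickness=1.0)
        res = add_boundaries_and_layers([lay], 1.0, split20)
        assert res.R_specular[0] == pytest.approx(((1.4 - 1) / (1.4 + 1)) ** 2, rel=1e-12)

    def test_absorption_decreases_reflectance_monotonically(self, grid):
        r_prev = None
        for cabs in (1.0, 5.0, 15.0, 30.0):
            r = forward_spectrum(build_slab("phantom", PhantomParams(cabs, 1.6), grid))
            if r_prev is not None:
                assert np.all(r < r_prev)
            r_prev = r

    def test_spectrum_smooth_for_smooth_inputs(self, grid):
        # no quadrature- or doubling-induced jumps between adjacent 5-nm
        # points when the optical-property curves themselves are smooth
        lay = LayerOpticalProperties(
            mua=0.1 + 0.5 * (grid - 430) / 270,
            mus=200.0 * (grid / 500.0) ** -1.0,
            g=0.82,
            n=1.4,
            thickness=2.0,
        )
        r = add_boundaries_and_layers([lay], 1.0).R_total
        # spline through every other point must reproduce the skipped points:
        # genuine spectral curvature interpolates, discretization jitter won't
        from scipy.interpolate import CubicSpline

        cs = CubicSpline(grid[::2], r[::2])
        assert np.abs(cs(grid[1::2]) - r[1::2]).max() < 1e-4

    def test_quadrature_convergence_20_vs_40(self):
        rng = np.random.default_rng(7)
        for _ in range(4):
            mua = rng.uniform(0.1, 1.1)
            musp = rng.uniform(8, 40)
            g = rng.choice([0.0, 0.82])
            n = rng.choice([1.0, 1.4])
            mus = musp / (1 - g) if g > 0 else musp
            lay = LayerOpticalProperties(mua=mua, mus=mus, g=g, n=n, thickness=2.0)
            r20 = add_boundaries_and_layers([lay], 1.0, QuadratureScheme.split(20, n)).R_total
            r40 = add_boundaries_and_layers([lay], 1.0, QuadratureScheme.split(40, n)).R_total
            assert abs(r20[0] - r40[0]) < 5e-4

    def test_two_layer_reduces_to_one_when_identical(self, grid, split20):
        lay = LayerOpticalProperties(mua=0.5, mus=50.0, g=0.82, n=1.4, thickness=0.5)
        lay2 = LayerOpticalProperties(mua=0.5, mus=50.0, g=0.82, n=1.4, thickness=1.0)
        r_split = add_boundaries_and_layers([lay, lay], 1.0, split20).R_total
        r_whole = add_boundaries_and_layers([lay2], 1.0, split20).R_total
        assert np.allclose(r_split, r_whole, atol=1e-9)

    def test_empty_stack_rejected(self, radau20):
        with pytest.raises(ValueError):
            add_boundaries_and_layers([], 1.0, radau20)
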