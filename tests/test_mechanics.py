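import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaffsim.mechanics import (
    OgdenMaterial,
    OssFieldParams,
    PrincipalStrains,
    PrincipalStretches,
    octahedral_shear_strain,
    octahedral_shear_strain_uniaxial,
    oss_node_factors,
    principal_strains,
    reduced_order_oss_field,
    strain_energy,
    uniaxial_incompressible_stretches,
    uniaxial_nominal_stress,
)

# frozen oracle: independent scalar evaluation of the one-term Ogden energy
# at lambda = (0.9, 0.9^-1/2, 0.9^-1/2) with mu1=-5.8 kPa, alpha1=-1.3
W_REF_10PCT = 0.06428360943544009


class TestOgdenMaterial:
    def test_reference_shear_modulus(self):
        assert OgdenMaterial().shear_modulus == pytest.approx(3.77)

    def test_inconsistent_term_lengths_rejected(self):
        with pytest.raises(ValueError):
            OgdenMaterial(mu=(-5.8,), alpha=(-1.3, 2.0), d=(0.0,))

    def test_nonpositive_reference_stiffness_rejected(self):
        with pytest.raises(ValueError):
            OgdenMaterial(mu=(-5.8,), alpha=(1.3,), d=(0.0,))


class TestStrainEnergy:
    def test_zero_at_reference(self):
        assert strain_energy(PrincipalStretches(1, 1, 1), OgdenMaterial()) == 0.0

    def test_uniaxial_10pct_matches_frozen_scalar(self):
        st10 = uniaxial_incompressible_stretches(0.10)
        W = strain_energy(st10, OgdenMaterial())
        assert W == pytest.approx(W_REF_10PCT, rel=1e-9)

    def test_symmetric_under_stretch_permutation(self):
        mat = OgdenMaterial()
        lams = (0.9, 0.9**-0.5, 0.9**-0.5)
        import itertools

        vals = {
            strain_energy(PrincipalStretches(*p), mat)
            for p in itertools.permutations(lams)
        }
        assert max(vals) - min(vals) < 1e-14

    def test_incompressible_with_volume_change_rejected(self):
        with pytest.raises(ValueError):
            strain_energy(PrincipalStretches(0.9, 1.0, 1.0), OgdenMaterial())

    def test_reference_is_local_minimum(self, rng):
        mat = OgdenMaterial()
        for _ in range(50):
            e = rng.uniform(1e-4, 0.15)
            assert strain_energy(uniaxial_incompressible_stretches(e), mat) > 0


class TestUniaxialKinematics:
    @pytest.mark.parametrize(
        "e,lat",
        [(0.0, 1.0), (0.10, 1.0540925533894598), (0.03, 1.015346165133619)],
    )
    def test_incompressible_stretches(self, e, lat):
        s = uniaxial_incompressible_stretches(e)
        assert s.l1 == pytest.approx(1 - e)
        assert s.l2 == pytest.approx(lat) and s.l3 == pytest.approx(lat)
        assert s.J == pytest.approx(1.0, abs=1e-12)

    def test_full_compression_rejected(self):
        with pytest.raises(ValueError):
            uniaxial_incompressible_stretches(1.0)

    def test_principal_strains_subtract_one(self):
        s = uniaxial_incompressible_stretches(0.10)
        eps = principal_strains(s)
        np.testing.assert_allclose(
            eps.as_array(), [-0.1, 0.0540925533894598, 0.0540925533894598]
        )


class TestOctahedralShearStrain:
    def test_hydrostatic_state_gives_zero(self):
        assert octahedral_shear_strain(PrincipalStrains(0.05, 0.05, 0.05)) == 0.0

    @pytest.mark.parametrize(
        "e,expected",
        [(0.10, 0.14527985257604953), (0.03, 0.04275277448904941)],
    )
    def test_uniaxial_closed_form(self, e, expected):
        eps = principal_strains(uniaxial_incompressible_stretches(e))
        assert octahedral_shear_strain(eps) == pytest.approx(expected, rel=1e-12)
        assert octahedral_shear_strain_uniaxial(e) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        e1=st.floats(-0.5, 0.5),
        e2=st.floats(-0.5, 0.5),
        e3=st.floats(-0.5, 0.5),
        c=st.floats(-0.3, 0.3),
    )
    def test_invariant_under_permutation_and_hydrostatic_shift(self, e1, e2, e3, c):
        base = octahedral_shear_strain(PrincipalStrains(e1, e2, e3))
        perm = octahedral_shear_strain(PrincipalStrains(e2, e3, e1))
        shifted = octahedral_shear_strain(PrincipalStrains(e1 + c, e2 + c, e3 + c))
        assert perm == pytest.approx(base, abs=1e-12)
        assert shifted == pytest.approx(base, abs=1e-9)


class TestNominalStress:
    def test_stress_free_reference(self):
        assert uniaxial_nominal_stress(0.0, OgdenMaterial()) == 0.0

    def test_small_strain_slope_is_minus_three_g0(self):
        mat = OgdenMaterial()
        e = 1e-6
        P = uniaxial_nominal_stress(e, mat)
        assert P / e == pytest.approx(-3 * 3.77, rel=1e-4)

    def test_compression_gives_negative_stress(self):
        assert uniaxial_nominal_stress(0.05, OgdenMaterial()) < 0

    def test_matches_finite_difference_of_energy(self):
        # dW/d(lambda1) along the incompressible uniaxial path
        mat = OgdenMaterial()
        e = 0.08
        h = 1e-7

        def W(ee):
            return strain_energy(uniaxial_incompressible_stretches(ee), mat)

        # dW/de = -dW/dlambda since lambda1 = 1 - e
        fd = -(W(e + h) - W(e - h)) / (2 * h)
        assert uniaxial_nominal_stress(e, mat) == pytest.approx(fd, rel=1e-6)


class TestReducedOrderField:
    def test_zero_compression_gives_zero_field(self, coarse_mesh):
        oss = reduced_order_oss_field(coarse_mesh, 0.0, seed=1)
        assert np.all(oss == 0)

    def test_intersections_hotter_than_free_spans(self, coarse_mesh):
        oss = reduced_order_oss_field(coarse_mesh, 0.05, seed=1)
        mi = oss[coarse_mesh.node_region == "intersection"].mean()
        mf = oss[coarse_mesh.node_region == "strand_free"].mean()
        assert mi > mf

    def test_degenerate_params_reproduce_affine_exactly(self, coarse_mesh):
        params = OssFieldParams(
            g_intersection=1.0,
            g_strand_free=1.0,
            g_strand_top=1.0,
            g_strand_bottom=1.0,
            sigma_log=0.0,
            normalize_mean=False,
        )
        oss = reduced_order_oss_field(coarse_mesh, 0.07, params=params, seed=3)
        np.testing.assert_array_equal(oss, np.full(coarse_mesh.n_nodes, octahedral_shear_strain_uniaxial(0.07)))

    def test_peak_in_time_at_peak_compression(self, coarse_mesh):
        e_t = np.array([0.0, 0.04, 0.1, 0.06, 0.0])
        oss = reduced_order_oss_field(coarse_mesh, e_t, seed=5)
        assert np.all(np.argmax(oss, axis=0) == 2)

    def test_seed_reproducibility(self, coarse_mesh):
        a = oss_node_factors(coarse_mesh, seed=11)
        b = oss_node_factors(coarse_mesh, seed=11)
        c = oss_node_factors(coarse_mesh, seed=12)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_default_surface_mean_is_half_affine(self, coarse_mesh):
        # deterministic normalization targets E[factor] = 0.5
        f = oss_node_factors(coarse_mesh, seed=2)
        assert f.mean() == pytest.approx(0.5, rel=0.05)
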