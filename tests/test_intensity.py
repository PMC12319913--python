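"""Normal-mode gradients, IR absorption, Raman invariants and cross sections."""

import numpy as np
import pytest
from conftest import random_rotation

from phvaspec import (eigenanalyze, ir_intensity, make_diatomic, mass_weight,
                      raman_cross_section, raman_invariants,
                      transform_gradients, units)
from phvaspec.intensity import ModeGradients, RamanInvariants


def _modes_from(record):
    return eigenanalyze(mass_weight(record.H_partial, record.core_masses))


class TestTransformGradients:
    def test_one_hot_eigenvector_picks_one_row(self):
        """A mode displacing only atom 1 along x returns that atom's
        dipole-gradient row divided by sqrt(m)."""
        record, _ = make_diatomic(0.3, 4.0, 4.0)
        modes = _modes_from(record)
        modes.eigenvectors[:, 0] = 0.0
        modes.eigenvectors[0, 0] = 1.0  # atom 0, x, in mass-weighted coords
        out = transform_gradients(record.D_mu, record.D_alpha, modes,
                                  record.core_masses, kept_labels=[1])
        assert np.allclose(out.dmu_dq[0], record.D_mu[0] / 2.0)  # sqrt(4)=2

    def test_zero_dipole_gradient_gives_zero(self):
        record, _ = make_diatomic(0.3, 1.0, 2.0)
        modes = _modes_from(record)
        out = transform_gradients(np.zeros_like(record.D_mu), record.D_alpha,
                                  modes, record.core_masses)
        assert np.array_equal(out.dmu_dq, np.zeros((6, 3)))

    def test_joint_rotation_leaves_intensities_invariant(self, rng):
        record, _ = make_diatomic(0.5, 1.5, 9.0)
        modes = _modes_from(record)
        grads = transform_gradients(record.D_mu, record.D_alpha, modes,
                                    record.core_masses, kept_labels=[1])
        Q = random_rotation(rng)
        R = np.kron(np.eye(2), Q)
        H_rot = R @ record.H_partial @ R.T
        Dmu_rot = R @ record.D_mu @ Q.T
        Dal_rot = np.einsum("ab,bjk,pj,qk->apq", R, record.D_alpha, Q, Q)
        modes_rot = eigenanalyze(mass_weight(H_rot, record.core_masses))
        grads_rot = transform_gradients(Dmu_rot, Dal_rot, modes_rot,
                                        record.core_masses, kept_labels=[1])
        d0 = np.linalg.norm(grads.dmu_dq[0])
        d1 = np.linalg.norm(grads_rot.dmu_dq[0])
        assert d1**2 == pytest.approx(d0**2, abs=1e-10 * max(d0**2, 1))
        S0 = raman_invariants(grads).activity[0]
        S1 = raman_invariants(grads_rot).activity[0]
        assert S1 == pytest.approx(S0, rel=1e-9)

    def test_unknown_label_rejected(self):
        record, _ = make_diatomic(0.3, 1.0, 1.0)
        modes = _modes_from(record)
        with pytest.raises(ValueError, match="label"):
            transform_gradients(record.D_mu, record.D_alpha, modes,
                                record.core_masses, kept_labels=[7])


class TestIRIntensity:
    def test_zero_gradient_zero_absorption(self):
        g = ModeGradients(labels=np.array([1]), dmu_dq=np.zeros((1, 3)),
                          dalpha_dq=np.zeros((1, 3, 3)))
        assert ir_intensity(g)[0] == 0.0

    def test_unit_debye_per_angstrom_amu_gives_42_256(self):
        """The classic conversion: |dmu/dQ|^2 of 1 (D/(A amu^1/2))^2 maps
        to ~42.256 km/mol.  Expected value recomputed here from CODATA
        constants through an independent arithmetic path."""
        NA, eps0, c = units.N_AVOGADRO, units.EPSILON0, units.C_LIGHT_M_S
        debye = 1e-21 / c
        d_si = debye / (1e-10 * np.sqrt(units.DALTON_KG))
        expected_km_mol = NA / (12 * eps0 * c**2) * d_si**2 / 1000.0
        assert expected_km_mol == pytest.approx(42.256, abs=0.01)
        # same quantity through the package: express 1 D/(A amu^1/2) in a.u.
        dmu_au = d_si / units.DMU_DQ_AU_TO_SI
        g = ModeGradients(labels=np.array([1]),
                          dmu_dq=np.array([[dmu_au, 0.0, 0.0]]),
                          dalpha_dq=np.zeros((1, 3, 3)))
        assert ir_intensity(g)[0] == pytest.approx(expected_km_mol, rel=1e-12)

    def test_quadratic_scaling(self, rng):
        d = rng.normal(size=(1, 3))
        g1 = ModeGradients(np.array([1]), d, np.zeros((1, 3, 3)))
        g2 = ModeGradients(np.array([1]), 2 * d, np.zeros((1, 3, 3)))
        assert ir_intensity(g2)[0] == pytest.approx(4 * ir_intensity(g1)[0],
                                                    rel=1e-12)


class TestRamanInvariants:
    def test_isotropic_tensor(self):
        d = 1.7
        g = ModeGradients(np.array([1]), np.zeros((1, 3)),
                          (d * np.eye(3))[None])
        inv = raman_invariants(g)
        assert inv.a_iso[0] == pytest.approx(d)
        assert inv.gamma2[0] == pytest.approx(0.0, abs=1e-14)
        assert inv.activity[0] == pytest.approx(45 * d * d)

    def test_uniaxial_tensor_hand_values(self):
        g = ModeGradients(np.array([1]), np.zeros((1, 3)),
                          np.diag([1.0, 0.0, 0.0])[None])
        inv = raman_invariants(g)
        assert inv.a_iso[0] == pytest.approx(1 / 3)
        assert inv.gamma2[0] == pytest.approx(1.0)
        assert inv.activity[0] == pytest.approx(45 / 9 + 7)  # = 12

    def test_rotation_invariance(self, rng):
        A = rng.normal(size=(3, 3))
        A = A + A.T
        Q = random_rotation(rng)
        g1 = ModeGradients(np.array([1]), np.zeros((1, 3)), A[None])
        g2 = ModeGradients(np.array([1]), np.zeros((1, 3)), (Q @ A @ Q.T)[None])
        assert raman_invariants(g2).activity[0] == pytest.approx(
            raman_invariants(g1).activity[0], rel=1e-10)

    def test_asymmetric_tensor_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 1.0
        g = ModeGradients(np.array([1]), np.zeros((1, 3)), A[None])
        with pytest.raises(ValueError, match="symmetric"):
            raman_invariants(g)


class TestRamanCrossSection:
    @staticmethod
    def _inv(S):
        # uniaxial tensor scaled so the activity equals S
        a = np.sqrt(S / 12.0)
        return RamanInvariants(a_iso=np.array([a / 3]), gamma2=np.array([a**2]))

    def test_zero_activity_zero_cross_section(self):
        inv = RamanInvariants(a_iso=np.array([0.0]), gamma2=np.array([0.0]))
        assert raman_cross_section(inv, np.array([1000.0]))[0] == 0.0

    def test_low_temperature_limit(self):
        inv = self._inv(5.0)
        nu = np.array([800.0])
        cold = raman_cross_section(inv, nu, temperature=1e-6)
        h, c, kB = units.H_PLANCK_J_S, units.C_LIGHT_M_S, units.K_BOLTZMANN_J_K
        nu_si = nu * 100
        nu_in = 1.0 / (514.5e-9)
        S_si = inv.activity * units.DALPHA_DQ_AU_TO_SI**2
        expected = (h / (8 * np.pi**2 * c * nu_si) * (2 * np.pi) ** 4 / 45
                    * (nu_in - nu_si) ** 4 * S_si)
        assert cold[0] == pytest.approx(expected[0], rel=1e-9)

    def test_quartic_scattering_law(self):
        """At fixed activity and band center, sigma' scales with the
        fourth power of (nu_in - nu_I): halving vs doubling the offset
        gives the 1/16 ratio."""
        inv = self._inv(3.0)
        nu_I = 1000.0
        wl2 = 1e7 / (2 * nu_I)  # nm such that nu_in = 2 nu_I
        wl3 = 1e7 / (3 * nu_I)
        s2 = raman_cross_section(inv, np.array([nu_I]), wavelength_nm=wl2)
        s3 = raman_cross_section(inv, np.array([nu_I]), wavelength_nm=wl3)
        assert s2[0] / s3[0] == pytest.approx(1.0 / 16.0, rel=1e-12)

    def test_nonpositive_wavenumber_advises_filtering(self):
        inv = self._inv(1.0)
        with pytest.raises(ValueError, match="pseudo"):
            raman_cross_section(inv, np.array([-10.0]))


class TestDegenerateBlocks:
    def test_intensity_sum_invariant_under_degenerate_basis_choice(self, rng):
        """Rotating the eigenbasis inside a degenerate block changes the
        individual sticks but not the summed IR intensity of the block."""
        record, _ = make_diatomic(0.5, 2.0, 2.0)
        modes = _modes_from(record)
        # the five zero modes are degenerate; mix two of them
        V = modes.eigenvectors.copy()
        th = 0.7
        V[:, 2], V[:, 3] = (np.cos(th) * V[:, 2] + np.sin(th) * V[:, 3],
                            -np.sin(th) * V[:, 2] + np.cos(th) * V[:, 3])
        mixed = type(modes)(wavenumbers=modes.wavenumbers, eigenvectors=V,
                            cartesian_displacements=modes.cartesian_displacements,
                            masses=modes.masses)
        labels = [3, 4]
        a0 = ir_intensity(transform_gradients(record.D_mu, record.D_alpha,
                                              modes, record.core_masses, labels))
        a1 = ir_intensity(transform_gradients(record.D_mu, record.D_alpha,
                                              mixed, record.core_masses, labels))
        assert a1.sum() == pytest.approx(a0.sum(), rel=1e-10, abs=1e-18)
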