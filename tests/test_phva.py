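"""Mass-weighting, eigenanalysis, rigid-body bases, pseudo-mode filtering."""

import numpy as np
import pytest
from conftest import random_rotation

from phvaspec import (ModeFilterRule, eigenanalyze, filter_modes, make_cluster,
                      make_diatomic, mass_weight, pseudo_contributions,
                      trans_rot_basis, units)
from phvaspec.phva import MassWeightedHessian, PseudoProfile


class TestMassWeight:
    def test_unit_masses_identity(self, rng):
        H = rng.normal(size=(6, 6))
        H = H + H.T
        assert np.array_equal(mass_weight(H, [1.0, 1.0]).matrix, H)

    def test_block_scaling(self):
        H = np.ones((6, 6))
        out = mass_weight(H, [4.0, 9.0]).matrix
        assert np.allclose(out[:3, :3], 1 / 4)
        assert np.allclose(out[3:, 3:], 1 / 9)
        assert np.allclose(out[:3, 3:], 1 / 6)

    def test_symmetry_preserved(self, rng):
        H = rng.normal(size=(9, 9))
        H = H + H.T
        out = mass_weight(H, [1.5, 2.5, 12.0]).matrix
        assert np.abs(out - out.T).max() < 1e-12

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mass_weight(np.zeros((6, 6)), [1.0, -2.0])


class TestEigenanalyze:
    def test_diatomic_closed_form(self):
        k, m = 0.37, 1.007825
        record, nu_exact = make_diatomic(k, m, m)
        modes = eigenanalyze(mass_weight(record.H_partial, record.core_masses))
        assert modes.wavenumbers[0] == pytest.approx(nu_exact, rel=1e-9)
        # one stretch + five zero modes
        assert np.abs(modes.wavenumbers[1:]).max() < 1e-6 * nu_exact

    def test_zero_matrix_gives_zero_wavenumbers(self):
        modes = eigenanalyze(mass_weight(np.zeros((6, 6)), [1.0, 2.0]))
        assert np.array_equal(modes.wavenumbers, np.zeros(6))

    def test_negative_eigenvalue_maps_to_negative_wavenumber(self):
        lam = 0.02
        M = np.diag([-lam, 0.0, 0.0])
        modes = eigenanalyze(MassWeightedHessian(matrix=M, masses=np.array([1.0])))
        expected = -np.sqrt(lam) * units.WAVENUMBER_PER_SQRT_EIGVAL
        assert modes.wavenumbers[-1] == pytest.approx(expected, rel=1e-12)
        assert (modes.wavenumbers[:-1] == 0).all()

    def test_eigenvectors_orthonormal_and_sorted(self, rng):
        H = rng.normal(size=(12, 12))
        H = H + H.T
        modes = eigenanalyze(mass_weight(H, [1.0, 2.0, 3.0, 4.0]))
        V = modes.eigenvectors
        assert np.abs(V.T @ V - np.eye(12)).max() < 1e-10
        assert (np.diff(modes.wavenumbers) <= 1e-9).all()

    def test_rotation_invariance_of_wavenumbers(self, rng):
        record, _ = make_diatomic(0.5, 1.5, 7.0)
        Q = random_rotation(rng)
        R3 = np.kron(np.eye(2), Q)
        H_rot = R3 @ record.H_partial @ R3.T
        nu0 = eigenanalyze(mass_weight(record.H_partial, record.core_masses)).wavenumbers
        nu1 = eigenanalyze(mass_weight(H_rot, record.core_masses)).wavenumbers
        # zero modes carry O(eps * ||H||) eigenvalue noise -> ~1e-4 cm^-1
        assert np.allclose(nu0, nu1, rtol=1e-9, atol=1e-3)

    def test_asymmetric_input_rejected(self):
        M = np.zeros((3, 3))
        M[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            eigenanalyze(MassWeightedHessian(matrix=M, masses=np.array([1.0])))


class TestTransRotBasis:
    def test_nonlinear_triatomic_has_six_vectors(self):
        R = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        basis = trans_rot_basis(R, [16.0, 1.0, 1.0])
        assert basis.n_vectors == 6 and basis.n_rot == 3
        G = basis.vectors.T @ basis.vectors
        assert np.abs(G - np.eye(6)).max() < 1e-10

    def test_collinear_diatomic_has_five(self):
        R = np.array([[0.0, 0, 0], [0, 0, 1.5]])
        basis = trans_rot_basis(R, [1.0, 1.0])
        assert basis.n_vectors == 5 and basis.n_rot == 2

    def test_equal_masses_metrics_coincide(self):
        R = np.array([[0.0, 0, 0], [1.3, 0, 0], [0.2, 1.1, 0], [0, 0.3, 0.9]])
        m = [3.5] * 4
        b_cart = trans_rot_basis(R, m, metric="cartesian")
        b_mw = trans_rot_basis(R, m, metric="mass_weighted")
        assert np.allclose(b_cart.vectors, b_mw.vectors, atol=1e-12)

    def test_coincident_atoms_rejected(self):
        R = np.zeros((3, 3))
        with pytest.raises(ValueError, match="coincide"):
            trans_rot_basis(R, [1.0, 1.0, 1.0])


class TestPseudoContributions:
    def test_isolated_molecule_completeness(self, decoupled_snapshot):
        """At zero coupling the rigid modes carry the whole 3+n_rot weight
        and every vibrational mode is exactly orthogonal to it (in the
        metric where the eigenvectors are orthonormal)."""
        record, _ = decoupled_snapshot
        modes = eigenanalyze(mass_weight(record.H_partial, record.core_masses))
        basis = trans_rot_basis(record.core_coords, record.core_masses,
                                metric="mass_weighted")
        prof = pseudo_contributions(modes, basis)
        total = prof.total
        nvib = modes.n_modes - basis.n_vectors
        assert total[:nvib].max() < 1e-8
        assert total.sum() == pytest.approx(3 + basis.n_rot, abs=1e-6)
        assert np.allclose(total[nvib:], 1.0, atol=1e-8)

    def test_bounds_hold_in_both_metrics(self, acetone_spec):
        record, _ = make_cluster(acetone_spec, seed=3)
        modes = eigenanalyze(mass_weight(record.H_partial, record.core_masses))
        for metric in ("cartesian", "mass_weighted"):
            basis = trans_rot_basis(record.core_coords, record.core_masses,
                                    metric=metric)
            prof = pseudo_contributions(modes, basis)
            assert (prof.total >= -1e-12).all()
            assert prof.total.max() <= 1 + 1e-9

    def test_homonuclear_stretch_has_no_rigid_character(self):
        record, _ = make_diatomic(0.4, 2.0, 2.0)
        modes = eigenanalyze(mass_weight(record.H_partial, record.core_masses))
        for metric in ("cartesian", "mass_weighted"):
            basis = trans_rot_basis(record.core_coords, record.core_masses,
                                    metric=metric)
            prof = pseudo_contributions(modes, basis)
            assert prof.total[0] < 1e-12  # the stretch, label 1

    def test_parseval_sum_mass_weighted(self, acetone_spec):
        record, _ = make_cluster(acetone_spec, seed=8)
        modes = eigenanalyze(mass_weight(record.H_partial, record.core_masses))
        basis = trans_rot_basis(record.core_coords, record.core_masses,
                                metric="mass_weighted")
        prof = pseudo_contributions(modes, basis)
        assert prof.total.sum() == pytest.approx(3 + basis.n_rot, abs=1e-6)


class TestFilterModes:
    @staticmethod
    def _profile(totals):
        totals = np.asarray(totals, dtype=float)
        return PseudoProfile(translational=totals / 2, rotational=totals / 2)

    def test_threshold_discards_high_mean_labels(self, rng):
        """Mirror of the workflow's 30-mode case: eight lowest-frequency
        labels carry substantial mean pseudo character, the rest ~0."""
        profiles = []
        for _ in range(40):
            t = rng.uniform(0.0, 0.01, size=30)
            t[22:] = rng.uniform(0.3, 0.9, size=8)
            profiles.append(self._profile(t))
        kept = filter_modes(profiles, ModeFilterRule("threshold", tau=0.1))
        assert list(kept) == list(range(1, 23))

    def test_fixed_count_discards_lowest_frequency_labels(self):
        profiles = [self._profile(np.zeros(30))] * 3
        kept = filter_modes(profiles, ModeFilterRule("fixed_count", n_lowest=6))
        assert list(kept) == list(range(1, 25))

    def test_single_snapshot_mean_is_itself(self):
        t = np.zeros(12)
        t[9:] = 0.8
        kept = filter_modes([self._profile(t)],
                            ModeFilterRule("threshold", tau=0.1))
        assert list(kept) == list(range(1, 10))

    def test_ensemble_mean_decides_not_single_snapshot(self):
        """A label that spikes in one configuration but is quiet on
        average survives; one that is persistently high is discarded."""
        quiet_spike = np.array([0.9] + [0.0] * 9)  # label 1 spikes once
        persistent = np.array([0.0] * 9 + [0.5])  # label 10 always high
        profiles = [self._profile(quiet_spike + persistent)]
        profiles += [self._profile(persistent)] * 19
        kept = filter_modes(profiles, ModeFilterRule("threshold", tau=0.1))
        assert 1 in kept and 10 not in kept

    def test_empty_keep_set_rejected(self):
        profiles = [self._profile(np.full(6, 0.9))]
        with pytest.raises(ValueError, match="every mode"):
            filter_modes(profiles, ModeFilterRule("threshold", tau=0.1))
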