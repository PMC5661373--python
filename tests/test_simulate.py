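"""Density-matrix simulator: profiles, invariants, and independent oracles.

Two oracle routes are used.  The textbook product-operator closed forms
(cos(pi*J*TE) echo modulation, editing refocusing) describe the secular
(weak-coupling) Hamiltonian, so they are checked against the simulator's
weak-coupling mode, where they must hold to near machine precision.  The
default full isotropic Hamiltonian is checked against a brute-force
matrix-exponential propagation written independently here, and its
first-order-in-J/delta-nu strong-coupling deviation from the weak-coupling
closed form is pinned as converging at large shift separation.
"""

import numpy as np
import pytest
from scipy.linalg import expm

from gabaedit.simulate import (density_matrix_trajectory, inversion_profile,
                               make_basis, scheme_edit_centers,
                               simulate_press_basing, BasisSet)
from gabaedit.spins import SpinSystem, build_spin_system

J_AX = 7.3


def ax_system(shift_a=3.01, shift_x=1.89):
    return SpinSystem("AX", (shift_a, shift_x),
                      np.array([[0.0, J_AX], [J_AX, 0.0]]))


class TestInversionProfile:
    def test_on_resonance_full_inversion(self):
        assert inversion_profile(0.0, 60.0) == pytest.approx(-1.0)

    def test_far_off_resonance_untouched(self):
        assert inversion_profile(50 * 60.0, 60.0) == pytest.approx(1.0, abs=1e-6)

    def test_half_width_value_matches_closed_form(self):
        # 1 - 2*exp(-4 ln2 (fwhm/2)^2 / fwhm^2) = 1 - 2*exp(-ln2) = 0
        assert inversion_profile(30.0, 60.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("offset", [3.0, 17.5, 120.0])
    def test_even_and_monotone(self, offset):
        assert inversion_profile(offset, 60.0) == inversion_profile(-offset, 60.0)
        assert inversion_profile(offset, 60.0) < inversion_profile(offset * 1.5, 60.0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            inversion_profile(10.0, 0.0)


class TestDensityMatrixInvariants:
    def test_trace_and_hermiticity_preserved(self, params):
        traj = density_matrix_trajectory(build_spin_system("GABA"), params,
                                         edit_center_ppm=2.0)
        purity0 = None
        for label, rho in traj:
            assert abs(np.trace(rho)) < 1e-12
            assert np.allclose(rho, rho.conj().T, atol=1e-12)
            purity = np.trace(rho @ rho).real
            if purity0 is None:
                purity0 = purity
            assert purity == pytest.approx(purity0, abs=1e-10)

    def test_te_zero_spectrum_integral_equals_proton_count(self, params):
        p0 = params.replace(te_ms=1e-9)
        for name in ("GABA", "NAA", "Cr"):
            system = build_spin_system(name)
            fid = simulate_press_basing(system, p0)
            integral = np.sum(fid.to_spectrum().values) / params.n_points
            assert integral == pytest.approx(sum(system.proton_scale),
                                             rel=1e-9, abs=1e-9)

    def test_oversized_system_refused(self, params):
        big = SpinSystem("big", tuple([1.0 + 0.1 * i for i in range(8)]),
                         np.zeros((8, 8)))
        simulate_press_basing(big, params)  # 256 is allowed...
        with pytest.raises(ValueError, match="8-spin"):
            SpinSystem("bigger", tuple([1.0] * 9), np.zeros((9, 9)))


class TestWeakCouplingClosedForms:
    """Product-operator oracles against the matching (secular) Hamiltonian."""

    def test_echo_modulation_cos_pi_j_te(self, params):
        p0 = params.replace(te_ms=1e-9)
        sys = ax_system()
        f_te = simulate_press_basing(sys, params, None, coupling="weak", detect=[0])
        f_0 = simulate_press_basing(sys, p0, None, coupling="weak", detect=[0])
        ratio = (f_te.samples[0] / f_0.samples[0]).real
        assert ratio == pytest.approx(np.cos(np.pi * J_AX * params.te_s), abs=1e-9)

    def test_editing_refocuses_j_evolution(self, params):
        p0 = params.replace(te_ms=1e-9)
        sys = ax_system()
        f_ed = simulate_press_basing(sys, params, 1.89, coupling="weak", detect=[0])
        f_0 = simulate_press_basing(sys, p0, None, coupling="weak", detect=[0])
        assert (f_ed.samples[0] / f_0.samples[0]).real == pytest.approx(1.0, abs=1e-9)

    def test_difference_recovers_the_refocused_doublet(self, params):
        sys = ax_system()
        f_ne = simulate_press_basing(sys, params, None, coupling="weak", detect=[0])
        f_ed = simulate_press_basing(sys, params, 1.89, coupling="weak", detect=[0])
        diff0 = (f_ne.samples[0] - f_ed.samples[0]).real
        expected = np.cos(np.pi * J_AX * params.te_s) - 1.0
        assert diff0 == pytest.approx(expected, abs=1e-9)


class TestFullHamiltonianOracle:
    """Independent brute-force expm propagation of the same sequence."""

    @staticmethod
    def brute_force_fid(shift_a, shift_x, params, edit_center_ppm, t_samples):
        d = 4
        sx = np.array([[0, .5], [.5, 0]], complex)
        sy = np.array([[0, -.5j], [.5j, 0]], complex)
        sz = np.array([[.5, 0], [0, -.5]], complex)
        e = np.eye(2)
        Ix, Iy, Iz = np.kron(sx, e), np.kron(sy, e), np.kron(sz, e)
        Sx, Sy, Sz = np.kron(e, sx), np.kron(e, sy), np.kron(e, sz)
        nu_a = params.offset_hz(shift_a)
        nu_x = params.offset_hz(shift_x)
        H = 2 * np.pi * (nu_a * Iz + nu_x * Sz
                         + J_AX * (Ix @ Sx + Iy @ Sy + Iz @ Sz))
        rot = lambda op, th: expm(-1j * th * op)
        U90 = rot(Ix + Sx, np.pi / 2)
        U180 = rot(Iy + Sy, np.pi)
        if edit_center_ppm is None:
            Ue = np.eye(d)
        else:
            off = np.array([nu_a, nu_x]) - params.offset_hz(edit_center_ppm)
            th = np.arccos(np.clip(inversion_profile(off, params.edit_fwhm_hz),
                                   -1, 1))
            Ue = rot(Ix, th[0]) @ rot(Sx, th[1])
        te = params.te_s
        rho = Iz + Sz
        for item in [U90, te / 8, U180, te / 8, Ue, 3 * te / 8, U180,
                     te / 8, Ue, te / 4]:
            if isinstance(item, float):
                u = expm(-1j * H * item)
                rho = u @ rho @ u.conj().T
            else:
                rho = item @ rho @ item.conj().T
        Fm = (Ix - 1j * Iy) + (Sx - 1j * Sy)
        out = np.empty(len(t_samples), dtype=complex)
        for i, t in enumerate(t_samples):
            u = expm(-1j * H * t)
            out[i] = -4j / d * np.trace(u @ rho @ u.conj().T @ Fm)
        return out

    @pytest.mark.parametrize("edit", [None, 1.89])
    def test_matches_brute_force_to_1e10(self, params, edit):
        sys = ax_system()
        fid = simulate_press_basing(sys, params, edit)
        idx = np.arange(0, params.n_points, 256)
        oracle = self.brute_force_fid(3.01, 1.89, params, edit,
                                      params.time_axis()[idx])
        assert np.max(np.abs(fid.samples[idx] - oracle)) < 1e-10

    def test_strong_coupling_deviation_vanishes_with_separation(self, params):
        """Full-H echo amplitude approaches cos(pi*J*TE) as J/dnu -> 0."""
        p0 = params.replace(te_ms=1e-9)
        expected = np.cos(np.pi * J_AX * params.te_s)

        def deviation(shift_a, shift_x):
            sys = ax_system(shift_a, shift_x)
            f_te = simulate_press_basing(sys, params, None, detect=[0])
            f_0 = simulate_press_basing(sys, p0, None, detect=[0])
            return abs(f_te.samples[0] / f_0.samples[0] - expected)

        # ~350 J separation: first-order strong-coupling artifact below 1%
        assert deviation(9.5, 1.0) < 0.01
        # and it is genuinely larger at GABA-like separation (documented)
        assert deviation(3.01, 1.89) > deviation(9.5, 1.0)


class TestEditingSchemes:
    def test_symmetric_scheme_centers_average_to_1p7(self, params):
        on, off = scheme_edit_centers("symmetric_1p7", params)
        assert (on + off) / 2 == pytest.approx(1.7)

    def test_water_symmetric_mirrors_about_carrier(self, params):
        on, off = scheme_edit_centers("water_symmetric", params)
        assert (on + off) / 2 == pytest.approx(params.carrier_ppm)

    def test_unknown_scheme_rejected(self, params):
        with pytest.raises(ValueError, match="scheme"):
            scheme_edit_centers("mystery", params)

    def test_basis_contains_required_metabolites(self, basis_sym):
        for name in ("NAA", "Glu", "Gln", "GABA", "GSH", "NAAG"):
            assert name in basis_sym.entries
            assert set(basis_sym.entries[name]) == {"edited", "non_edited"}

    def test_basis_deterministic(self, params, basis_sym):
        again = make_basis(params, "symmetric_1p7", metabolites=("GABA",))
        assert np.array_equal(again.entries["GABA"]["edited"].samples,
                              basis_sym.entries["GABA"]["edited"].samples)

    def test_distant_edit_leaves_uncoupled_spin_unchanged(self, params):
        cr = build_spin_system("Cr")
        plain = simulate_press_basing(cr, params, None)
        edited = simulate_press_basing(cr, params, 2.0)
        rel = np.max(np.abs(edited.samples - plain.samples)) \
            / np.max(np.abs(plain.samples))
        assert rel < 1e-9

    def test_swapping_edit_centers_negates_the_difference(self, params):
        gaba = build_spin_system("GABA")
        s_on = simulate_press_basing(gaba, params, 2.0)
        s_off = simulate_press_basing(gaba, params, 1.4)
        diff = s_off.samples - s_on.samples
        diff_swapped = s_on.samples - s_off.samples
        assert np.array_equal(diff_swapped, -diff)

    def test_hdf5_round_trip(self, tmp_path, params):
        basis = make_basis(params, "symmetric_1p7", metabolites=("GABA", "Cr"))
        path = str(tmp_path / "basis.h5")
        basis.save_hdf5(path)
        loaded = BasisSet.load_hdf5(path)
        assert loaded.scheme == "symmetric_1p7"
        assert loaded.params == basis.params
        assert np.array_equal(loaded.entries["GABA"]["non_edited"].samples,
                              basis.entries["GABA"]["non_edited"].samples)
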