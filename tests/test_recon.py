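"""Reconstruction: DFT oracle, registration recovery, combination, widths."""

import numpy as np
import pytest

from gabaedit.experiments import drift_correction_experiment
from gabaedit.recon import (apply_freq_phase, combine_coils, csi_reconstruct,
                            difference_spectrum, estimate_freq_phase,
                            linewidth_fwhm, spatial_ifft)
from gabaedit.sequence import FID, SequenceParams, Spectrum, ppm_axis
from gabaedit.simulate import make_basis
from gabaedit.synth import EncodingSpec, MultiCoilCSI, PhantomConfig, \
    generate_acquisition, make_sensitivities


def wrap_kspace(k, params, n_avg=1, n_coil=1):
    """Package a (nx, ny, t) k-space array as a MultiCoilCSI."""
    nx, ny, nt = k.shape
    data = k[None, None, None, :, :, None, :].astype(complex)
    data = np.broadcast_to(data, (2, n_avg, n_coil, nx, ny, 1, nt)).copy()
    enc = EncodingSpec(matrix=(nx, ny, 1), n_averages=n_avg)
    return MultiCoilCSI(data=data, encoding=enc, params=params)


class TestSpatialTransform:
    def test_single_voxel_passthrough(self, small_params):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(2, 3, 2, 1, 1, 1, small_params.n_points)) + 0j
        raw = MultiCoilCSI(data=data, encoding=EncodingSpec.single_voxel(3),
                           params=small_params)
        out = csi_reconstruct(raw, half_voxel_shift=True)
        assert np.array_equal(out, data)

    @pytest.mark.parametrize("shift", [0.0, 0.5])
    def test_point_source_matches_direct_dft(self, shift):
        """ifft + ramp equals an explicit DFT including the shift term."""
        params = SequenceParams(n_points=16, sweep_hz=6000.0)
        rng = np.random.default_rng(1)
        nx = ny = 8
        img = np.zeros((nx, ny, 16), dtype=complex)
        img[3, 5] = rng.normal(size=16) + 1j * rng.normal(size=16)
        k = np.fft.fft2(img, axes=(0, 1))
        raw = wrap_kspace(k, params)
        out = csi_reconstruct(raw, half_voxel_shift=(shift != 0.0))[0, 0, 0, :, :, 0]
        # direct DFT oracle: image at (x + shift) reconstructed from k-space
        kx = np.fft.fftfreq(nx) * nx
        ky = np.fft.fftfreq(ny) * ny
        oracle = np.zeros_like(img)
        for x in range(nx):
            for y in range(ny):
                phase = np.exp(2j * np.pi * (kx[:, None] * (x + shift) / nx
                                             + ky[None, :] * (y + shift) / ny))
                oracle[x, y] = np.tensordot(k, phase, axes=([0, 1], [0, 1])) \
                    / (nx * ny)
        assert np.max(np.abs(out - oracle)) < 1e-10

    def test_opposite_half_shifts_cancel(self):
        rng = np.random.default_rng(2)
        k = rng.normal(size=(1, 1, 1, 8, 8, 1, 4)) \
            + 1j * rng.normal(size=(1, 1, 1, 8, 8, 1, 4))
        img = spatial_ifft(k, axes=(3, 4), shift_voxels=(0.5, 0.5))
        k2 = np.fft.fft2(img, axes=(3, 4))
        back = spatial_ifft(k2, axes=(3, 4), shift_voxels=(-0.5, -0.5))
        plain = spatial_ifft(k, axes=(3, 4))
        assert np.max(np.abs(back - plain)) < 1e-12

    def test_parseval_energy_conserved(self):
        rng = np.random.default_rng(3)
        k = rng.normal(size=(2, 1, 2, 8, 8, 1, 32)) \
            + 1j * rng.normal(size=(2, 1, 2, 8, 8, 1, 32))
        img = spatial_ifft(k, axes=(3, 4), shift_voxels=(0.5, 0.5))
        e_k = np.sum(np.abs(k) ** 2)
        e_img = np.sum(np.abs(img) ** 2) * 64  # ifft2 scaling over 8x8
        assert e_img == pytest.approx(e_k, rel=1e-10)


@pytest.fixture(scope="module")
def cr_series_setup():
    params = SequenceParams()
    basis = make_basis(params, "symmetric_1p7",
                       metabolites=("Cr", "NAA", "Cho", "water"))
    phantom = PhantomConfig(grid_shape=(1, 1, 1), concentrations={
        "brain": {"Cr": 0.66, "NAA": 1.0, "Cho": 0.26}}, linewidth_hz=9.0)
    coils = make_sensitivities(1, (1, 1, 1), uniform=True)
    raw = generate_acquisition(basis, phantom, coils,
                               EncodingSpec.single_voxel(1), noise_sd=0.0)
    return params, raw.data[1, 0, 0, 0, 0, 0, :]


class TestRegistration:
    def test_no_drift_noiseless_estimates_zero(self, cr_series_setup):
        params, s = cr_series_setup
        est = estimate_freq_phase(np.stack([s, s, s]), params)
        assert np.max(np.abs(est.freq_hz)) < 1e-6
        assert np.max(np.abs(est.phase_deg)) < 1e-5

    def test_constant_phase_recovered_within_one_degree(self, cr_series_setup):
        params, s = cr_series_setup
        t = params.time_axis()
        s2 = s * np.exp(1j * np.deg2rad(30.0))
        est = estimate_freq_phase(np.stack([s, s2]), params)
        assert est.phase_deg[1] == pytest.approx(30.0, abs=1.0)
        assert est.freq_hz[1] == pytest.approx(0.0, abs=0.05)

    def test_frequency_shift_recovered(self, cr_series_setup):
        params, s = cr_series_setup
        t = params.time_axis()
        series = np.stack([s * np.exp(-2j * np.pi * f * t)
                           for f in (0.0, 1.0, 5.0, 12.0, 25.0)])
        est = estimate_freq_phase(series, params)
        assert np.allclose(est.freq_hz, [0.0, 1.0, 5.0, 12.0, 25.0], atol=0.05)

    def test_applying_negated_estimates_aligns_series(self, cr_series_setup):
        params, s = cr_series_setup
        t = params.time_axis()
        s2 = s * np.exp(-2j * np.pi * 3.0 * t + 1j * 0.4)
        series = np.stack([s, s2])
        est = estimate_freq_phase(series, params)
        aligned = apply_freq_phase(series, params, est)
        rel = np.max(np.abs(aligned[1] - aligned[0])) / np.max(np.abs(s))
        assert rel < 1e-3

    def test_snr_floor_returns_zero_with_warning(self, cr_series_setup):
        params, _ = cr_series_setup
        rng = np.random.default_rng(0)
        noise = rng.normal(size=(2, params.n_points)) \
            + 1j * rng.normal(size=(2, params.n_points))
        with pytest.warns(UserWarning, match="SNR floor"):
            est = estimate_freq_phase(noise, params)
        assert np.all(est.freq_hz == 0)

    def test_linear_drift_recovery_and_artifact_removal(self):
        """0.2 Hz/average drift: truth recovered, Cr artifact suppressed."""
        out = drift_correction_experiment(n_averages=32, seed=4)
        assert out["freq_rms_error_hz"] <= 0.1
        assert out["artifact_reduction_factor"] >= 10.0


class TestCoilCombination:
    def test_single_unit_coil_identity(self):
        fid = np.arange(8, dtype=complex)[None, :]
        assert np.array_equal(combine_coils(fid, np.ones(1)), fid[0])

    def test_equal_signals_unit_sensitivities_preserved(self):
        fid = (np.random.default_rng(0).normal(size=16)
               + 1j * np.random.default_rng(1).normal(size=16))
        stacked = np.broadcast_to(fid, (8, 16))
        out = combine_coils(stacked, np.ones(8))
        assert np.allclose(out, fid, atol=1e-12)

    def test_all_zero_sensitivities_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            combine_coils(np.ones((2, 4), dtype=complex), np.zeros(2))

    def test_combined_snr_beats_best_single_coil(self):
        """Sensitivity weighting: ensemble SNR >= max single-coil SNR."""
        rng = np.random.default_rng(7)
        n_coils, n_draws, n_t = 8, 100, 64
        sens = rng.normal(size=n_coils) + 1j * rng.normal(size=n_coils)
        signal = np.exp(2j * np.pi * 0.05 * np.arange(n_t))
        combined = np.empty((n_draws, n_t), dtype=complex)
        per_coil = np.empty((n_draws, n_coils, n_t), dtype=complex)
        for d in range(n_draws):
            noise = rng.normal(size=(n_coils, n_t)) \
                + 1j * rng.normal(size=(n_coils, n_t))
            data = sens[:, None] * signal + noise
            per_coil[d] = data
            combined[d] = combine_coils(data, sens)
        def snr(x, s_amp):
            return s_amp / x.std(ddof=1)
        snr_comb = snr(combined - signal, 1.0)
        snr_single = max(snr(per_coil[:, c, :] - sens[c] * signal,
                             np.abs(sens[c])) for c in range(n_coils))
        assert snr_comb >= snr_single


class TestDifferenceAndWidth:
    def test_identical_inputs_zero_and_swap_negates(self, small_params):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=small_params.n_points) + 0j
        spec = Spectrum(values=vals, ppm_axis=ppm_axis(small_params),
                        params=small_params)
        other = Spectrum(values=2 * vals, ppm_axis=ppm_axis(small_params),
                         params=small_params)
        assert np.all(difference_spectrum(spec, spec).values == 0)
        d1 = difference_spectrum(other, spec).values
        d2 = difference_spectrum(spec, other).values
        assert np.array_equal(d2, -d1)

    def test_axis_mismatch_rejected(self, small_params):
        vals = np.zeros(small_params.n_points, dtype=complex)
        a = Spectrum(values=vals, ppm_axis=ppm_axis(small_params),
                     params=small_params)
        b = Spectrum(values=vals, ppm_axis=ppm_axis(small_params) + 0.1,
                     params=small_params)
        with pytest.raises(ValueError, match="axes"):
            difference_spectrum(a, b)

    def test_gaba_difference_multiplet_at_3ppm(self, basis_sym):
        """The cycle difference concentrates GABA signal near 3.01 ppm.

        With difference defined as non-edited minus edited and the edit-on
        pulse refocusing the 3.01 ppm J-evolution, the multiplet appears
        with negative absorption amplitude (the package's documented sign).
        """
        diff = basis_sym.difference_fids()["GABA"].broadened(9.0).to_spectrum()
        region = diff.window_mask(2.7, 3.3)  # away from the inverted 1.89 ppm
        mag = np.where(region, np.abs(diff.values), 0.0)
        peak_ppm = diff.ppm_axis[np.argmax(mag)]
        assert peak_ppm == pytest.approx(3.01, abs=0.05)
        window = diff.window_mask(2.9, 3.12)
        assert np.sum(diff.values[window].real) < 0

    def test_lorentzian_width_closed_form(self, params):
        """FWHM of exp(-R2 t) is R2/pi, and doubles when R2 doubles."""
        t = params.time_axis()
        nu = params.offset_hz(3.0)
        for lw in (8.0, 16.0):
            r2 = np.pi * lw
            fid = FID(samples=np.exp(-2j * np.pi * nu * t - r2 * t),
                      dwell_s=params.dwell_s, params=params)
            width = linewidth_fwhm(fid.to_spectrum(), 3.0)
            assert width == pytest.approx(r2 / np.pi, rel=0.02)

    def test_zero_decay_singlet_resolution_limited(self, params):
        t = params.time_axis()
        nu = params.offset_hz(3.0)
        fid = FID(samples=np.exp(-2j * np.pi * nu * t), dwell_s=params.dwell_s,
                  params=params)
        width = linewidth_fwhm(fid.to_spectrum(), 3.0)
        assert width <= 2.0 * params.sweep_hz / params.n_points

    def test_no_peak_in_window_rejected(self, params):
        t = params.time_axis()
        nu = params.offset_hz(3.0)
        fid = FID(samples=np.exp(-2j * np.pi * nu * t - 30 * t),
                  dwell_s=params.dwell_s, params=params)
        with pytest.raises(ValueError, match="local maximum"):
            linewidth_fwhm(fid.to_spectrum(), 8.0)
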