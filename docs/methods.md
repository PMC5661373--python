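# Methods

`gabaedit` models the complete measurement chain of a J-difference edited
GABA acquisition at 7 T — spin physics, raw-data generation, reconstruction,
quantification, and test–retest scoring. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish about real measurements.

## Spin simulation

Each metabolite is a system of up to 8 coupled spins-1/2 (Hilbert dimension
≤ 256) with chemical shifts (ppm) and a symmetric scalar-coupling matrix
(Hz) taken from the standard proton-metabolite literature compilations and
recorded in one table of record (`gabaedit/spins.py`). Some systems are
deliberately reduced: creatine is its 3.027 ppm methyl singlet (weight 3),
glutathione keeps the cysteinyl CH–CH₂ subsystem plus the glycine singlet,
and the macromolecule pool is a two-spin pseudo-system — a 3.0 ppm resonance
J-coupled (7 Hz) to a partner at 1.7 ppm — which is exactly the coupling
topology that makes MM co-edit.

The rotating-frame Hamiltonian is H = Σᵢ 2πνᵢ Iᵢz + Σᵢ<ⱼ 2πJᵢⱼ Iᵢ·Iⱼ with
νᵢ the offset from the carrier (water, 4.7 ppm; 297.2 MHz at 7 T). The full
isotropic coupling term is kept, so strong-coupling effects are present by
default; a `coupling="weak"` option truncates to the secular 2πJ IᵢzIⱼz
form, which is the physics the textbook product-operator formulas describe
and is what those closed forms are verified against in the tests. This
distinction matters: hard-pulse echoes amplify strong-coupling corrections
to first order in J/Δν, so at GABA-like separations the full Hamiltonian
legitimately deviates from cos(πJ·TE) by a percent or two — a real PRESS
artifact, not an implementation error. The full-Hamiltonian propagation is
instead validated against an independent brute-force matrix-exponential
oracle (agreement ~1e-12 relative).

The sequence is an idealised double spin echo of total duration TE = 68 ms:
hard 90°ₓ at t = 0, hard 180°_y at TE/8 and 5TE/8 (separation TE/2 refocuses
chemical shift exactly at the echo), and two instantaneous frequency-
selective inversions at TE/4 and 3TE/4 (separation TE/2 refocuses the
J-evolution of any spin whose partner both pulses invert). The selective
pulse rotates each spin about x by arccos(p), where
p(f) = 1 − 2·exp(−4 ln2 · f²/FWHM²) is a Gaussian longitudinal inversion
profile (default FWHM 60 Hz — a placeholder for the scanner's pulse, exposed
in `SequenceParams`). The pulse is unitary and instantaneous; the gradient
spoiling that a real BASING/MEGA pair applies to spuriously excited
transverse magnetization is not modelled, so single-cycle spectra carry
small dispersive artifacts near partially rotated resonances. These cancel
in any quantity compared between cycles or schemes.

Two editing schemes are built in: `symmetric_1p7` places the edit-on/off
cycles at 2.0 and 1.4 ppm (mirrored about 1.7 ppm), `water_symmetric` at
2.0 and 7.4 ppm (mirrored about water). Because the MM pseudo-system's
1.7 ppm partner sits exactly midway between 2.0 and 1.4 ppm, both cycles
perturb it identically and its difference response cancels to numerical
noise (~1e-11 % of the water-symmetric response), while the GABA difference
agrees between schemes to ~4e-5 %.

**Sign convention.** The difference spectrum is non-edited − edited, with
"edited" the 2.0 ppm cycle. Since that cycle *refocuses* the GABA 3.01 ppm
multiplet (and TE ≈ 1/(2J) dephases it in the other cycle), the GABA
multiplet appears with negative absorption amplitude in the raw difference.
Quantification is sign-consistent — data and basis differences are computed
identically — so fitted amplitudes are positive.

## Synthetic acquisitions

The generator produces raw `(cycle, average, coil, kx, ky, kz, time)`
arrays for the two protocols: single-voxel (1×1×1, default 64 edited + 64
non-edited averages) and phase-encoded (8×8×1, one shot per cycle). Voxel
signals are concentration-weighted basis FIDs with Lorentzian broadening
(default 9 Hz, the anterior-cingulate creatine linewidth scale; the MM
pseudo-system gets +30 Hz to stand for its short T₂), optional residual
water (broadened 25 Hz), coil weighting by smooth low-order complex
polynomial maps, and spatial encoding by forward 2-D FFT. The default
phantom is NAA 1.0, Cr 0.66, Cho 0.26, Glu 0.8, Gln 0.25, GABA 0.1,
GSH 0.2, NAAG 0.15, MM 0.3 (relative units), giving fitted GABA/NAA ≈ 0.1,
the magnitude seen in vivo.

Injected imperfections, all with recorded ground truth: per-average
frequency drift (linear by default; the average index runs across the
blocked edited-then-non-edited ordering, so drift produces a systematic
inter-cycle offset), zero-order phase jitter, and i.i.d. circular Gaussian
noise per sample and coil (`noise_sd` is the standard deviation of each
real/imaginary component; default 0.02, which puts the per-average Cr peak
SNR near 475). Coil noise correlation is not modelled. Out-of-volume
contamination ("unspoiled coherence") is phenomenological: named spectral
components at chosen grid positions; in single-voxel mode they leak in
attenuated by the outer-volume-suppression efficiency (default 95%
suppression), with phase encoding they are localised and reach the target
voxel only through point-spread-function sidelobes of the half-voxel-shifted
grid.

The SNR knob used by the fitting experiments is the *per-average* spectral
SNR of the NAA peak; the experiments then carry the noise level left after
the protocol's 64 averages. The sweep 5–50 per average (effective 40–400)
reproduces reported GABA CRLBs of roughly 5–45%, bracketing the 6–21%
published for this protocol.

## Reconstruction

Order of operations: spatial inverse FFT (with the half-voxel in-plane
shift applied as an exact k-space linear phase, verified against a direct
DFT oracle to 1e-10) → per-coil, per-average frequency/phase registration →
sensitivity-weighted coil combination (conj(s)·x / Σ|s|², amplitude-
preserving) → averaging → cycle difference.

Registration is time-domain least squares against the first average,
restricted to a reference band (default 2.9–3.1 ppm, creatine, present in
both cycles). Three details proved load-bearing and are worth recording:

* the band filter uses Gaussian (15 Hz) edges — a brick-wall mask rings as
  a sinc in time and destroys the registration objective;
* the last ~85 ms of the record are excluded because FFT filtering is
  circular and wraps the t = 0 edge response into the tail, and the *first*
  10 ms are excluded because smooth in-band baselines (Lorentzian tails of
  strong cycle-dependent resonances such as the edited NAA acetyl) live at
  early times and otherwise bias cross-cycle alignment by ~0.15 Hz;
* each average is first registered to its predecessor (small, always
  in-basin shifts), the running total seeds a global re-registration to the
  first average, and a final pass re-registers the raw average after
  demodulating the estimated shift, which removes the band-edge bias of
  large accumulated drifts.

Under the default study conditions (0.2 Hz/average, 64+64 averages,
noise 0.02) the injected drift is recovered to ~0.01 Hz RMS and the
creatine subtraction artifact in the difference spectrum shrinks ~15-fold;
the residual floor is the genuine cycle difference in the creatine window
(NAA-acetyl tails), not registration error. At a per-average Cr SNR of 20
the single-average information bound for this band is itself ~0.1 Hz, so
sub-0.1 Hz recovery should not be expected there.

Linewidths are measured as absorption-mode FWHM: the spectrum is
interpolated exactly by time-domain zero filling, the local peak is phased
from its apex, and half-height crossings are found on the fine grid — a
Lorentzian of decay rate R₂ yields R₂/π to well under 1%.

## Quantification

The fitter models the real part of the phased spectrum over 1.8–4.1 ppm as
a non-negative linear combination of basis spectra (broadened to the
expected linewidth) plus a Legendre polynomial baseline (default order 2 —
a deliberate simplification of spline baselines), with three optional
global nonlinear refinements (zero-order phase applied to the data,
frequency shift and extra damping applied to the basis) optimised by
Nelder–Mead with the amplitudes re-solved by bounded least squares at every
step. Noise is estimated from the fit residual; CRLBs are
σ·sqrt(diag((DᵀD)⁻¹)) of the full linearised design, reported as % of each
amplitude, with a 999% sentinel at zero amplitude; inclusion requires CRLB
strictly below 20%. Collinear basis pairs (|correlation| > 0.9999) raise an
error naming the pair.

GSH is omitted from difference-spectrum fit bases: its only coupling
partner (cysteinyl CH, 4.56 ppm) is untouched by either editing cycle, so
its difference response is identically zero and the column would be
degenerate. It remains in the basis set and in non-edited fits.

Calibration, measured by the experiments: across 100 datasets over the SNR
sweep the median absolute relative GABA error (~8%) sits below the median
reported CRLB (~12%), and at fixed SNR the Monte-Carlo amplitude sd is
within ~5% of the mean CRLB.

**GABA+ mechanism and its magnitude.** Fitting water-symmetric differences
of the MM-bearing phantom yields a strictly larger GABA amplitude than
symmetric-1.7 fitting of the same phantom — the overestimation mechanism.
With the 60 Hz Gaussian profile the co-edited MM amplitude is only ~0.1% of
the GABA difference signal, far below the 1.76-fold excess published for in
vivo data: that magnitude depends on the true broad MM pool and the real
pulse profile, neither of which this narrow-profile, two-spin stand-in
claims to reproduce. The 1.76 figure in the acceptance output is computed
from the published GABA+/NAA and GABA/NAA ratios (0.58 and 0.21), which are
inputs.

## Reproducibility metrics

Two-point CV uses the n−1 sample standard deviation, 100·(|a−b|/√2)/mean —
the only convention that reproduces the bundled reference table's printed
CVs (14 of 15 pairs at ±0.1 pp; the remaining pair, ACC subject 3, is
internally inconsistent in the source and is flagged rather than repaired).
Region summaries follow the source's own conventions: the ACC mean (3.6%)
averages the printed per-subject CVs, the LSTG (6.0%) and RCaud (16.9%)
means equal the means of the recomputed pair CVs.

Dice overlap of oriented boxes is computed by rasterisation on a common
grid (default 0.5 mm; error is O(resolution/edge)), not analytic polytope
intersection — it handles arbitrary orientations with a testable bound.
Affine transforms map boxes via polar decomposition (rotation × stretch);
anisotropic stretch or shear beyond 1e-3 warns, since the image of a box is
then only approximately a box. Tissue fractions sample the GM/WM/CSF
probability volumes (NIfTI, voxel→mm affines, 0-based indices, RAS mm)
trilinearly over the rasterised box and normalise the three means to 100%.
The paired t-test is two-sided with n−1 degrees of freedom; identical
sequences return (0, 1); no multiple-testing correction is applied (single
test family). Chemical-shift displacement is offset·larmor/bandwidth as a
fraction of the selected dimension; the default over-excitation factor is
1.9.

## Problem sizes and determinism

Default spectra are 2048 points over 6000 Hz. The simulation-based
experiments use the full protocol sizes (64+64 averages, 8×8×1 grids, 100-
and 200-repeat Monte-Carlo loops); everything is seeded explicitly and
bit-exactly reproducible, including the pipeline manifest checksums.
Hypothesis-based property tests run derandomised.

## What the synthetic data do not show

The generator emulates controlled imperfections, not scanners: no B₀ field
maps or eddy currents, no shaped-pulse or gradient effects, no motion or
cardiac pulsation, no coil noise correlation, no true broad MM baseline,
and relaxation only as post-hoc line broadening. Passing tests therefore
establish the correctness and internal calibration of the algorithms under
the stated models — not that real 7 T data will achieve the same CVs,
CRLBs or artifact suppression. Published in-vivo outcomes (dice 0.92–0.95,
regional linewidths, tissue-fraction tables) depend on human scans and are
used here only as format references and fixed regression inputs.
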