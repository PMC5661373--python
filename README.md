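# gabaedit

Simulation and analysis of J-difference edited GABA spectroscopy at 7 T:
density-matrix simulation of PRESS with symmetric spectral editing,
synthetic multi-coil acquisitions with controlled imperfections,
reconstruction with spectral registration and coil combination,
linear-combination quantification with Cramér–Rao bounds, and the
test–retest statistics used to validate automated voxel prescription.

It is written for MRS methods developers and students who want a fully
inspectable, seeded model of the edited-GABA measurement chain — every
stage that a scanner-plus-LCModel pipeline hides is an importable function
with ground truth attached.

## The science in brief

GABA's 3.01 ppm ²CH₂ resonance hides under creatine. Its scalar coupling
(J ≈ 7.3 Hz) to the 1.89 ppm ³CH₂ protons makes it editable: in a PRESS
echo of TE = 68 ms ≈ 1/(2J) the 3.01 ppm multiplet dephases as
cos(πJ·TE) ≈ 0, but a frequency-selective inversion applied twice to the
1.89 ppm partner refocuses the J-evolution and restores it. The cycle
difference (non-edited − edited) then isolates GABA.

Macromolecules at 3.0 ppm couple to partners at 1.7 ppm and co-edit,
inflating GABA to "GABA+". Placing the two editing cycles at 2.0 and
1.4 ppm — *symmetric about 1.7 ppm* — makes both cycles act identically on
the MM system so its difference response cancels, while GABA is unaffected.
The package simulates this from the full spin Hamiltonian
H = Σᵢ 2πνᵢ Iᵢz + Σᵢ<ⱼ 2πJᵢⱼ Iᵢ·Iⱼ, builds edited/non-edited basis sets,
generates 1×1×1 (64+64 averages) or 8×8×1 phase-encoded multi-coil raw
data, reconstructs (k-space FFT with half-voxel shift, per-coil/average
frequency–phase registration, sensitivity-weighted combination), fits the
difference spectrum by non-negative linear combination with a polynomial
baseline, and scores test–retest runs with two-point CVs
(100·(|a−b|/√2)/mean), dice overlap of prescribed voxel boxes, center
shifts, tissue fractions and paired t-tests.

## Worked example

`examples/01_editing_mechanism.py` runs the two-spin editing experiment:

```
3.01 ppm in-phase amplitude, TE -> 0 reference :   1.0000
plain echo at TE = 68 ms               :   0.0113   (cos(pi*J*TE) = 0.0113)
editing pulse on the 1.89 ppm partner          :   1.0000
cycle difference (plain - edited)              :  -0.9887
```

The plain echo keeps ~1% of the doublet, the editing pulse restores it
fully, and the difference carries essentially the whole resonance — the
signal that editing extracts from under creatine. The other examples cover
the MM-cancellation phantom experiment (`02`), out-of-volume contamination
under single-voxel vs phase-encoded acquisition (`03`), quantification of
a noisy 64-average dataset with CRLBs (`04` — GABA comes back at
0.093 ± (16.8% CRLB) against a true 0.1), and the test–retest reference
table (`05` — region mean CVs 3.6 / 6.0 / 16.9%).

A thin CLI mirrors the pipeline stages
(`gabaedit simulate-basis / synth / recon / quant / repro / run`); `run`
drives everything from one YAML config and writes an HDF5 container plus a
manifest with checksums that make the run bit-exactly repeatable.

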