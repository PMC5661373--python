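"""Symmetric-1.7 editing cancels co-edited macromolecule signal.

Macromolecules resonating at 3.0 ppm couple to partners at 1.7 ppm, so a
conventional editing pair (2.0 ppm on / mirrored-about-water off) co-edits
them into the GABA region.  Placing the two cycles at 2.0 and 1.4 ppm —
symmetric about 1.7 ppm — makes both cycles act identically on the MM
system, so its difference response cancels while the GABA difference is
untouched (the phantom result this package's editing scheme reproduces).
"""

from gabaedit.experiments import mm_cancellation_experiment

out = mm_cancellation_experiment()

print("3.0 ppm MM difference amplitude")
print(f"  water-symmetric editing : {out['mm_amp_water_symmetric']:.4f}")
print(f"  symmetric-1.7 editing   : {out['mm_amp_symmetric_1p7']:.3e}")
print(f"  residual                : {out['mm_residual_pct']:.3e} %  (< 5% required)")
print()
print("GABA 3.01 ppm difference intensity between the two schemes")
print(f"  disagreement            : {out['gaba_scheme_disagreement_pct']:.3e} %  (< 2% required)")
print()
print("The MM response survives only under water-symmetric editing; the GABA")
print("signal is identical under both schemes, so the symmetric-1.7 scheme")
print("measures GABA rather than GABA+MM.")
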