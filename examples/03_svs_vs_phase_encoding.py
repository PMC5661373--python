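"""Out-of-volume contamination: single-voxel vs 8x8x1 phase encoding.

A lipid-like contaminant outside the volume of interest leaks into a
single-voxel acquisition attenuated only by the outer-volume suppression
efficiency; with 8x8x1 phase encoding it is localised to its own voxel
and reaches the target voxel only through point-spread-function sidelobes.
"""

from gabaedit.experiments import contamination_experiment

out = contamination_experiment()

print("3.0 ppm residual from an out-of-volume contaminant (unit amplitude)")
print(f"  single-voxel (95% OVS suppression) : {out['svs_residual']:.4f}")
print(f"  8x8x1 phase encoding (PSF leakage) : {out['csi_residual']:.4f}")
print(f"  SVS / CSI ratio                    : {out['svs_over_csi']:.1f}x")
print()
print("Phase encoding pushes the contamination below the outer-volume-")
print("suppressed single-voxel level without extra scan time, which is why")
print("the 8x8x1 scheme removes the unspoiled-coherence artifacts.")
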