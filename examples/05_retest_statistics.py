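"""Test-retest reproducibility statistics on the bundled reference table.

Five subjects, three brain regions, two scans each: the two-point CV
(|a-b|/sqrt(2) over the mean, in %) scores each GABA/NAA pair, and the
region means summarise how reproducible automated voxel prescription
makes the measurement.
"""

from gabaedit.experiments import retest_statistics
from gabaedit.metrics import overestimation_factor, paired_t

stats = retest_statistics()
table = stats["table"]

print(table[["roi", "subject", "gaba_naa_scan1", "gaba_naa_scan2",
             "cv_pct_printed", "cv_pct_recomputed"]].to_string(index=False))
print(f"\npairs reproducing the printed CV at ±0.1 pp: "
      f"{stats['n_matching_printed']}/{stats['n_pairs']}")
print(f"mean CV  ACC   : {stats['acc_mean_printed_cv_pct']:.1f}% (printed per-subject CVs)")
print(f"mean CV  LSTG  : {stats['lstg_mean_recomputed_cv_pct']:.1f}%")
print(f"mean CV  RCaud : {stats['rcaud_mean_recomputed_cv_pct']:.1f}%")

t, p = paired_t(table.gaba_naa_scan1.to_numpy(), table.gaba_naa_scan2.to_numpy())
print(f"\npaired t-test scan1 vs scan2 (all 15 pairs): t = {t:.2f}, p = {p:.2f}")
print(f"GABA+ overestimation from ratios 0.58 vs 0.21: "
      f"{overestimation_factor(0.58, 0.21):.2f}-fold")
print("\nACC and temporal-gyrus CVs sit well below the caudate's, and no")
print("systematic between-session shift is detectable.")
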