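"""Slice profiles, the dependent-region gradient, and cohort summaries.

Shows the ventral-to-dorsal Gd distribution of a phantom (the supine
instillate pools dorsally) and recomputes the published cohort summary
statistics from the reference per-specimen measurements.
"""

import numpy as np

import lungquant as lq
from lungquant import refdata
from lungquant.metrics import slice_profile, summarize_cohort

ds = lq.build_phantom(lq.PhantomSpec(seed=0).with_resolution((96, 96, 72)))
conc = lq.ConcentrationResult(
    c_map=ds.truth_concentration,
    r1_post=ds.truth_t1_post.with_data(1000.0 / ds.truth_t1_post.data),
    r1_pre=1000.0 / ds.spec.t1_pre_ms,
    invalid_voxel_count=0,
    negative_clamped_count=0,
)

prof = slice_profile(conc.c_map_clamped, ds.truth_labels, ds.spec.spacing, "ventral-dorsal")
per = prof.table["PER"].to_numpy()
mid = len(per) // 2
print(f"PER Gd amount, ventral half: {per[:mid].sum():.1f} umol; "
      f"dorsal half: {per[mid:].sum():.1f} umol")
print(f"profile sum {per.sum():.2f} umol == region amount "
      f"{lq.gd_amount(conc, ds.truth_labels, ds.spec.spacing, 'PER'):.2f} umol (conserved)")
print("Dorsal excess reflects gravity-dependent pooling in a supine subject.\n")

print("cohort summaries recomputed from the reference per-specimen tables:")
for label, column, table in [
    ("PDF (%)", "pdf_pct", refdata.distribution_table()),
    ("PVF (%)", "pvf_pct", refdata.distribution_table()),
    ("Gd amount (umol)", "gd_amount_umol", refdata.quantification_table()),
    ("T1 post (ms)", "t1_post_ms", refdata.quantification_table()),
]:
    s = summarize_cohort(table[column])
    print(f"  {label:<18} mean {s.mean:7.2f}  SD {s.sd:6.2f}  CoV {s.cov_pct:5.1f}%")
print("\nThe mean recovered Gd amount (93.5 umol) sits close to the 100 umol "
      "nominally instilled; PDF ~84% means most of the dose reached the "
      "peripheral lung rather than staying in the conducting airways.")
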