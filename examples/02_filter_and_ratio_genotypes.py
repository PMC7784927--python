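"""From raw allele read counts to a complete ratio-genotype matrix.

Simulates capture-seq read counts at 60X, applies the retention filters
(datapoint depth >= 2, site mean depth >= 60, missingness <= 0.2,
MAF >= 0.05), and converts to continuous genotypes #a/(#A+#a).
"""

import numpy as np

import tetragp as tg

mm = tg.simulate_marker_map(n_chrom=4, markers_per_chrom=60, seed=1)
founders = tg.simulate_founders(12, mm, maf_range=(0.05, 0.5), seed=2)
plan = tg.simpop.random_cross_plan(founders.founder_ids, 8, 12, seed=3)
ped, dosages, _ = tg.simulate_crosses(founders, plan, mm, seed=4)
rc = tg.simulate_read_counts(dosages, ped.individual_id, mm.marker_id,
                             mean_depth=60, min_depth=0, seed=5)

filtered, report = tg.apply_filters(rc, mm, tg.FilterThresholds())
print(report.to_json())
# The report counts what each step removed: low-depth datapoints set missing,
# markers dropped for shallow site coverage or low minor-allele frequency.

m = tg.ratio_genotypes(filtered)
print(f"\nratio matrix: {m.m.shape[0]} individuals x {m.m.shape[1]} markers, "
      f"entries in [{m.m.min():.3f}, {m.m.max():.3f}]")
# At 60X the read ratio approximates dosage/4 (0, .25, .5, .75, 1):
d_kept = dosages[:, np.isin(mm.marker_id, filtered.marker_ids)]
keep_i = np.isin(ped.individual_id, filtered.individual_ids)
err = np.abs(m.m - d_kept[keep_i] / 4)
print(f"mean |ratio - dosage/4| = {err.mean():.4f}")
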