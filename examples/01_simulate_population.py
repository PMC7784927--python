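"""Simulate a small autotetraploid breeding population.

Builds a marker map (12 chromosomes, markers grouped under capture probes),
draws tetraploid founders with LD along chromosomes, crosses them into
biparental families by tetrasomic meiosis, and prints the dosage and family
structure of the offspring.
"""

import numpy as np

import tetragp as tg

mm = tg.simulate_marker_map(n_chrom=12, markers_per_chrom=50, markers_per_probe=18, seed=1)
founders = tg.simulate_founders(20, mm, maf_range=(0.1, 0.5), ld_rho=0.5, seed=2)
plan = tg.simpop.random_cross_plan(founders.founder_ids, n_families=10,
                                   offspring_per_family=15, size_cv=0.4, seed=3)
ped, dosages, _ = tg.simulate_crosses(founders, plan, mm, seed=4)

print(f"map: {mm.n_markers} markers on {len(mm.chromosomes)} chromosomes, "
      f"{len(np.unique(mm.probe_id))} probes")
print(f"population: {ped.n_individuals} offspring in {len(ped.families())} families")
sizes = sorted(len(v) for v in ped.families().values())
print(f"family sizes: {sizes}")
print(f"dosage range {dosages.min()}..{dosages.max()}, "
      f"mean {dosages.mean():.2f} (0-4 alternative-allele copies per locus)")

# dosage class frequencies: tetraploids have five genotype classes per locus
freq = np.bincount(dosages.ravel(), minlength=5) / dosages.size
print("dosage class frequencies:", np.round(freq, 3))
# A mean near 2x the allele frequency and all five classes populated shows
# tetrasomic segregation at work.
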