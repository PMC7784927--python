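"""The structured sampling designs of the optimization experiments.

Cumulative marker series balanced over chromosomes, probe selections at
fixed spacing, fixed test sets, and the two training-set compositions.
"""

import numpy as np

import tetragp as tg

mm = tg.simulate_marker_map(n_chrom=12, markers_per_chrom=60, markers_per_probe=6, seed=1)

# nested marker-density series: every 500-set is inside its 720-set
(series,) = tg.sample_marker_series(mm, sizes=[240, 500, 720], n_reps=1, seed=2)
counts = np.bincount(mm.chrom[np.isin(mm.marker_id, series.markers(500))])[1:]
print("markers per chromosome at size 500:", counts, "(sum", counts.sum(), ")")
print("nested:", set(series.markers(240)) <= set(series.markers(500)))

# probe series: fixed index stride within chromosomes, random start
(pseries,) = tg.sample_probe_series(mm, nprobes=[24, 60], n_starts=1, seed=3)
print(f"nprobe=24 -> {len(pseries.probe_sets[24])} probes, "
      f"{len(pseries.markers(24))} induced markers (6 per probe)")

# fixed test sets reused across all factors; training pools never overlap them
ids = [f"g{k}" for k in range(720)]
tests = tg.make_test_sets(ids, size=200, n_reps=5, seed=4)
pool = np.setdiff1d(np.array(ids, dtype=object), tests[0])
random_train = tg.training_series_random(pool, sizes=[120, 240, 480], seed=5)
print("random training sizes:", {s: len(v) for s, v in random_train.items()})

ped = tg.Pedigree(ids, [f"F{k // 16:02d}" for k in range(720)],
                  ["A"] * 720, ["B"] * 720)
fam_train = tg.training_series_by_family(ped, pool, per_family=[1, 3, 6], seed=6)
print("family-quota training sizes:", {k: len(v) for k, v in fam_train.items()})
# 45 families of 16: level k contributes ~45k individuals (minus test overlap).
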