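"""Structured sampling designs for the resampling experiments.

Four design families drive the factorial study:

* cumulative (nested) marker-density series balanced across chromosomes;
* probe sets at fixed index spacing within chromosomes, with random starts
  (probe sets at different counts are NOT nested — the fixed-spacing rule
  precludes it, and only marker and training series are cumulative);
* fixed test sets of constant size reused across every factor of a replicate;
* nested training series, either random or with a per-family quota.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MarkerMap, child_seed
from .simpop import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSetSeries",
    "ProbeSetSeries",
    "sample_marker_series",
    "sample_probe_series",
    "make_test_sets",
    "training_series_random",
    "training_series_by_family",
]

#: marker-count levels of the density experiment
DEFAULT_MARKER_SIZES = (500, 1_000, 2_000, 3_000, 5_000, 10_000, 20_000, 40_000, 60_000)
#: probe-count levels
DEFAULT_NPROBES = (50, 100, 500, 1_000, 2_000, 3_000, 5_000)
#: random training-set sizes
DEFAULT_TRAIN_SIZES = (120, 240, 480, 960, 1_560)
#: per-family training quotas
DEFAULT_FAMILY_LEVELS = (1, 3, 6, 9, 12, 15)


@dataclass(frozen=True)
class MarkerSetSeries:
    """Nested marker sets: each size's set contains every smaller set."""

    sizes: tuple
    sets: dict  # size -> np.ndarray of marker ids
    replicate: int
    seed: int

    def markers(self, size: int) -> np.ndarray:
        return self.sets[size]


@dataclass(frozen=True)
class ProbeSetSeries:
    """Probe selections per nprobe level with their induced marker sets."""

    nprobes: tuple
    probe_sets: dict  # nprobe -> np.ndarray of probe ids
    marker_sets: dict  # nprobe -> np.ndarray of marker ids
    start_offsets: dict  # nprobe -> {chrom: offset}
    replicate: int
    seed: int

    def markers(self, nprobe: int) -> np.ndarray:
        return self.marker_sets[nprobe]


def sample_marker_series(
    marker_map: MarkerMap, sizes=DEFAULT_MARKER_SIZES, n_reps: int = 5, seed: int = 0
) -> list:
    """Cumulative marker-density series, balanced across chromosomes.

    For each size the per-chromosome quota is floor(size/n_chrom) with the
    remainder spread one marker each over the currently least-loaded
    chromosomes (random tie-break), so per-size per-chromosome counts differ
    by at most one.  Increments between consecutive sizes are sampled without
    replacement from the yet-unselected markers, preserving strict nesting.
    A chromosome with too few markers spills its shortfall to the others with
    a logged warning.
    """
    sizes = tuple(sorted(int(s) for s in sizes))
    if sizes[0] < 1:
        raise ValueError("sizes must be positive")
    if sizes[-1] > marker_map.n_markers:
        raise ValueError("largest size exceeds the number of mapped markers")
    chroms = list(marker_map.chromosomes)
    out = []
    for rep in range(n_reps):
        rep_seed = child_seed(seed, 0, rep)
        rng = np.random.default_rng(rep_seed)
        shuffled = {
            c: marker_map.marker_id[marker_map.chrom_indices(int(c))][
                rng.permutation(len(marker_map.chrom_indices(int(c))))
            ]
            for c in chroms
        }
        avail = {c: len(shuffled[c]) for c in chroms}
        count = {c: 0 for c in chroms}
        sets: dict = {}
        for size in sizes:
            base = size // len(chroms)
            target = {c: max(count[c], min(base, avail[c])) for c in chroms}
            short = [c for c in chroms if min(base, avail[c]) < base]
            if short:
                logger.warning(
                    "chromosomes %s exhausted below quota %d; spilling", short, base
                )
            total = sum(target.values())
            while total < size:
                room = [c for c in chroms if target[c] < avail[c]]
                if not room:
                    raise ValueError("not enough markers to reach the requested size")
                lo = min(target[c] for c in room)
                pick = rng.choice([c for c in room if target[c] == lo])
                target[pick] += 1
                total += 1
            count = target
            sets[size] = np.concatenate([shuffled[c][: count[c]] for c in chroms])
        out.append(MarkerSetSeries(sizes, sets, rep, rep_seed))
    return out


def _probe_table(marker_map: MarkerMap) -> pd.DataFrame:
    if marker_map.probe_id is None:
        raise ValueError("marker map carries no probe assignments")
    df = pd.DataFrame(
        {
            "probe": marker_map.probe_id,
            "chrom": marker_map.chrom,
            "pos": marker_map.pos,
        }
    )
    return (
        df.groupby("probe", sort=False)
        .agg(chrom=("chrom", "first"), pos=("pos", "min"))
        .reset_index()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )


def sample_probe_series(
    marker_map: MarkerMap, nprobes=DEFAULT_NPROBES, n_starts: int = 5, seed: int = 0
) -> list:
    """Probe selections at fixed index spacing with random start offsets.

    Per replicate and nprobe level, each chromosome receives a quota
    proportional to its probe count (largest-remainder rounding); probes are
    ordered by position and picked every ``stride = floor(available/quota)``
    ranks from a random offset in [0, stride).  The induced marker set is the
    union of the selected probes' markers.
    """
    probes = _probe_table(marker_map)
    total = len(probes)
    nprobes = tuple(int(k) for k in nprobes)
    if max(nprobes) > total:
        raise ValueError("nprobe exceeds the number of probes in the map")
    chroms = probes["chrom"].unique()
    probe_markers = {
        p: marker_map.marker_id[marker_map.probe_id == p] for p in probes["probe"]
    }
    out = []
    for rep in range(n_starts):
        rep_seed = child_seed(seed, 1, rep)
        rng = np.random.default_rng(rep_seed)
        probe_sets, marker_sets, offsets = {}, {}, {}
        for nprobe in nprobes:
            counts = probes["chrom"].value_counts().reindex(chroms).to_numpy()
            quota = _largest_remainder(nprobe * counts / total, nprobe, cap=counts)
            chosen, offs = [], {}
            for c, q in zip(chroms, quota):
                sub = probes.loc[probes["chrom"] == c, "probe"].to_numpy()
                if q == 0:
                    logger.info("nprobe=%d: chromosome %s receives no probes", nprobe, c)
                    continue
                stride = len(sub) // q
                off = int(rng.integers(stride)) if stride > 1 else 0
                offs[int(c)] = off
                chosen.append(sub[off::stride][:q])
            probe_ids = np.concatenate(chosen)
            probe_sets[nprobe] = probe_ids
            marker_sets[nprobe] = np.concatenate([probe_markers[p] for p in probe_ids])
            offsets[nprobe] = offs
        out.append(ProbeSetSeries(nprobes, probe_sets, marker_sets, offsets, rep, rep_seed))
    return out


def _largest_remainder(raw: np.ndarray, total: int, cap: np.ndarray) -> np.ndarray:
    """Integer allocation summing to ``total`` by the largest-remainder
    method, with per-cell caps."""
    base = np.minimum(np.floor(raw).astype(int), cap)
    rem = total - base.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    i = 0
    while rem > 0:
        c = order[i % len(order)]
        if base[c] < cap[c]:
            base[c] += 1
            rem -= 1
        i += 1
        if i > 10 * len(order) and rem > 0:
            raise ValueError("caps too tight for requested allocation")
    return base


def make_test_sets(ids, size: int = 200, n_reps: int = 5, seed: int = 0) -> list:
    """Fixed test (validation) sets: simple random samples without
    replacement, one per replicate, reused across every factor of the grid."""
    ids = np.asarray(list(ids), dtype=object)
    if size >= len(ids):
        raise ValueError("test size must be smaller than the population")
    out = []
    for rep in range(n_reps):
        rng = np.random.default_rng(child_seed(seed, 2, rep))
        out.append(rng.choice(ids, size=size, replace=False))
    return out


def training_series_random(pool_ids, sizes=DEFAULT_TRAIN_SIZES, seed: int = 0) -> dict:
    """Nested random training sets of the requested sizes from the pool."""
    pool = np.asarray(list(pool_ids), dtype=object)
    sizes = tuple(sorted(int(s) for s in sizes))
    if sizes[-1] > len(pool):
        raise ValueError("largest training size exceeds the pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    return {s: pool[order[:s]] for s in sizes}


def training_series_by_family(
    pedigree: Pedigree,
    pool_ids=None,
    per_family=DEFAULT_FAMILY_LEVELS,
    min_family_size: int = 10,
    seed: int = 0,
) -> dict:
    """Nested family-quota training sets.

    Families with fewer than ``min_family_size`` members (in the pedigree)
    are excluded.  At level k each retained family contributes
    min(k, members available in the pool) individuals; levels are cumulative.
    ``pool_ids`` should already exclude the test individuals.
    """
    fams = pedigree.families()
    eligible = {f: members for f, members in fams.items() if len(members) >= min_family_size}
    if not eligible:
        raise ValueError(f"no family has >= {min_family_size} members")
    pool = None if pool_ids is None else set(pool_ids)
    rng = np.random.default_rng(seed)
    shuffled = {}
    for f in sorted(eligible):
        members = [m for m in eligible[f] if pool is None or m in pool]
        members = list(np.array(members, dtype=object)[rng.permutation(len(members))])
        shuffled[f] = members
    out = {}
    for k in sorted(int(k) for k in per_family):
        out[k] = np.array(
            [m for f in sorted(shuffled) for m in shuffled[f][:k]], dtype=object
        )
    return out
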