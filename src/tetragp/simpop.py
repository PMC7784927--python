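"""Synthetic autotetraploid breeding population generator.

Emulates the structure of a capture-seq-genotyped blueberry breeding
population: ~12 chromosomes of mapped biallelic markers grouped under capture
probes, biparental families from outcrossing tetraploid parents, allele
dosages 0-4 from tetrasomic (bivalent-pairing) meiosis, additive traits of
differing architecture measured over two seasons, and read counts whose total
depth is truncated-Poisson with a binomial allele split plus sequencing
error.

The meiosis model is the standard autotetraploid baseline: the four homologs
are randomly partitioned into two bivalents, crossovers occur at Poisson rate
along the genetic map, and the gamete receives one recombinant chromatid per
bivalent.  Double reduction, multivalent and preferential pairing are out of
scope; with bivalent pairing the single-locus gamete law is the closed-form
hypergeometric draw of 2 alleles from the parent's 4, which the test suite
asserts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MarkerMap, ReadCountMatrix, sample_truncated_poisson

__all__ = [
    "MarkerMap",
    "FounderHaplotypes",
    "Pedigree",
    "TraitArchitecture",
    "TrueGeneticValues",
    "simulate_marker_map",
    "simulate_founders",
    "make_gamete",
    "simulate_crosses",
    "random_cross_plan",
    "simulate_phenotypes",
    "simulate_read_counts",
]


@dataclass(frozen=True)
class FounderHaplotypes:
    """Phased founder genomes: 4 binary haplotypes per founder (0 = reference
    allele, 1 = alternative)."""

    founder_ids: np.ndarray
    haplotypes: np.ndarray  # (n_founders, 4, n_markers) uint8

    def __post_init__(self):
        object.__setattr__(self, "founder_ids", np.asarray(self.founder_ids, dtype=object))
        object.__setattr__(self, "haplotypes", np.asarray(self.haplotypes, dtype=np.uint8))
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 4:
            raise ValueError("haplotypes must have shape (n_founders, 4, n_markers)")
        if self.haplotypes.shape[0] != len(self.founder_ids):
            raise ValueError("founder id count does not match haplotype array")
        if self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def of(self, founder_id) -> np.ndarray:
        idx = np.flatnonzero(self.founder_ids == founder_id)
        if len(idx) == 0:
            raise KeyError(f"unknown founder id {founder_id!r}")
        return self.haplotypes[idx[0]]

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(np.int64)


@dataclass(frozen=True)
class Pedigree:
    """One biparental family per cross; both parents are founders."""

    individual_id: np.ndarray
    family_id: np.ndarray
    parent1_id: np.ndarray
    parent2_id: np.ndarray

    def __post_init__(self):
        for name in ("individual_id", "family_id", "parent1_id", "parent2_id"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=object))
        n = len(self.individual_id)
        if any(len(getattr(self, f)) != n for f in ("family_id", "parent1_id", "parent2_id")):
            raise ValueError("pedigree fields have unequal lengths")
        if len(set(self.individual_id)) != n:
            raise ValueError("duplicate individual ids in pedigree")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    def families(self) -> dict:
        out: dict = {}
        for ind, fam in zip(self.individual_id, self.family_id):
            out.setdefault(fam, []).append(ind)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individual_id,
                "family": self.family_id,
                "parent1": self.parent1_id,
                "parent2": self.parent2_id,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            df["individual"].to_numpy(),
            df["family"].to_numpy(),
            df["parent1"].to_numpy(),
            df["parent2"].to_numpy(),
        )


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive trait: number of QTL, effect-size law, target narrow-sense
    heritability of a single-season record, and per-year fixed shifts."""

    n_qtl: int
    h2: float
    effect_distribution: str = "normal"
    year_effects: tuple = (0.0, 0.0)
    mu: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must be in (0, 1]")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        if self.effect_distribution not in ("normal", "gamma-signed"):
            raise ValueError("effect_distribution must be 'normal' or 'gamma-signed'")


@dataclass(frozen=True)
class TrueGeneticValues:
    """Ground-truth additive genetic values: g_true is the dosage-weighted sum
    of QTL effects for each individual."""

    individual_ids: np.ndarray
    g_true: np.ndarray
    qtl_marker_ids: np.ndarray
    qtl_effects: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.g_true, index=list(self.individual_ids), name="g_true")

    def write_tsv(self, path) -> None:
        pd.DataFrame({"individual": self.individual_ids, "g_true": self.g_true}).to_csv(
            path, sep="\t", index=False
        )


def simulate_marker_map(
    n_chrom: int = 12,
    markers_per_chrom: int = 900,
    markers_per_probe: int = 18,
    chrom_length_cm: float = 100.0,
    bp_per_cm: int = 500_000,
    seed: int = 0,
) -> MarkerMap:
    """Marker map with equally many markers per chromosome, markers grouped
    ``markers_per_probe`` under consecutive capture probes (the study's probes
    yielded ~18 SNPs each), and jittered positions."""
    rng = np.random.default_rng(seed)
    mids, chroms, poss, cms, probes = [], [], [], [], []
    for c in range(1, n_chrom + 1):
        cm = np.sort(rng.uniform(0.0, chrom_length_cm, size=markers_per_chrom))
        pos = (cm * bp_per_cm).astype(np.int64)
        # keep pos strictly sorted even after integer truncation
        pos = np.maximum.accumulate(pos) + np.arange(markers_per_chrom)
        for j in range(markers_per_chrom):
            mids.append(f"chr{c:02d}_m{j + 1:05d}")
            probes.append(f"chr{c:02d}_p{j // markers_per_probe + 1:04d}")
        chroms.append(np.full(markers_per_chrom, c))
        poss.append(pos)
        cms.append(cm)
    return MarkerMap(
        np.array(mids, dtype=object),
        np.concatenate(chroms),
        np.concatenate(poss),
        np.concatenate(cms),
        np.array(probes, dtype=object),
    )


def simulate_founders(
    n_founders: int,
    marker_map: MarkerMap,
    maf_range: tuple = (0.1, 0.5),
    ld_rho: float = 0.0,
    seed: int = 0,
) -> FounderHaplotypes:
    """Draw founder haplotypes with per-marker allele frequencies uniform in
    ``maf_range`` and first-order Markov LD along each chromosome.

    The LD chain copies the previous marker's allele with probability
    ``ld_rho`` and otherwise draws a fresh Bernoulli(p_k), giving correlation
    decay rho^k between markers k steps apart; chromosomes are independent.
    """
    low, high = maf_range
    if not (0.0 < low <= high < 1.0):
        raise ValueError("maf_range must satisfy 0 < low <= high < 1")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    if n_founders < 1:
        raise ValueError("need at least one founder")
    rng = np.random.default_rng(seed)
    m = marker_map.n_markers
    freqs = rng.uniform(low, high, size=m)
    n_hap = 4 * n_founders
    haps = np.empty((n_hap, m), dtype=np.uint8)
    for c in marker_map.chromosomes:
        idx = marker_map.chrom_indices(int(c))
        haps[:, idx[0]] = rng.random(n_hap) < freqs[idx[0]]
        for k in idx[1:]:
            fresh = (rng.random(n_hap) < freqs[k]).astype(np.uint8)
            copy = rng.random(n_hap) < ld_rho
            haps[:, k] = np.where(copy, haps[:, k - 1], fresh)
    ids = np.array([f"P{i + 1:03d}" for i in range(n_founders)], dtype=object)
    return FounderHaplotypes(ids, haps.reshape(n_founders, 4, m))


def _recombine_pair(
    h_a: np.ndarray, h_b: np.ndarray, cm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant chromatid from a bivalent of two homologs.

    Crossover count ~ Poisson(map length in Morgans) at uniform cM positions;
    the transmitted chromatid starts on a random homolog and switches at each
    crossover.
    """
    length_morgans = (cm[-1] - cm[0]) / 100.0
    n_co = rng.poisson(length_morgans)
    start = rng.integers(2)
    if n_co == 0:
        return h_a if start == 0 else h_b
    breaks = np.sort(rng.uniform(cm[0], cm[-1], size=n_co))
    strand = (start + np.searchsorted(breaks, cm, side="right")) % 2
    return np.where(strand == 0, h_a, h_b)


def make_gamete(
    parent_haplotypes: np.ndarray, marker_map: MarkerMap, seed=None
) -> np.ndarray:
    """Simulate one diploid gamete (2 x n_markers) from a tetraploid parent.

    Per chromosome the 4 homologs are partitioned at random into 2 bivalents
    and one recombinant chromatid per bivalent is transmitted, so each gamete
    carries 2 of the parent's 4 homologous copies (tetrasomic inheritance).
    """
    haps = np.asarray(parent_haplotypes)
    if haps.ndim != 2 or haps.shape[0] != 4:
        raise ValueError("parent haplotypes must have shape (4, n_markers)")
    if haps.shape[1] != marker_map.n_markers:
        raise ValueError("parent haplotypes do not match the marker map")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamete = np.empty((2, haps.shape[1]), dtype=np.uint8)
    for c in marker_map.chromosomes:
        idx = marker_map.chrom_indices(int(c))
        cm = marker_map.cm[idx]
        perm = rng.permutation(4)
        for b, (i, j) in enumerate(((perm[0], perm[1]), (perm[2], perm[3]))):
            gamete[b, idx] = _recombine_pair(haps[i, idx], haps[j, idx], cm, rng)
    return gamete


def random_cross_plan(
    founder_ids,
    n_families: int,
    offspring_per_family: int,
    size_cv: float = 0.0,
    min_offspring: int = 2,
    seed: int = 0,
) -> list:
    """Random biparental cross plan: each family pairs two distinct founders,
    founders may appear in several crosses (outcrossing population).

    ``size_cv`` > 0 draws unequal family sizes (mean ``offspring_per_family``,
    coefficient of variation ``size_cv``, floor ``min_offspring``), emulating
    the uneven cross sizes of real breeding programs.
    """
    rng = np.random.default_rng(seed)
    ids = list(founder_ids)
    if len(ids) < 2:
        raise ValueError("need at least two founders")
    if size_cv > 0:
        sizes = np.maximum(
            np.round(
                rng.normal(offspring_per_family, size_cv * offspring_per_family, n_families)
            ).astype(int),
            min_offspring,
        )
    else:
        sizes = np.full(n_families, offspring_per_family, dtype=int)
    plan = []
    seen = set()
    for k in range(n_families):
        for _attempt in range(1000):
            p1, p2 = rng.choice(len(ids), size=2, replace=False)
            pair = (min(p1, p2), max(p1, p2))
            if pair not in seen:
                seen.add(pair)
                break
        plan.append((ids[pair[0]], ids[pair[1]], int(sizes[k])))
    return plan


def simulate_crosses(
    founders: FounderHaplotypes,
    cross_plan: list,
    marker_map: MarkerMap,
    seed: int = 0,
):
    """Simulate offspring of biparental crosses.

    Each offspring unites one gamete from each parent (4 homologs); dosage is
    the count of alternative alleles among them.

    Returns
    -------
    (pedigree, dosages, haplotypes) :
        ``dosages`` is an (n_offspring, n_markers) integer array in 0..4
        aligned to pedigree order; ``haplotypes`` the phased
        (n_offspring, 4, n_markers) array.
    """
    rng = np.random.default_rng(seed)
    lookup = {f: i for i, f in enumerate(founders.founder_ids)}
    inds, fams, p1s, p2s = [], [], [], []
    hap_rows = []
    for k, (p1, p2, n_off) in enumerate(cross_plan):
        if p1 not in lookup or p2 not in lookup:
            missing = p1 if p1 not in lookup else p2
            raise KeyError(f"unknown parent id {missing!r} in cross plan")
        if n_off < 1:
            raise ValueError("n_offspring must be >= 1")
        fam = f"F{k + 1:03d}"
        h1 = founders.haplotypes[lookup[p1]]
        h2 = founders.haplotypes[lookup[p2]]
        for j in range(n_off):
            g1 = make_gamete(h1, marker_map, rng)
            g2 = make_gamete(h2, marker_map, rng)
            hap_rows.append(np.vstack([g1, g2]))
            inds.append(f"{fam}_{j + 1:03d}")
            fams.append(fam)
            p1s.append(p1)
            p2s.append(p2)
    ped = Pedigree(
        np.array(inds, dtype=object),
        np.array(fams, dtype=object),
        np.array(p1s, dtype=object),
        np.array(p2s, dtype=object),
    )
    haps = np.stack(hap_rows)
    dosages = haps.sum(axis=1).astype(np.int64)
    return ped, dosages, haps


def simulate_phenotypes(
    dosages: np.ndarray,
    individual_ids,
    marker_ids,
    architecture: TraitArchitecture,
    years=(2014, 2015),
    seed: int = 0,
):
    """Simulate additive phenotype records over years.

    QTL are sampled uniformly among markers; effects come from the requested
    law; residual variance is set so Var(g)/(Var(g)+sigma_e^2) equals the
    target h2 in this population.  Record for individual j in year t is
    mu + year_effect_t + g_j + e_jt with iid normal residuals.

    Returns (records DataFrame with columns individual/year/value,
    TrueGeneticValues).
    """
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if architecture.n_qtl > m:
        raise ValueError("n_qtl exceeds the number of markers")
    if len(architecture.year_effects) != len(years):
        raise ValueError("year_effects length must match years")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(m, size=architecture.n_qtl, replace=False))
    if architecture.effect_distribution == "normal":
        eff = rng.normal(0.0, 1.0, size=architecture.n_qtl)
    else:  # gamma-signed: heavy-tailed magnitudes with random signs
        eff = rng.gamma(0.4, 1.0, size=architecture.n_qtl) * rng.choice(
            [-1.0, 1.0], size=architecture.n_qtl
        )
    g = d[:, qtl] @ eff
    var_g = float(np.var(g))
    if var_g == 0.0:
        raise ValueError("zero genetic variance in the simulated population")
    sigma_e = np.sqrt(var_g * (1.0 - architecture.h2) / architecture.h2)
    rows = []
    ids = np.asarray(individual_ids, dtype=object)
    for t, (year, shift) in enumerate(zip(years, architecture.year_effects)):
        e = rng.normal(0.0, sigma_e, size=n) if sigma_e > 0 else np.zeros(n)
        vals = architecture.mu + shift + g + e
        rows.append(pd.DataFrame({"individual": ids, "year": year, "value": vals}))
    records = pd.concat(rows, ignore_index=True)
    truth = TrueGeneticValues(
        ids, g, np.asarray(marker_ids, dtype=object)[qtl], eff
    )
    return records, truth


def simulate_read_counts(
    dosages: np.ndarray,
    individual_ids,
    marker_ids,
    mean_depth: float,
    min_depth: int = 2,
    error_rate: float = 0.001,
    seed: int = 0,
    clamp: bool = False,
) -> ReadCountMatrix:
    """Capture-seq-style read counts for given dosages.

    Total depth per cell is Poisson(mean_depth) conditioned on >= min_depth;
    the alternative-read count is Binomial(n, p) with
    p = (d/4)(1-error_rate) + (1-d/4)*error_rate — a symmetric per-read
    miscall rate folded into the allele split.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    d = np.asarray(dosages)
    if d.min(initial=0) < 0 or d.max(initial=0) > 4:
        raise ValueError("dosages must be in 0..4")
    rng = np.random.default_rng(seed)
    depth = sample_truncated_poisson(rng, mean_depth, min_depth, d.shape, clamp=clamp)
    p = (d / 4.0) * (1.0 - error_rate) + (1.0 - d / 4.0) * error_rate
    ao = rng.binomial(depth, p)
    return ReadCountMatrix(ao, depth - ao, individual_ids, marker_ids)
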