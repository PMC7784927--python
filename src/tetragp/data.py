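"""Core data containers shared across the package.

The raw observable of the whole pipeline is a pair of integer read-count
matrices (alternative-allele counts AO and reference-allele counts RO per
individual x marker, the layout used by public allele-depth deposits).  Everything downstream —
continuous ratio genotypes, the genomic relationship matrix, depth
downsampling — derives from it.  Markers live on a genetic/physical map and
are grouped under capture probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass(frozen=True)
class MarkerMap:
    """Map of biallelic markers: chromosome, physical and genetic position,
    and optional capture-probe grouping.

    Markers must be sorted by (chromosome, position); within each chromosome
    positions and centimorgan coordinates are non-decreasing, and probe groups
    are contiguous.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray
    probe_id: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "marker_id", _as_str_array(self.marker_id))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=np.int64))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        object.__setattr__(self, "cm", np.asarray(self.cm, dtype=float))
        if self.probe_id is not None:
            object.__setattr__(self, "probe_id", _as_str_array(self.probe_id))
        n = len(self.marker_id)
        if n == 0:
            raise ValueError("marker map is empty")
        for name in ("chrom", "pos", "cm"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"marker map field {name!r} has wrong length")
        if self.probe_id is not None and len(self.probe_id) != n:
            raise ValueError("marker map field 'probe_id' has wrong length")
        if np.any(self.pos < 0) or np.any(self.cm < 0):
            raise ValueError("positions must be non-negative")
        # sorted by chromosome, non-decreasing pos/cM within chromosome
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("markers must be sorted by (chrom, pos)")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            if np.any(np.diff(self.cm[sel]) < 0):
                raise ValueError(f"cM positions decrease within chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    def subset(self, marker_ids) -> "MarkerMap":
        """Map restricted to the given markers (map order preserved)."""
        keep = np.isin(self.marker_id, np.asarray(marker_ids, dtype=object))
        return MarkerMap(
            self.marker_id[keep],
            self.chrom[keep],
            self.pos[keep],
            self.cm[keep],
            None if self.probe_id is None else self.probe_id[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker": self.marker_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "cM": self.cm,
            }
        )
        if self.probe_id is not None:
            df["probe"] = self.probe_id
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        probe = df["probe"].to_numpy() if "probe" in df.columns else None
        return cls(
            df["marker"].to_numpy(),
            df["chrom"].to_numpy(),
            df["pos"].to_numpy(),
            df["cM"].to_numpy(),
            probe,
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MarkerMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class ReadCountMatrix:
    """Per individual x marker allele read counts.

    ``ao`` holds alternative-allele counts (the ratio formula's #a), ``ro``
    reference counts (#A).  ``missing`` marks datapoints that carry no usable
    reads (e.g. set missing by the minimum-depth filter); counts at missing
    cells are zeroed and ignored.
    """

    ao: np.ndarray
    ro: np.ndarray
    individual_ids: np.ndarray
    marker_ids: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.ao = np.asarray(self.ao, dtype=np.int64)
        self.ro = np.asarray(self.ro, dtype=np.int64)
        self.individual_ids = _as_str_array(self.individual_ids)
        self.marker_ids = _as_str_array(self.marker_ids)
        if self.ao.shape != self.ro.shape:
            raise ValueError("AO and RO shapes disagree")
        if self.ao.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("count matrix shape does not match id lengths")
        if np.any(self.ao < 0) or np.any(self.ro < 0):
            raise ValueError("read counts must be non-negative")
        if self.missing is None:
            self.missing = np.zeros(self.ao.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.ao.shape:
                raise ValueError("missing mask shape disagrees")
        self.ao = np.where(self.missing, 0, self.ao)
        self.ro = np.where(self.missing, 0, self.ro)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def depth(self) -> np.ndarray:
        """Total reads AO+RO per cell (0 at missing cells)."""
        return self.ao + self.ro

    def ratios(self) -> np.ndarray:
        """AO/(AO+RO) with NaN at missing or zero-depth cells."""
        d = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(d > 0, self.ao / np.where(d > 0, d, 1.0), np.nan)
        return np.where(self.missing, np.nan, r)

    def subset(self, individuals=None, markers=None) -> "ReadCountMatrix":
        ii = (
            np.arange(self.n_individuals)
            if individuals is None
            else _index_of(self.individual_ids, individuals, "individual")
        )
        jj = (
            np.arange(self.n_markers)
            if markers is None
            else _index_of(self.marker_ids, markers, "marker")
        )
        return ReadCountMatrix(
            self.ao[np.ix_(ii, jj)],
            self.ro[np.ix_(ii, jj)],
            self.individual_ids[ii],
            self.marker_ids[jj],
            self.missing[np.ix_(ii, jj)],
        )

    # --- TSV pair: individuals as rows, markers as columns ---
    def write_tsv(self, ao_path, ro_path) -> None:
        for mat, path in ((self.ao, ao_path), (self.ro, ro_path)):
            df = pd.DataFrame(
                mat.astype(object), index=self.individual_ids, columns=self.marker_ids
            )
            df = df.mask(self.missing, "NA")
            df.to_csv(path, sep="\t", index_label="individual")

    def equals(self, other: "ReadCountMatrix") -> bool:
        return (
            np.array_equal(self.ao, other.ao)
            and np.array_equal(self.ro, other.ro)
            and np.array_equal(self.missing, other.missing)
            and np.array_equal(self.individual_ids, other.individual_ids)
            and np.array_equal(self.marker_ids, other.marker_ids)
        )


def _index_of(haystack: np.ndarray, wanted, what: str) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(haystack)}
    try:
        return np.array([lookup[w] for w in wanted], dtype=np.int64)
    except KeyError as e:
        raise KeyError(f"unknown {what} id: {e.args[0]!r}") from None


@dataclass(frozen=True)
class ContinuousGenotypes:
    """Ratio-genotype matrix M with entries #a/(#A+#a) in [0, 1].

    Continuous genotypes sidestep allele-dosage calling: the read ratio is
    used directly as the marker covariate.
    """

    m: np.ndarray
    individual_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        object.__setattr__(self, "individual_ids", _as_str_array(self.individual_ids))
        object.__setattr__(self, "marker_ids", _as_str_array(self.marker_ids))
        if self.m.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("M shape does not match id lengths")
        if np.any(~np.isfinite(self.m)) or self.m.min(initial=0) < 0 or self.m.max(initial=0) > 1:
            raise ValueError("ratio genotypes must be finite and in [0, 1]")

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.m, index=self.individual_ids, columns=self.marker_ids).to_csv(
            path, sep="\t", index_label="individual"
        )

    @classmethod
    def read_tsv(cls, path) -> "ContinuousGenotypes":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), df.index.to_numpy(object), df.columns.to_numpy(object))


def sample_truncated_poisson(
    rng: np.random.Generator, lam: float, min_depth: int, size, clamp: bool = False
) -> np.ndarray:
    """Poisson(lam) draws conditioned on (or clamped to) >= min_depth.

    The truncated variant resamples the lower tail by inverse-CDF on the
    conditional distribution; the clamp variant replaces sub-threshold draws
    with min_depth (sensitivity alternative, not the default semantics).
    """
    if lam <= 0:
        raise ValueError("mean depth must be positive")
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if clamp:
        return np.maximum(rng.poisson(lam, size=size), min_depth).astype(np.int64)
    if min_depth == 0:
        return rng.poisson(lam, size=size).astype(np.int64)
    lo = stats.poisson.cdf(min_depth - 1, lam)
    u = rng.uniform(size=size)
    return stats.poisson.ppf(lo + u * (1.0 - lo), lam).astype(np.int64)


def truncated_poisson_mean(lam: float, min_depth: int) -> float:
    """Analytic mean of Poisson(lam) conditioned on >= min_depth."""
    if min_depth <= 0:
        return lam
    tail = stats.poisson.sf(min_depth - 1, lam)
    # E[X; X >= t] = lam * P(X >= t-1)
    return lam * stats.poisson.sf(min_depth - 2, lam) / tail


def child_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31 derived from a master seed and an
    integer key path (scenario index, replicate, ...)."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))
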