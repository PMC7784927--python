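"""Read-count input, marker/datapoint filtering, ratio genotypes, LSMeans.

Input is either an AO/RO TSV pair (individuals as rows, markers
as columns) or a VCF with per-sample allele depths.  Filtering follows the
study design for a high-depth capture-seq panel: a chromosome whitelist,
a per-datapoint minimum depth (2X, to avoid imputation), a per-site mean
depth floor (60X), missing-fraction caps on markers then individuals (0.2),
and a minor-allele-frequency floor (0.05) estimated from the read ratios.

Continuous ("ratio") genotypes #a/(#A+#a) replace dosage calling entirely;
phenotypes are adjusted to least-squares means from a genotype+year
fixed-effects model before prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import ContinuousGenotypes, MarkerMap, ReadCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "read_counts",
    "read_counts_vcf",
    "apply_filters",
    "ratio_genotypes",
    "lsmeans",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Marker/datapoint retention thresholds (defaults are the study's)."""

    min_site_mean_depth: float = 60.0
    min_datapoint_depth: int = 2
    max_missing: float = 0.2
    min_maf: float = 0.05
    chrom_whitelist: frozenset | None = None

    def __post_init__(self):
        if self.min_site_mean_depth < 0 or self.min_datapoint_depth < 0:
            raise ValueError("depth thresholds must be non-negative")
        if not (0.0 <= self.max_missing <= 1.0):
            raise ValueError("max_missing must be in [0, 1]")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.chrom_whitelist is not None:
            object.__setattr__(self, "chrom_whitelist", frozenset(int(c) for c in self.chrom_whitelist))


@dataclass
class FilterReport:
    """Per-step drop counts from :func:`apply_filters`."""

    markers_in: int = 0
    individuals_in: int = 0
    markers_dropped_chrom: int = 0
    datapoints_set_missing_depth: int = 0
    markers_dropped_site_depth: int = 0
    markers_dropped_missing: int = 0
    individuals_dropped_missing: int = 0
    markers_dropped_maf: int = 0
    markers_out: int = 0
    individuals_out: int = 0
    residual_missing_datapoints: int = 0
    notes: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def read_counts(ao_path, ro_path) -> ReadCountMatrix:
    """Read the AO/RO TSV pair (rows individuals, columns markers, 'NA' for
    missing datapoints).  Individual and marker ids must agree between the
    two files."""
    ao = pd.read_csv(ao_path, sep="\t", index_col=0)
    ro = pd.read_csv(ro_path, sep="\t", index_col=0)
    if not ao.index.equals(ro.index) or not ao.columns.equals(ro.columns):
        raise ValueError("AO and RO files disagree on individual or marker ids")
    ao_v = ao.apply(pd.to_numeric, errors="coerce").to_numpy(float)
    ro_v = ro.apply(pd.to_numeric, errors="coerce").to_numpy(float)
    missing = np.isnan(ao_v) | np.isnan(ro_v)
    return ReadCountMatrix(
        np.nan_to_num(ao_v).astype(np.int64),
        np.nan_to_num(ro_v).astype(np.int64),
        ao.index.to_numpy(object),
        ao.columns.to_numpy(object),
        missing,
    )


def read_counts_vcf(vcf_path) -> ReadCountMatrix:
    """Extract per-sample allele depths from a VCF.

    Only biallelic SNP records are used (multiallelic records are skipped and
    counted in the log); AO is the alternative-allele depth, RO the reference
    depth, taken from the AD format field.  Records failing QUAL >= 10 or
    MQ >= 20 (when present) are dropped — these mapping/call-quality filters
    only exist upstream of AO/RO tables.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = np.array(vcf.samples, dtype=object)
    ao_cols, ro_cols, mids = [], [], []
    n_multi = n_qual = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if v.QUAL is not None and v.QUAL < 10:
            n_qual += 1
            continue
        mq = v.INFO.get("MQ")
        if mq is not None and mq < 20:
            n_qual += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} lacks an AD field")
        ad = np.asarray(ad)
        ro_cols.append(ad[:, 0])
        ao_cols.append(ad[:, 1])
        mids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    if n_qual:
        logger.info("dropped %d VCF records failing QUAL/MQ filters", n_qual)
    if not mids:
        raise ValueError("no usable biallelic records in VCF")
    ao = np.stack(ao_cols, axis=1).astype(np.int64)
    ro = np.stack(ro_cols, axis=1).astype(np.int64)
    missing = (ao < 0) | (ro < 0)
    return ReadCountMatrix(
        np.where(missing, 0, ao), np.where(missing, 0, ro),
        samples, np.array(mids, dtype=object), missing,
    )


def apply_filters(
    rc: ReadCountMatrix, marker_map: MarkerMap, thresholds: FilterThresholds
) -> tuple:
    """Apply the retention filters in a fixed, documented order.

    1. chromosome whitelist; 2. datapoints with depth < min_datapoint_depth
    set missing; 3. markers with site-mean depth (over non-missing) below
    min_site_mean_depth dropped; 4. markers then individuals exceeding the
    missing fraction dropped; 5. markers below the MAF floor dropped, the
    allele frequency being the mean of per-individual read ratios.

    Returns (filtered ReadCountMatrix, FilterReport).
    """
    report = FilterReport(markers_in=rc.n_markers, individuals_in=rc.n_individuals)
    pos = {m: i for i, m in enumerate(marker_map.marker_id)}
    try:
        chrom = np.array([marker_map.chrom[pos[m]] for m in rc.marker_ids])
    except KeyError as e:
        raise KeyError(f"marker {e.args[0]!r} absent from the marker map") from None

    # 1. chromosome whitelist
    if thresholds.chrom_whitelist is not None:
        keep = np.isin(chrom, sorted(thresholds.chrom_whitelist))
        report.markers_dropped_chrom = int((~keep).sum())
        rc = rc.subset(markers=rc.marker_ids[keep])

    ao, ro, missing = rc.ao.copy(), rc.ro.copy(), rc.missing.copy()

    # 2. datapoint minimum depth
    low = (~missing) & ((ao + ro) < thresholds.min_datapoint_depth)
    report.datapoints_set_missing_depth = int(low.sum())
    missing |= low
    ao[low] = 0
    ro[low] = 0

    # 3. site mean depth over non-missing datapoints
    depth = (ao + ro).astype(float)
    with np.errstate(invalid="ignore"):
        nz = (~missing).sum(axis=0)
        site_mean = np.where(nz > 0, depth.sum(axis=0) / np.maximum(nz, 1), 0.0)
    keep_m = site_mean >= thresholds.min_site_mean_depth
    report.markers_dropped_site_depth = int((~keep_m).sum())
    ao, ro, missing = ao[:, keep_m], ro[:, keep_m], missing[:, keep_m]
    mids = rc.marker_ids[keep_m]

    # 4. missing fraction: markers first, then individuals
    frac_m = missing.mean(axis=0) if missing.size else np.zeros(len(mids))
    keep_m = frac_m <= thresholds.max_missing
    report.markers_dropped_missing = int((~keep_m).sum())
    ao, ro, missing, mids = ao[:, keep_m], ro[:, keep_m], missing[:, keep_m], mids[keep_m]
    frac_i = missing.mean(axis=1) if missing.size else np.zeros(rc.n_individuals)
    keep_i = frac_i <= thresholds.max_missing
    report.individuals_dropped_missing = int((~keep_i).sum())
    ao, ro, missing = ao[keep_i], ro[keep_i], missing[keep_i]
    iids = rc.individual_ids[keep_i]

    # 5. MAF on mean per-individual ratios
    if len(mids):
        d = (ao + ro).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(missing | (d == 0), np.nan, ao / np.maximum(d, 1.0))
        freq = np.nanmean(r, axis=0)
        maf = np.minimum(freq, 1.0 - freq)
        keep_m = maf >= thresholds.min_maf
        report.markers_dropped_maf = int((~keep_m).sum())
        ao, ro, missing, mids = ao[:, keep_m], ro[:, keep_m], missing[:, keep_m], mids[keep_m]

    report.markers_out = len(mids)
    report.individuals_out = len(iids)
    report.residual_missing_datapoints = int(missing.sum())
    if report.markers_out == 0:
        raise ValueError(f"all markers filtered out; report: {report.to_json()}")
    out = ReadCountMatrix(ao, ro, iids, mids, missing)
    return out, report


def ratio_genotypes(rc: ReadCountMatrix, impute_missing: bool = True) -> ContinuousGenotypes:
    """Continuous genotypes M_ij = AO_ij / (AO_ij + RO_ij).

    A non-missing zero-depth datapoint is an error (the minimum-depth filter
    guarantees none survive).  Residual missing cells — possible because the
    2X datapoint rule combined with the 20% missing cap can leave a few —
    are mean-imputed per marker as a last resort (logged); the prediction
    model requires a complete M.
    """
    depth = rc.depth.astype(float)
    bad = (~rc.missing) & (depth == 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"zero-depth datapoint at individual {rc.individual_ids[i]!r}, "
            f"marker {rc.marker_ids[j]!r}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(depth > 0, rc.ao / np.maximum(depth, 1.0), np.nan)
    m = np.where(rc.missing, np.nan, m)
    n_missing = int(np.isnan(m).sum())
    if n_missing:
        if not impute_missing:
            raise ValueError(f"{n_missing} missing datapoints and imputation disabled")
        logger.info("mean-imputing %d residual missing datapoints", n_missing)
        col_mean = np.nanmean(m, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.5)
        idx = np.where(np.isnan(m))
        m[idx] = col_mean[idx[1]]
    return ContinuousGenotypes(m, rc.individual_ids, rc.marker_ids)


def lsmeans(records: pd.DataFrame, value_col: str = "value") -> pd.Series:
    """Least-squares (adjusted) means per genotype from a two-way
    fixed-effects model value ~ genotype + year.

    The LSMean of genotype g is its fitted value averaged over an unweighted
    grid of all years — identical to the adjusted means of standard
    statistical practice, and equal to the simple genotype mean on balanced
    data.  Raises on a rank-deficient design.
    """
    df = records[["individual", "year", value_col]].dropna()
    genos = pd.Index(sorted(df["individual"].unique()))
    years = pd.Index(sorted(df["year"].unique()))
    if len(genos) < 2:
        raise ValueError("need at least two genotypes")
    if not np.isfinite(df[value_col].to_numpy(float)).all():
        raise ValueError("non-finite phenotype values")
    g_idx = df["individual"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    y_idx = df["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
    n = len(df)
    p = 1 + (len(genos) - 1) + (len(years) - 1)
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    for i in range(1, len(genos)):
        X[g_idx == i, i] = 1.0
    for t in range(1, len(years)):
        X[y_idx == t, len(genos) - 1 + t] = 1.0
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient genotype/year design (confounded levels)")
    beta, *_ = np.linalg.lstsq(X, df[value_col].to_numpy(float), rcond=None)
    intercept = beta[0]
    g_eff = np.concatenate([[0.0], beta[1 : len(genos)]])
    y_eff = np.concatenate([[0.0], beta[len(genos) :]])
    vals = intercept + g_eff + y_eff.mean()
    return pd.Series(vals, index=list(genos), name="lsmean")
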