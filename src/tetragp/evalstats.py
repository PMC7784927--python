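"""Scoring and summary statistics for the resampling experiments.

Predictive ability is the Pearson correlation between predicted and adjusted
phenotypes in the held-out test set; MSE its squared-error companion
(optionally standardized by the variance of the observations).  Factor
levels are compared by one-way ANOVA with all-pairwise Tukey HSD tests at
alpha = 0.05, summarized as a compact letter display where levels sharing a
letter do not differ significantly and 'a' marks the highest mean.  The
module also exposes the PCA variance-explained summary of relationship
matrices and the sequencing-budget arithmetic (genome size x depth vs.
flow-cell yield).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import GMatrix

__all__ = [
    "predictive_ability",
    "mse",
    "TukeyGrouping",
    "tukey_cld",
    "pc_variance_explained",
    "BudgetResult",
    "sequencing_budget",
]


def predictive_ability(pred, obs) -> float:
    """Pearson product-moment correlation between predictions and observed
    (adjusted) phenotypes."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("pred and obs must be 1-d of equal length")
    if len(p) < 3:
        raise ValueError("need at least three pairs")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("zero variance in predictions or observations")
    return float(np.corrcoef(p, o)[0, 1])


def mse(pred, obs, standardized: bool = False) -> float:
    """Mean squared difference between predictions and observations; the
    standardized variant divides by the variance of the observations."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("pred and obs must have equal length")
    out = float(np.mean((p - o) ** 2))
    if standardized:
        v = float(np.var(o))
        if v == 0:
            raise ValueError("zero variance in observations")
        out /= v
    return out


@dataclass(frozen=True)
class TukeyGrouping:
    """Tukey HSD summary: per-level means and compact letter display."""

    table: pd.DataFrame  # columns: level, mean, letters (sorted by mean desc)
    alpha: float
    pvalues: pd.DataFrame  # symmetric matrix of pairwise HSD p-values

    def letters(self) -> dict:
        return dict(zip(self.table["level"], self.table["letters"]))

    def share_letter(self, a, b) -> bool:
        la, lb = self.letters()[a], self.letters()[b]
        return bool(set(la) & set(lb))


def tukey_cld(values: pd.DataFrame, level_col: str = "level",
              value_col: str = "value", alpha: float = 0.05) -> TukeyGrouping:
    """All-pairwise Tukey HSD with compact letter display.

    A one-way ANOVA across factor levels supplies the pooled within-level
    variance; each pair is compared by the studentized-range statistic
    q = |m_i - m_j| / sqrt(MSW/2 (1/n_i + 1/n_j)).  Letters are assembled by
    the insert-and-absorb algorithm and assigned in descending order of the
    level means.
    """
    df = values[[level_col, value_col]].dropna()
    groups = df.groupby(level_col, sort=False)
    levels = list(groups.groups)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two factor levels")
    ns = groups.size()
    if (ns < 2).any():
        bad = ns[ns < 2].index.tolist()
        raise ValueError(f"levels with a single replicate: {bad}")
    means = groups[value_col].mean()
    n_total = len(df)
    dfe = n_total - k
    msw = float(
        sum(((g[value_col] - g[value_col].mean()) ** 2).sum() for _, g in groups) / dfe
    )

    pmat = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    sig_pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            if msw == 0:
                p = 0.0 if means[a] != means[b] else 1.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                q = abs(means[a] - means[b]) / se
                p = float(stats.studentized_range.sf(q, k, dfe))
            pmat.loc[a, b] = pmat.loc[b, a] = p
            if p < alpha:
                sig_pairs.append((a, b))

    order = means.sort_values(ascending=False).index.tolist()
    letters = _insert_absorb(order, sig_pairs)
    table = pd.DataFrame(
        {"level": order, "mean": [means[l] for l in order], "letters": [letters[l] for l in order]}
    )
    return TukeyGrouping(table=table, alpha=alpha, pvalues=pmat)


def _insert_absorb(order: list, sig_pairs: list) -> dict:
    """Compact letter display via insert-and-absorb.

    Maintains letter columns (sets of mutually non-separated levels); each
    significant pair splits every column containing both; columns that are
    subsets of others are absorbed.  Letters follow the level order (highest
    mean first).
    """
    cols = [set(order)]
    for a, b in sig_pairs:
        new_cols = []
        for col in cols:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # drop empties and duplicates, absorb proper-subset columns
        uniq = []
        for c in new_cols:
            if c and c not in uniq:
                uniq.append(c)
        cols = [c for c in uniq if not any(c < d for d in uniq)]
    # order columns by the position of their best (highest-mean) member
    rank = {lvl: i for i, lvl in enumerate(order)}
    cols.sort(key=lambda c: min(rank[l] for l in c))
    alphabet = string.ascii_lowercase
    out = {lvl: "" for lvl in order}
    for i, col in enumerate(cols):
        letter = alphabet[i] if i < 26 else f"z{i}"
        for lvl in col:
            out[lvl] += letter
    return out


def pc_variance_explained(G: GMatrix | np.ndarray, k: int = 1) -> np.ndarray:
    """Percentage of variance explained by the top-k principal components of
    a relationship matrix: 100 * lambda_j / sum_i max(lambda_i, 0)."""
    mat = G.g if isinstance(G, GMatrix) else np.asarray(G, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("G must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    w = np.linalg.eigvalsh((mat + mat.T) / 2.0)[::-1]
    denom = np.clip(w, 0.0, None).sum()
    if denom == 0:
        raise ValueError("G has no positive eigenvalues")
    return 100.0 * w[:k] / denom


@dataclass(frozen=True)
class BudgetResult:
    """Sequencing budget: data volume per sample and multiplexing capacity."""

    gb_per_sample: float
    samples_per_run: int


def sequencing_budget(
    genome_gb: float = 0.6,
    depth: float = 12.0,
    flowcell_gb: float = 3000.0,
    rounding: str = "nearest",
) -> BudgetResult:
    """How many samples fit on a flow cell at a target depth.

    gb_per_sample = genome_gb x depth; samples_per_run = flowcell_gb /
    gb_per_sample, rounded to the nearest integer by default (floor/ceil
    available)."""
    if genome_gb <= 0 or depth <= 0 or flowcell_gb <= 0:
        raise ValueError("all budget inputs must be positive")
    gb = genome_gb * depth
    ratio = flowcell_gb / gb
    if rounding == "nearest":
        n = int(np.floor(ratio + 0.5))
    elif rounding == "floor":
        n = int(np.floor(ratio))
    elif rounding == "ceil":
        n = int(np.ceil(ratio))
    else:
        raise ValueError("rounding must be 'nearest', 'floor' or 'ceil'")
    return BudgetResult(gb_per_sample=gb, samples_per_run=n)
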