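"""Ratio-genotype G-BLUP: relationship matrix, Gibbs sampler, BLUP oracle.

The genomic relationship matrix follows the ratio parameterization
G = ZZ'/h, where Z is the column-centered ratio-genotype matrix M and
h = sum_i s_i^2 with s_i^2 the sample variance (divisor n-1) of centered
marker column z_i.  Centering forces zero row sums, and the (n-1) divisor
makes trace(G) = n-1 an exact identity on complete data — both are asserted
by the test suite.

The mixed model is y = mu + g + e with g ~ MVN(0, G sigma_a^2) and
e ~ MVN(0, I sigma_e^2), one adjusted phenotype per genotype.  It is fit by
Gibbs sampling with scaled-inverse-chi-square priors on both variances
(degrees of freedom df0, prior scales from an R2 split of the phenotypic
variance — the reference-software default convention).  The sampler works in
the eigenbasis of the training block of G, where the conditional posterior
of the genetic coefficients is diagonal, and draws the non-training genetic
values each iteration from their conditional MVN given the training vector,
so training and test values are sampled jointly.  A deterministic
closed-form BLUP at fixed variance components serves as the oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ContinuousGenotypes, _index_of

logger = logging.getLogger(__name__)

__all__ = ["GMatrix", "GblupFit", "build_g", "fit_gibbs", "fit_closed_form", "predict"]


@dataclass(frozen=True)
class GMatrix:
    """Genomic relationship matrix G = ZZ'/h with its scale metadata."""

    g: np.ndarray
    individual_ids: np.ndarray
    h: float
    n_markers: int

    def __post_init__(self):
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        object.__setattr__(
            self, "individual_ids", np.asarray(self.individual_ids, dtype=object)
        )
        n = len(self.individual_ids)
        if self.g.shape != (n, n):
            raise ValueError("G shape does not match individual ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def indices(self, ids) -> np.ndarray:
        return _index_of(self.individual_ids, ids, "individual")

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.g, index=self.individual_ids, columns=self.individual_ids).to_csv(
            path, sep="\t", index_label="individual"
        )


@dataclass
class GblupFit:
    """Fitted model state: posterior means (or BLUP solution) for the
    intercept and every individual's genetic value, plus variance components
    and chain metadata."""

    individual_ids: np.ndarray
    mu: float
    g_hat: np.ndarray
    sigma2_a: float
    sigma2_e: float
    train_ids: np.ndarray
    method: str
    n_stored: int = 0
    diagnostics: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.g_hat, index=list(self.individual_ids), name="g_hat")


def build_g(m: ContinuousGenotypes) -> GMatrix:
    """G = ZZ'/h from a complete ratio-genotype matrix.

    Monomorphic columns contribute zero to both ZZ' and h and are tolerated;
    if every marker is monomorphic the scale h is zero and the matrix is
    undefined.
    """
    M = m.m
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    Z = M - M.mean(axis=0, keepdims=True)
    s2 = (Z**2).sum(axis=0) / (n - 1)
    h = float(s2.sum())
    if h <= 0.0:
        raise ValueError("all markers are monomorphic; G is undefined")
    G = (Z @ Z.T) / h
    G = (G + G.T) / 2.0
    return GMatrix(G, m.individual_ids, h, M.shape[1])


def _clipped_eigh(mat: np.ndarray, what: str):
    """Eigendecomposition with PSD handling: eigenvalues in
    (-1e-8 * trace, 0) are clipped to zero with a warning; anything more
    negative is an error."""
    w, v = np.linalg.eigh(mat)
    tr = max(np.trace(mat), 1.0)
    if w.min() < -1e-8 * tr:
        raise ValueError(f"{what} is not positive semi-definite (min eig {w.min():.3e})")
    if w.min() < 0:
        logger.debug("%s: clipping %d tiny negative eigenvalues", what, int((w < 0).sum()))
    return np.clip(w, 0.0, None), v


def _prepare_partition(G: GMatrix, train_ids, y: pd.Series):
    train_ids = np.asarray(list(train_ids), dtype=object)
    tr = G.indices(train_ids)
    all_idx = np.arange(G.n_individuals)
    te = np.setdiff1d(all_idx, tr)
    yv = y.reindex(list(train_ids)).to_numpy(float)
    if np.any(~np.isfinite(yv)):
        raise ValueError("non-finite or missing phenotype among training individuals")
    return train_ids, tr, te, yv


def fit_gibbs(
    y: pd.Series,
    G: GMatrix,
    train_ids,
    n_iter: int = 35_000,
    burn_in: int = 5_000,
    thin: int = 5,
    df0: float = 5.0,
    r2: float = 0.5,
    seed: int = 0,
    fix_variances: tuple | None = None,
) -> GblupFit:
    """Gibbs sampler for the G-BLUP mixed model.

    Parameters follow the study's chain settings (35,000 iterations, 5,000
    burn-in, thinning of five, default hyper-parameters df0=5, R2=0.5).
    ``fix_variances=(sigma2_a, sigma2_e)`` freezes the variance components,
    which makes the posterior mean comparable to the closed-form BLUP oracle.

    Genetic values of non-training individuals are drawn jointly each
    iteration from their conditional MVN given the sampled training vector.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    train_ids, tr, te, yv = _prepare_partition(G, train_ids, y)
    n_t = len(tr)
    rng = np.random.default_rng(seed)

    G_tt = G.g[np.ix_(tr, tr)]
    lam, V = _clipped_eigh(G_tt, "training block of G")
    keep = lam > 1e-10 * max(lam.max(), 1.0)
    lam, V = lam[keep], V[:, keep]
    r = V.shape[1]

    # conditional pieces for the non-training block
    if len(te):
        G_st = G.g[np.ix_(te, tr)]
        B = (G_st @ V) / lam  # maps eigen coefficients to conditional means
        S = G.g[np.ix_(te, te)] - (B * lam) @ B.T
        ws, vs = _clipped_eigh((S + S.T) / 2.0, "conditional covariance of G")
        L_s = vs * np.sqrt(ws)
    else:
        B = L_s = None

    var_y = float(np.var(yv, ddof=1)) if n_t > 1 else 1.0
    if var_y == 0.0:
        var_y = 1e-8
    S0_e = var_y * (1.0 - r2) * (df0 + 2.0)
    S0_a = var_y * r2 * (df0 + 2.0) / max(np.mean(np.diag(G_tt)), 1e-12)

    sigma2_a, sigma2_e = (var_y * r2, var_y * (1 - r2))
    if fix_variances is not None:
        sigma2_a, sigma2_e = float(fix_variances[0]), float(fix_variances[1])
        if sigma2_a <= 0 or sigma2_e <= 0:
            raise ValueError("fixed variances must be positive")

    mu = float(np.mean(yv))
    c = np.zeros(r)
    sum_mu = 0.0
    sum_g = np.zeros(G.n_individuals)
    chain_a, chain_e = [], []
    n_stored = 0

    for it in range(n_iter):
        # genetic coefficients in the eigenbasis: diagonal posterior
        resid0 = yv - mu
        prec = 1.0 / sigma2_e + 1.0 / (lam * sigma2_a)
        mean_c = (V.T @ resid0) / sigma2_e / prec
        c = mean_c + rng.standard_normal(r) / np.sqrt(prec)
        g_t = V @ c

        # intercept (flat prior)
        mu = rng.normal(np.mean(yv - g_t), np.sqrt(sigma2_e / n_t))

        if fix_variances is None:
            e = yv - mu - g_t
            sigma2_e = (e @ e + S0_e) / rng.chisquare(df0 + n_t)
            quad = float(np.sum(c**2 / lam))
            sigma2_a = (quad + S0_a) / rng.chisquare(df0 + r)

        if it >= burn_in and (it - burn_in) % thin == 0:
            g_all = np.zeros(G.n_individuals)
            g_all[tr] = g_t
            if len(te):
                g_all[te] = B @ c + np.sqrt(sigma2_a) * (
                    L_s @ rng.standard_normal(L_s.shape[1])
                )
            sum_mu += mu
            sum_g += g_all
            chain_a.append(sigma2_a)
            chain_e.append(sigma2_e)
            n_stored += 1

    chain_a = np.asarray(chain_a)
    chain_e = np.asarray(chain_e)
    diag = {
        "ess_sigma2_a": _ess(chain_a),
        "ess_sigma2_e": _ess(chain_e),
        "split_rhat_sigma2_a": _split_rhat(chain_a),
        "n_eigen_components": int(r),
    }
    logger.info("gibbs diagnostics: %s", diag)
    return GblupFit(
        individual_ids=G.individual_ids,
        mu=sum_mu / n_stored,
        g_hat=sum_g / n_stored,
        sigma2_a=float(chain_a.mean()),
        sigma2_e=float(chain_e.mean()),
        train_ids=train_ids,
        method="gibbs",
        n_stored=n_stored,
        diagnostics=diag,
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(n / (1.0 + 2.0 * s))


def _split_rhat(x: np.ndarray) -> float:
    n = len(x) // 2
    if n < 5:
        return float("nan")
    a, b = x[:n], x[n : 2 * n]
    w = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0
    if w == 0:
        return 1.0
    mean_all = np.mean([a.mean(), b.mean()])
    bvar = n * ((a.mean() - mean_all) ** 2 + (b.mean() - mean_all) ** 2)
    var_plus = (n - 1) / n * w + bvar / n
    return float(np.sqrt(var_plus / w))


def fit_closed_form(
    y: pd.Series, G: GMatrix, train_ids, sigma2_a: float, sigma2_e: float
) -> GblupFit:
    """Deterministic BLUP at fixed variance components.

    Solves generalized least squares for mu with V = sigma2_a G_tt +
    sigma2_e I, sets g_train = sigma2_a G_tt V^{-1} (y - mu), and predicts
    non-training individuals through the conditional expectation
    sigma2_a G_{s,t} V^{-1} (y - mu) implied by the partitioned G.
    """
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    train_ids, tr, te, yv = _prepare_partition(G, train_ids, y)
    G_tt = G.g[np.ix_(tr, tr)]
    Vmat = sigma2_a * G_tt + sigma2_e * np.eye(len(tr))
    try:
        Vinv_y = np.linalg.solve(Vmat, yv)
        Vinv_1 = np.linalg.solve(Vmat, np.ones(len(tr)))
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular mixed-model system: {e}") from None
    mu = float(np.ones(len(tr)) @ Vinv_y / (np.ones(len(tr)) @ Vinv_1))
    alpha = np.linalg.solve(Vmat, yv - mu)
    g_all = sigma2_a * (G.g[:, tr] @ alpha)
    return GblupFit(
        individual_ids=G.individual_ids,
        mu=mu,
        g_hat=g_all,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        train_ids=train_ids,
        method="closed_form",
    )


def predict(fit: GblupFit, ids) -> pd.Series:
    """Predicted values mu + g for the requested individuals."""
    ids = list(ids)
    idx = _index_of(fit.individual_ids, ids, "individual")
    in_train = set(fit.train_ids) & set(ids)
    if in_train:
        logger.info("%d requested individuals were in the training set", len(in_train))
    return pd.Series(fit.mu + fit.g_hat[idx], index=ids, name="prediction")
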