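"""Precision-weighted moderated linear models for count matrices.

The modelling pathway mirrors the limma/voom tradition for ATAC and RNA count
matrices:

1. counts are converted to log2 counts per million (log-CPM);
2. observation-level precision weights come from a smoothed mean-variance
   trend (lowess of the quarter-root residual variance against average
   log-count), evaluated at each observation's fitted log-count and raised to
   the inverse fourth power;
3. per-sample quality weights are estimated by an iterative moment scheme on
   standardized residual variances (clipped to [0.25, 4], geometric mean 1);
4. repeated measures on the same donor are absorbed by a single consensus
   intra-donor correlation rho, used in a generalized least squares fit with
   block-equicorrelated errors;
5. residual variances are shrunk towards a scaled inverse chi-square prior
   whose hyperparameters (prior df d0, prior variance s0^2) are obtained by
   matching moments of the log variances (digamma/trigamma inversion);
6. contrasts over the group-means design yield moderated t statistics with
   d0 + residual df degrees of freedom, and Benjamini-Hochberg adjustment.

The combined aging contrast of the study is the sum of per-subset old-minus-
young differences, (naive/old - naive/young) + (CM/old - CM/young) +
(EM/old - EM/young), evaluated separately per lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

LOG2E6 = np.log2(1e6)


class ContrastError(ValueError):
    """A contrast references a group absent from the design."""


@dataclass(frozen=True)
class ContrastSpec:
    """Named linear combination of group-mean coefficients."""

    name: str
    weights: Mapping[str, float]

    def vector(self, groups: Sequence[str]) -> np.ndarray:
        missing = set(self.weights) - set(groups)
        if missing:
            raise ContrastError(
                f"contrast {self.name!r} references unknown group(s): {sorted(missing)}"
            )
        return np.array([self.weights.get(g, 0.0) for g in groups])


def aging_contrast(lineage: str, subsets: Sequence[str] = ("naive", "CM", "EM")) -> ContrastSpec:
    """Combined aging contrast: sum of per-subset (old - young) differences."""
    w: dict[str, float] = {}
    for sub in subsets:
        w[f"{lineage}_{sub}_old"] = 1.0
        w[f"{lineage}_{sub}_young"] = -1.0
    return ContrastSpec(f"aging_{lineage}", w)


def subset_age_contrast(lineage: str, subset: str) -> ContrastSpec:
    return ContrastSpec(
        f"age_{subset}_{lineage}",
        {f"{lineage}_{subset}_old": 1.0, f"{lineage}_{subset}_young": -1.0},
    )


def differentiation_contrast(
    lineage: str, high: str = "EM", low: str = "naive"
) -> ContrastSpec:
    """Average EM-minus-naive difference within a lineage, across age groups."""
    return ContrastSpec(
        f"differentiation_{lineage}",
        {
            f"{lineage}_{high}_old": 0.5,
            f"{lineage}_{high}_young": 0.5,
            f"{lineage}_{low}_old": -0.5,
            f"{lineage}_{low}_young": -0.5,
        },
    )


@dataclass
class WeightedMatrix:
    """log-CPM values with observation weights, sample weights and donor blocks."""

    logcpm: pd.DataFrame                 # features x samples
    obs_weights: np.ndarray              # same shape, strictly positive
    sample_weights: pd.Series            # per sample
    lib_sizes: pd.Series
    groups: pd.Series                    # sample -> design group label
    donors: pd.Series | None = None      # sample -> donor id
    rho: float = 0.0                     # consensus intra-donor correlation

    def __post_init__(self) -> None:
        if self.obs_weights.shape != self.logcpm.shape:
            raise ValueError("obs_weights shape mismatch")
        if not np.all(np.isfinite(self.obs_weights)) or np.any(self.obs_weights <= 0):
            raise ValueError("observation weights must be positive and finite")
        if np.any(self.sample_weights <= 0):
            raise ValueError("sample weights must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def combined_weights(self) -> np.ndarray:
        return self.obs_weights * self.sample_weights.to_numpy()[None, :]


@dataclass
class DifferentialTable:
    """Tidy per-feature, per-contrast moderated test results."""

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    residual_df: float
    rho: float = 0.0

    def for_contrast(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == name]
        if sub.empty:
            raise KeyError(f"no contrast named {name!r}")
        return sub.set_index("feature_id")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    return counts / lib * 1e6


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2((count + 0.5) / (libsize + 1) * 1e6)."""
    lib = counts.sum(axis=0)
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def filter_low_counts(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> pd.DataFrame:
    """Keep features with CPM >= min_cpm in at least min_samples samples."""
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    if min_samples <= 0:
        return counts
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    out = counts.loc[keep]
    if out.empty:
        raise ValueError(
            f"no features pass min_cpm={min_cpm} in >= {min_samples} samples; "
            "lower the thresholds"
        )
    return out


def design_matrix(groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    labels = sorted(groups.unique())
    X = np.zeros((len(groups), len(labels)))
    for j, g in enumerate(labels):
        X[(groups == g).to_numpy(), j] = 1.0
    return X, labels


def _block_correlation(donors: pd.Series, rho: float) -> np.ndarray:
    d = donors.to_numpy()
    same = d[:, None] == d[None, :]
    C = np.where(same, rho, 0.0)
    np.fill_diagonal(C, 1.0)
    return C


def _gls_fit(
    Y: np.ndarray, W: np.ndarray, X: np.ndarray, T: np.ndarray | None
) -> dict[str, np.ndarray]:
    """Batched per-feature weighted (optionally whitened) least squares.

    Y, W: (G, n); X: (n, k); T: whitening transform with T C T' = I or None.
    Returns coefficients, residual variance, df and unscaled coefficient
    covariances.
    """
    G, n = Y.shape
    k = X.shape[1]
    SW = np.sqrt(W)
    Xw = SW[:, :, None] * X[None, :, :]           # (G, n, k)
    Yw = SW * Y
    if T is not None:
        Xw = np.einsum("mn,gnk->gmk", T, Xw)
        Yw = Yw @ T.T
    A = np.einsum("gnk,gnl->gkl", Xw, Xw)
    b = np.einsum("gnk,gn->gk", Xw, Yw)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    resid = Yw - np.einsum("gnk,gk->gn", Xw, beta)
    df = n - k
    sigma2 = (resid**2).sum(axis=1) / df
    Ainv = np.linalg.inv(A)
    return {"beta": beta, "sigma2": sigma2, "df": df, "cov_unscaled": Ainv,
            "resid_white": resid}


def normalize_and_weight(
    counts: pd.DataFrame,
    groups: pd.Series,
    donors: pd.Series | None = None,
    span: float = 0.5,
    n_weight_iter: int = 5,
    n_corr_features: int = 500,
) -> WeightedMatrix:
    """Compute log-CPM, precision weights, sample quality weights and rho.

    ``groups`` assigns every sample (column) to one design group; ``donors``
    optionally assigns samples to donors for the consensus correlation.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    groups = groups.loc[counts.columns]
    Y = log_cpm(counts).to_numpy(dtype=float)
    X, _ = design_matrix(groups)
    G, n = Y.shape

    # mean-variance trend (voom-style): quarter-root variance vs mean log-count
    fit0 = _gls_fit(Y, np.ones_like(Y), X, None)
    sx = Y.mean(axis=1) + np.mean(np.log2(lib.to_numpy() + 1.0)) - LOG2E6
    sy = np.sqrt(np.sqrt(fit0["sigma2"]))
    lo = lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], np.maximum(lo[:, 1], 1e-6)
    fitted_logcpm = np.einsum("nk,gk->gn", X, fit0["beta"])
    fitted_logcount = fitted_logcpm + (np.log2(lib.to_numpy() + 1.0) - LOG2E6)[None, :]
    trend = np.interp(fitted_logcount, lx, ly)
    obs_w = trend ** -4.0

    # sample quality weights: moment scheme on standardized residual variances
    gamma = np.ones(n)
    for _ in range(n_weight_iter):
        W = obs_w * gamma[None, :]
        fit = _gls_fit(Y, W, X, None)
        # whitened residuals have variance sigma2 * (1 - leverage); ignore
        # leverage and rescale per sample
        r2 = fit["resid_white"] ** 2 / np.maximum(fit["sigma2"], 1e-12)[:, None]
        v = r2.mean(axis=0) / gamma  # residuals already scaled by sqrt(gamma)
        # v estimates 1/gamma up to a common factor
        new = 1.0 / np.maximum(v, 1e-12)
        new = np.clip(new, 0.25, 4.0)
        new /= np.exp(np.mean(np.log(new)))
        new = np.clip(new, 0.25, 4.0)
        if np.max(np.abs(new - gamma)) < 1e-4:
            gamma = new
            break
        gamma = new

    # consensus intra-donor correlation
    rho = 0.0
    if donors is not None:
        donors = donors.loc[counts.columns]
        sizes = donors.value_counts()
        if (sizes >= 2).any():
            W = obs_w * gamma[None, :]
            fit = _gls_fit(Y, W, X, None)
            z = fit["resid_white"] / np.sqrt(np.maximum(fit["sigma2"], 1e-12))[:, None]
            top = np.argsort(-Y.mean(axis=1))[: min(n_corr_features, G)]
            d = donors.to_numpy()
            same = (d[:, None] == d[None, :]) & ~np.eye(n, dtype=bool)
            pairs = np.argwhere(np.triu(same))
            if len(pairs):
                zi = z[np.ix_(top, pairs[:, 0])]
                zj = z[np.ix_(top, pairs[:, 1])]
                num = (zi * zj).mean(axis=1)
                den = (z[top] ** 2).mean(axis=1)
                r = np.clip(num / np.maximum(den, 1e-12), -0.95, 0.95)
                rho = float(np.tanh(np.mean(np.arctanh(r))))
        else:
            logger.info("no donor with >= 2 samples; rho fixed at 0")

    return WeightedMatrix(
        logcpm=pd.DataFrame(Y, index=counts.index, columns=counts.columns),
        obs_weights=obs_w,
        sample_weights=pd.Series(gamma, index=counts.columns),
        lib_sizes=lib,
        groups=groups,
        donors=donors,
        rho=rho,
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_f_dist(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse chi-square prior to observed variances.

    Returns (d0, s0^2): prior degrees of freedom and prior variance.  d0 is
    +inf when the log-variances are underdispersed relative to chi-square
    sampling noise.
    """
    s2 = np.maximum(np.asarray(sigma2, dtype=float), 1e-300)
    deg = df / 2.0
    e = np.log(s2) - digamma(deg) + np.log(deg)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, deg))
    if evar > 0:
        x = trigamma_inverse(evar)
        d0 = 2.0 * x
        s02 = float(np.exp(emean + digamma(x) - np.log(x)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def moderate_variances(
    sigma2: np.ndarray, df: float, robust: bool = True
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of residual variances.

    When ``robust``, the prior is fitted on variances winsorized at the
    1st/99th percentiles so extreme features do not drive the hyperparameters;
    each feature's own (unwinsorized) variance is then shrunk.
    """
    s2 = np.asarray(sigma2, dtype=float)
    fit_on = s2
    if robust and len(s2) >= 10:
        lo, hi = np.percentile(s2, [1, 99])
        fit_on = np.clip(s2, lo, hi)
    d0, s02 = fit_f_dist(fit_on, df)
    if not np.isfinite(d0):
        logger.info("prior df non-finite; variances fully shrunk to the prior")
        return np.full_like(s2, s02), d0, s02
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


def fit_differential(
    wm: WeightedMatrix,
    contrasts: Sequence[ContrastSpec],
    robust: bool = True,
) -> DifferentialTable:
    """GLS group-means fit + empirical-Bayes moderated contrasts."""
    Y = wm.logcpm.to_numpy(dtype=float)
    W = wm.combined_weights
    X, labels = design_matrix(wm.groups)
    counts_per_group = wm.groups.value_counts()
    empty = [g for g in labels if counts_per_group.get(g, 0) == 0]
    if empty:
        raise ContrastError(f"empty design group(s): {empty}")

    T = None
    if wm.donors is not None and abs(wm.rho) > 1e-12:
        C = _block_correlation(wm.donors, wm.rho)
        L = np.linalg.cholesky(C)
        T = np.linalg.inv(L)

    fit = _gls_fit(Y, W, X, T)
    df = float(fit["df"])
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    s2_post, d0, s02 = moderate_variances(fit["sigma2"], df, robust=robust)
    df_total = df + d0 if np.isfinite(d0) else np.inf

    ave = Y.mean(axis=1)
    rows = []
    for spec in contrasts:
        c = spec.vector(labels)
        est = fit["beta"] @ c
        varfac = np.einsum("k,gkl,l->g", c, fit["cov_unscaled"], c)
        se = np.sqrt(s2_post * varfac)
        tstat = est / se
        dist_df = df_total if np.isfinite(df_total) else 1e12
        p = 2.0 * stats.t.sf(np.abs(tstat), dist_df)
        q = bh_adjust(p)
        rows.append(pd.DataFrame({
            "feature_id": wm.logcpm.index,
            "contrast": spec.name,
            "log_fc": est,
            "ave_logcpm": ave,
            "t": tstat,
            "p_value": p,
            "q_value": q,
            "df_residual": df,
        }))
    table = pd.concat(rows, ignore_index=True)
    return DifferentialTable(
        table=table, prior_df=d0, prior_var=s02, residual_df=df, rho=wm.rho
    )


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
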