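"""Variable-feature PCA and donor-level stratified permutation inference.

PCA is run on the most variable features (defaults: 5000 peaks for ATAC, 500
genes for RNA) and principal-component scores are compared between lineages
(paired within donor, stratified by subset and age), between age groups
(two-sample, stratified by lineage and subset) and along the differentiation
axis (trend test per stratum, combined by Stouffer).  The exchangeability unit
of every permutation scheme is the donor, never the individual sample:
lineage labels are flipped per donor, age labels are reassigned per donor, and
subset labels are shuffled within each donor block.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: arrangements at or below this bound are enumerated exhaustively
EXHAUSTIVE_LIMIT = 20_000
DEFAULT_N_PERM = 10_000
_EPS = 1e-12


@dataclass
class PCAResult:
    feature_ids: list[str]
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    variance_fractions: np.ndarray

    def component(self, k: int) -> pd.Series:
        """1-based principal-component scores."""
        return self.scores[f"PC{k}"]


@dataclass
class PermutationResult:
    statistic: float
    p_value: float
    sidedness: str
    scheme: str
    n_arrangements: int
    exhaustive: bool
    seed: int | None = None


def top_variable_features(matrix: pd.DataFrame, n: int) -> list[str]:
    """Ids of the n largest row variances; ties broken by feature id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(zip(-var.to_numpy(), var.index.astype(str)))
    return [fid for _, fid in order[: min(n, len(order))]]


def pca_scores(matrix: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """Feature-centered SVD of a features-x-samples matrix.

    Scores are sample projections, loadings are unit-norm per component, and
    variance fractions are squared singular values over their total.  Signs
    are fixed so each component's largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("matrix is constant; no variance to decompose")
    n_components = min(n_components, min(Xc.shape))
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(n_components):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1.0
            Vt[k, :] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(
        Vt[:n_components].T * S[:n_components], index=matrix.columns, columns=cols
    )
    loadings = pd.DataFrame(U[:, :n_components], index=matrix.index, columns=cols)
    varfrac = S**2 / np.sum(S**2)
    return PCAResult(
        feature_ids=[str(i) for i in matrix.index],
        scores=scores,
        loadings=loadings,
        variance_fractions=varfrac[:n_components],
    )


def pc_loading_peaks(pca: PCAResult, component: int, n: int = 500) -> list[str]:
    """Ids of the n largest-|loading| features for a component (ties by id)."""
    col = f"PC{component}"
    if col not in pca.loadings:
        raise ValueError(f"component {component} not fitted")
    load = pca.loadings[col]
    order = sorted(zip(-load.abs().to_numpy(), load.index.astype(str)))
    return [fid for _, fid in order[: min(n, len(order))]]


def _donor_stratum_means(
    values: pd.Series, samples: pd.DataFrame, strata_cols: list[str], by: str
) -> pd.DataFrame:
    df = samples.copy()
    df["_value"] = values.loc[df.index].to_numpy()
    df["_stratum"] = list(zip(*[df[c] for c in strata_cols])) if strata_cols else "all"
    return df


def paired_stratified_perm_test(
    values: pd.Series,
    samples: pd.DataFrame,
    pair_on: str = "lineage",
    strata: tuple[str, ...] = ("subset", "age_group"),
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> PermutationResult:
    """Donor-paired comparison of two labels of ``pair_on``, stratified.

    The statistic is the unweighted mean over strata of the within-stratum
    mean paired difference (second label minus first, labels sorted).  The
    null flips each donor's pair labels as a unit across all strata
    (sign-flip); exhaustive when 2^donors <= 20,000, otherwise Monte Carlo
    with add-one smoothing.  Two-sided via |statistic|.
    """
    df = _donor_stratum_means(values, samples, list(strata), pair_on)
    labels = sorted(df[pair_on].unique())
    if len(labels) != 2:
        raise ValueError(f"{pair_on} must have exactly two labels, got {labels}")
    wide = df.pivot_table(
        index=["donor", "_stratum"], columns=pair_on, values="_value", aggfunc="mean"
    )
    if wide[labels].isna().any().any():
        bad = wide[wide[labels].isna().any(axis=1)].index[0]
        raise ValueError(f"donor {bad[0]} lacks a {pair_on} label in stratum {bad[1]}")
    diff = (wide[labels[1]] - wide[labels[0]]).unstack("_stratum")  # donors x strata
    # a donor need not appear in every stratum (e.g. age strata); the
    # statistic mean_strata(mean_donors-in-stratum diff) collapses to a
    # per-donor weighted contribution c_d, flipped as a unit under the null
    n_per_stratum = diff.notna().sum(axis=0)
    if (n_per_stratum == 0).any():
        empty = n_per_stratum.index[n_per_stratum == 0].tolist()
        raise ValueError(f"stratum with no complete pairs: {empty}")
    S = diff.shape[1]
    contrib = (diff / n_per_stratum).sum(axis=1, skipna=True) / S
    m = contrib.to_numpy()
    D = len(m)
    obs = float(m.sum())
    total = 2**D
    if total <= EXHAUSTIVE_LIMIT:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=D)))
        null = signs @ m
        p = float(np.mean(np.abs(null) >= abs(obs) - _EPS))
        return PermutationResult(obs, p, "two-sided", "paired_signflip", total, True, seed)
    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_perm, D))
    null = signs @ m
    b = int(np.sum(np.abs(null) >= abs(obs) - _EPS))
    return PermutationResult(
        obs, (b + 1) / (n_perm + 1), "two-sided", "paired_signflip", n_perm, False, seed
    )


def twosample_stratified_perm_test(
    values: pd.Series,
    samples: pd.DataFrame,
    group_on: str = "age_group",
    strata: tuple[str, ...] = ("lineage", "subset"),
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    alternative: str = "two-sided",
    order: tuple[str, str] | None = None,
) -> PermutationResult:
    """Stratified two-sample comparison with donor-level group relabelling.

    Statistic: mean over strata of (mean of ``order[1]`` minus mean of
    ``order[0]``).  When ``order`` is omitted, young/old labels default to
    (young, old) -- i.e. the statistic is old minus young -- and any other
    pair is taken in sorted order.  The null reassigns the ``group_on`` label
    at the donor level, preserving group sizes and keeping each donor's
    samples together.
    """
    df = _donor_stratum_means(values, samples, list(strata), group_on)
    labels = sorted(df[group_on].unique())
    if len(labels) != 2:
        raise ValueError(f"{group_on} must have exactly two labels, got {labels}")
    if order is not None:
        if sorted(order) != labels:
            raise ValueError(f"order {order} does not match labels {labels}")
        labels = list(order)
    elif set(labels) == {"young", "old"}:
        labels = ["young", "old"]
    per = df.pivot_table(index="donor", columns="_stratum", values="_value", aggfunc="mean")
    if per.isna().any().any():
        bad = per.columns[per.isna().any(axis=0)].tolist()
        raise ValueError(f"stratum missing donors: {bad}")
    donor_group = df.groupby("donor")[group_on].agg(lambda s: s.iloc[0])
    if (df.groupby("donor")[group_on].nunique() > 1).any():
        raise ValueError(f"{group_on} must be constant within donor")
    strata_missing = [
        s for s in df["_stratum"].unique()
        if df[df["_stratum"] == s][group_on].nunique() < 2
    ]
    if strata_missing:
        raise ValueError(f"stratum with a single {group_on} label: {strata_missing}")
    m = per.mean(axis=1)  # per-donor mean over strata
    donors = m.index.to_numpy()
    vals = m.to_numpy()
    is_b = (donor_group.loc[donors] == labels[1]).to_numpy()
    n_b, n_a = int(is_b.sum()), int((~is_b).sum())

    def stat(mask: np.ndarray) -> float:
        return float(vals[mask].mean() - vals[~mask].mean())

    obs = stat(is_b)
    total = math.comb(len(donors), n_b)
    if total <= EXHAUSTIVE_LIMIT:
        count = 0
        for combo in itertools.combinations(range(len(donors)), n_b):
            mask = np.zeros(len(donors), dtype=bool)
            mask[list(combo)] = True
            s = stat(mask)
            if alternative == "two-sided":
                count += abs(s) >= abs(obs) - _EPS
            elif alternative == "greater":
                count += s >= obs - _EPS
            else:
                count += s <= obs + _EPS
        return PermutationResult(
            obs, count / total, alternative, "group_relabel", total, True, seed
        )
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        mask = np.zeros(len(donors), dtype=bool)
        mask[rng.choice(len(donors), size=n_b, replace=False)] = True
        s = stat(mask)
        if alternative == "two-sided":
            b += abs(s) >= abs(obs) - _EPS
        elif alternative == "greater":
            b += s >= obs - _EPS
        else:
            b += s <= obs + _EPS
    return PermutationResult(
        obs, (b + 1) / (n_perm + 1), alternative, "group_relabel", n_perm, False, seed
    )


def _stouffer_trend(
    values: np.ndarray, ranks: np.ndarray, stratum_indices: list[np.ndarray]
) -> float:
    """Spearman-per-stratum trend statistic combined by Stouffer (equal weights).

    Spearman is computed as the Pearson correlation of rank-transformed values
    (identical to scipy.stats.spearmanr, including midranks for ties).
    """
    zs = []
    for ix in stratum_indices:
        v, r = values[ix], ranks[ix]
        if len(np.unique(v)) <= 1 or len(np.unique(r)) <= 1:
            logger.info("constant scores or ranks in a stratum; z set to 0")
            zs.append(0.0)
            continue
        c = np.corrcoef(stats.rankdata(v), stats.rankdata(r))[0, 1]
        if not np.isfinite(c):
            zs.append(0.0)
            continue
        c = min(max(c, -0.999999), 0.999999)
        zs.append(c * math.sqrt(len(ix) - 1))
    return float(np.sum(zs) / math.sqrt(max(len(zs), 1)))


def stratified_trend_test(
    values: pd.Series,
    samples: pd.DataFrame,
    rank_col: str = "subset_rank",
    strata: tuple[str, ...] = ("lineage", "age_group"),
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> PermutationResult:
    """Combined ordinal trend test across strata.

    Per stratum, Spearman correlation of score against the ordinal rank
    (naive < CM < EM), converted to z and combined by Stouffer with equal
    weights.  The null permutes the ordinal labels within each donor(-lineage)
    block; exhaustive when the product of per-block permutation counts is
    <= 20,000.  Two-sided.
    """
    df = _donor_stratum_means(values, samples, list(strata), rank_col)
    if (df.groupby("_stratum")[rank_col].nunique() < 2).any():
        raise ValueError("each stratum needs >= 2 distinct ordinal levels")
    vals = df["_value"].to_numpy(dtype=float)
    base = df[rank_col].to_numpy(dtype=float).copy()
    stratum_indices = [np.asarray(ix, dtype=int)
                       for ix in df.groupby("_stratum").indices.values()]
    obs = _stouffer_trend(vals, base, stratum_indices)

    block_cols = ["donor"] + (["lineage"] if "lineage" in samples.columns else [])
    df["_block"] = list(zip(*[df[c] for c in block_cols]))
    blocks = df.groupby("_block").indices
    sizes = [len(idx) for idx in blocks.values()]
    total = int(np.prod([math.factorial(s) for s in sizes]))
    idx_lists = [np.asarray(idx, dtype=int) for idx in blocks.values()]

    if total <= EXHAUSTIVE_LIMIT:
        block_perms = [list(itertools.permutations(range(s))) for s in sizes]
        count = 0
        for combo in itertools.product(*block_perms):
            ranks = base.copy()
            for idx, perm in zip(idx_lists, combo):
                ranks[idx] = base[idx][list(perm)]
            if abs(_stouffer_trend(vals, ranks, stratum_indices)) >= abs(obs) - _EPS:
                count += 1
        return PermutationResult(
            obs, count / total, "two-sided", "trend_combined", total, True, seed
        )
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        ranks = base.copy()
        for idx in idx_lists:
            ranks[idx] = base[idx][rng.permutation(len(idx))]
        if abs(_stouffer_trend(vals, ranks, stratum_indices)) >= abs(obs) - _EPS:
            b += 1
    return PermutationResult(
        obs, (b + 1) / (n_perm + 1), "two-sided", "trend_combined", n_perm, False, seed
    )


def ordering_probability(
    group_means: dict[str, float], hypothesized_order: list[str]
) -> tuple[bool, float]:
    """Chance probability of one prespecified complete ordering of group means.

    Under exchangeability every one of the g! complete orders of g group
    means is equally likely, so a single prespecified order has null
    probability 1/g!.  Returns whether the observed means realize the order
    (strictly decreasing along ``hypothesized_order``) and that probability.
    """
    if len(hypothesized_order) < 2:
        raise ValueError("need at least two groups")
    missing = [g for g in hypothesized_order if g not in group_means]
    if missing:
        raise ValueError(f"groups missing from means: {missing}")
    vals = [group_means[g] for g in hypothesized_order]
    if len(set(vals)) != len(vals):
        raise ValueError("tied group means: ordering undefined")
    matches = all(a > b for a, b in zip(vals, vals[1:]))
    return matches, 1.0 / math.factorial(len(hypothesized_order))
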