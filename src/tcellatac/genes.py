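"""Peak-to-gene assignment, EASE term enrichment and gene-set shift tests.

Peaks are assigned to the gene with the nearest TSS (distance 0 when the TSS
falls inside the peak, otherwise the base-pair gap to the nearest peak edge),
optionally capped at 10 kb.  Term enrichment uses the EASE score, a
conservative one-sided Fisher exact p computed after decrementing the overlap
by one.  Gene-set shifts in per-gene log2 fold differences (the ribosomal
RPL/RPS/MRP analysis) use the Wilcoxon rank-sum test of set versus all other
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust


def read_gene_model(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str,
                                            "chrom": str, "strand": str})
    need = {"gene_id", "symbol", "chrom", "tss", "strand"}
    if not need.issubset(df.columns):
        raise ValueError(f"gene model needs columns {sorted(need)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids")
    if (df["tss"] < 0).any():
        raise ValueError("negative TSS position")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def _peak_gene_distance(start: int, end: int, tss: int) -> int:
    """0 if the TSS lies inside [start, end); else gap to the nearest edge."""
    return max(0, start - tss, tss - end)


def nearest_gene(
    atlas, genes: pd.DataFrame, max_dist: float = 10_000
) -> pd.DataFrame:
    """Map each atlas peak to its nearest gene TSS within ``max_dist``.

    Returns a DataFrame (peak_id, gene_id, symbol, distance); peaks without a
    gene within the cap are omitted.  Ties go to the smallest gene_id.
    """
    if genes.empty:
        raise ValueError("empty gene model")
    per_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for c, sub in genes.groupby("chrom")
    }
    rows = []
    frame = atlas.to_frame() if hasattr(atlas, "to_frame") else atlas
    for _, peak in frame.iterrows():
        chrom = str(peak["chrom"])
        if chrom not in per_chrom:
            continue
        sub = per_chrom[chrom]
        tss = sub["tss"].to_numpy()
        start, end = int(peak["start"]), int(peak["end"])
        i = np.searchsorted(tss, start)
        j = np.searchsorted(tss, end)
        cand = set(range(max(0, i - 1), min(len(sub), j + 1)))
        best_d, best_gene, best_sym = None, None, None
        for idx in sorted(cand):
            d = _peak_gene_distance(start, end, int(tss[idx]))
            gid = sub.at[idx, "gene_id"]
            if best_d is None or d < best_d or (d == best_d and gid < best_gene):
                best_d, best_gene, best_sym = d, gid, sub.at[idx, "symbol"]
        if best_d is not None and best_d <= max_dist:
            rows.append({"peak_id": peak["peak_id"], "gene_id": best_gene,
                         "symbol": best_sym, "distance": best_d})
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "symbol", "distance"])


def ease_enrichment(
    gene_list: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    ease_threshold: float = 0.1,
) -> pd.DataFrame:
    """EASE-score term enrichment of a gene list against a background.

    For each term the 2x2 table of list membership vs term membership over the
    background gives a one-sided Fisher exact p; the EASE score recomputes the
    tail after decrementing the overlap by one (floor at zero), which
    penalizes single-gene overlaps.  Terms with EASE < ``ease_threshold`` are
    flagged enriched; a BH-adjusted EASE column is also reported.
    """
    bg = set(map(str, background))
    lst = set(map(str, gene_list)) & bg
    if not set(map(str, gene_list)) <= bg:
        raise ValueError("gene list must be a subset of the background")
    N, n = len(bg), len(lst)
    rows = []
    for term, members in sorted(term_sets.items()):
        K = len(set(map(str, members)) & bg)
        a = len(set(map(str, members)) & lst)
        fisher = float(stats.hypergeom.sf(a - 1, N, K, n)) if a > 0 else 1.0
        ease = float(stats.hypergeom.sf(a - 2, N, K, n)) if a > 1 else 1.0
        rows.append({"term": term, "overlap": a, "term_size": K,
                     "list_size": n, "background_size": N,
                     "fisher_p": min(fisher, 1.0), "ease_p": min(ease, 1.0)})
    out = pd.DataFrame(rows)
    out["ease_q"] = bh_adjust(out["ease_p"].to_numpy())
    out["enriched"] = out["ease_p"] < ease_threshold
    return out.sort_values(["ease_p", "term"], kind="mergesort").reset_index(drop=True)


@dataclass
class GeneSetShiftResult:
    set_name: str
    n_set: int
    n_rest: int
    statistic: float
    p_value: float
    median_set: float
    median_rest: float
    alternative: str
    exact: bool


def geneset_shift_test(
    fold_differences: pd.Series,
    gene_set: Iterable[str],
    set_name: str = "set",
    alternative: str = "two-sided",
    exact_limit: int = 12,
) -> GeneSetShiftResult:
    """Wilcoxon rank-sum test of a gene set's fold differences vs all others.

    Exact enumeration when the combined sample size is <= ``exact_limit`` and
    there are no ties; otherwise the normal approximation with tie correction.
    """
    vals = fold_differences.dropna()
    in_set = vals.index.astype(str).isin(set(map(str, gene_set)))
    x, y = vals[in_set].to_numpy(), vals[~in_set].to_numpy()
    if len(x) == 0:
        raise ValueError(f"gene set {set_name!r} has no genes with data")
    if len(y) == 0:
        raise ValueError("complement is empty")
    n = len(x) + len(y)
    no_ties = len(np.unique(np.concatenate([x, y]))) == n
    exact = n <= exact_limit and no_ties
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return GeneSetShiftResult(
        set_name=set_name, n_set=len(x), n_rest=len(y),
        statistic=float(res.statistic), p_value=float(res.pvalue),
        median_set=float(np.median(x)), median_rest=float(np.median(y)),
        alternative=alternative, exact=exact,
    )
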