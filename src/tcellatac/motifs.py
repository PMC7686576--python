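"""Motif-set enrichment over annotated peaks.

Sequence-level motif scanning is out of scope: peaks arrive already annotated
with motif occurrences (motif_id, family, peak_id), and enrichment of a
foreground peak set against a disjoint background is the one-sided
hypergeometric tail on the annotated universe.  Family reduction keeps the
most significant member per transcription-factor family; motif intensity
summarizes accessibility over motif-bearing peaks as a per-group z-score.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust


def read_motif_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"motif_id", "family", "peak_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"motif annotation needs columns {sorted(need)}")
    return df.drop_duplicates(["motif_id", "peak_id"]).reset_index(drop=True)


def motif_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each motif in the foreground.

    Universe = foreground ∪ background (must be disjoint).  For a motif
    occurring in n universe peaks, with K foreground peaks of which k carry
    the motif, p = P(X >= k) for X ~ Hypergeom(N, n, K).  Rows are BH-adjusted
    across motifs and ranked by p (ties by motif id).
    """
    fg = set(map(str, foreground))
    bg = set(map(str, background))
    if not fg:
        raise ValueError("empty foreground")
    if fg & bg:
        raise ValueError("foreground and background must be disjoint")
    universe = fg | bg
    N, K = len(universe), len(fg)
    rows = []
    for (motif, family), sub in annotation.groupby(["motif_id", "family"], sort=True):
        peaks = set(sub["peak_id"]) & universe
        n = len(peaks)
        k = len(peaks & fg)
        p = float(stats.hypergeom.sf(k - 1, N, n, K))
        rows.append({"motif_id": motif, "family": family,
                     "k_overlap": k, "K_foreground": K, "n_motif": n,
                     "N_universe": N, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "motif_id"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def best_per_family(rows: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per family: the smallest p (ties by motif id)."""
    if "family" not in rows.columns:
        raise ValueError("rows lack a family column")
    ordered = rows.sort_values(["p_value", "motif_id"], kind="mergesort")
    out = ordered.drop_duplicates("family", keep="first")
    return out.sort_values(["p_value", "motif_id"], kind="mergesort").reset_index(drop=True)


def motif_intensity(
    normalized: pd.DataFrame,
    motif_peaks: Iterable[str],
    sample_groups: pd.Series,
) -> pd.Series:
    """Per-group z-score of the median accessibility over motif-bearing peaks.

    For each group the group-mean normalized accessibility is taken per peak,
    the median over the motif's peaks summarizes the group, and the group
    summaries are z-scored (mean 0, population SD 1) across groups.
    """
    peaks = [p for p in map(str, motif_peaks)]
    if not peaks:
        raise ValueError("empty motif peak set")
    missing = set(peaks) - set(normalized.index.astype(str))
    if missing:
        raise ValueError(f"motif peaks absent from matrix: {sorted(missing)[:5]}")
    groups = sample_groups.loc[normalized.columns]
    if groups.nunique() < 2:
        raise ValueError("z-score undefined with a single group")
    med = {}
    for g, cols in groups.groupby(groups).groups.items():
        med[g] = float(normalized.loc[peaks, list(cols)].mean(axis=1).median())
    s = pd.Series(med).sort_index()
    sd = s.std(ddof=0)
    if sd == 0:
        return s * 0.0
    return (s - s.mean()) / sd
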