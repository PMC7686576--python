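"""Consensus peak atlas construction and insertion counting.

Per-sample ATAC peak calls (BED, 0-based half-open) are pooled into a single
consensus atlas: a candidate peak is retained when peaks from at least
``min_samples`` distinct samples overlap it by >= 1 bp, and retained peaks are
then merged to a fixed point whenever their overlap covers at least
``merge_frac`` of the shorter peak.  Tn5 insertion events (single-base
positions) are afterwards counted per atlas peak per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class BedParseError(ValueError):
    """A BED line that violates the interval contract (start < end, integers)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakAtlas:
    """Ordered consensus peaks with stable ids and per-peak sample support."""

    intervals: list[GenomicInterval]
    support: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.support:
            self.support = [0] * len(self.intervals)
        if len(self.support) != len(self.intervals):
            raise ValueError("support length must match intervals")

    @property
    def peak_ids(self) -> list[str]:
        return [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.intervals]

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "peak_id": self.peak_ids,
                "support": self.support,
            }
        )

    def to_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakAtlas":
        ivs = [
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
        support = [int(x) for x in df["support"]] if "support" in df else []
        return cls(ivs, support)

    @classmethod
    def from_bed(cls, path) -> "PeakAtlas":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "peak_id", "support"],
        )
        return cls.from_frame(df)


def read_peak_beds(
    paths: Sequence, sample_ids: Sequence[str] | None = None
) -> dict[str, list[GenomicInterval]]:
    """Read one BED3+ file per sample into sorted interval lists.

    Extra columns beyond the first three are ignored.  Malformed coordinates
    raise :class:`BedParseError` naming the offending line.
    """
    if sample_ids is None:
        sample_ids = [str(p) for p in paths]
    if len(sample_ids) != len(paths):
        raise ValueError("sample_ids must match paths")
    out: dict[str, list[GenomicInterval]] = {}
    for sid, path in zip(sample_ids, paths):
        ivs: list[GenomicInterval] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                if start < 0 or start >= end:
                    raise BedParseError(
                        f"{path}:{lineno}: invalid interval start={start} end={end}"
                    )
                ivs.append(GenomicInterval(chrom, start, end))
        out[sid] = sorted(ivs)
    return out


def _union_merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge strictly overlapping (>=1 bp) intervals; touching ones stay apart."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out.pop()
            iv = GenomicInterval(iv.chrom, prev.start, max(prev.end, iv.end))
        out.append(iv)
    return out


def _merge_fixed_point(
    intervals: list[GenomicInterval], merge_frac: float
) -> list[GenomicInterval]:
    """Union intervals overlapping >= merge_frac of the shorter, to a fixed point.

    Deterministic rule: repeatedly merge the leftmost qualifying pair in sorted
    order.  The result is independent of the input order because the scan is
    over the sorted list.
    """
    ivs = sorted(intervals)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(ivs):
            j = i + 1
            # merging extends ends only, so sorted-by-start order is preserved
            while j < len(ivs) and ivs[j].chrom == ivs[i].chrom and ivs[j].start < ivs[i].end:
                ov = ivs[i].overlap(ivs[j])
                if ov >= merge_frac * min(len(ivs[i]), len(ivs[j])):
                    ivs[i] = GenomicInterval(
                        ivs[i].chrom, ivs[i].start, max(ivs[i].end, ivs[j].end)
                    )
                    del ivs[j]
                    changed = True
                else:
                    j += 1
            i += 1
    return ivs


def _split_residual_overlaps(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Resolve overlaps below the merge threshold by splitting at the overlap midpoint."""
    ivs = sorted(ivs)
    out: list[GenomicInterval] = []
    for iv in ivs:
        while out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out.pop()
            mid = (iv.start + min(prev.end, iv.end)) // 2
            # degenerate containment: keep the union instead of zero-length pieces
            if mid <= prev.start or mid >= iv.end:
                iv = GenomicInterval(iv.chrom, prev.start, max(prev.end, iv.end))
            else:
                out.append(GenomicInterval(prev.chrom, prev.start, mid))
                iv = GenomicInterval(iv.chrom, mid, max(prev.end, iv.end))
        out.append(iv)
    return out


def _support(
    intervals: Sequence[GenomicInterval],
    peaksets: Mapping[str, Sequence[GenomicInterval]],
) -> list[int]:
    """Number of distinct samples with >=1 bp overlap per interval."""
    counts = np.zeros(len(intervals), dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for idx, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append(idx)
    iv_starts = np.array([iv.start for iv in intervals], dtype=np.int64) \
        if intervals else np.empty(0, dtype=np.int64)
    iv_ends = np.array([iv.end for iv in intervals], dtype=np.int64) \
        if intervals else np.empty(0, dtype=np.int64)
    for sample_ivs in peaksets.values():
        for chrom in {iv.chrom for iv in sample_ivs}:
            if chrom not in by_chrom:
                continue
            sub = sorted(iv for iv in sample_ivs if iv.chrom == chrom)
            s_starts = np.array([iv.start for iv in sub], dtype=np.int64)
            s_ends = np.array([iv.end for iv in sub], dtype=np.int64)
            rows = np.array(by_chrom[chrom])
            lo = np.searchsorted(s_ends, iv_starts[rows], side="right")
            hi = np.searchsorted(s_starts, iv_ends[rows], side="left")
            counts[rows] += hi > lo
    return counts.tolist()


def build_consensus(
    peaksets: Mapping[str, Sequence[GenomicInterval]],
    min_samples: int = 2,
    merge_frac: float = 0.5,
) -> PeakAtlas:
    """Build the consensus atlas from per-sample peak calls.

    Candidates are the pooled per-sample peaks (pre-merged at any-overlap
    within each sample); a candidate is shared when >= ``min_samples`` distinct
    samples overlap it by at least one base.  Shared candidates are merged to a
    fixed point whenever the pairwise overlap is >= ``merge_frac`` of the
    shorter peak; overlaps below the threshold are resolved by splitting at the
    overlap midpoint so the final atlas is non-overlapping.  Support is
    recomputed on the final intervals and pieces falling below ``min_samples``
    are dropped.
    """
    if not peaksets:
        raise ValueError("no peak sets supplied")
    if min_samples > len(peaksets):
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({len(peaksets)})"
        )
    premerged = {sid: _union_merge(ivs) for sid, ivs in peaksets.items()}
    candidates = [iv for ivs in premerged.values() for iv in ivs]
    if not candidates:
        raise ValueError("all peak sets are empty")
    supp = _support(candidates, premerged)
    retained = [iv for iv, s in zip(candidates, supp) if s >= min_samples]
    merged = _merge_fixed_point(retained, merge_frac)
    final = _split_residual_overlaps(merged)
    final_supp = _support(final, premerged)
    keep = [(iv, s) for iv, s in zip(final, final_supp) if s >= min_samples]
    if not keep:
        return PeakAtlas([], [])
    ivs, ss = zip(*keep)
    return PeakAtlas(list(ivs), list(ss))


def count_insertions(
    insertions: Mapping[str, pd.DataFrame | np.ndarray],
    atlas: PeakAtlas,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Count single-base insertion events per atlas peak per sample.

    ``insertions`` maps sample id to either a DataFrame with ``chrom``/``pos``
    columns or, when all positions live on one chromosome (pass ``chrom``), a
    bare position array.  An insertion at position p is assigned to the unique
    atlas peak with start <= p < end; positions outside all peaks are ignored
    and positions on unknown chromosomes are skipped with a warning.
    """
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    frame = atlas.to_frame()
    frame["row"] = np.arange(len(frame))
    for c, sub in frame.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        per_chrom[str(c)] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["row"].to_numpy(),
        )
    mat = np.zeros((len(atlas), len(insertions)), dtype=np.int64)
    n_skipped = 0
    for col, (sid, ins) in enumerate(insertions.items()):
        if isinstance(ins, pd.DataFrame):
            groups = [(str(c), g["pos"].to_numpy()) for c, g in ins.groupby("chrom")]
        else:
            if chrom is None:
                raise ValueError("bare position arrays require the chrom argument")
            groups = [(chrom, np.asarray(ins))]
        for c, pos in groups:
            if c not in per_chrom:
                n_skipped += len(pos)
                logger.warning(
                    "sample %s: %d insertions on unknown chromosome %s skipped",
                    sid, len(pos), c,
                )
                continue
            starts, ends, rows = per_chrom[c]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            ok[ok] &= pos[ok] < ends[idx[ok]]
            np.add.at(mat[:, col], rows[idx[ok]], 1)
    out = pd.DataFrame(mat, index=atlas.peak_ids, columns=list(insertions))
    out.attrs["n_skipped_unknown_chrom"] = n_skipped
    return out
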