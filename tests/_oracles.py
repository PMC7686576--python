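"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's data structures and algorithms: the
consensus oracle is a naive all-pairs fixed-point merge, the hypergeometric
oracle enumerates subsets, and the BH oracle follows the step-up definition
literally.
"""

from __future__ import annotations

import itertools
from math import comb


def _overlap(a: tuple, b: tuple) -> int:
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def _merge_any_overlap(ivs: list[tuple]) -> list[tuple]:
    out: list[tuple] = []
    for iv in sorted(ivs):
        if out and out[-1][0] == iv[0] and iv[1] < out[-1][2]:
            prev = out.pop()
            iv = (iv[0], prev[1], max(prev[2], iv[2]))
        out.append(iv)
    return out


def consensus_oracle(
    peaksets: dict[str, list[tuple]], min_samples: int = 2, merge_frac: float = 0.5
) -> list[tuple]:
    """All-pairs reference implementation of consensus atlas construction.

    Semantics: per-sample any-overlap pre-merge; pooled candidates retained
    when >= min_samples distinct samples overlap them by >= 1 bp; repeated
    merge of the leftmost qualifying pair (overlap >= merge_frac of the
    shorter); residual overlaps split at the overlap midpoint; support
    recomputed and low-support pieces dropped.  Returns (chrom, start, end,
    support) tuples sorted by position.
    """
    premerged = {sid: _merge_any_overlap(ivs) for sid, ivs in peaksets.items()}

    def support_of(iv: tuple) -> int:
        return sum(
            any(_overlap(iv, other) > 0 for other in ivs)
            for ivs in premerged.values()
        )

    candidates = sorted(iv for ivs in premerged.values() for iv in ivs)
    retained = [iv for iv in candidates if support_of(iv) >= min_samples]

    # fixed point of the documented left-to-right sweep: for each interval in
    # sorted order, absorb every qualifying overlapping successor; repeat the
    # whole pass until nothing changes
    changed = True
    while changed:
        changed = False
        retained.sort()
        i = 0
        while i < len(retained):
            j = i + 1
            while j < len(retained):
                a, b = retained[i], retained[j]
                ov = _overlap(a, b)
                if ov > 0 and ov >= merge_frac * min(a[2] - a[1], b[2] - b[1]):
                    retained[i] = (a[0], min(a[1], b[1]), max(a[2], b[2]))
                    del retained[j]
                    changed = True
                else:
                    j += 1
            i += 1

    # residual sub-threshold overlaps: split at the overlap midpoint, left to right
    retained.sort()
    out: list[tuple] = []
    for iv in retained:
        while out and out[-1][0] == iv[0] and iv[1] < out[-1][2]:
            prev = out.pop()
            mid = (iv[1] + min(prev[2], iv[2])) // 2
            if mid <= prev[1] or mid >= iv[2]:
                iv = (iv[0], prev[1], max(prev[2], iv[2]))
            else:
                out.append((prev[0], prev[1], mid))
                iv = (iv[0], mid, max(prev[2], iv[2]))
        out.append(iv)

    return [(c, s, e, support_of((c, s, e)))
            for c, s, e in out if support_of((c, s, e)) >= min_samples]


def hypergeom_tail_oracle(k: int, N: int, n: int, K: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, n marked, K drawn), exactly."""
    total = comb(N, K)
    acc = 0
    for x in range(k, min(n, K) + 1):
        if N - n >= K - x:
            acc += comb(n, x) * comb(N - n, K - x)
    return acc / total


def hypergeom_enumeration_oracle(k: int, universe: int, marked: set, draw: int) -> float:
    """Enumerate all foreground choices of a small universe; P(overlap >= k)."""
    items = list(range(universe))
    hits = 0
    total = 0
    for fg in itertools.combinations(items, draw):
        total += 1
        if len(set(fg) & marked) >= k:
            hits += 1
    return hits / total


def bh_oracle(pvals: list[float]) -> list[float]:
    """Literal step-up definition of Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = min(val, 1.0)
        prev = val
    return adj
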