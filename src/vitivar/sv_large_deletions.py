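"""Large-deletion calling from discordant, uniquely mapped read pairs.

A pair whose mapped distance falls in [10 kb, 1 Mb] is incompatible with
the sequencing insert and taken as evidence of a deletion spanning its
inner gap.  Multi-mapping pairs are removed first, so duplicated regions
within a chromosome cannot masquerade as deletions.  Pairs are clustered
by single-linkage on their implied deleted intervals and a call is
emitted for every cluster with at least three supporting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from vitivar.io_formats import AlignedPair


@dataclass
class DeletionCall:
    chrom: str
    start: int
    end: int
    support: int
    pair_ids: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def bed_name(self) -> str:
        return "LDEL"


def _implied_interval(
    pair: AlignedPair, insert_mean: float, read_len: int
) -> tuple[int, int] | None:
    """Deleted interval a discordant pair implies.

    The fragment covers [pos1, pos2 + read_len) on the reference but only
    ≈ insert_mean bp of sample sequence, so the deletion lies inside
    [pos1 + read_len, pos2] shrunk by the expected insert at the right edge.
    """
    start = pair.pos1 + read_len
    end = pair.pos2 - int(insert_mean)
    if end <= start:
        return None
    return start, end


def find_large_deletions(
    pairs: Iterable[AlignedPair],
    min_dist: int = 10_000,
    max_dist: int = 1_000_000,
    min_support: int = 3,
    insert_mean: float = 500.0,
    read_len: int = 100,
) -> list[DeletionCall]:
    """Cluster discordant unique pairs into deletion calls.

    Discordant = unique and mapped distance within [min_dist, max_dist].
    Clusters are single-linkage chains of pairs whose implied deleted
    intervals overlap; a cluster of ≥ ``min_support`` pairs yields a call
    whose interval is the intersection of the implied intervals (median
    endpoints as fallback if, after trimming, the intersection is empty).
    """
    if max_dist <= min_dist:
        raise ValueError("max_dist must exceed min_dist")
    candidates: list[tuple[str, int, int, int]] = []  # chrom, start, end, pair_id
    for idx, pair in enumerate(pairs):
        if not pair.unique:
            continue
        if not min_dist <= pair.distance <= max_dist:
            continue
        implied = _implied_interval(pair, insert_mean, read_len)
        if implied is None:
            continue
        candidates.append((pair.chrom, implied[0], implied[1], idx))
    candidates.sort()

    calls: list[DeletionCall] = []
    cluster: list[tuple[str, int, int, int]] = []
    reach = -1
    for cand in candidates:
        chrom, start, end, _idx = cand
        if cluster and (chrom != cluster[0][0] or start > reach):
            _emit(cluster, min_support, calls)
            cluster = []
            reach = -1
        cluster.append(cand)
        reach = max(reach, end)
    if cluster:
        _emit(cluster, min_support, calls)
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def _emit(
    cluster: Sequence[tuple[str, int, int, int]],
    min_support: int,
    calls: list[DeletionCall],
) -> None:
    if len(cluster) < min_support:
        return
    chrom = cluster[0][0]
    starts = np.array([c[1] for c in cluster])
    ends = np.array([c[2] for c in cluster])
    lo, hi = int(starts.max()), int(ends.min())
    if hi <= lo:
        lo, hi = int(np.median(starts)), int(np.median(ends))
        if hi <= lo:
            return
    calls.append(
        DeletionCall(
            chrom=chrom,
            start=lo,
            end=hi,
            support=len(cluster),
            pair_ids=[c[3] for c in cluster],
        )
    )
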