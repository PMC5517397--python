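"""Runs of homozygosity (ROH) from genotyped SNPs.

A window of 500 consecutive SNPs slides one SNP at a time; a window is
homozygous when it contains at most one heterozygous-or-missing call.
Each SNP is scored by the fraction of windows spanning it that are
homozygous, and maximal runs of high-scoring SNPs at least 50 kb long
become ROH regions.  Because hemizygous deletions mimic homozygosity in
genotype data, ROHs overlapping coverage-loss segments are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from vitivar.variant_calling import VariantCall


@dataclass
class ROHRegion:
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int
    excluded: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def snp_density(self) -> float:
        return self.n_snps / self.length if self.length else 0.0

    @property
    def bed_name(self) -> str:
        return "ROH"


def snp_scores(
    het: np.ndarray, window_snps: int, max_het_per_window: int
) -> np.ndarray:
    """Per-SNP fraction of spanning windows that are homozygous.

    ``het`` is a boolean array (heterozygous-or-missing) over SNPs in
    position order.  Windows are every run of ``window_snps`` consecutive
    SNPs; a window is homozygous iff it holds ≤ ``max_het_per_window``
    flagged SNPs.
    """
    m = het.shape[0]
    w = window_snps
    if m < w:
        raise ValueError("fewer SNPs than window size")
    cs = np.concatenate(([0], np.cumsum(het.astype(np.int64))))
    win_het = cs[w:] - cs[:-w]  # window starting at index 0..m-w
    hom = (win_het <= max_het_per_window).astype(np.int64)
    hcs = np.concatenate(([0], np.cumsum(hom)))
    idx = np.arange(m)
    lo = np.maximum(idx - w + 1, 0)
    hi = np.minimum(idx, m - w)
    return (hcs[hi + 1] - hcs[lo]) / (hi - lo + 1)


def find_roh(
    calls: Sequence[VariantCall],
    window_snps: int = 500,
    max_het_per_window: int = 1,
    min_length: int = 50_000,
    hit_fraction: float = 0.05,
    missing_positions: Mapping[str, Iterable[int]] | None = None,
) -> list[ROHRegion]:
    """Scan genotyped SNPs for runs of homozygosity.

    SNPs with score ≥ ``hit_fraction`` form candidate runs (the scanning
    tool's documented semantics: a SNP qualifies when at least that
    fraction of the windows spanning it is homozygous); maximal runs
    spanning at least ``min_length`` bp are emitted with boundaries at
    their first/last SNP.  ``missing_positions`` (per chromosome)
    optionally marks cohort-genotyped sites uncallable in this sample;
    they count toward the per-window heterozygous-or-missing allowance.
    Chromosomes with fewer SNPs than the window are skipped.
    """
    import warnings

    by_chrom: dict[str, dict[int, bool]] = {}
    for c in calls:
        if c.kind != "SNP":
            continue
        sites = by_chrom.setdefault(c.chrom, {})
        # duplicate positions deduplicate; het wins (conservative)
        sites[c.pos] = sites.get(c.pos, False) or c.zygosity == "het"
    if missing_positions:
        for chrom, poss in missing_positions.items():
            sites = by_chrom.setdefault(chrom, {})
            for p in poss:
                sites[p] = True

    regions: list[ROHRegion] = []
    for chrom in sorted(by_chrom):
        sites = by_chrom[chrom]
        if len(sites) < window_snps:
            warnings.warn(
                f"{chrom}: {len(sites)} SNPs < window of {window_snps}, skipped",
                stacklevel=2,
            )
            continue
        positions = np.array(sorted(sites))
        het = np.array([sites[p] for p in positions.tolist()])
        scores = snp_scores(het, window_snps, max_het_per_window)
        good = scores >= hit_fraction
        # maximal runs of qualifying SNPs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], good.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            start = int(positions[a])
            end = int(positions[b - 1]) + 1
            if end - start >= min_length:
                regions.append(
                    ROHRegion(
                        chrom=chrom,
                        start=start,
                        end=end,
                        n_snps=int(b - a),
                        n_het=int(het[a:b].sum()),
                    )
                )
    return regions


def exclude_loss_overlap(
    rohs: Sequence[ROHRegion], losses: Sequence
) -> tuple[list[ROHRegion], list[ROHRegion]]:
    """Partition ROHs by overlap with loss/PAV segments.

    Any ROH sharing at least 1 bp with a loss is excluded (it may reflect
    hemizygosity rather than true homozygosity).  Returns (kept, excluded);
    excluded regions are flagged, not silently dropped.
    """
    loss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in losses:
        loss_by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    kept, dropped = [], []
    for roh in rohs:
        hit = any(
            roh.start < e and s < roh.end
            for s, e in loss_by_chrom.get(roh.chrom, [])
        )
        roh.excluded = hit
        (dropped if hit else kept).append(roh)
    return kept, dropped


def roh_summary(rohs_per_sample: Mapping[str, Sequence[ROHRegion]]) -> pd.DataFrame:
    """Per-sample ROH statistics with a private/shared partition.

    A region is private when it overlaps no ROH of any other sample;
    bp-level private totals come from exact interval subtraction.  Mean
    length is total bp divided by region count.
    """
    samples = list(rohs_per_sample)
    merged = {
        s: _merge([(r.chrom, r.start, r.end) for r in rohs_per_sample[s]])
        for s in samples
    }
    rows = []
    for s in samples:
        regs = list(rohs_per_sample[s])
        others = _merge(
            [iv for o in samples if o != s for iv in merged[o]]
        )
        private_regs = [
            r for r in regs if not _overlaps_any(r.chrom, r.start, r.end, others)
        ]
        private_bp = sum(
            _subtract_bp(chrom, s0, e0, others)
            for chrom, s0, e0 in merged[s]
        )
        rows.append(
            {
                "sample": s,
                "n_roh": len(regs),
                "total_bp": sum(r.length for r in regs),
                "mean_length": (
                    sum(r.length for r in regs) / len(regs) if regs else 0.0
                ),
                "mean_snp_density": (
                    float(np.mean([r.snp_density for r in regs])) if regs else 0.0
                ),
                "n_private": len(private_regs),
                "private_total_bp": sum(r.length for r in private_regs),
                "private_mean_length": (
                    sum(r.length for r in private_regs) / len(private_regs)
                    if private_regs
                    else 0.0
                ),
                "private_bp_exclusive": private_bp,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def _merge(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def _overlaps_any(
    chrom: str, start: int, end: int, merged: Sequence[tuple[str, int, int]]
) -> bool:
    return any(c == chrom and start < e and s < end for c, s, e in merged)


def _subtract_bp(
    chrom: str, start: int, end: int, merged: Sequence[tuple[str, int, int]]
) -> int:
    covered = 0
    for c, s, e in merged:
        if c == chrom:
            lo, hi = max(start, s), min(end, e)
            if lo < hi:
                covered += hi - lo
    return (end - start) - covered
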