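"""Cross-sample summary statistics.

The arithmetic behind the per-cultivar polymorphism tables: het/hom
ratios, per-Mbp densities over covered reference bases, delta-GC at SNP
sites, shared/private partitions of interval sets (CNVs, large
deletions, ROHs) at region and bp level, and the normalized 20-kb
genome-wide visualization track.  Printed-table emulation rounds
half-up at one decimal.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from vitivar.io_formats import PileupTrack
from vitivar.variant_calling import VariantCall

Interval = tuple[str, int, int]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (what printed tables use), not banker's."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def het_hom_ratio(n_het: int, n_hom: int, ndigits: int | None = 1) -> float:
    """Heterozygous/homozygous count ratio; one decimal by default.

    ``ndigits=None`` returns the raw ratio.
    """
    if n_hom <= 0:
        raise ValueError("n_hom must be positive")
    ratio = n_het / n_hom
    return ratio if ndigits is None else round_half_up(ratio, ndigits)


def density_per_mbp(count: int, covered: int, ndigits: int | None = 1) -> float:
    """Events per megabase of covered reference sequence."""
    if covered <= 0:
        raise ValueError("covered bases must be positive")
    density = 1e6 * count / covered
    return density if ndigits is None else round_half_up(density, ndigits)


def private_fraction(total_bp: int, private_bp: int, ndigits: int | None = 1) -> float:
    """Percentage of a sample's total called bp that is private to it."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    if not 0 <= private_bp <= total_bp:
        raise ValueError("require 0 <= private_bp <= total_bp")
    pct = 100.0 * private_bp / total_bp
    return pct if ndigits is None else round_half_up(pct, ndigits)


def delta_gc(calls: Sequence[VariantCall]) -> float:
    """GC shift introduced by SNP alternate alleles, in percentage points.

    100 × [fraction of alt alleles in {G,C} − fraction of ref alleles in
    {G,C}] over all SNP sites.  Positive values mean the sample is more
    GC-rich than the reference at its polymorphic sites.
    """
    snps = [c for c in calls if c.kind == "SNP"]
    if not snps:
        raise ValueError("no SNP calls")
    alt_gc = sum(1 for c in snps if c.alt_allele in "GC")
    ref_gc = sum(1 for c in snps if c.ref_allele in "GC")
    return 100.0 * (alt_gc - ref_gc) / len(snps)


# ---------------------------------------------------------------------------
# shared / private interval partition
# ---------------------------------------------------------------------------


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def _overlap_bp(a: Interval, merged: Sequence[Interval]) -> int:
    chrom, start, end = a
    total = 0
    for c, s, e in merged:
        if c == chrom:
            lo, hi = max(start, s), min(end, e)
            if lo < hi:
                total += hi - lo
    return total


def shared_private_partition(
    sets: Mapping[str, Sequence[Interval]],
    reciprocal: float = 0.0,
) -> dict:
    """Region- and bp-level sharing across samples.

    A region of sample A is shared with sample B when it overlaps a region
    of B (any overlap by default; ``reciprocal`` requires that fraction of
    reciprocal overlap).  Region labels are private (one sample),
    common-to-all, or shared-by-k; percentages are over all regions of all
    samples.  The bp-level partition is exact interval algebra on the
    merged per-sample sets and conserves each sample's merged total.
    """
    samples = list(sets)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    merged = {s: _merge(sets[s]) for s in samples}

    labels: dict[str, list[tuple[Interval, int]]] = {}
    n_regions = 0
    n_private = 0
    n_common = 0
    for s in samples:
        rows = []
        for region in sets[s]:
            sharers = 1
            for other in samples:
                if other == s:
                    continue
                if _shares(region, merged[other], reciprocal):
                    sharers += 1
            rows.append((region, sharers))
            n_regions += 1
            if sharers == 1:
                n_private += 1
            if sharers == len(samples):
                n_common += 1
        labels[s] = rows

    bp = {}
    for s in samples:
        others = _merge([iv for o in samples if o != s for iv in merged[o]])
        total = sum(e - st for _c, st, e in merged[s])
        shared = sum(_overlap_bp(iv, others) for iv in merged[s])
        bp[s] = {"total_bp": total, "shared_bp": shared, "private_bp": total - shared}

    return {
        "labels": labels,
        "n_regions": n_regions,
        "n_private": n_private,
        "n_common_to_all": n_common,
        "pct_private": 100.0 * n_private / n_regions if n_regions else 0.0,
        "pct_common_to_all": 100.0 * n_common / n_regions if n_regions else 0.0,
        "bp": bp,
    }


def _shares(region: Interval, merged_other: Sequence[Interval], reciprocal: float) -> bool:
    chrom, start, end = region
    length = end - start
    for c, s, e in merged_other:
        if c != chrom:
            continue
        lo, hi = max(start, s), min(end, e)
        if lo >= hi:
            continue
        if reciprocal <= 0.0:
            return True
        if (hi - lo) >= reciprocal * length and (hi - lo) >= reciprocal * (e - s):
            return True
    return False


# ---------------------------------------------------------------------------
# cohort table and genome track
# ---------------------------------------------------------------------------


def cohort_table(samples: Mapping[str, Mapping[str, object]]) -> pd.DataFrame:
    """Polymorphism-statistics table from per-sample raw counts.

    Each sample supplies ``covered_bases``, ``n_hom_snps``, ``n_het_snps``,
    ``n_hom_indels``, ``n_het_indels`` and optionally ``snp_calls`` (for
    delta-GC).  Every printed cell is recomputed from those raw counts
    (self-consistency by construction).
    """
    rows = []
    for name, d in samples.items():
        covered = int(d["covered_bases"])
        hom_s, het_s = int(d["n_hom_snps"]), int(d["n_het_snps"])
        hom_i, het_i = int(d.get("n_hom_indels", 0)), int(d.get("n_het_indels", 0))
        row = {
            "sample": name,
            "covered_bases": covered,
            "hom_snps": hom_s,
            "het_snps": het_s,
            "het_hom_snp_ratio": het_hom_ratio(het_s, hom_s) if hom_s else float("nan"),
            "snp_density": density_per_mbp(hom_s + het_s, covered),
            "hom_snp_density": density_per_mbp(hom_s, covered),
            "het_snp_density": density_per_mbp(het_s, covered),
            "hom_indels": hom_i,
            "het_indels": het_i,
            "het_hom_indel_ratio": (
                het_hom_ratio(het_i, hom_i) if hom_i else float("nan")
            ),
            "indel_density": density_per_mbp(hom_i + het_i, covered),
        }
        if d.get("snp_calls"):
            row["delta_gc"] = round_half_up(delta_gc(d["snp_calls"]), 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def genome_track(
    tracks: Mapping[str, PileupTrack] | PileupTrack,
    window: int = 20_000,
) -> pd.DataFrame:
    """Windowed coverage track normalized to the genome average.

    Adjacent ``window``-bp windows; the per-window value is the mean depth
    over covered (depth > 0) positions, divided by the genome-wide mean
    over covered positions.  Uncovered windows get value 0.  The output is
    a tidy frame suitable for circular-plot tooling.
    """
    if isinstance(tracks, PileupTrack):
        tracks = {tracks.chrom: tracks}
    total = 0.0
    n_cov = 0
    for t in tracks.values():
        covered = t.depth[t.depth > 0]
        total += float(covered.sum())
        n_cov += covered.size
    if n_cov == 0:
        raise ValueError("no covered positions")
    genome_mean = total / n_cov
    rows = []
    for chrom, t in tracks.items():
        depth = t.depth.astype(np.float64)
        length = depth.shape[0]
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        sums = np.add.reduceat(depth, starts)
        counts = np.add.reduceat((depth > 0).astype(np.float64), starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        for s, e, v, c in zip(starts, ends, means, counts):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(e),
                    "value": float(v) / genome_mean,
                    "covered_bases": int(c),
                }
            )
    return pd.DataFrame(rows)
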