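"""SNP and small-indel calling from a unique-read pileup.

The caller is deliberately threshold-based.  A site yields a call only
when, jointly:

* depth ≥ genome-average coverage (computed over covered positions),
* the alternate allele is supported by at least half that average,
* alternate allele frequency ≥ 0.2 (screens residual somatic mosaicism),
* a one-sided exact binomial test rejects the sequencing-error explanation
  at p ≤ 0.05,
* depth does not exceed mean + 6·SD (collapsed-repeat guard).

Each filter can be toggled off independently; the call set is the pure
conjunction of the active filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from vitivar.io_formats import PileupTrack

#: depth below which a position does not count as covered at all
MIN_COVERED_DEPTH = 3


@dataclass
class CoverageStats:
    """Genome-average depth over covered (depth ≥ 3) positions."""

    mean: float
    sd: float
    covered_bases: int


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 0-based; indels anchored to the preceding base
    ref_allele: str
    alt_allele: str
    kind: str  # SNP | insertion | deletion
    zygosity: str  # hom | het
    depth: int
    alt_count: int
    p_value: float = 1.0

    @property
    def allele_freq(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def is_indel(self) -> bool:
        return self.kind != "SNP"


def coverage_stats(pileup: Mapping[str, PileupTrack] | PileupTrack) -> CoverageStats:
    """Mean/SD of depth over positions covered by at least 3 reads."""
    tracks = [pileup] if isinstance(pileup, PileupTrack) else list(pileup.values())
    if not tracks:
        raise ValueError("empty pileup")
    total = 0
    total_sq = 0.0
    n = 0
    for track in tracks:
        depth = track.depth
        covered = depth[depth >= MIN_COVERED_DEPTH].astype(np.float64)
        total += covered.sum()
        total_sq += np.square(covered).sum()
        n += covered.size
    if n == 0:
        raise ValueError("no position covered by >= 3 reads")
    mean = total / n
    var = max(total_sq / n - mean * mean, 0.0)
    return CoverageStats(mean=float(mean), sd=float(np.sqrt(var)), covered_bases=n)


def variant_significance(ref_count: int, alt_count: int, error_rate: float = 0.01,
                         method: str = "binomial") -> float:
    """P-value that ``alt_count`` observations arose from sequencing error.

    One-sided exact binomial tail P[X ≥ alt_count | n = ref+alt, p = error]
    by default; ``method='fisher'`` runs a one-sided Fisher exact test of
    the observed counts against the expected error split instead.
    """
    if ref_count < 0 or alt_count < 0 or (ref_count == 0 and alt_count == 0):
        raise ValueError("counts must be non-negative and not both zero")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    depth = ref_count + alt_count
    if alt_count == 0:
        return 1.0
    if method == "binomial":
        return float(stats.binom.sf(alt_count - 1, depth, error_rate))
    if method == "fisher":
        expected_alt = int(round(depth * error_rate))
        table = [[alt_count, ref_count], [expected_alt, depth - expected_alt]]
        return float(stats.fisher_exact(table, alternative="greater")[1])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CallingParams:
    """Filter thresholds; every filter is independently toggleable."""

    error_rate: float = 0.01
    p_cutoff: float = 0.05
    min_allele_freq: float = 0.2
    hom_threshold: float = 0.75
    excess_depth_sds: float = 6.0
    support_base: str = "mean"  # 'mean' or 'site': denominator of the support rule
    use_depth_filter: bool = True
    use_support_filter: bool = True
    use_freq_filter: bool = True
    use_significance_filter: bool = True
    use_excess_depth_filter: bool = True
    significance_method: str = "binomial"


def call_variants(
    pileup: Mapping[str, PileupTrack] | PileupTrack,
    stats_: CoverageStats,
    params: CallingParams | None = None,
    ref: Mapping[str, "object"] | None = None,
) -> list[VariantCall]:
    """Emit SNP/indel calls passing the conjunction of active filters.

    ``ref`` (assembly mapping) supplies reference alleles for VCF-style
    output; without it the reference allele is reported as ``N``.
    Multi-allelic sites keep only the most-supported alternate allele.
    """
    params = params or CallingParams()
    tracks = [pileup] if isinstance(pileup, PileupTrack) else list(pileup.values())
    calls: list[VariantCall] = []
    for track in tracks:
        ref_seq = ref[track.chrom].seq if ref is not None else None
        for pos in sorted(track.alleles):
            obs = track.alleles[pos]
            allele, alt_count = max(obs.items(), key=lambda kv: (kv[1], kv[0]))
            depth = int(track.depth[pos])
            if depth == 0:
                continue
            if params.use_depth_filter and depth < stats_.mean:
                continue
            support_floor = (
                stats_.mean / 2.0 if params.support_base == "mean" else depth / 2.0
            )
            if params.use_support_filter and alt_count < support_floor:
                continue
            freq = alt_count / depth
            if params.use_freq_filter and freq < params.min_allele_freq:
                continue
            if params.use_excess_depth_filter and depth > stats_.mean + params.excess_depth_sds * stats_.sd:
                continue
            p_value = variant_significance(
                depth - alt_count, alt_count, params.error_rate,
                method=params.significance_method,
            )
            if params.use_significance_filter and p_value > params.p_cutoff:
                continue
            zygosity = "hom" if freq >= params.hom_threshold else "het"
            ref_base = ref_seq[pos] if ref_seq else "N"
            if allele.startswith("+"):
                kind = "insertion"
                ref_allele, alt_allele = ref_base, ref_base + allele[1:]
            elif allele.startswith("-"):
                kind = "deletion"
                ref_allele, alt_allele = ref_base + allele[1:], ref_base
            else:
                kind = "SNP"
                ref_allele, alt_allele = ref_base, allele
            calls.append(
                VariantCall(
                    chrom=track.chrom,
                    pos=pos,
                    ref_allele=ref_allele,
                    alt_allele=alt_allele,
                    kind=kind,
                    zygosity=zygosity,
                    depth=depth,
                    alt_count=alt_count,
                    p_value=p_value,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls
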