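"""Synthetic diploid genomes with fully known implanted variation.

The generator emulates what the pipeline sees in a real resequencing
experiment — a diploid sample diverged from a haploid reference by
homozygous/heterozygous SNPs and small indels, implanted copy-number
segments, large deletions and forced-homozygosity blocks — rendered as
noisy pileup tracks and aligned read-pair records.  Every implanted
event is recorded in a :class:`TruthSet`, the parameter-recovery oracle
for the downstream callers.

Depth is modelled positionally: per-position read depth is Poisson with
rate ``coverage × local copy number / 2`` summed over haplotypes, and
allele observations are binomial splits of that depth with symmetric
substitution errors.  No read-level FASTQ is produced; the pipeline's
filters act on counts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from vitivar.io_formats import AlignedPair, GenomeSequence, PileupTrack

_BASES = np.array(list("ACGT"))
_OTHER = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


# ---------------------------------------------------------------------------
# specification and truth types
# ---------------------------------------------------------------------------


@dataclass
class VariantSpec:
    """Implantation parameters for one synthetic diploid sample.

    Rates are per-bp event probabilities.  ``cnv_segments`` are
    (chrom, start, end, copy_number) with total copy number in {0,1,3,4};
    ``large_deletions`` are (chrom, start, end[, zygosity]) intervals
    (zygosity 'hom' by default); ``roh_blocks`` are intervals forced
    homozygous; ``repeat_regions`` mark intervals whose read pairs are
    emitted as multi-mapping (non-unique).
    """

    snp_rate_hom: float = 1e-3
    snp_rate_het: float = 2e-3
    indel_rate: float = 1e-4
    indel_max_len: int = 10
    cnv_segments: list[tuple] = field(default_factory=list)
    large_deletions: list[tuple] = field(default_factory=list)
    roh_blocks: list[tuple] = field(default_factory=list)
    repeat_regions: list[tuple] = field(default_factory=list)
    allow_overlap: bool = False
    seed: int = 0

    def validate(self, ref: Mapping[str, GenomeSequence]) -> None:
        for rate in (self.snp_rate_hom, self.snp_rate_het, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        for label, intervals in (
            ("cnv_segments", self.cnv_segments),
            ("large_deletions", self.large_deletions),
            ("roh_blocks", self.roh_blocks),
            ("repeat_regions", self.repeat_regions),
        ):
            for item in intervals:
                chrom, start, end = item[0], item[1], item[2]
                if chrom not in ref:
                    raise ValueError(f"{label}: unknown chromosome {chrom!r}")
                if not 0 <= start < end <= ref[chrom].length:
                    raise ValueError(f"{label}: interval ({start},{end}) out of bounds")
        if not self.allow_overlap:
            cnv = [(c, s, e) for c, s, e, *_ in self.cnv_segments]
            dele = [(c, s, e) for c, s, e, *_ in self.large_deletions]
            for c1, s1, e1 in cnv + dele:
                for c2, s2, e2 in self.roh_blocks:
                    if c1 == c2 and s1 < e2 and s2 < e1:
                        raise ValueError(
                            "cnv/deletion implant overlaps a roh_block; set "
                            "allow_overlap=True if intended"
                        )


@dataclass
class TruthSet:
    """Every implanted event, the oracle for parameter-recovery tests."""

    snps: list[tuple] = field(default_factory=list)  # (chrom, pos, ref, alt, zygosity)
    indels: list[tuple] = field(default_factory=list)  # (chrom, pos, ref, alt, kind, zygosity)
    cnv: list[tuple] = field(default_factory=list)  # (chrom, start, end, copy_number)
    deletions: list[tuple] = field(default_factory=list)  # (chrom, start, end, zygosity)
    rohs: list[tuple] = field(default_factory=list)  # (chrom, start, end)


@dataclass
class _ChromVariants:
    """Per-chromosome implanted small variants, split by carrier haplotype."""

    # pos -> (alt_base, zygosity, hap)  hap in {0,1}, ignored for hom
    snps: dict[int, tuple[str, str, int]] = field(default_factory=dict)
    # pos (anchor) -> (allele_key, zygosity, hap, length)
    indels: dict[int, tuple[str, str, int, int]] = field(default_factory=dict)


@dataclass
class DiploidSample:
    """A reference assembly plus implanted variation on two haplotypes."""

    ref: Mapping[str, GenomeSequence]
    variants: dict[str, _ChromVariants]
    cnv_segments: list[tuple]  # (chrom, start, end, copy_number)
    large_deletions: list[tuple]  # (chrom, start, end, zygosity)
    roh_blocks: list[tuple]
    repeat_regions: list[tuple]
    truth: TruthSet


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------


def simulate_reference(
    n_chrom: int, length: int, gc: float = 0.35, seed: int = 0
) -> dict[str, GenomeSequence]:
    """I.i.d. random assembly of ``n_chrom`` chromosomes of ``length`` bp.

    Base probabilities are symmetric within the AT and GC pairs, so the
    expected G+C fraction is exactly ``gc``.
    """
    if length < 10**5:
        raise ValueError("chromosome length must be >= 1e5")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for i in range(1, n_chrom + 1):
        name = f"chr{i}"
        seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
        out[name] = GenomeSequence(name, seq)
    return out


# ---------------------------------------------------------------------------
# variant implantation
# ---------------------------------------------------------------------------


def implant_variants(
    ref: Mapping[str, GenomeSequence], spec: VariantSpec
) -> tuple[DiploidSample, TruthSet]:
    """Place SNPs/indels/CNVs/deletions/ROH blocks; return sample + truth.

    Heterozygous SNPs differ between the two haplotypes (carrier chosen at
    random); homozygous SNPs are shared.  Inside ``roh_blocks`` every SNP
    is homozygous.  Small variants are never placed inside implanted
    large deletions or copy-0 segments (they would be unobservable).
    """
    spec.validate(ref)
    rng = np.random.default_rng(spec.seed)
    truth = TruthSet()
    variants: dict[str, _ChromVariants] = {}

    deletions = [
        (c, s, e, (rest[0] if rest else "hom"))
        for c, s, e, *rest in spec.large_deletions
    ]
    zero_cn = [(c, s, e) for c, s, e, cn in spec.cnv_segments if cn == 0]

    for chrom, gseq in ref.items():
        length = gseq.length
        seq = gseq.seq
        cv = _ChromVariants()
        variants[chrom] = cv

        blocked = _interval_mask(length, [
            (s, e) for c, s, e, _z in deletions if c == chrom
        ] + [(s, e) for c, s, e in zero_cn if c == chrom])
        roh_mask = _interval_mask(
            length, [(s, e) for c, s, e in spec.roh_blocks if c == chrom]
        )

        taken = set()

        def _place(n: int, allowed: np.ndarray) -> list[int]:
            candidates = np.flatnonzero(allowed)
            if candidates.size == 0 or n == 0:
                return []
            n = min(n, candidates.size)
            chosen = rng.choice(candidates, size=n, replace=False)
            out = [int(p) for p in chosen if p not in taken]
            taken.update(out)
            return out

        free = ~blocked
        # hom SNPs anywhere observable; het SNPs only outside ROH blocks
        n_hom = rng.poisson(spec.snp_rate_hom * length)
        for pos in _place(int(n_hom), free):
            ref_base = seq[pos]
            alt = _OTHER[ref_base][rng.integers(3)] if ref_base != "N" else "A"
            cv.snps[pos] = (alt, "hom", 0)
            truth.snps.append((chrom, pos, ref_base, alt, "hom"))
        n_het = rng.poisson(spec.snp_rate_het * length)
        for pos in _place(int(n_het), free & ~roh_mask):
            ref_base = seq[pos]
            alt = _OTHER[ref_base][rng.integers(3)] if ref_base != "N" else "A"
            hap = int(rng.integers(2))
            cv.snps[pos] = (alt, "het", hap)
            truth.snps.append((chrom, pos, ref_base, alt, "het"))
        # indels: half hom, half het (het only outside ROH blocks)
        n_indel = int(rng.poisson(spec.indel_rate * length))
        n_indel_hom = int(rng.binomial(n_indel, 0.5))
        for zyg, n in (("hom", n_indel_hom), ("het", n_indel - n_indel_hom)):
            allowed = free if zyg == "hom" else free & ~roh_mask
            for pos in _place(n, allowed):
                if pos + spec.indel_max_len + 1 >= length:
                    continue
                ilen = int(rng.integers(1, spec.indel_max_len + 1))
                hap = 0 if zyg == "hom" else int(rng.integers(2))
                anchor = seq[pos]
                if rng.random() < 0.5:  # insertion after pos
                    ins = "".join(_BASES[rng.integers(0, 4, size=ilen)])
                    cv.indels[pos] = ("+" + ins, zyg, hap, ilen)
                    truth.indels.append((chrom, pos, anchor, anchor + ins, "insertion", zyg))
                else:  # deletion of the ilen bases after pos
                    deleted = seq[pos + 1 : pos + 1 + ilen]
                    cv.indels[pos] = ("-" + deleted, zyg, hap, ilen)
                    truth.indels.append((chrom, pos, anchor + deleted, anchor, "deletion", zyg))

    truth.cnv = [(c, s, e, cn) for c, s, e, cn in spec.cnv_segments]
    truth.deletions = list(deletions)
    truth.rohs = [(c, s, e) for c, s, e in spec.roh_blocks]
    truth.snps.sort()
    truth.indels.sort()

    sample = DiploidSample(
        ref=ref,
        variants=variants,
        cnv_segments=truth.cnv,
        large_deletions=deletions,
        roh_blocks=truth.rohs,
        repeat_regions=[tuple(r) for r in spec.repeat_regions],
        truth=truth,
    )
    return sample, truth


def _interval_mask(length: int, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


# ---------------------------------------------------------------------------
# pileup simulation
# ---------------------------------------------------------------------------


def _haplotype_rates(sample: DiploidSample, chrom: str, coverage: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-position Poisson depth rate for each haplotype."""
    length = sample.ref[chrom].length
    lam0 = np.full(length, coverage / 2.0)
    lam1 = np.full(length, coverage / 2.0)
    for c, s, e, cn in sample.cnv_segments:
        if c != chrom:
            continue
        copies0 = (cn + 1) // 2  # extra copies ride haplotype 0
        copies1 = cn // 2
        lam0[s:e] = coverage / 2.0 * copies0
        lam1[s:e] = coverage / 2.0 * copies1
    for c, s, e, zyg in sample.large_deletions:
        if c != chrom:
            continue
        lam0[s:e] = 0.0
        if zyg == "hom":
            lam1[s:e] = 0.0
    # small implanted deletions shadow their span on the carrier haplotype
    cv = sample.variants[chrom]
    for pos, (allele, zyg, hap, ilen) in cv.indels.items():
        if allele.startswith("-"):
            span = slice(pos + 1, pos + 1 + ilen)
            if zyg == "hom":
                lam0[span] = 0.0
                lam1[span] = 0.0
            elif hap == 0:
                lam0[span] = 0.0
            else:
                lam1[span] = 0.0
    return lam0, lam1


def simulate_pileup(
    sample: DiploidSample,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
    source: str = "unique_reads",
) -> dict[str, PileupTrack]:
    """Render a sample as per-chromosome pileup tracks.

    Depth at each position is Poisson(coverage × copy/2) summed over the
    two haplotypes; allele observations are binomial splits with symmetric
    substitution errors at ``error_rate``.  Copy-0 regions get depth 0.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    tracks: dict[str, PileupTrack] = {}
    for chrom, gseq in sample.ref.items():
        length = gseq.length
        seq = gseq.seq
        lam0, lam1 = _haplotype_rates(sample, chrom, coverage)
        d0 = rng.poisson(lam0)
        d1 = rng.poisson(lam1)
        depth = (d0 + d1).astype(np.int32)
        track = PileupTrack(chrom, depth, {}, source)
        tracks[chrom] = track

        cv = sample.variants[chrom]
        variant_positions = set(cv.snps) | set(cv.indels)

        if error_rate > 0.0:
            n_err = rng.binomial(depth, error_rate)
            err_pos = np.flatnonzero(n_err)
            # split errors across the three non-reference bases
            n = n_err[err_pos]
            a = rng.binomial(n, 1.0 / 3.0)
            b = rng.binomial(n - a, 0.5)
            c = n - a - b
            for pos, counts in zip(err_pos.tolist(), np.stack([a, b, c], axis=1).tolist()):
                if pos in variant_positions:
                    continue  # handled below with the true allele
                others = _OTHER.get(seq[pos], ["A", "C", "G"])
                obs = {}
                for base, cnt in zip(others, counts):
                    if cnt:
                        obs[base] = int(cnt)
                if obs:
                    track.alleles[pos] = obs

        for pos, (alt, zyg, hap) in cv.snps.items():
            d_tot = int(depth[pos])
            if d_tot == 0:
                continue
            if zyg == "hom":
                d_alt_hap = d_tot
            else:
                lam_c = lam0[pos] if hap == 0 else lam1[pos]
                lam_t = lam0[pos] + lam1[pos]
                frac = float(lam_c / lam_t) if lam_t > 0 else 0.0
                d_alt_hap = int(rng.binomial(d_tot, frac))
            # reads from the alt haplotype stay alt unless an error flips them
            alt_obs = int(rng.binomial(d_alt_hap, 1.0 - error_rate))
            # reads from the ref haplotype can err into the alt base
            alt_obs += int(rng.binomial(d_tot - d_alt_hap, error_rate / 3.0))
            if alt_obs:
                track.alleles[pos] = {alt: alt_obs}

        for pos, (allele, zyg, hap, _ilen) in cv.indels.items():
            d_tot = int(depth[pos])
            if d_tot == 0:
                continue
            if zyg == "hom":
                count = d_tot
            else:
                lam_c = lam0[pos] if hap == 0 else lam1[pos]
                lam_t = lam0[pos] + lam1[pos]
                frac = float(lam_c / lam_t) if lam_t > 0 else 0.0
                count = int(rng.binomial(d_tot, frac))
            if count:
                track.alleles.setdefault(pos, {})[allele] = count
    return tracks


def simulate_reference_pileup(
    ref: Mapping[str, GenomeSequence], coverage: float = 40.0, seed: int = 0
) -> dict[str, PileupTrack]:
    """Simulated-coverage track for the reference itself (copy 2 everywhere).

    Stands in for re-aligning simulated reference reads: a homogeneous
    Poisson depth track at the stated coverage, used as the digital-CGH
    denominator to damp shared coverage artifacts.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    return {
        name: PileupTrack(
            name,
            rng.poisson(coverage, size=seq.length).astype(np.int32),
            {},
            "all_proper_pairs",
        )
        for name, seq in ref.items()
    }


# ---------------------------------------------------------------------------
# read-pair simulation
# ---------------------------------------------------------------------------


def simulate_pairs(
    sample: DiploidSample,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    pair_depth: float = 0.02,
    read_len: int = 100,
    seed: int = 0,
) -> list[AlignedPair]:
    """Draw read pairs uniformly from the haplotypes, mapped to reference.

    ``pair_depth`` is pairs per bp (both haplotypes combined).  Pairs whose
    fragment spans an implanted deletion of length L map on the reference
    at a distance inflated by ≈ L.  Pairs overlapping ``repeat_regions``
    are flagged non-unique; everything else is unique and proper.
    """
    if not insert_mean > insert_sd > 0:
        raise ValueError("require insert_mean > insert_sd > 0")
    rng = np.random.default_rng(seed)
    pairs: list[AlignedPair] = []
    for chrom, gseq in sample.ref.items():
        length = gseq.length
        repeat = sorted(
            (s, e) for c, s, e in sample.repeat_regions if c == chrom
        )
        for hap in (0, 1):
            dels = sorted(
                (s, e)
                for c, s, e, zyg in sample.large_deletions
                if c == chrom and (zyg == "hom" or (hap == 0))
            )
            del_len = sum(e - s for s, e in dels)
            hap_len = length - del_len
            # anchors: haplotype-space position of each deletion start
            anchors = []
            cum = 0
            for s, e in dels:
                anchors.append(s - cum)
                cum += e - s
            anchors_arr = np.array(anchors)
            cumlen = np.concatenate(([0], np.cumsum([e - s for s, e in dels])))

            n_pairs = rng.poisson(pair_depth / 2.0 * hap_len)
            max_start = hap_len - int(insert_mean + 6 * insert_sd) - 1
            if max_start <= 0 or n_pairs == 0:
                continue
            starts = rng.integers(0, max_start, size=n_pairs)
            inserts = np.maximum(
                np.round(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
                2 * read_len,
            )
            mate_starts = starts + inserts - read_len
            ref1 = _hap_to_ref(starts, anchors_arr, cumlen)
            ref2 = _hap_to_ref(mate_starts, anchors_arr, cumlen)
            for p1, p2 in zip(ref1.tolist(), ref2.tolist()):
                unique = not any(
                    p1 < re and rs < p2 + read_len for rs, re in repeat
                )
                pairs.append(AlignedPair(chrom, p1, p2, unique=unique, proper=True))
    pairs.sort(key=lambda p: (p.chrom, p.pos1, p.pos2))
    return pairs


def _hap_to_ref(x: np.ndarray, anchors: np.ndarray, cumlen: np.ndarray) -> np.ndarray:
    if anchors.size == 0:
        return x
    idx = np.searchsorted(anchors, x, side="right")
    return x + cumlen[idx]


# ---------------------------------------------------------------------------
# gene-model simulation (plumbing for the genic-impact stage)
# ---------------------------------------------------------------------------


def simulate_gene_models(
    ref: Mapping[str, GenomeSequence],
    n_genes: int = 20,
    n_exons: int = 2,
    exon_len: int = 300,
    intron_len: int = 200,
    utr_len: int = 100,
    seed: int = 0,
) -> list:
    """Non-overlapping multi-exon gene models spread over the assembly.

    Exon lengths are multiples of 3 so every model is translation-complete;
    strands alternate.  Purely synthetic plumbing for exercising the
    variant-projection and stop-codon logic.
    """
    from vitivar.io_formats import GeneModel

    rng = np.random.default_rng(seed)
    exon_len -= exon_len % 3
    models = []
    chroms = list(ref)
    gene_span = utr_len + n_exons * exon_len + (n_exons - 1) * intron_len + utr_len
    i = 0
    while len(models) < n_genes and i < n_genes * 4:
        i += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        limit = ref[chrom].length - gene_span - 1
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if any(m.chrom == chrom and start < m._end and m._start < start + gene_span
               for m in models):
            continue
        strand = "+" if len(models) % 2 == 0 else "-"
        gid = f"gene{len(models) + 1}"
        cds = []
        pos = start + utr_len
        for _ in range(n_exons):
            cds.append((pos, pos + exon_len))
            pos += exon_len + intron_len
        pos -= intron_len
        utr5 = [(start, start + utr_len)]
        utr3 = [(pos, pos + utr_len)]
        if strand == "-":
            utr5, utr3 = utr3, utr5
            cds = cds[::-1]
            utr5 = utr5[::-1]
            utr3 = utr3[::-1]
        model = GeneModel(gid, chrom, strand, cds, utr5, utr3)
        model._start = start  # type: ignore[attr-defined]
        model._end = start + gene_span  # type: ignore[attr-defined]
        models.append(model)
    return models
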