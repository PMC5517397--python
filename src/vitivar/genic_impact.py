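"""Protein-level consequences of called variants.

Variants are projected onto gene models (CDS / 5'UTR / 3'UTR, strand
aware), CDS SNPs are evaluated codon-by-codon — jointly when several
SNPs hit one codon — for premature stops, lost ("new") stops and amino
acid replacements, CDS indels are split into frameshift vs in-frame, and
per-gene selection pressure is estimated as NG86 dN/dS with Jukes–Cantor
correction on transcripts carrying more than five CDS SNPs.

NG86 conventions used here (and by the test oracles): mutations creating
a stop codon count as nonsynonymous when counting sites; codons that are
stops (or carry N) in either sequence are skipped; multi-substitution
codons average the difference counts over all substitution orderings,
excluding pathways that pass through a stop codon unless every pathway
does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

from intervaltree import IntervalTree
from scipy import stats

from vitivar.io_formats import GeneModel, GenomeSequence, reverse_complement
from vitivar.variant_calling import VariantCall

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        bases = "TCAG"
        for a in bases:
            for b in bases:
                for c in bases:
                    codon = a + b + c
                    _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE


def translate_codon(codon: str) -> str:
    """Single-codon translation; '*' for stop, 'X' for ambiguous."""
    if "N" in codon:
        return "X"
    return _codon_table()[codon]


STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ImpactRecord:
    gene_id: str
    region: str  # CDS | UTR5 | UTR3
    consequence: str
    zygosity: str
    variant: VariantCall
    detail: dict = field(default_factory=dict)


@dataclass
class SelectionResult:
    gene_id: str
    n_snps: int
    dn: float | None
    ds: float | None
    dnds: float | None
    p_value: float
    class_: str  # purifying | diversifying | neutral/ns
    n_sites: float = 0.0  # nonsynonymous sites (N)
    s_sites: float = 0.0  # synonymous sites (S)
    nd: float = 0.0  # pathway-averaged nonsynonymous differences (Nd)
    sd: float = 0.0  # pathway-averaged synonymous differences (Sd)
    flags: list[str] = field(default_factory=list)
    method: str = "NG86+JC"


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def project_variants(
    calls: Sequence[VariantCall], models: Sequence[GeneModel]
) -> list[tuple[VariantCall, str | None, str | None]]:
    """Label each call with every overlapping model's region.

    Returns (call, gene_id, region) triples; intergenic calls appear once
    with (None, None).  A call overlapping several transcripts or regions
    yields one triple per overlap.  SNPs use their single base; indels use
    the span they alter (insertion point, or deleted bases).
    """
    trees: dict[str, IntervalTree] = {}
    for model in models:
        tree = trees.setdefault(model.chrom, IntervalTree())
        for region, attr in (
            ("CDS", "cds_intervals"),
            ("UTR5", "utr5_intervals"),
            ("UTR3", "utr3_intervals"),
        ):
            for s, e in getattr(model, attr):
                tree.addi(s, e, (model.gene_id, region))
    out: list[tuple[VariantCall, str | None, str | None]] = []
    for call in calls:
        if call.kind == "SNP":
            span = (call.pos, call.pos + 1)
        elif call.kind == "deletion":
            span = (call.pos + 1, call.pos + len(call.ref_allele))
        else:  # insertion between pos and pos+1
            span = (call.pos, call.pos + 2)
        hits = trees.get(call.chrom, IntervalTree()).overlap(*span)
        if not hits:
            out.append((call, None, None))
            continue
        for hit in sorted(hits, key=lambda h: (h.data, h.begin)):
            gene_id, region = hit.data
            out.append((call, gene_id, region))
    return out


# ---------------------------------------------------------------------------
# stop-codon events
# ---------------------------------------------------------------------------


def _cds_position_map(model: GeneModel) -> list[int]:
    """Genomic position of each CDS base, in translation order."""
    ivals = sorted(model.cds_intervals)
    positions = [p for s, e in ivals for p in range(s, e)]
    if model.strand == "-":
        positions.reverse()
    return positions


def detect_stop_changes(
    model: GeneModel,
    cds_seq: str,
    calls: Sequence[VariantCall],
    assembly: Mapping[str, GenomeSequence] | None = None,
    downstream_scan: int = 3000,
) -> list[ImpactRecord]:
    """Classify CDS SNPs of one transcript codon-by-codon.

    Emits stop_gain for an internal codon turned into a stop,
    stop_lost_new_stop when the annotated terminal stop is destroyed
    (with the next in-frame downstream stop located within
    ``downstream_scan`` bp when the assembly is supplied), and
    synonymous/missense otherwise.  SNPs sharing a codon are applied
    jointly.  Incomplete models (CDS length not divisible by 3) are
    skipped with a warning.
    """
    import warnings

    if len(cds_seq) % 3 != 0:
        warnings.warn(
            f"{model.gene_id}: CDS length {len(cds_seq)} not divisible by 3, skipped",
            stacklevel=2,
        )
        return []
    positions = _cds_position_map(model)
    pos_to_idx = {p: i for i, p in enumerate(positions)}
    by_codon: dict[int, list[VariantCall]] = {}
    for call in calls:
        if call.kind != "SNP" or call.chrom != model.chrom:
            continue
        idx = pos_to_idx.get(call.pos)
        if idx is None:
            continue
        by_codon.setdefault(idx // 3, []).append(call)

    n_codons = len(cds_seq) // 3
    records: list[ImpactRecord] = []
    for codon_idx, codon_calls in sorted(by_codon.items()):
        ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
        alt_codon = list(ref_codon)
        for call in codon_calls:
            idx = pos_to_idx[call.pos]
            base = call.alt_allele
            if model.strand == "-":
                base = reverse_complement(base)
            alt_codon[idx % 3] = base
        alt_codon = "".join(alt_codon)
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt_codon)
        zygosity = (
            "hom" if all(c.zygosity == "hom" for c in codon_calls) else "het"
        )
        detail = {"codon_index": codon_idx, "ref_codon": ref_codon, "alt_codon": alt_codon}
        if codon_idx < n_codons - 1 and ref_aa != "*" and alt_aa == "*":
            consequence = "stop_gain"
        elif codon_idx == n_codons - 1 and ref_aa == "*" and alt_aa != "*":
            consequence = "stop_lost_new_stop"
            if assembly is not None:
                detail["new_stop_offset"] = _next_inframe_stop(
                    model, assembly, downstream_scan
                )
        elif ref_aa == alt_aa:
            consequence = "synonymous"
        else:
            consequence = "missense"
        for call in codon_calls:
            records.append(
                ImpactRecord(
                    gene_id=model.gene_id,
                    region="CDS",
                    consequence=consequence,
                    zygosity=zygosity,
                    variant=call,
                    detail=detail,
                )
            )
    return records


def _next_inframe_stop(
    model: GeneModel, assembly: Mapping[str, GenomeSequence], limit: int
) -> int | None:
    """Codon offset (1 = first codon past the CDS) of the next in-frame stop."""
    seq = assembly[model.chrom].seq
    ivals = sorted(model.cds_intervals)
    if model.strand == "+":
        tail = seq[ivals[-1][1] : ivals[-1][1] + limit]
    else:
        start = max(ivals[0][0] - limit, 0)
        tail = reverse_complement(seq[start : ivals[0][0]])
    for k in range(0, len(tail) - 2, 3):
        if tail[k : k + 3] in STOPS:
            return k // 3 + 1
    return None


# ---------------------------------------------------------------------------
# frameshifts
# ---------------------------------------------------------------------------


def detect_frameshifts(
    model: GeneModel, indel_calls: Sequence[VariantCall]
) -> list[ImpactRecord]:
    """Split CDS indels into frameshift vs in-frame events.

    Only the CDS-overlapping part of an indel counts: a deletion
    straddling an exon boundary contributes the deleted bases inside the
    CDS, and an insertion counts only when its insertion point is inside
    the CDS.  Frameshift iff the net altered CDS length is not a multiple
    of three.
    """
    records = []
    ivals = sorted(model.cds_intervals)
    for call in indel_calls:
        if call.kind == "SNP" or call.chrom != model.chrom:
            continue
        if call.kind == "insertion":
            inside = any(s <= call.pos < e - 1 for s, e in ivals)
            net = (len(call.alt_allele) - len(call.ref_allele)) if inside else 0
        else:
            del_start = call.pos + 1
            del_end = call.pos + len(call.ref_allele)
            net = -sum(
                max(0, min(del_end, e) - max(del_start, s)) for s, e in ivals
            )
        if net == 0:
            continue
        records.append(
            ImpactRecord(
                gene_id=model.gene_id,
                region="CDS",
                consequence="frameshift" if net % 3 != 0 else "inframe_indel",
                zygosity=call.zygosity,
                variant=call,
                detail={"net_cds_length_change": net},
            )
        )
    return records


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------


def _synonymous_site_fraction(codon: str) -> float:
    """Synonymous fraction of the 9 possible single-base changes (0..3).

    Changes producing a stop codon count as nonsynonymous.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for i in range(3):
        for base in "ACGT":
            if base == codon[i]:
                continue
            mutated = codon[:i] + base + codon[i + 1 :]
            if translate_codon(mutated) == aa:
                syn += 1.0
    return syn / 3.0


def _codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over substitution orderings.

    Pathways through stop codons are discarded; if all are blocked the
    average falls back to every pathway.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if translate_codon(nxt) == translate_codon(current):
                sd += 1.0
            else:
                nd += 1.0
            if nxt in STOPS:
                blocked = True
            current = nxt
        paths.append((sd, nd, blocked))
    usable = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def compute_dnds(
    ref_cds: str,
    alt_cds: str,
    gene_id: str = "",
    n_snps: int | None = None,
    alpha: float = 0.05,
) -> SelectionResult:
    """NG86 dN/dS between two gap-free, equal-length codon sequences.

    Synonymous/nonsynonymous site counts are averaged between the two
    sequences, difference counts are pathway-averaged per codon, rates
    are Jukes–Cantor corrected (d = −(3/4)·ln(1 − 4p/3)) and a Fisher
    exact test on the rounded (Nd, N−Nd; Sd, S−Sd) table gives the
    significance of the selection signal.
    """
    if len(ref_cds) != len(alt_cds):
        raise ValueError("sequences must be equal length (codon alignment)")
    if len(ref_cds) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_diff_sites = 0
    for k in range(0, len(ref_cds), 3):
        c1 = ref_cds[k : k + 3]
        c2 = alt_cds[k : k + 3]
        if "N" in c1 or "N" in c2 or c1 in STOPS or c2 in STOPS:
            continue
        s_sites = (_synonymous_site_fraction(c1) + _synonymous_site_fraction(c2)) / 2.0
        S += s_sites
        N += 3.0 - s_sites
        sd, nd = _codon_path_diffs(c1, c2)
        Sd += sd
        Nd += nd
        n_diff_sites += sum(1 for i in range(3) if c1[i] != c2[i])
    if n_snps is None:
        n_snps = n_diff_sites

    flags: list[str] = []
    if n_snps <= 5:
        flags.append("too_few_snps")
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    dn = _jukes_cantor(pN)
    ds = _jukes_cantor(pS)
    if dn is None:
        flags.append("dn_saturated")
    if ds is None:
        flags.append("ds_saturated")
    if ds == 0.0:
        flags.append("ds_zero")
        dnds = None
    elif dn is None or ds is None:
        dnds = None
    else:
        dnds = dn / ds
    table = [
        [int(round(Nd)), max(int(round(N - Nd)), 0)],
        [int(round(Sd)), max(int(round(S - Sd)), 0)],
    ]
    p_value = float(stats.fisher_exact(table)[1])
    if dnds is not None and p_value < alpha and dnds < 1.0:
        class_ = "purifying"
    elif dnds is not None and p_value < alpha and dnds > 1.0:
        class_ = "diversifying"
    else:
        class_ = "neutral/ns"
    return SelectionResult(
        gene_id=gene_id,
        n_snps=n_snps,
        dn=dn,
        ds=ds,
        dnds=dnds,
        p_value=p_value,
        class_=class_,
        n_sites=N,
        s_sites=S,
        nd=Nd,
        sd=Sd,
        flags=flags,
    )


def selection_scan(
    models: Sequence[GeneModel],
    assembly: Mapping[str, GenomeSequence],
    calls: Sequence[VariantCall],
    min_snps: int = 6,
) -> list[SelectionResult]:
    """dN/dS per transcript for transcripts with > 5 CDS SNPs.

    The alternate CDS is built by applying every alternate SNP allele
    (homozygous and heterozygous) to the reference CDS; transcripts with
    CDS indels are excluded so the alignment stays gap-free.
    """
    snps_by_chrom: dict[str, dict[int, str]] = {}
    indel_pos: dict[str, set[int]] = {}
    for call in calls:
        if call.kind == "SNP":
            snps_by_chrom.setdefault(call.chrom, {})[call.pos] = call.alt_allele
        else:
            indel_pos.setdefault(call.chrom, set()).add(call.pos)
    results = []
    for model in models:
        if not model.is_complete:
            continue
        positions = _cds_position_map(model)
        pos_set = set(positions)
        if indel_pos.get(model.chrom) and pos_set & indel_pos[model.chrom]:
            continue
        chrom_snps = snps_by_chrom.get(model.chrom, {})
        hits = {p: chrom_snps[p] for p in pos_set & chrom_snps.keys()}
        if len(hits) < min_snps:
            continue
        ref_cds = model.spliced_cds(assembly)
        alt = list(ref_cds)
        for i, p in enumerate(positions):
            if p in hits:
                base = hits[p]
                alt[i] = reverse_complement(base) if model.strand == "-" else base
        results.append(
            compute_dnds("".join(ref_cds), "".join(alt), model.gene_id, len(hits))
        )
    return results


# ---------------------------------------------------------------------------
# pseudogenes
# ---------------------------------------------------------------------------


def classify_pseudogenes(
    stop_events: Mapping[str, Mapping[str, int]]
) -> dict:
    """Partition putative pseudogenes by cross-sample sharing.

    ``stop_events[sample][gene]`` is the premature-stop count for that
    gene in that sample.  A gene is a putative pseudogene when it carries
    at least one premature stop in at least one sample.  Returns the gene
    sets, the multi-stop subset, and the specific-to-one / shared-by-all
    / intermediate partition with percentages.
    """
    samples = list(stop_events)
    genes: dict[str, set[str]] = {}
    multi: set[str] = set()
    for sample in samples:
        for gene, count in stop_events[sample].items():
            if count >= 1:
                genes.setdefault(gene, set()).add(sample)
            if count >= 2:
                multi.add(gene)
    n_samples = len(samples)
    specific = {g for g, ss in genes.items() if len(ss) == 1}
    shared_all = {g for g, ss in genes.items() if len(ss) == n_samples and n_samples > 1}
    intermediate = set(genes) - specific - shared_all
    total = len(genes)
    pct = lambda s: 100.0 * len(s) / total if total else 0.0
    return {
        "pseudogenes": genes,
        "n_pseudogenes": total,
        "multi_stop": multi,
        "specific": specific,
        "shared_by_all": shared_all,
        "intermediate": intermediate,
        "pct_specific": pct(specific),
        "pct_shared_by_all": pct(shared_all),
        "pct_intermediate": pct(intermediate),
    }
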