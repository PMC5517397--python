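"""Impact annotation: projection, stop logic, frameshifts, NG86 dN/dS."""

import math
from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq

from vitivar.genic_impact import (
    classify_pseudogenes,
    compute_dnds,
    detect_frameshifts,
    detect_stop_changes,
    project_variants,
    selection_scan,
)
from vitivar.io_formats import GeneModel, GenomeSequence, reverse_complement
from vitivar.variant_calling import VariantCall

from conftest import make_cds_sequence

STOPS = {"TAA", "TAG", "TGA"}


def _snp(pos, ref, alt, zygosity="hom", chrom="chr1"):
    return VariantCall(chrom, pos, ref, alt, "SNP", zygosity, 40, 40, 1e-9)


def _assembly_with_cds(cds, flank=200, extra="TTTGATTTTAA" * 300):
    """chr1 = flank + cds (plus strand) + downstream sequence."""
    seq = "A" * flank + cds + extra
    seq = seq[: max(len(seq), 1000)]
    asm = {"chr1": GenomeSequence("chr1", seq)}
    model = GeneModel("g1", "chr1", "+", cds_intervals=[(flank, flank + len(cds))])
    return asm, model


class TestProjectVariants:
    def test_minus_strand_cds_label(self, tiny_assembly):
        model = GeneModel("gm", "chr1", "-", cds_intervals=[(100, 400)])
        out = project_variants([_snp(250, "A", "G")], [model])
        assert out == [(out[0][0], "gm", "CDS")]

    def test_intron_variant_unlabeled(self, tiny_assembly):
        model = GeneModel("gm", "chr1", "+",
                          cds_intervals=[(100, 200), (300, 400)])
        out = project_variants([_snp(250, "A", "G")], [model])
        assert out[0][1] is None and out[0][2] is None

    def test_utr_labels(self):
        model = GeneModel("gm", "chr1", "+", cds_intervals=[(100, 400)],
                          utr5_intervals=[(50, 100)], utr3_intervals=[(400, 450)])
        out = project_variants([_snp(60, "A", "G"), _snp(440, "A", "G")], [model])
        assert {(g, r) for _c, g, r in out} == {("gm", "UTR5"), ("gm", "UTR3")}

    def test_matches_bruteforce_interval_scan(self):
        rng = np.random.default_rng(3)
        models = []
        for k in range(10):
            s = int(rng.integers(0, 90_000))
            models.append(
                GeneModel(f"g{k}", "chr1", "+",
                          cds_intervals=[(s, s + 300)],
                          utr5_intervals=[(s - 100, s)] if s >= 100 else [],
                          utr3_intervals=[(s + 300, s + 400)])
            )
        calls = [_snp(int(p), "A", "G") for p in rng.integers(0, 100_000, 100)]
        got = {
            (c.pos, g, r) for c, g, r in project_variants(calls, models) if g
        }
        expect = set()
        for c in calls:
            for m in models:
                for region, ivals in (("CDS", m.cds_intervals),
                                      ("UTR5", m.utr5_intervals),
                                      ("UTR3", m.utr3_intervals)):
                    if any(s <= c.pos < e for s, e in ivals):
                        expect.add((c.pos, m.gene_id, region))
        assert got == expect


class TestStopChanges:
    def test_stop_gain_hand_case(self):
        # CDS "ATG AAA TGA": A->T at codon 2 first base makes TAA
        asm, model = _assembly_with_cds("ATGAAATGA")
        cds = model.spliced_cds(asm)
        records = detect_stop_changes(model, cds, [_snp(203, "A", "T")], asm)
        assert len(records) == 1 and records[0].consequence == "stop_gain"

    def test_third_base_synonymous(self):
        asm, model = _assembly_with_cds("ATGAAATGA")
        cds = model.spliced_cds(asm)
        records = detect_stop_changes(model, cds, [_snp(205, "A", "G")], asm)
        assert records[0].consequence == "synonymous"

    def test_stop_lost_finds_next_inframe_stop(self):
        asm, model = _assembly_with_cds("ATGAAATGA")
        cds = model.spliced_cds(asm)
        records = detect_stop_changes(model, cds, [_snp(206, "A", "C")], asm)
        assert records[0].consequence == "stop_lost_new_stop"
        assert records[0].detail["new_stop_offset"] is not None

    def test_incomplete_model_skipped(self):
        asm, model = _assembly_with_cds("ATGAAATG")
        with pytest.warns(UserWarning):
            assert detect_stop_changes(model, "ATGAAATG", [_snp(203, "A", "T")]) == []

    def test_compound_codon_evaluated_jointly(self):
        # two SNPs in one codon: AAA -> TGA only when applied together
        asm, model = _assembly_with_cds("ATGAAATGA")
        cds = model.spliced_cds(asm)
        calls = [_snp(203, "A", "T"), _snp(204, "A", "G")]
        records = detect_stop_changes(model, cds, calls, asm)
        assert all(r.consequence == "stop_gain" for r in records)
        assert len(records) == 2  # one record per contributing SNP

    def test_minus_strand_alt_complemented(self):
        # minus-strand gene; genomic T->A at the CDS-middle codon's
        # first base (transcript orientation) must read as A->T
        cds = "ATGAAATGA"
        genomic = reverse_complement(cds)
        seq = "G" * 200 + genomic + "G" * 600
        asm = {"chr1": GenomeSequence("chr1", seq)}
        model = GeneModel("g1", "chr1", "-", cds_intervals=[(200, 209)])
        assert model.spliced_cds(asm) == cds
        # transcript position 3 (codon 2 base 1) = genomic index 200+9-1-3=205
        records = detect_stop_changes(model, cds, [_snp(205, "T", "A")], asm)
        assert records[0].consequence == "stop_gain"

    def test_random_snps_match_translation_diff_oracle(self):
        rng = np.random.default_rng(11)
        total_snps = 0
        while total_snps < 500:
            cds = make_cds_sequence(rng, 80)
            asm, model = _assembly_with_cds(cds)
            calls = []
            codon_of = {}
            for p in sorted(rng.choice(len(cds), size=12, replace=False).tolist()):
                ref = cds[p]
                alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
                if alt == ref:
                    continue
                calls.append(_snp(200 + p, ref, alt))
                codon_of[200 + p] = p // 3
            total_snps += len(calls)
            records = detect_stop_changes(model, cds, calls, asm)
            # oracle: apply all SNPs, translate both sequences codon-by-codon
            alt_seq = list(cds)
            for c in calls:
                alt_seq[c.pos - 200] = c.alt_allele
            alt_seq = "".join(alt_seq)
            n_codons = len(cds) // 3
            expect = {}
            for ci in range(n_codons):
                r = str(Seq(cds[ci * 3 : ci * 3 + 3]).translate())
                a = str(Seq(alt_seq[ci * 3 : ci * 3 + 3]).translate())
                if r == a:
                    verdict = "synonymous"
                elif ci < n_codons - 1 and r != "*" and a == "*":
                    verdict = "stop_gain"
                elif ci == n_codons - 1 and r == "*" and a != "*":
                    verdict = "stop_lost_new_stop"
                else:
                    verdict = "missense"
                expect[ci] = verdict
            got = {r.detail["codon_index"]: r.consequence for r in records}
            assert got == {
                ci: v for ci, v in expect.items()
                if ci in {codon_of[c.pos] for c in calls}
            }


class TestFrameshifts:
    def _model(self):
        return GeneModel("g1", "chr1", "+", cds_intervals=[(100, 200), (300, 400)])

    def _indel(self, pos, ref, alt, kind):
        return VariantCall("chr1", pos, ref, alt, kind, "hom", 40, 40, 1e-9)

    def test_two_bp_deletion_frameshift(self):
        call = self._indel(150, "AGG", "A", "deletion")
        records = detect_frameshifts(self._model(), [call])
        assert records[0].consequence == "frameshift"

    def test_three_bp_insertion_inframe(self):
        call = self._indel(150, "A", "AGGG", "insertion")
        records = detect_frameshifts(self._model(), [call])
        assert records[0].consequence == "inframe_indel"

    def test_exon_boundary_counts_cds_overlap_only(self):
        # 4-bp deletion of bases 198..201: only 198,199 are CDS -> net -2
        call = self._indel(197, "ANNNN"[:5], "A", "deletion")
        records = detect_frameshifts(self._model(), [call])
        assert records[0].detail["net_cds_length_change"] == -2
        assert records[0].consequence == "frameshift"

    def test_intronic_indel_ignored(self):
        call = self._indel(250, "AG", "A", "deletion")
        assert detect_frameshifts(self._model(), [call]) == []


# ------------------------------------------------------------------ NG86 oracle

def _oracle_syn_fraction(codon):
    aa = str(Seq(codon).translate())
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b != codon[i]:
                mutated = codon[:i] + b + codon[i + 1 :]
                if str(Seq(mutated).translate()) == aa:
                    syn += 1
    return syn / 3.0


def _oracle_path_diffs(c1, c2):
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if str(Seq(nxt).translate()) == str(Seq(cur).translate()):
                sd += 1
            else:
                nd += 1
            if nxt in STOPS:
                blocked = True
            cur = nxt
        paths.append((sd, nd, blocked))
    ok = [p for p in paths if not p[2]] or paths
    return (sum(p[0] for p in ok) / len(ok), sum(p[1] for p in ok) / len(ok))


def _oracle_dnds(ref_cds, alt_cds):
    S = N = Sd = Nd = 0.0
    for k in range(0, len(ref_cds), 3):
        c1, c2 = ref_cds[k : k + 3], alt_cds[k : k + 3]
        if "N" in c1 or "N" in c2 or c1 in STOPS or c2 in STOPS:
            continue
        s = (_oracle_syn_fraction(c1) + _oracle_syn_fraction(c2)) / 2
        S += s
        N += 3 - s
        sd, nd = _oracle_path_diffs(c1, c2)
        Sd += sd
        Nd += nd
    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(Nd / N), jc(Sd / S)


class TestComputeDnds:
    def test_identical_sequences_neutral(self):
        cds = "ATGAAACCCGGG"
        res = compute_dnds(cds, cds)
        assert res.dn == 0.0 and res.ds == 0.0
        assert res.class_ == "neutral/ns"

    def test_single_synonymous_difference_hand_count(self):
        # TTT -> TTC: Phe -> Phe, Sd=1 Nd=0
        res = compute_dnds("TTT", "TTC")
        assert res.sd == 1.0 and res.nd == 0.0
        assert res.dn == 0.0

    def test_random_pairs_match_exhaustive_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            ref = make_cds_sequence(rng, 300)
            alt = list(ref)
            for p in rng.choice(len(ref), size=25, replace=False):
                alt[p] = "ACGT"[int(rng.integers(4))]
            alt = "".join(alt)
            res = compute_dnds(ref, alt)
            dn_o, ds_o = _oracle_dnds(ref, alt)
            assert res.dn == pytest.approx(dn_o, abs=1e-9)
            assert res.ds == pytest.approx(ds_o, abs=1e-9)

    def test_symmetric_under_sequence_swap(self):
        rng = np.random.default_rng(22)
        ref = make_cds_sequence(rng, 100)
        alt = list(ref)
        for p in rng.choice(len(ref), size=12, replace=False):
            alt[p] = "ACGT"[int(rng.integers(4))]
        alt = "".join(alt)
        a = compute_dnds(ref, alt)
        b = compute_dnds(alt, ref)
        assert a.dn == pytest.approx(b.dn, abs=1e-12)
        assert a.ds == pytest.approx(b.ds, abs=1e-12)

    def test_ds_zero_flagged_not_infinite(self):
        # ATG AAA: A->C at codon2 pos1 is nonsynonymous only
        res = compute_dnds("ATGAAA", "ATGCAA")
        assert res.dnds is None and "ds_zero" in res.flags

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compute_dnds("ATG", "ATGAAA")

    def test_selection_scan_requires_more_than_five_snps(self):
        rng = np.random.default_rng(23)
        cds = make_cds_sequence(rng, 200)
        asm, model = _assembly_with_cds(cds)
        calls = []
        for p in sorted(rng.choice(len(cds) - 3, size=4, replace=False).tolist()):
            ref = cds[p]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            calls.append(_snp(200 + p, ref, alt))
        assert selection_scan([model], asm, calls) == []


class TestClassifyPseudogenes:
    def test_single_sample_gene_specific(self):
        result = classify_pseudogenes(
            {"a": {"g1": 1}, "b": {}, "c": {}, "d": {}}
        )
        assert result["specific"] == {"g1"}
        assert result["pct_specific"] == 100.0

    def test_shared_by_all_fraction(self):
        events = {
            "a": {"g1": 1, "g2": 1},
            "b": {"g1": 2, "g3": 1},
            "c": {"g1": 1},
        }
        result = classify_pseudogenes(events)
        assert result["shared_by_all"] == {"g1"}
        assert result["pct_shared_by_all"] == pytest.approx(100 / 3)
        assert result["multi_stop"] == {"g1"}

    def test_random_incidence_matrix_matches_set_algebra(self):
        rng = np.random.default_rng(31)
        samples = [f"s{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(60)]
        events = {
            s: {g: int(rng.integers(0, 3)) for g in genes} for s in samples
        }
        result = classify_pseudogenes(events)
        membership = {
            g: {s for s in samples if events[s].get(g, 0) >= 1} for g in genes
        }
        membership = {g: ss for g, ss in membership.items() if ss}
        assert result["specific"] == {g for g, ss in membership.items() if len(ss) == 1}
        assert result["shared_by_all"] == {
            g for g, ss in membership.items() if len(ss) == 4
        }
        assert (result["pct_specific"] + result["pct_shared_by_all"]
                + result["pct_intermediate"]) == pytest.approx(100.0)
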