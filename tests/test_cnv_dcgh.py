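"""Digital-CGH: windowed ratio, CBS vs exhaustive oracle, classification."""

import math

import numpy as np
import pytest

from vitivar.cnv_dcgh import (
    RatioProfile,
    Segment,
    cbs_segment,
    classify_segments,
    ratio_profile,
    te_overlap,
)
from vitivar.io_formats import PileupTrack
from vitivar.synthetic_data import (
    VariantSpec,
    implant_variants,
    simulate_pileup,
    simulate_reference,
    simulate_reference_pileup,
)


def _profile(values, window=500, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    starts = np.arange(n) * window
    return RatioProfile(
        chrom=chrom, window_size=window, window_starts=starts,
        window_ends=starts + window, target_mean_depth=np.ones(n),
        reference_mean_depth=np.ones(n), log2_ratio=values,
        zero_flag=np.zeros(n, dtype=bool), masked=np.zeros(n, dtype=bool),
    )


# --------------------------------------------------------------------- oracle

def _oracle_max_arc(vals):
    n = len(vals)
    if n < 2:
        return None
    sd = vals.std(ddof=1)
    if sd == 0:
        return None
    total = vals.sum()
    best = (-1.0, 0, 0)
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            mean_in = vals[i:j].mean()
            mean_out = (total - vals[i:j].sum()) / (n - k)
            t = abs(mean_in - mean_out) / (sd * math.sqrt(1 / k + 1 / (n - k)))
            if t > best[0]:
                best = (t, i, j)
    return best


def _oracle_cbs(values, alpha, n_perm, seed):
    """Independent exhaustive-search CBS sharing the permutation protocol."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    accepted = []

    def rec(lo, hi):
        vals = values[lo:hi]
        res = _oracle_max_arc(vals)
        if res is None:
            return
        obs, i, j = res
        rng = np.random.default_rng([seed, lo, hi - lo])
        max_exceed = alpha * (1 + n_perm) - 1
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(vals)
            if _oracle_max_arc(perm)[0] >= obs - 1e-12:
                exceed += 1
                if exceed > max_exceed:
                    return
        if (1 + exceed) / (1 + n_perm) <= alpha:
            cuts = [c for c in (lo + i, lo + j) if 0 < c < n and c not in (lo, hi)]
            accepted.extend(cuts)
            pieces = sorted({lo, hi, *cuts})
            for a, b in zip(pieces, pieces[1:]):
                if b - a >= 2:
                    rec(a, b)

    rec(0, n)
    return sorted(accepted)


class TestRatioProfile:
    def test_identical_tracks_log2_zero(self):
        depth = np.random.default_rng(0).poisson(30, 10_000).astype(np.int32)
        t = {"chr1": PileupTrack("chr1", depth)}
        r = {"chr1": PileupTrack("chr1", depth.copy())}
        prof = ratio_profile(t, r)["chr1"]
        assert np.allclose(prof.log2_ratio, 0.0)

    def test_copy4_region_near_plus_one(self):
        # CNV kept a small fraction of the genome: the digital-CGH
        # normalization uses the genome-wide mean, which large implants shift
        ref = simulate_reference(1, 1_000_000, seed=40)
        spec = VariantSpec(snp_rate_hom=0, snp_rate_het=0, indel_rate=0,
                           cnv_segments=[("chr1", 100_000, 120_000, 4)], seed=40)
        sample, _t = implant_variants(ref, spec)
        target = simulate_pileup(sample, coverage=30, seed=41)
        reference = simulate_reference_pileup(ref, coverage=40, seed=42)
        prof = ratio_profile(target, reference)["chr1"]
        sel = (prof.window_starts >= 100_000) & (prof.window_ends <= 120_000)
        assert abs(prof.log2_ratio[sel].mean() - 1.0) < 0.1

    def test_hom_deletion_zero_flagged(self):
        ref = simulate_reference(1, 300_000, seed=43)
        spec = VariantSpec(snp_rate_hom=0, snp_rate_het=0, indel_rate=0,
                           large_deletions=[("chr1", 100_000, 130_000)], seed=43)
        sample, _t = implant_variants(ref, spec)
        target = simulate_pileup(sample, coverage=30, seed=44)
        reference = simulate_reference_pileup(ref, coverage=40, seed=45)
        prof = ratio_profile(target, reference)["chr1"]
        sel = (prof.window_starts >= 100_000) & (prof.window_ends <= 130_000)
        assert prof.zero_flag[sel].all()

    def test_short_final_window_kept(self):
        t = {"chr1": PileupTrack("chr1", np.full(1200, 10, dtype=np.int32))}
        r = {"chr1": PileupTrack("chr1", np.full(1200, 10, dtype=np.int32))}
        with pytest.warns(UserWarning):
            prof = ratio_profile(t, r, window=500)["chr1"]
        assert prof.n_windows == 3
        assert prof.window_ends[-1] - prof.window_starts[-1] == 200


class TestCbsSegment:
    def test_step_profile_exact_changepoints(self):
        rng = np.random.default_rng(50)
        values = rng.normal(0, 0.1, 50)
        values[15:35] += 1.0
        cps, segs = cbs_segment(_profile(values), alpha=0.01, n_perm=500, seed=1)
        assert cps == [15, 35]
        assert len(segs) == 3
        assert abs(segs[1].mean_log2_ratio - 1.0) < 0.1

    def test_matches_exhaustive_oracle(self):
        for trial in range(3):
            rng = np.random.default_rng(60 + trial)
            values = rng.normal(0, 0.25, 40)
            values[10:20] += 0.8
            values[30:] -= 0.6
            cps, _segs = cbs_segment(_profile(values), alpha=0.01, n_perm=200,
                                     seed=trial)
            assert cps == _oracle_cbs(values, 0.01, 200, trial)

    def test_null_false_positive_rate(self):
        # pure noise: accepted changepoints in <= 5% of runs at alpha 0.01
        hits = 0
        for run in range(100):
            rng = np.random.default_rng(1000 + run)
            values = rng.normal(0, 0.2, 200)
            cps, _ = cbs_segment(_profile(values), alpha=0.01, n_perm=400, seed=run)
            hits += bool(cps)
        assert hits <= 5

    def test_single_window_degenerate(self):
        cps, segs = cbs_segment(_profile([0.5]), seed=0)
        assert cps == [] and len(segs) == 1

    def test_constant_profile_single_segment(self):
        cps, segs = cbs_segment(_profile([0.3] * 30), seed=0)
        assert cps == [] and len(segs) == 1

    def test_low_n_perm_warns(self):
        with pytest.warns(UserWarning):
            cbs_segment(_profile([0.0, 1.0, 0.0]), n_perm=50, seed=0)

    def test_segment_lengths_conserve_profile(self):
        rng = np.random.default_rng(70)
        values = rng.normal(0, 0.2, 80)
        values[20:50] += 1.2
        prof = _profile(values)
        _cps, segs = cbs_segment(prof, seed=2)
        assert sum(s.length for s in segs) == 80 * 500
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start

    def test_shift_invariance(self):
        rng = np.random.default_rng(80)
        values = rng.normal(0, 0.2, 60)
        values[25:40] += 1.0
        cps1, _ = cbs_segment(_profile(values), seed=3)
        cps2, _ = cbs_segment(_profile(values + 5.0), seed=3)
        assert cps1 == cps2

    @pytest.mark.parametrize("alphas", [(0.05, 0.01, 0.001)])
    def test_alpha_monotonicity(self, alphas):
        rng = np.random.default_rng(90)
        values = rng.normal(0, 0.3, 60)
        values[10:25] += 0.5
        values[40:50] -= 0.7
        counts = [
            len(cbs_segment(_profile(values), alpha=a, n_perm=400, seed=4)[0])
            for a in alphas
        ]
        assert counts == sorted(counts, reverse=True)


class TestClassifySegments:
    def test_gain_loss_neutral_by_mean(self):
        segs = [
            Segment("chr1", 0, 3000, 1.0, 6),
            Segment("chr1", 3000, 13_000, -0.2, 20),
            Segment("chr1", 13_000, 20_000, -0.9, 14),
        ]
        out = classify_segments(segs)
        assert [s.class_ for s in out] == ["gain", "neutral", "loss"]

    def test_short_segment_not_retained(self):
        out = classify_segments([Segment("chr1", 0, 500, 1.5, 1)])
        assert out[0].class_ == "neutral"

    def test_pav_from_zero_flags(self):
        values = np.full(10, -6.0)
        prof = _profile(values)
        prof.zero_flag[:] = True
        out = classify_segments([Segment("chr1", 0, 5000, -6.0, 10)], prof)
        assert out[0].class_ == "PAV"


class TestTeOverlap:
    def test_te_covering_half_of_every_gain(self):
        segs = [
            Segment("chr1", 0, 2000, 1.0, 4, class_="gain"),
            Segment("chr1", 10_000, 14_000, 1.0, 8, class_="gain"),
        ]
        tes = [("chr1", 0, 1000), ("chr1", 10_000, 12_000)]
        assert te_overlap(segs, tes)["gain"] == pytest.approx(0.5)

    def test_disjoint_tes_zero(self):
        segs = [Segment("chr1", 0, 2000, 1.0, 4, class_="gain")]
        assert te_overlap(segs, [("chr1", 5000, 6000)])["gain"] == 0.0

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(7)
        length = 100_000
        segs = []
        pos = 0
        for _ in range(20):
            pos += int(rng.integers(500, 2000))
            end = pos + int(rng.integers(500, 3000))
            if end > length:
                break
            segs.append(Segment("chr1", pos, end, 0.8,
                                (end - pos) // 500, class_="gain"))
            pos = end
        tes = []
        for _ in range(50):
            s = int(rng.integers(0, length - 2000))
            tes.append(("chr1", s, s + int(rng.integers(100, 2000))))
        frac = te_overlap(segs, tes)["gain"]
        bitmap_te = np.zeros(length, dtype=bool)
        for _c, s, e in tes:
            bitmap_te[s:e] = True
        inter = sum(bitmap_te[s.start : s.end].sum() for s in segs)
        total = sum(s.length for s in segs)
        assert abs(frac - inter / total) < 1e-12
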