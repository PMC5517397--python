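"""Digital-CGH copy-number detection.

The coverage ratio between a target sample (all-proper-pairs pileup) and
a simulated-coverage reference track is computed in 500-bp adjacent
windows, log2-transformed after per-track normalization, segmented by
circular binary segmentation (CBS) with a permutation test, and the
resulting segments classified as gain / loss / PAV / neutral.  PAV
(presence/absence variation) — reference covered, target empty — is
reported as a subtype of loss.

The CBS statistic is the standardized difference of means between an arc
of windows and its complement; a split is accepted when its permutation
p-value is at or below ``alpha``.  The permutation stream for a segment
is derived deterministically from (seed, segment offset, segment length),
so results are reproducible and independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from vitivar.io_formats import PileupTrack

DEFAULT_WINDOW = 500
DEFAULT_PSEUDOCOUNT = 0.5
#: log2(1.5): 1.5-fold change, the conventional single-copy cut at 2n
DEFAULT_GAIN_CUT = 0.58
DEFAULT_LOSS_CUT = -0.58
DEFAULT_MIN_LEN = 1000


@dataclass
class RatioProfile:
    chrom: str
    window_size: int
    window_starts: np.ndarray  # bp, per window
    window_ends: np.ndarray  # bp (last window may be short)
    target_mean_depth: np.ndarray
    reference_mean_depth: np.ndarray
    log2_ratio: np.ndarray
    zero_flag: np.ndarray  # target raw depth 0 while reference covered
    masked: np.ndarray  # reference raw depth 0: window unusable

    @property
    def n_windows(self) -> int:
        return int(self.log2_ratio.shape[0])


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    mean_log2_ratio: float
    n_windows: int
    class_: str = "neutral"
    p_value: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def bed_name(self) -> str:
        return self.class_


def ratio_profile(
    target: Mapping[str, PileupTrack],
    reference: Mapping[str, PileupTrack],
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, RatioProfile]:
    """Windowed normalized log2 coverage ratio, target over reference.

    Each track is normalized by its own genome-wide mean depth before the
    ratio ("digital CGH"), so tracks of different sequencing depth are
    comparable.  A pseudocount stabilizes near-empty windows; zero-flag
    and mask use the raw (pre-pseudocount) depths.
    """
    if set(target) != set(reference):
        raise ValueError("target and reference cover different chromosomes")
    t_mean = _genome_mean(target.values())
    r_mean = _genome_mean(reference.values())
    if t_mean == 0 or r_mean == 0:
        raise ValueError("track with zero genome-wide mean depth")
    profiles = {}
    for chrom in target:
        t_depth = target[chrom].depth
        r_depth = reference[chrom].depth
        if t_depth.shape != r_depth.shape:
            raise ValueError(f"track length mismatch on {chrom!r}")
        length = t_depth.shape[0]
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        if length % window:
            warnings.warn(
                f"{chrom}: final window short ({length % window} bp), kept",
                stacklevel=2,
            )
        t_win = np.add.reduceat(t_depth.astype(np.float64), starts) / (ends - starts)
        r_win = np.add.reduceat(r_depth.astype(np.float64), starts) / (ends - starts)
        log2 = np.log2(
            ((t_win + pseudocount) / t_mean) / ((r_win + pseudocount) / r_mean)
        )
        profiles[chrom] = RatioProfile(
            chrom=chrom,
            window_size=window,
            window_starts=starts,
            window_ends=ends,
            target_mean_depth=t_win,
            reference_mean_depth=r_win,
            log2_ratio=log2,
            zero_flag=(t_win == 0) & (r_win > 0),
            masked=(r_win == 0),
        )
    return profiles


def _genome_mean(tracks: Iterable[PileupTrack]) -> float:
    total = 0.0
    n = 0
    for t in tracks:
        total += float(t.depth.sum())
        n += t.depth.shape[0]
    return total / n if n else 0.0


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------


def _max_arc_stat(values: np.ndarray) -> tuple[float, int, int] | None:
    """Best (|t|, i, j) over all arcs [i, j); None if untestable."""
    n = values.shape[0]
    if n < 2:
        return None
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        return None
    prefix = np.concatenate(([0.0], np.cumsum(values)))
    total = prefix[-1]
    best = (-1.0, 0, 0)
    for k in range(1, n):
        inside = prefix[k:] - prefix[:-k]  # arc sums, start i = 0..n-k
        mean_in = inside / k
        mean_out = (total - inside) / (n - k)
        t = np.abs(mean_in - mean_out) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
        i = int(np.argmax(t))
        if t[i] > best[0]:
            best = (float(t[i]), i, i + k)
    return best


def _batch_max_stat(matrix: np.ndarray) -> np.ndarray:
    """Row-wise max arc statistic for a (m, n) batch of permuted values."""
    m, n = matrix.shape
    sd = matrix.std(axis=1, ddof=1)
    sd[sd == 0.0] = np.inf
    prefix = np.concatenate(
        (np.zeros((m, 1)), np.cumsum(matrix, axis=1)), axis=1
    )
    total = prefix[:, -1:]
    best = np.zeros(m)
    for k in range(1, n):
        inside = prefix[:, k:] - prefix[:, :-k]
        mean_in = inside / k
        mean_out = (total - inside) / (n - k)
        t = np.abs(mean_in - mean_out).max(axis=1) / np.sqrt(1.0 / k + 1.0 / (n - k))
        best = np.maximum(best, t)
    return best / sd


def _split_test(
    values: np.ndarray,
    offset: int,
    alpha: float,
    n_perm: int,
    seed: int,
    chunk: int = 100,
) -> tuple[int, int, float] | None:
    """Permutation-test the best arc of a segment; return (i, j, p) if accepted.

    The permutation stream is seeded from (seed, offset, len(values)), so a
    given segment is tested identically regardless of what happened
    elsewhere in the recursion, and decisions are monotone in ``alpha``.
    Evaluation stops early once the exceedance count guarantees p > alpha.
    """
    best = _max_arc_stat(values)
    if best is None:
        return None
    observed, i, j = best
    rng = np.random.default_rng([seed, offset, values.shape[0]])
    max_exceed = alpha * (1 + n_perm) - 1  # beyond this, p > alpha is certain
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        batch = np.stack([rng.permutation(values) for _ in range(m)])
        stats = _batch_max_stat(batch)
        exceed += int((stats >= observed - 1e-12).sum())
        done += m
        if exceed > max_exceed:
            return None
    p = (1 + exceed) / (1 + n_perm)
    if p <= alpha:
        return i, j, p
    return None


def cbs_segment(
    profile: RatioProfile,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[int], list[Segment]]:
    """Circular binary segmentation of one chromosome's ratio profile.

    Returns the accepted changepoints (window indices) and the maximal
    constant segments with their mean log2 ratios.  A split is accepted
    iff its permutation p-value ≤ ``alpha``; accepted halves are recursed
    into.  A constant or single-window profile yields one segment.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives poor p-value resolution", stacklevel=2
        )
    values = np.asarray(profile.log2_ratio, dtype=np.float64)
    n = values.shape[0]
    boundaries: list[tuple[int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        result = _split_test(values[lo:hi], lo, alpha, n_perm, seed)
        if result is None:
            return
        i, j, p = result
        cuts = [c for c in (lo + i, lo + j) if 0 < c < n and c not in (lo, hi)]
        for c in cuts:
            boundaries.append((c, p))
        pieces = sorted({lo, hi, *cuts})
        for a, b in zip(pieces, pieces[1:]):
            if b - a >= 2:
                recurse(a, b)

    if n >= 2:
        recurse(0, n)

    changepoints = sorted(c for c, _p in boundaries)
    p_at = dict(boundaries)
    edges = [0, *changepoints, n]
    segments = []
    for a, b in zip(edges, edges[1:]):
        segments.append(
            Segment(
                chrom=profile.chrom,
                start=int(profile.window_starts[a]),
                end=int(profile.window_ends[b - 1]),
                mean_log2_ratio=float(values[a:b].mean()),
                n_windows=b - a,
                p_value=min(p_at.get(a, 1.0), p_at.get(b, 1.0)) if changepoints else 1.0,
            )
        )
    return changepoints, segments


# ---------------------------------------------------------------------------
# classification and TE overlap
# ---------------------------------------------------------------------------


def classify_segments(
    segments: Sequence[Segment],
    profile: RatioProfile | None = None,
    gain_cut: float = DEFAULT_GAIN_CUT,
    loss_cut: float = DEFAULT_LOSS_CUT,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[Segment]:
    """Label segments gain / loss / PAV / neutral.

    A segment is PAV when it contains at least ``min_len`` bp of
    consecutive zero-flagged windows (reference covered, target empty);
    otherwise gain/loss by the mean log2 ratio against the cuts.  Calls
    shorter than ``min_len`` are left neutral (not retained as events).
    PAV is a loss subtype: losses = {loss, PAV}.
    """
    out = []
    for seg in segments:
        class_ = "neutral"
        if seg.length >= min_len:
            if profile is not None and _longest_zero_run_bp(profile, seg) >= min_len:
                class_ = "PAV"
            elif seg.mean_log2_ratio >= gain_cut:
                class_ = "gain"
            elif seg.mean_log2_ratio <= loss_cut:
                class_ = "loss"
        out.append(
            Segment(
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                mean_log2_ratio=seg.mean_log2_ratio,
                n_windows=seg.n_windows,
                class_=class_,
                p_value=seg.p_value,
            )
        )
    return out


def _longest_zero_run_bp(profile: RatioProfile, seg: Segment) -> int:
    sel = (profile.window_starts >= seg.start) & (profile.window_ends <= seg.end)
    flags = profile.zero_flag[sel]
    ends = profile.window_ends[sel]
    starts = profile.window_starts[sel]
    best = run = 0
    for f, s, e in zip(flags, starts, ends):
        run = run + (e - s) if f else 0
        best = max(best, run)
    return best


def te_overlap(
    segments: Sequence[Segment], te_intervals: Sequence[tuple[str, int, int]]
) -> dict[str, float]:
    """Fraction of called bp per class overlapped by transposable elements.

    Exact interval arithmetic: TE intervals are merged per chromosome, then
    (segment ∩ TE) bp is summed per class and divided by the class's total
    segment bp.
    """
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in sorted(
        (c, s, e) for c, s, e, *_ in (tuple(t) for t in te_intervals)
    ):
        runs = merged.setdefault(chrom, [])
        if runs and s <= runs[-1][1]:
            runs[-1] = (runs[-1][0], max(runs[-1][1], e))
        else:
            runs.append((s, e))
    totals: dict[str, int] = {}
    overlaps: dict[str, int] = {}
    for seg in segments:
        totals[seg.class_] = totals.get(seg.class_, 0) + seg.length
        ov = 0
        for s, e in merged.get(seg.chrom, []):
            lo, hi = max(s, seg.start), min(e, seg.end)
            if lo < hi:
                ov += hi - lo
        overlaps[seg.class_] = overlaps.get(seg.class_, 0) + ov
    return {
        class_: (overlaps[class_] / totals[class_] if totals[class_] else 0.0)
        for class_ in totals
    }
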