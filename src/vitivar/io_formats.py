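"""Formats and shared coordinate conventions.

Everything in memory is 0-based half-open.  VCF and GFF3 are 1-based
(GFF3 closed, VCF anchored); conversion happens here and only here.
Indel alleles follow VCF anchoring: the stored position is the base
preceding the event and ref/alt strings share that anchor base.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

_VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file; the message names the offending line/record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """One chromosome/contig of an assembly, uppercase over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("empty sequence name")
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A transcript: CDS and UTR intervals in transcription order.

    Intervals are (start, end) 0-based half-open genomic coordinates.
    For minus-strand models the lists run 3'→5' in genomic terms, i.e.
    the first interval is the transcription start.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    utr5_intervals: list[tuple[int, int]] = field(default_factory=list)
    utr3_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def is_complete(self) -> bool:
        return self.cds_length % 3 == 0

    def spliced_cds(self, assembly: Mapping[str, GenomeSequence]) -> str:
        """Concatenated CDS in translation order (reverse-complemented on −)."""
        chrom_seq = assembly[self.chrom].seq
        parts = [chrom_seq[s:e] for s, e in sorted(self.cds_intervals)]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass
class PileupTrack:
    """Per-position depth plus sparse non-reference allele observations.

    ``alleles[pos]`` maps an allele key to its observation count: a single
    base for a substitution, ``+SEQ`` for an insertion after ``pos`` and
    ``-SEQ`` for a deletion of SEQ starting at ``pos + 1`` (VCF anchoring).
    At every position the allele counts sum to at most ``depth[pos]``.
    """

    chrom: str
    depth: np.ndarray
    alleles: dict[int, dict[str, int]] = field(default_factory=dict)
    source: str = "unique_reads"

    @property
    def length(self) -> int:
        return int(self.depth.shape[0])

    def ref_count(self, pos: int) -> int:
        obs = self.alleles.get(pos)
        non_ref = sum(obs.values()) if obs else 0
        return int(self.depth[pos]) - non_ref


@dataclass(frozen=True)
class AlignedPair:
    """A mapped read pair, reduced to the evidence the pipeline consumes."""

    chrom: str
    pos1: int
    pos2: int
    unique: bool = True
    proper: bool = True

    def __post_init__(self) -> None:
        if self.pos1 > self.pos2:
            object.__setattr__(self, "pos1", self.pos2)
            object.__setattr__(self, "pos2", self.pos1)

    @property
    def distance(self) -> int:
        return self.pos2 - self.pos1


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, GenomeSequence]:
    """Read a FASTA file into an ordered {name: GenomeSequence} mapping."""
    sequences: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if not record.id:
            raise FormatError(f"{path}: record with empty header")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {record.id!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {record.id!r} contains invalid characters {sorted(bad)}"
            )
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate sequence name {record.id!r}")
        sequences[record.id] = GenomeSequence(record.id, seq)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return sequences


def write_fasta(sequences: Mapping[str, GenomeSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in sequences.values():
            fh.write(f">{seq.name}\n")
            for i in range(0, seq.length, width):
                fh.write(seq.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gff3_models(
    path: str | os.PathLike, assembly: Mapping[str, GenomeSequence]
) -> list[GeneModel]:
    """Read mRNA/CDS/UTR features into per-transcript GeneModels.

    CDS, five_prime_UTR and three_prime_UTR features are grouped by their
    ``Parent`` attribute.  Interval lists come back in transcription order
    and are validated against the assembly bounds.
    """
    transcripts: dict[str, GeneModel] = {}
    feature_map = {
        "CDS": "cds_intervals",
        "five_prime_UTR": "utr5_intervals",
        "three_prime_UTR": "utr3_intervals",
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype not in ("mRNA", "transcript") and ftype not in feature_map:
                continue
            try:
                start = int(start_s) - 1  # GFF3 is 1-based closed
                end = int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if chrom not in assembly:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > assembly[chrom].length or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: interval [{start_s},{end_s}] outside "
                    f"chromosome {chrom!r} bounds"
                )
            attrs = _parse_gff_attributes(attrs_s)
            if ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                if not tid:
                    raise FormatError(f"{path}:{lineno}: mRNA without ID attribute")
                transcripts.setdefault(tid, GeneModel(tid, chrom, strand))
            else:
                parent = attrs.get("Parent")
                if not parent:
                    raise FormatError(f"{path}:{lineno}: {ftype} without Parent attribute")
                for tid in parent.split(","):
                    model = transcripts.setdefault(tid, GeneModel(tid, chrom, strand))
                    if model.chrom != chrom:
                        raise FormatError(
                            f"{path}:{lineno}: transcript {tid!r} spans chromosomes"
                        )
                    getattr(model, feature_map[ftype]).append((start, end))
    for model in transcripts.values():
        reverse = model.strand == "-"
        for attr in ("cds_intervals", "utr5_intervals", "utr3_intervals"):
            ivals = sorted(getattr(model, attr))
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise FormatError(
                        f"{path}: transcript {model.gene_id!r} has overlapping "
                        f"{attr.split('_')[0].upper()} intervals"
                    )
            if reverse:
                ivals.reverse()
            setattr(model, attr, ivals)
    return list(transcripts.values())


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.split(";"):
        part = part.strip()
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


# ---------------------------------------------------------------------------
# alignments → pileup
# ---------------------------------------------------------------------------


def build_pileup(
    alignments: str | os.PathLike | Iterable,
    assembly: Mapping[str, GenomeSequence],
    source_mode: str = "unique_reads",
) -> dict[str, PileupTrack]:
    """Accumulate depth and allele counts from coordinate-sorted alignments.

    ``source_mode='unique_reads'`` keeps only unambiguously mapped reads
    (the variant-calling evidence); ``'all_proper_pairs'`` keeps every
    properly paired read (the coverage-analysis evidence).  Input is a SAM
    file path or an iterable of pysam AlignedSegment records.
    """
    import pysam

    if source_mode not in ("unique_reads", "all_proper_pairs"):
        raise ValueError(f"unknown source_mode {source_mode!r}")

    tracks = {
        name: PileupTrack(name, np.zeros(seq.length, dtype=np.int32), {}, source_mode)
        for name, seq in assembly.items()
    }

    if isinstance(alignments, (str, os.PathLike)):
        reader = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        records: Iterator = iter(reader)
    else:
        records = iter(alignments)

    last_pos: dict[str, int] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        chrom = rec.reference_name
        if chrom not in tracks:
            raise FormatError(f"alignment references unknown chromosome {chrom!r}")
        if rec.reference_start < last_pos.get(chrom, -1):
            raise FormatError("alignment input is not coordinate-sorted")
        last_pos[chrom] = rec.reference_start
        if source_mode == "unique_reads":
            try:
                unique = rec.get_tag("XT") == "U"
            except KeyError:
                unique = rec.mapping_quality > 0
            if not unique:
                continue
        else:
            if rec.is_paired and not rec.is_proper_pair:
                continue
        _accumulate_read(tracks[chrom], rec, assembly[chrom].seq)
    return tracks


def _accumulate_read(track: PileupTrack, rec, ref_seq: str) -> None:
    """Walk a read's CIGAR, adding depth, mismatches and anchored indels."""
    read_seq = rec.query_sequence or ""
    rpos = rec.reference_start
    qpos = 0
    depth = track.depth
    for op, length in rec.cigartuples or []:
        if op in (0, 7, 8):  # M / = / X
            depth[rpos : rpos + length] += 1
            for k in range(length):
                base = read_seq[qpos + k] if read_seq else "N"
                if base != "N" and base != ref_seq[rpos + k]:
                    _bump(track, rpos + k, base)
            rpos += length
            qpos += length
        elif op == 1:  # insertion; anchored to preceding ref base
            if rpos > 0:
                _bump(track, rpos - 1, "+" + read_seq[qpos : qpos + length])
            qpos += length
        elif op == 2:  # deletion; anchored to preceding ref base
            if rpos > 0:
                _bump(track, rpos - 1, "-" + ref_seq[rpos : rpos + length])
            rpos += length
        elif op == 3:  # N: skipped region
            rpos += length
        elif op in (4,):  # soft clip
            qpos += length
        # H/P consume nothing relevant


def _bump(track: PileupTrack, pos: int, allele: str) -> None:
    obs = track.alleles.setdefault(pos, {})
    obs[allele] = obs.get(allele, 0) + 1


# ---------------------------------------------------------------------------
# AlignedPair TSV dialect
# ---------------------------------------------------------------------------

_PAIR_HEADER = ["chrom", "pos1", "pos2", "unique", "proper"]


def write_pairs_tsv(pairs: Iterable[AlignedPair], path: str | os.PathLike) -> None:
    """Write pairs in the documented TSV dialect (see README)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_PAIR_HEADER) + "\n")
        for p in pairs:
            fh.write(f"{p.chrom}\t{p.pos1}\t{p.pos2}\t{int(p.unique)}\t{int(p.proper)}\n")


def read_pairs_tsv(path: str | os.PathLike) -> list[AlignedPair]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            chrom, pos1, pos2, unique, proper = fields
            pairs.append(
                AlignedPair(chrom, int(pos1), int(pos2), bool(int(unique)), bool(int(proper)))
            )
    return pairs


# ---------------------------------------------------------------------------
# pileup TSV (sparse allele observations + dense depth run-length encoded)
# ---------------------------------------------------------------------------


def write_pileup_tsv(tracks: Mapping[str, PileupTrack], path: str | os.PathLike) -> None:
    """Serialize pileup tracks: run-length depth lines and allele lines."""
    with open(path, "w") as fh:
        for track in tracks.values():
            fh.write(f"#chrom={track.chrom}\tlength={track.length}\tsource={track.source}\n")
            depth = track.depth
            boundaries = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(depth)]))
            for s, e in zip(starts, ends):
                fh.write(f"D\t{s}\t{e}\t{int(depth[s])}\n")
            for pos in sorted(track.alleles):
                for allele, count in sorted(track.alleles[pos].items()):
                    fh.write(f"A\t{pos}\t{allele}\t{count}\n")


def read_pileup_tsv(path: str | os.PathLike) -> dict[str, PileupTrack]:
    tracks: dict[str, PileupTrack] = {}
    current: PileupTrack | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#chrom="):
                meta = dict(part.split("=", 1) for part in line[1:].split("\t"))
                current = PileupTrack(
                    meta["chrom"],
                    np.zeros(int(meta["length"]), dtype=np.int32),
                    {},
                    meta.get("source", "unique_reads"),
                )
                tracks[meta["chrom"]] = current
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: data before track header")
            fields = line.split("\t")
            if fields[0] == "D":
                s, e, d = int(fields[1]), int(fields[2]), int(fields[3])
                current.depth[s:e] = d
            elif fields[0] == "A":
                pos, allele, count = int(fields[1]), fields[2], int(fields[3])
                current.alleles.setdefault(pos, {})[allele] = count
            else:
                raise FormatError(f"{path}:{lineno}: unknown record type {fields[0]!r}")
    return tracks


# ---------------------------------------------------------------------------
# VCF / BED output
# ---------------------------------------------------------------------------


def write_vcf(
    calls: Sequence,
    path: str | os.PathLike,
    sample_name: str = "SAMPLE",
    assembly: Mapping[str, GenomeSequence] | None = None,
) -> None:
    """Write SNP/indel calls as VCF 4.2 (1-based; GT + AF/PV in INFO)."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if assembly:
            for seq in assembly.values():
                fh.write(f"##contig=<ID={seq.name},length={seq.length}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=PV,Number=1,Type=Float,Description="Variant p-value">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name + "\n"
        )
        for c in calls:
            if c.pos < 0:
                raise ValueError(f"negative coordinate in call at {c.chrom}:{c.pos}")
            gt = "1/1" if c.zygosity == "hom" else "0/1"
            info = f"AF={c.allele_freq:.6g};PV={c.p_value:.6g};DP={c.depth}"
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\tPASS\t"
                f"{info}\tGT\t{gt}\n"
            )


def read_vcf_calls(path: str | os.PathLike) -> list:
    """Read back VCF written by :func:`write_vcf` (round-trip support)."""
    from vitivar.variant_calling import VariantCall

    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt = fields[:5]
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            gt = fields[9] if len(fields) > 9 else "0/1"
            if len(ref) == len(alt) == 1:
                kind = "SNP"
            elif len(alt) > len(ref):
                kind = "insertion"
            else:
                kind = "deletion"
            depth = int(info.get("DP", 0))
            af = float(info.get("AF", 0.0))
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=int(pos) - 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    kind=kind,
                    zygosity="hom" if gt == "1/1" else "het",
                    depth=depth,
                    alt_count=int(round(af * depth)),
                    p_value=float(info.get("PV", 1.0)),
                )
            )
    return calls


def write_bed(
    intervals: Sequence[tuple[str, int, int, str]] | Sequence,
    path: str | os.PathLike,
    score_of=None,
) -> None:
    """Write intervals as BED (0-based half-open) with a class name field.

    Accepts either (chrom, start, end, name) tuples or objects with
    ``chrom``/``start``/``end`` attributes plus a ``name`` attribute or
    BED-class property.
    """
    rows = []
    for item in intervals:
        if isinstance(item, tuple):
            chrom, start, end, name = item[:4]
            score = item[4] if len(item) > 4 else 0
        else:
            chrom, start, end = item.chrom, item.start, item.end
            name = getattr(item, "bed_name", None) or getattr(item, "name", ".")
            score = score_of(item) if score_of else 0
        if start < 0:
            raise ValueError(f"negative coordinate {chrom}:{start}")
        rows.append((chrom, int(start), int(end), str(name), score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t.\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            name = fields[3] if len(fields) > 3 else "."
            out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out
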