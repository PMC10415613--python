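"""Splice-junction discovery and I/O.

A junction is one intron call: ``(chrom, start, end, strand)`` where *start*
and *end* are the 1-based first and last intronic base (STAR ``SJ.out.tab``
convention — the same convention the junction-ID notation
``chrN:start-end(strand)`` uses).  Junctions carry per-sample supporting read
counts; a read supports a junction once per distinct N-gap in its CIGAR,
provided both flanking aligned blocks span at least ``min_anchor`` reference
bases.

Strand is taken from the aligner's strand attribute (``XS`` tag) when
present; otherwise, when a genome is supplied, it is inferred from the intron
boundary dinucleotides (GT..AG -> ``+``, CT..AC -> ``-``); otherwise it is
``.`` (unknown).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional

import pysam

__all__ = [
    "Junction",
    "SampleMeta",
    "JunctionError",
    "extract_junctions",
    "read_sj_table",
    "write_junction_table",
    "read_junction_table",
    "format_junction_id",
    "parse_junction_id",
    "junctions_to_bed",
]

CANONICAL_MOTIFS = {"GT-AG": "+", "CT-AC": "-"}

#: STAR SJ.out.tab motif codes.
_SJ_MOTIF = {0: "other", 1: "GT-AG", 2: "CT-AC", 3: "GC-AG", 4: "CT-GC", 5: "AT-AC", 6: "GT-AT"}
_SJ_MOTIF_INV = {v: k for k, v in _SJ_MOTIF.items()}
_SJ_STRAND = {0: ".", 1: "+", 2: "-"}
_SJ_STRAND_INV = {".": 0, "+": 1, "-": 2}


class JunctionError(ValueError):
    """Raised on malformed junction records, IDs, or alignment input."""


@dataclass
class Junction:
    """One intron call with per-sample supporting read counts.

    Identity is ``(chrom, start, end, strand)``; ``counts`` maps
    sample-id -> non-negative read count.
    """

    chrom: str
    start: int  # 1-based first intronic base
    end: int  # 1-based last intronic base
    strand: str = "."
    motif: str = "other"
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise JunctionError(
                f"junction start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise JunctionError(f"invalid strand {self.strand!r}")
        for sample, n in self.counts.items():
            if n < 0:
                raise JunctionError(f"negative count for sample {sample!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def junction_id(self) -> str:
        return format_junction_id(self)

    def total_count(self) -> int:
        return sum(self.counts.values())

    def donor(self) -> int:
        """Genomic coordinate of the intron base adjacent to the donor exon."""
        return self.start if self.strand != "-" else self.end

    def acceptor(self) -> int:
        """Genomic coordinate of the intron base adjacent to the acceptor exon."""
        return self.end if self.strand != "-" else self.start


@dataclass
class SampleMeta:
    """Per-sample metadata: group label, optional mutation CCF, blacklist flags.

    CCF is the cancer-cell fraction carrying the mutation, on a 0-100 scale.
    """

    sample_id: str
    group: str
    ccf: Optional[float] = None
    excluded_gene: bool = False

    def __post_init__(self) -> None:
        if self.ccf is not None and not 0 <= self.ccf <= 100:
            raise ValueError(f"CCF out of [0, 100]: {self.ccf}")


_JUNCTION_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+\-.])\)$")


def format_junction_id(junction: Junction) -> str:
    """Render the ``chrN:start-end(strand)`` junction identifier."""
    return f"{junction.chrom}:{junction.start}-{junction.end}({junction.strand})"


def parse_junction_id(text: str) -> tuple:
    """Parse ``chrN:start-end(strand)`` into ``(chrom, start, end, strand)``."""
    m = _JUNCTION_ID_RE.match(text.strip())
    if m is None:
        raise JunctionError(f"malformed junction ID: {text!r}")
    return (m["chrom"], int(m["start"]), int(m["end"]), m["strand"])


def _intron_motif(genome, chrom: str, start: int, end: int) -> str:
    """Donor/acceptor dinucleotide pair from 1-based inclusive intron bounds."""
    donor = str(genome[chrom][start - 1 : start + 1]).upper()
    acceptor = str(genome[chrom][end - 2 : end]).upper()
    pair = f"{donor}-{acceptor}"
    return pair if pair in _SJ_MOTIF_INV else "other"


def _infer_strand(motif: str) -> str:
    if motif in ("GT-AG", "GC-AG", "AT-AC"):
        return "+"
    if motif in ("CT-AC", "CT-GC", "GT-AT"):
        return "-"
    return "."


def _read_gaps(read: pysam.AlignedSegment) -> Iterator[tuple]:
    """Yield ``(intron_start, intron_end, left_anchor, right_anchor)`` per N gap.

    Coordinates are 1-based inclusive intron bounds.  Anchors are the number
    of reference bases consumed by aligned blocks between this gap and the
    nearest read end or neighbouring gap.
    """
    cigar = read.cigartuples
    if cigar is None:
        raise JunctionError(f"read {read.query_name!r} lacks a CIGAR")
    # Split into segments between N operations, tracking reference extent.
    ref_pos = read.reference_start  # 0-based
    segment_ref = 0  # reference bases aligned in the current segment
    segments = []  # aligned ref-lengths between gaps
    gaps = []  # (start0, length)
    for op, length in cigar:
        if op == 3:  # N
            gaps.append((ref_pos, length))
            segments.append(segment_ref)
            segment_ref = 0
            ref_pos += length
        elif op in (0, 2, 7, 8):  # M, D, =, X consume reference
            ref_pos += length
            segment_ref += length
        elif op in (1, 4, 5, 6):  # I, S, H, P do not consume reference
            continue
        else:
            raise JunctionError(f"read {read.query_name!r}: unsupported CIGAR op {op}")
    segments.append(segment_ref)
    for i, (gap_start0, gap_len) in enumerate(gaps):
        yield (gap_start0 + 1, gap_start0 + gap_len, segments[i], segments[i + 1])


def extract_junctions(
    alignments: Iterable[pysam.AlignedSegment],
    sample_id: str,
    min_anchor: int = 8,
    min_mapq: int = 0,
    genome=None,
    require_unique: bool = False,
) -> Dict[tuple, Junction]:
    """Extract junctions with counts for one sample from spliced alignments.

    Each distinct N gap of each read contributes at most one count to its
    junction; a read must anchor the gap with ``>= min_anchor`` aligned
    reference bases on both sides.  ``genome`` (a mapping of chrom -> sequence
    supporting slicing, e.g. :class:`pyfaidx.Fasta`) enables motif lookup and
    motif-based strand inference for reads without an ``XS`` tag.

    Returns a dict keyed by ``(chrom, start, end, strand)``.
    """
    out: Dict[tuple, Junction] = {}
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if require_unique and read.has_tag("NH") and read.get_tag("NH") > 1:
            continue
        chrom = read.reference_name
        xs = read.get_tag("XS") if read.has_tag("XS") else None
        for start, end, left, right in _read_gaps(read):
            if left < min_anchor or right < min_anchor:
                continue
            motif = _intron_motif(genome, chrom, start, end) if genome is not None else "other"
            if xs in ("+", "-"):
                strand = xs
            else:
                strand = _infer_strand(motif)
            key = (chrom, start, end, strand)
            junc = out.get(key)
            if junc is None:
                junc = Junction(chrom, start, end, strand, motif, {sample_id: 0})
                out[key] = junc
            junc.counts[sample_id] = junc.counts.get(sample_id, 0) + 1
    return out


def extract_junctions_from_sam(
    path: str,
    sample_id: str,
    min_anchor: int = 8,
    min_mapq: int = 0,
    genome=None,
    require_unique: bool = False,
) -> Dict[tuple, Junction]:
    """Open a SAM/BAM file and run :func:`extract_junctions` over it."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return extract_junctions(
            fh, sample_id, min_anchor=min_anchor, min_mapq=min_mapq, genome=genome,
            require_unique=require_unique,
        )


def read_sj_table(path: str, sample_id: str, include_multimappers: bool = False) -> Dict[tuple, Junction]:
    """Read a STAR-style ``SJ.out.tab`` junction table for one sample.

    Columns: chrom, intron start, intron end, strand code (0/1/2), motif code
    (0-6), annotated flag, unique-read count, multi-read count, max overhang.
    Unique-read counts are used unless ``include_multimappers`` is set.
    """
    out: Dict[tuple, Junction] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise JunctionError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            strand = _SJ_STRAND[int(fields[3])]
            motif = _SJ_MOTIF[int(fields[4])]
            count = int(fields[6])
            if include_multimappers:
                count += int(fields[7])
            junc = Junction(chrom, start, end, strand, motif, {sample_id: count})
            out[junc.key] = junc
    return out


def merge_junctions(per_sample: Mapping[str, Mapping[tuple, Junction]]) -> Dict[tuple, Junction]:
    """Merge per-sample junction dicts into one multi-sample junction set."""
    merged: Dict[tuple, Junction] = {}
    for sample_maps in per_sample.values():
        for key, junc in sample_maps.items():
            tgt = merged.get(key)
            if tgt is None:
                tgt = Junction(junc.chrom, junc.start, junc.end, junc.strand, junc.motif, {})
                merged[key] = tgt
            for sample, n in junc.counts.items():
                tgt.counts[sample] = tgt.counts.get(sample, 0) + n
    return merged


def write_junction_table(junctions: Iterable[Junction], path: str, samples: Optional[list] = None) -> None:
    """Write the multi-sample junction TSV (one count column per sample)."""
    juncs = sorted(junctions, key=lambda j: j.key)
    if samples is None:
        samples = sorted({s for j in juncs for s in j.counts})
    with open(path, "w") as fh:
        fh.write("junction_id\tchrom\tstart\tend\tstrand\tmotif\t" + "\t".join(samples) + "\n")
        for j in juncs:
            counts = "\t".join(str(j.counts.get(s, 0)) for s in samples)
            fh.write(f"{j.junction_id}\t{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{j.motif}\t{counts}\n")


def read_junction_table(path: str) -> Dict[tuple, Junction]:
    """Read the TSV written by :func:`write_junction_table` (exact inverse)."""
    out: Dict[tuple, Junction] = {}
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            line = fh.readline()
        header = line.rstrip("\n").split("\t")
        if header[:6] != ["junction_id", "chrom", "start", "end", "strand", "motif"]:
            raise JunctionError(f"{path}: unrecognized junction-table header")
        samples = header[6:]
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6 + len(samples):
                raise JunctionError(f"{path}:{lineno}: column count mismatch")
            junc = Junction(
                fields[1], int(fields[2]), int(fields[3]), fields[4], fields[5],
                {s: int(c) for s, c in zip(samples, fields[6:])},
            )
            out[junc.key] = junc
    return out


def junctions_to_bed(junctions: Iterable[Junction], path: str) -> None:
    """Export junctions as BED6 intervals (0-based half-open introns)."""
    with open(path, "w") as fh:
        for j in sorted(junctions, key=lambda j: j.key):
            fh.write(
                f"{j.chrom}\t{j.start - 1}\t{j.end}\t{j.junction_id}\t{j.total_count()}\t"
                f"{j.strand if j.strand != '.' else '.'}\n"
            )
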