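"""ORF-impact prediction for alternative 3' splice-site events.

An Alt3'ss event moves one intron's acceptor by a signed transcript-
orientation offset ``d`` (negative = upstream), inserting ``|d|`` formerly
intronic bases into the mRNA (d < 0) or removing ``d`` exonic bases
(d > 0).  The consequence on the transcript's reading frame is classified
as:

* ``UTR`` — the changed bases lie entirely in an untranslated region;
* ``ORF-preserving`` — in-frame change introducing no premature stop (or a
  stop shortening the protein by fewer than 100 aa without triggering NMD);
* ``ORF-disrupting`` with mechanism ``frameshift`` (net coding-length change
  not divisible by 3), ``PTC-NMD`` (new in-frame stop more than 50 nt
  upstream of the last exon-exon junction, the classical NMD rule) or
  ``truncation`` (in-frame stop shortening the protein by >= 100 aa without
  NMD);
* ``unknown`` — missing CDS annotation or sequence.

When both the NMD and the truncation rule fire, the call reports PTC-NMD
(mechanism precedence) and keeps both flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "ImpactCall",
    "load_transcripts",
    "map_event_to_transcript",
    "apply_acceptor_shift",
    "predict_impact",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    """A transcript: ordered exons, optional CDS bounds, genomic sequence.

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order (non-overlapping); ``cds_start``/``cds_end`` are the genomic min /
    max of the coding region.  ``genome`` maps chrom -> sliceable sequence
    (e.g. a :class:`pyfaidx.Fasta` or a plain dict of strings).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    genome: Optional[object] = None

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.transcript_id}: overlapping or unordered exons")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS annotation")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def introns(self) -> List[Tuple[int, int]]:
        """1-based inclusive intron intervals, ascending genomic order."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def _fetch(self, start: int, end: int) -> str:
        return str(self.genome[self.chrom][start - 1 : end]).upper()

    def mature_sequence(self) -> str:
        """Spliced mRNA sequence in transcript (5'->3') orientation."""
        seq = "".join(self._fetch(s, e) for s, e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def mrna_index(self, genomic_pos: int) -> int:
        """0-based mRNA index of an exonic genomic position."""
        offset = 0
        for s, e in self.exons:
            if s <= genomic_pos <= e:
                idx = offset + (genomic_pos - s)
                break
            offset += e - s + 1
        else:
            raise ValueError(f"position {genomic_pos} is not exonic in {self.transcript_id}")
        if self.strand == "-":
            total = sum(e - s + 1 for s, e in self.exons)
            idx = total - 1 - idx
        return idx

    def last_junction_index(self) -> Optional[int]:
        """mRNA index of the first base of the 3'-most exon (None if single-exon)."""
        if len(self.exons) < 2:
            return None
        lengths = [e - s + 1 for s, e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        return sum(lengths[:-1])

    def cds_interval_mrna(self) -> Tuple[int, int]:
        """0-based half-open CDS interval on the mRNA."""
        if not self.has_cds:
            raise ValueError(f"{self.transcript_id}: no CDS annotation")
        a = self.mrna_index(self.cds_start)
        b = self.mrna_index(self.cds_end)
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1


@dataclass
class ImpactCall:
    """ORF consequence of one event on one transcript."""

    category: str  # UTR | ORF-preserving | ORF-disrupting | unknown
    mechanism: Optional[str] = None  # frameshift | PTC-NMD | truncation
    net_change_nt: int = 0
    ptc_mrna_index: Optional[int] = None
    distance_to_last_junction: Optional[int] = None
    nmd_flag: bool = False
    truncation_flag: bool = False
    reason: Optional[str] = None


def load_transcripts(gtf_path: str, genome=None) -> Dict[str, TranscriptModel]:
    """Load transcript models from a GTF file (exon + CDS features)."""
    import gffutils

    db = gffutils.create_db(
        gtf_path, ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    models: Dict[str, TranscriptModel] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        meta[tid] = (feat.seqid, feat.strand)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(
            (feat.start, feat.end)
        )
    for tid, ex in exons.items():
        chrom, strand = meta[tid]
        cd = cds.get(tid)
        models[tid] = TranscriptModel(
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            exons=ex,
            cds_start=min(s for s, _ in cd) if cd else None,
            cds_end=max(e for _, e in cd) if cd else None,
            genome=genome,
        )
    return models


def _changed_interval(model: TranscriptModel, intron_index: int, d: int) -> Tuple[int, int]:
    """Genomic 1-based inclusive interval of the bases inserted or removed."""
    start, end = model.introns()[intron_index]
    if model.strand == "-":
        c = start
        a = c - d
    else:
        c = end
        a = c + d
    if model.strand == "-":
        return (min(a, c), max(a, c) - 1)
    return (min(a, c) + 1, max(a, c))


def map_event_to_transcript(
    model: TranscriptModel, intron_index: int, d: int
) -> str:
    """Region of the exonic segment an acceptor shift affects.

    Returns one of ``5'UTR``, ``CDS``, ``3'UTR`` or ``outside``; transcripts
    without CDS annotation return ``unknown``.
    """
    if intron_index < 0 or intron_index >= len(model.exons) - 1:
        return "outside"
    if not model.has_cds:
        return "unknown"
    lo, hi = _changed_interval(model, intron_index, d)
    if hi < model.exons[0][0] or lo > model.exons[-1][1]:
        return "outside"
    if hi < model.cds_start:
        return "5'UTR" if model.strand == "+" else "3'UTR"
    if lo > model.cds_end:
        return "3'UTR" if model.strand == "+" else "5'UTR"
    return "CDS"


def apply_acceptor_shift(
    model: TranscriptModel, intron_index: int, d: int
) -> TranscriptModel:
    """New transcript model with intron ``intron_index``'s acceptor moved by ``d``.

    ``d`` is in transcript orientation (negative = upstream, which extends
    the acceptor exon into the intron).
    """
    if d == 0:
        raise ValueError("acceptor shift of zero")
    introns = model.introns()
    if not 0 <= intron_index < len(introns):
        raise IndexError(f"intron index {intron_index} out of range")
    exons = [list(e) for e in model.exons]
    start, end = introns[intron_index]
    if model.strand == "-":
        new_acceptor = start - d  # acceptor = intron genomic start
        new_end = new_acceptor - 1  # acceptor exon ends just before the intron
        if new_end <= exons[intron_index][0] or new_acceptor >= end:
            raise ValueError("acceptor shift escapes the intron/exon bounds")
        exons[intron_index][1] = new_end
    else:
        new_acceptor = end + d
        new_start = new_acceptor + 1
        if new_start >= exons[intron_index + 1][1] or new_acceptor <= start:
            raise ValueError("acceptor shift escapes the intron/exon bounds")
        exons[intron_index + 1][0] = new_start
    return TranscriptModel(
        transcript_id=f"{model.transcript_id}|shift{d:+d}@i{intron_index}",
        chrom=model.chrom,
        strand=model.strand,
        exons=[tuple(e) for e in exons],
        cds_start=model.cds_start,
        cds_end=model.cds_end,
        genome=model.genome,
    )


def _first_stop(seq: str) -> Optional[int]:
    """Codon index of the first in-frame stop in ``seq`` (read from 0)."""
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i // 3
    return None


def predict_impact(
    model: TranscriptModel,
    intron_index: int,
    d: int,
    nmd_distance: int = 50,
    truncation_aa: int = 100,
) -> ImpactCall:
    """Classify the ORF consequence of moving one acceptor by ``d`` nt."""
    region = map_event_to_transcript(model, intron_index, d)
    if region == "unknown":
        return ImpactCall(category="unknown", reason="no-cds-annotation")
    if region == "outside":
        return ImpactCall(category="unknown", reason="event-outside-transcript")
    net = -d  # d < 0 inserts |d| exonic nt; d > 0 removes d nt
    if region in ("5'UTR", "3'UTR"):
        return ImpactCall(category="UTR", net_change_nt=net)
    if model.genome is None:
        return ImpactCall(category="unknown", reason="sequence-unavailable")

    # Reference protein length (aa, excluding the stop codon).
    cds_lo, cds_hi = model.cds_interval_mrna()
    ref_cds = model.mature_sequence()[cds_lo:cds_hi]
    ref_stop = _first_stop(ref_cds)
    ref_aa = ref_stop if ref_stop is not None else len(ref_cds) // 3

    shifted = apply_acceptor_shift(model, intron_index, d)
    mrna = shifted.mature_sequence()
    # CDS start (first base of the start codon) is upstream of the event and
    # retains its genomic coordinate.
    start_genomic = model.cds_start if model.strand == "+" else model.cds_end
    try:
        start_idx = shifted.mrna_index(start_genomic)
    except ValueError:
        return ImpactCall(category="unknown", reason="start-codon-lost", net_change_nt=net)

    if net % 3 != 0:
        return ImpactCall(
            category="ORF-disrupting", mechanism="frameshift", net_change_nt=net
        )

    coding = mrna[start_idx:]
    stop_codon = _first_stop(coding)
    if stop_codon is None:
        return ImpactCall(category="unknown", reason="no-stop-codon", net_change_nt=net)
    new_aa = stop_codon
    stop_end_idx = start_idx + stop_codon * 3 + 3  # mRNA index just past the stop

    last_junction = shifted.last_junction_index()
    dist = None if last_junction is None else last_junction - stop_end_idx
    nmd = dist is not None and dist > nmd_distance and new_aa < ref_aa
    truncated = (ref_aa - new_aa) >= truncation_aa

    if new_aa >= ref_aa:
        return ImpactCall(category="ORF-preserving", net_change_nt=net)
    if nmd:
        return ImpactCall(
            category="ORF-disrupting",
            mechanism="PTC-NMD",
            net_change_nt=net,
            ptc_mrna_index=stop_end_idx - 3,
            distance_to_last_junction=dist,
            nmd_flag=True,
            truncation_flag=truncated,
        )
    if truncated:
        return ImpactCall(
            category="ORF-disrupting",
            mechanism="truncation",
            net_change_nt=net,
            ptc_mrna_index=stop_end_idx - 3,
            distance_to_last_junction=dist,
            truncation_flag=True,
        )
    return ImpactCall(
        category="ORF-preserving",
        net_change_nt=net,
        ptc_mrna_index=stop_end_idx - 3,
        distance_to_last_junction=dist,
    )


def most_severe(calls: Sequence[ImpactCall]) -> ImpactCall:
    """Gene-level summary: the most severe per-transcript call."""
    severity = {"ORF-disrupting": 3, "ORF-preserving": 2, "UTR": 1, "unknown": 0}
    return max(calls, key=lambda c: severity.get(c.category, 0))
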