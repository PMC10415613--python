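"""Ground-truth simulator: toy genomes, annotations, junction counts, reads.

Each simulated gene carries one *event intron* with a strong canonical AG
acceptor (planted branch point, polypyrimidine tract and consensus acceptor
context) plus one cryptic AG acceptor at a configurable signed distance —
by default drawn uniformly from 10-30 nt upstream of the canonical 3'ss,
the regime characteristic of branch-point-factor hotspot mutations.  The
reference ("WT") group uses the cryptic acceptor at a low true PSI (~2) and
the contrast ("MUT") group at an elevated PSI (true dPSI 30-60), or equal
PSI under the null.  Genes cycle through explicitly constructed ORF
consequences (frameshift / preserving / PTC-NMD / truncation / UTR) so
impact prediction can be scored against truth.

Per sample, the event intron's total junction coverage is drawn from a
negative binomial (Poisson in the large-dispersion limit) and split between
the acceptors by a multinomial at the group's true PSI.  Emitted SAM reads
reproduce the simulated counts exactly at the configured anchor geometry;
sub-anchor distractor reads and unspliced filler reads are added and must
not produce junction counts.  All outputs are a pure function of the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .junctions import Junction

__all__ = [
    "SimConfig",
    "GeneTruth",
    "TruthTable",
    "make_genome_annotation",
    "simulate_counts",
    "simulate_reads",
    "write_fasta",
    "write_gtf",
]

STOPS = {"TAA", "TAG", "TGA"}
SAFE_CODONS = ("GCT", "GGA", "CTT", "ACC", "GAT", "TCA", "AAC", "CCG")
ORF_CLASSES = ("frameshift", "preserving", "ptc-nmd", "truncation", "utr")

EXON1_LEN = 120
CDS_OFFSET = 30  # ATG position within exon 1
EVENT_INTRON_LEN = 300
PLAIN_INTRON_LEN = 150
SPACER_LEN = 200


@dataclass
class SimConfig:
    """All knobs of the simulator; the seed fully determines every output."""

    seed: int = 0
    n_genes: int = 20
    chrom: str = "chrS1"
    n_replicates: Tuple[int, int] = (3, 3)  # (reference, contrast)
    group_labels: Tuple[str, str] = ("WT", "MUT")
    coverage_mean: float = 100.0
    coverage_dispersion: float = 10.0  # NB size parameter; large -> Poisson
    cryptic_ref_psi: float = 2.0  # true cryptic PSI (0-100) in the reference
    dpsi_range: Tuple[float, float] = (30.0, 60.0)
    null: bool = False  # contrast PSI equals reference PSI (no true change)
    #: (weight, low, high) components for the cryptic signed distance (nt)
    distance_components: Tuple[Tuple[float, int, int], ...] = ((1.0, -30, -10),)
    in_frame_distance: int = -21  # used by the mult-of-3 ORF classes
    intron_gc: float = 0.45
    exon_gc: float = 0.50
    read_len: int = 100
    anchor: int = 50  # aligned block length flanking each gap in emitted reads
    emit_xs: bool = True  # write the aligner strand attribute on reads
    n_filler_reads: int = 30
    n_subanchor_reads: int = 2  # per gene: distractor reads below the anchor
    max_multigap_reads: int = 3  # per 3-exon gene: reads spanning two introns

    def digest(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class GeneTruth:
    """Everything true about one simulated gene."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based genomic gene span
    end: int
    exons: List[Tuple[int, int]]  # genomic, ascending
    cds_start: int
    cds_end: int
    event_intron_index: int  # index into the transcript's intron list (genomic order)
    canonical_junction: Tuple[int, int]  # genomic 1-based inclusive intron
    cryptic_junction: Tuple[int, int]
    canonical_acceptor: int
    cryptic_acceptor: int
    distance: int  # signed, transcript orientation (negative = upstream)
    orf_class: str
    bp_distance: int  # planted branch A to canonical 3'ss, nt
    ref_psi: float  # true cryptic PSI per group (0-100)
    mut_psi: float
    other_introns: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class TruthTable:
    config: SimConfig
    genome: Dict[str, str]
    genes: List[GeneTruth]
    samples: Dict[str, str]  # sample id -> group label

    def annotated_introns(self) -> List[tuple]:
        """Canonical introns (the annotation; cryptic junctions are de novo)."""
        out = []
        for g in self.genes:
            out.append((g.chrom, *g.canonical_junction, g.strand))
            for s, e in g.other_introns:
                out.append((g.chrom, s, e, g.strand))
        return out


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> List[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _coding_block(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(SAFE_CODONS) for _ in range(n_codons))


def _sample_distance(rng: np.random.Generator, cfg: SimConfig) -> int:
    weights = np.array([w for w, _, _ in cfg.distance_components], dtype=float)
    weights /= weights.sum()
    k = rng.choice(len(weights), p=weights)
    _, lo, hi = cfg.distance_components[k]
    d = int(rng.integers(lo, hi + 1))
    return d if d != 0 else (1 if hi > 0 else -1)


def _event_intron(
    rng: np.random.Generator, cfg: SimConfig, d: int, stop_codon_index: Optional[int]
) -> Tuple[List[str], int]:
    """Build the event intron (transcript orientation) with planted motifs.

    Returns (sequence chars, branch-point distance).  ``d`` must be negative
    (cryptic acceptor inside the intron); ``stop_codon_index``, when set,
    plants TAA at that codon of the exonic insert the cryptic acceptor
    creates (codon 0 = first codon of the insert).
    """
    L = EVENT_INTRON_LEN
    seq = _rand_seq(rng, L, cfg.intron_gc)
    seq[0:6] = list("GTAAGT")  # donor consensus
    bp_dist = min(max(25, 4 - d), 44)
    # cryptic acceptor G at distance 1-d, A at 2-d
    crypt_dists = {1 - d, 2 - d}
    hept_span = set(range(bp_dist - 1, bp_dist + 6))
    if hept_span & crypt_dists:
        raise ValueError(
            f"cryptic distance {d} collides with the planted branch point at {bp_dist}"
        )
    i_a = L - bp_dist  # index of the branch A
    seq[i_a - 5 : i_a + 2] = list("TACTAAC")
    # polypyrimidine tract between the branch point and the acceptor AG
    py = rng.choice(["T", "C"], size=L - 3 - (i_a + 2), p=[0.7, 0.3])
    seq[i_a + 2 : L - 3] = list(py)
    seq[L - 3 :] = list("CAG")  # canonical acceptor
    # cryptic AG: G at index L-1+d, A at L-2+d (both intronic since d < 0)
    seq[L - 2 + d] = "A"
    seq[L - 1 + d] = "G"
    if stop_codon_index is not None:
        # the insert spans indices L+d .. L-1; plant TAA at the given codon
        j = L + d + 3 * stop_codon_index
        seq[j : j + 3] = list("TAA")
    return seq, bp_dist


def _plain_intron(rng: np.random.Generator, cfg: SimConfig) -> List[str]:
    L = PLAIN_INTRON_LEN
    seq = _rand_seq(rng, L, cfg.intron_gc)
    seq[0:6] = list("GTAAGT")
    i_a = L - 25
    seq[i_a - 5 : i_a + 2] = list("TACTAAC")
    py = rng.choice(["T", "C"], size=L - 3 - (i_a + 2), p=[0.7, 0.3])
    seq[i_a + 2 : L - 3] = list(py)
    seq[L - 3 :] = list("CAG")
    return seq


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _build_gene(
    rng: np.random.Generator, cfg: SimConfig, gene_index: int
) -> Tuple[str, dict]:
    """Construct one gene's transcript-orientation sequence and local layout."""
    orf_class = ORF_CLASSES[gene_index % len(ORF_CLASSES)]
    if orf_class == "frameshift":
        d = _sample_distance(rng, cfg)
        if d > 0:
            d = -d  # keep the cryptic acceptor intronic for constructed genes
        if d % 3 == 0:
            d = d + 1 if d + 1 != 0 else d - 1
    else:
        d = cfg.in_frame_distance
        if d >= 0 or d % 3 != 0:
            raise ValueError("in_frame_distance must be negative and divisible by 3")

    stop_idx = 2 if orf_class in ("ptc-nmd", "truncation") else None

    # exon 1: UTR filler + ATG + safe codons, ending CAG to complete the donor
    utr5 = "".join(_rand_seq(rng, CDS_OFFSET, cfg.exon_gc))
    coding1 = "ATG" + _coding_block(rng, (EXON1_LEN - CDS_OFFSET) // 3 - 2) + "CAG"
    exon1 = utr5 + coding1
    assert len(exon1) == EXON1_LEN

    pieces: List[str] = [exon1]
    local_exons: List[Tuple[int, int]] = [(0, EXON1_LEN - 1)]
    local_introns: List[Tuple[int, int]] = []
    pos = EXON1_LEN

    def add_intron(chars: List[str]) -> None:
        nonlocal pos
        pieces.append("".join(chars))
        local_introns.append((pos, pos + len(chars) - 1))
        pos += len(chars)

    def add_exon(seq: str) -> None:
        nonlocal pos
        pieces.append(seq)
        local_exons.append((pos, pos + len(seq) - 1))
        pos += len(seq)

    if orf_class in ("frameshift", "preserving", "truncation"):
        event_chars, bp_dist = _event_intron(rng, cfg, d, stop_idx)
        add_intron(event_chars)
        event_intron_local = local_introns[-1]
        coding2_len = 330 if orf_class == "truncation" else 120
        exon2 = _coding_block(rng, coding2_len // 3) + "TAA" + "".join(
            _rand_seq(rng, 80, cfg.exon_gc)
        )
        add_exon(exon2)
        cds_end_local = local_exons[-1][0] + coding2_len + 2  # last base of TAA
        event_index = 0
    elif orf_class == "ptc-nmd":
        event_chars, bp_dist = _event_intron(rng, cfg, d, stop_idx)
        add_intron(event_chars)
        event_intron_local = local_introns[-1]
        add_exon(_coding_block(rng, 67))  # 201 coding nt, frame flows through
        add_intron(_plain_intron(rng, cfg))
        exon3 = _coding_block(rng, 21) + "TAA" + "".join(_rand_seq(rng, 84, cfg.exon_gc))
        add_exon(exon3)
        cds_end_local = local_exons[-1][0] + 63 + 2
        event_index = 0
    else:  # utr: the event intron sits in the 3' UTR
        add_intron(_plain_intron(rng, cfg))
        exon2 = _coding_block(rng, 21) + "TAA" + "".join(_rand_seq(rng, 84, cfg.exon_gc))
        add_exon(exon2)
        cds_end_local = local_exons[-1][0] + 63 + 2
        event_chars, bp_dist = _event_intron(rng, cfg, d, None)
        add_intron(event_chars)
        event_intron_local = local_introns[-1]
        add_exon("".join(_rand_seq(rng, 150, cfg.exon_gc)))
        event_index = 1

    layout = {
        "orf_class": orf_class,
        "distance": d,
        "bp_distance": bp_dist,
        "local_exons": local_exons,
        "local_introns": local_introns,
        "event_intron_local": event_intron_local,
        "event_index": event_index,
        "cds_start_local": CDS_OFFSET,
        "cds_end_local": cds_end_local,
        "length": pos,
    }
    return "".join(pieces), layout


def make_genome_annotation(cfg: SimConfig) -> TruthTable:
    """Build the toy genome, transcript annotation and truth table.

    Deterministic: the same config (including seed) yields byte-identical
    sequences and coordinates.  Planted dinucleotides are verified against
    the assembled genome before returning.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_parts: List[str] = []
    genes: List[GeneTruth] = []
    offset = 0

    for gi in range(cfg.n_genes):
        spacer = "".join(_rand_seq(rng, SPACER_LEN, 0.5))
        chrom_parts.append(spacer)
        offset += SPACER_LEN
        strand = "+" if gi % 2 == 0 else "-"
        local_seq, lay = _build_gene(rng, cfg, gi)
        Lg = lay["length"]
        g0 = offset + 1  # 1-based genomic start of the gene

        def to_genomic(interval: Tuple[int, int]) -> Tuple[int, int]:
            ta, tb = interval
            if strand == "+":
                return (g0 + ta, g0 + tb)
            return (g0 + Lg - 1 - tb, g0 + Lg - 1 - ta)

        exons = sorted(to_genomic(e) for e in lay["local_exons"])
        introns_local = lay["local_introns"]
        event_local = lay["event_intron_local"]
        d = lay["distance"]
        canonical = to_genomic(event_local)
        cryptic_local = (event_local[0], event_local[1] + d)
        cryptic = to_genomic(cryptic_local)
        canonical_acceptor = canonical[1] if strand == "+" else canonical[0]
        cryptic_acceptor = cryptic[1] if strand == "+" else cryptic[0]
        cds_g = sorted(
            (
                (g0 + lay["cds_start_local"]) if strand == "+" else (g0 + Lg - 1 - lay["cds_start_local"]),
                (g0 + lay["cds_end_local"]) if strand == "+" else (g0 + Lg - 1 - lay["cds_end_local"]),
            )
        )
        other = sorted(
            to_genomic(iv) for iv in introns_local if iv != event_local
        )
        if cfg.null:
            ref_psi = mut_psi = cfg.cryptic_ref_psi
        else:
            ref_psi = cfg.cryptic_ref_psi
            mut_psi = ref_psi + float(rng.uniform(*cfg.dpsi_range))
        genes.append(
            GeneTruth(
                gene_id=f"gene{gi + 1:03d}",
                chrom=cfg.chrom,
                strand=strand,
                start=g0,
                end=g0 + Lg - 1,
                exons=exons,
                cds_start=cds_g[0],
                cds_end=cds_g[1],
                event_intron_index=[
                    i for i, iv in enumerate(sorted(to_genomic(x) for x in introns_local))
                    if iv == canonical
                ][0],
                canonical_junction=canonical,
                cryptic_junction=cryptic,
                canonical_acceptor=canonical_acceptor,
                cryptic_acceptor=cryptic_acceptor,
                distance=d,
                orf_class=lay["orf_class"],
                bp_distance=lay["bp_distance"],
                ref_psi=ref_psi,
                mut_psi=mut_psi,
                other_introns=other,
            )
        )
        chrom_parts.append(local_seq if strand == "+" else _revcomp(local_seq))
        offset += Lg

    chrom_parts.append("".join(_rand_seq(rng, SPACER_LEN, 0.5)))
    genome = {cfg.chrom: "".join(chrom_parts)}

    ref_n, mut_n = cfg.n_replicates
    samples = {f"{cfg.group_labels[0]}{i+1}": cfg.group_labels[0] for i in range(ref_n)}
    samples.update(
        {f"{cfg.group_labels[1]}{i+1}": cfg.group_labels[1] for i in range(mut_n)}
    )
    truth = TruthTable(config=cfg, genome=genome, genes=genes, samples=samples)
    _verify_truth(truth)
    return truth


def _verify_truth(truth: TruthTable) -> None:
    """Generation-time consistency scan: planted motifs are really in the genome."""
    seq = truth.genome[truth.config.chrom]

    def dinuc(pos: int) -> str:  # 1-based, two bases
        return seq[pos - 1 : pos + 1]

    for g in truth.genes:
        for s, e in [g.canonical_junction, g.cryptic_junction] + list(g.other_introns):
            if g.strand == "+":
                ok = dinuc(s) == "GT" and dinuc(e - 1) == "AG"
            else:
                ok = dinuc(s) == "CT" and dinuc(e - 1) == "AC"
            if not ok:
                raise AssertionError(
                    f"{g.gene_id}: intron {s}-{e} lacks the planted splice motif"
                )
        cds_len = 0
        for s, e in g.exons:
            lo, hi = max(s, g.cds_start), min(e, g.cds_end)
            if lo <= hi:
                cds_len += hi - lo + 1
        if cds_len % 3 != 0:
            raise AssertionError(f"{g.gene_id}: CDS length {cds_len} not divisible by 3")


def simulate_counts(
    truth: TruthTable, seed: Optional[int] = None
) -> Dict[str, Dict[tuple, Junction]]:
    """Per-sample junction sets with negative-binomial / multinomial counts.

    Event-intron coverage is NB(``coverage_mean``, ``coverage_dispersion``)
    per sample, split canonical-vs-cryptic by the group's true PSI; other
    introns get NB coverage entirely on their canonical acceptor.  Seeded
    and reproducible (defaults to the config seed + 1).
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    size = cfg.coverage_dispersion
    p_nb = size / (size + cfg.coverage_mean)
    out: Dict[str, Dict[tuple, Junction]] = {s: {} for s in truth.samples}

    def motif(strand: str) -> str:
        return "GT-AG" if strand == "+" else "CT-AC"

    for g in truth.genes:
        for sample, group in truth.samples.items():
            total = int(rng.negative_binomial(size, p_nb))
            psi = g.ref_psi if group == cfg.group_labels[0] else g.mut_psi
            n_cryptic = int(rng.binomial(total, psi / 100.0)) if total else 0
            n_canon = total - n_cryptic
            for (s, e), n in (
                (g.canonical_junction, n_canon),
                (g.cryptic_junction, n_cryptic),
            ):
                if n > 0:
                    key = (g.chrom, s, e, g.strand)
                    out[sample][key] = Junction(
                        g.chrom, s, e, g.strand, motif(g.strand), {sample: n}
                    )
            for s, e in g.other_introns:
                n = int(rng.negative_binomial(size, p_nb))
                if n > 0:
                    key = (g.chrom, s, e, g.strand)
                    out[sample][key] = Junction(
                        g.chrom, s, e, g.strand, motif(g.strand), {sample: n}
                    )
    return out


def simulate_reads(
    truth: TruthTable,
    counts: Dict[str, Dict[tuple, Junction]],
    sample: str,
    path: str,
) -> None:
    """Write a SAM file whose junction extraction reproduces ``counts[sample]``.

    Junction reads carry ``anchor``-length aligned blocks either side of
    each gap; where a gene has two counted introns, up to
    ``max_multigap_reads`` reads span both (contributing to each junction).
    Sub-anchor distractor reads and unspliced filler reads are appended and
    carry no countable junctions at the configured anchor.  The header
    records the config digest.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2 + _stable_hash(sample))
    genome = truth.genome
    anchor = cfg.anchor
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
        "CO": [f"juncscope-sim config digest {cfg.digest()} sample {sample}"],
    }
    juncs = counts[sample]
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        serial = 0

        def emit(pos0: int, cigar: List[Tuple[int, int]], strand: str) -> None:
            nonlocal serial
            serial += 1
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{sample}.r{serial}"
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigartuples = cigar
            qlen = sum(l for op, l in cigar if op in (0, 1, 4))
            a.query_sequence = "A" * qlen
            a.flag = 16 if strand == "-" else 0
            if cfg.emit_xs and strand in ("+", "-"):
                a.set_tag("XS", strand)
            out.write(a)

        remaining = {key: j.counts[sample] for key, j in juncs.items()}
        # multi-gap reads over gene pairs of counted introns
        for g in truth.genes:
            counted = [
                (s, e)
                for s, e in sorted([g.canonical_junction] + g.other_introns)
                if remaining.get((g.chrom, s, e, g.strand), 0) > 0
            ]
            if len(counted) < 2:
                continue
            (s1, e1), (s2, e2) = counted[0], counted[1]
            k1 = (g.chrom, s1, e1, g.strand)
            k2 = (g.chrom, s2, e2, g.strand)
            n_multi = min(remaining[k1], remaining[k2], cfg.max_multigap_reads)
            mid = s2 - e1 - 1
            for _ in range(n_multi):
                emit(
                    s1 - anchor - 1,  # 0-based start of the left anchor
                    [(0, anchor), (3, e1 - s1 + 1), (0, mid), (3, e2 - s2 + 1), (0, anchor)],
                    g.strand,
                )
            remaining[k1] -= n_multi
            remaining[k2] -= n_multi
        # single-gap reads for the rest
        for (chrom, s, e, strand), n in sorted(remaining.items()):
            for _ in range(n):
                emit(s - anchor - 1, [(0, anchor), (3, e - s + 1), (0, anchor)], strand)
        # distractor reads: anchors below the extraction threshold
        weak = max(1, min(4, anchor - 1))
        for g in truth.genes:
            s, e = g.canonical_junction
            for _ in range(cfg.n_subanchor_reads):
                emit(s - weak - 1, [(0, weak), (3, e - s + 1), (0, anchor)], g.strand)
        # unspliced filler reads anywhere on the chromosome
        chrom_len = len(genome[cfg.chrom])
        for _ in range(cfg.n_filler_reads):
            pos0 = int(rng.integers(0, chrom_len - cfg.read_len))
            emit(pos0, [(0, cfg.read_len)], ".")


def _stable_hash(text: str) -> int:
    return int(hashlib.sha1(text.encode()).hexdigest()[:6], 16)


def write_fasta(genome: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(truth: TruthTable, path: str) -> None:
    """Write the canonical transcript annotation (exons + CDS) as GTF."""
    lines = []
    for g in truth.genes:
        attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
        lines.append(
            (g.chrom, "juncscope_sim", "transcript", g.start, g.end, g.strand, attrs)
        )
        for s, e in g.exons:
            lines.append((g.chrom, "juncscope_sim", "exon", s, e, g.strand, attrs))
        for s, e in g.exons:
            lo, hi = max(s, g.cds_start), min(e, g.cds_end)
            if lo <= hi:
                lines.append((g.chrom, "juncscope_sim", "CDS", lo, hi, g.strand, attrs))
    with open(path, "w") as fh:
        for chrom, src, feat, s, e, strand, attrs in lines:
            fh.write(f"{chrom}\t{src}\t{feat}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")


def write_truth_table(truth: TruthTable, path: str) -> None:
    """Flat TSV of the per-gene truth (for inspection and external checks)."""
    cols = (
        "gene_id chrom strand start end event_intron_index canonical_start "
        "canonical_end cryptic_start cryptic_end distance category orf_class "
        "bp_distance ref_psi mut_psi"
    ).split()
    from .classify import distance_category

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in truth.genes:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.gene_id, g.chrom, g.strand, g.start, g.end,
                        g.event_intron_index, *g.canonical_junction,
                        *g.cryptic_junction, g.distance,
                        distance_category(g.distance), g.orf_class,
                        g.bp_distance, f"{g.ref_psi:g}", f"{g.mut_psi:g}",
                    )
                )
                + "\n"
            )
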