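"""Percent-spliced-in (PSI) quantification over splice-site choice groups.

Junctions sharing one donor are grouped into an :class:`AcceptorGroup` (an
alternative-3'ss choice set: one GT donor, several AG acceptors within the
intron); junctions sharing one acceptor form the symmetric
:class:`DonorGroup` (alternative 5'ss).  Within a group and sample, PSI of a
choice is the relative read frequency on a 0-100 scale::

    PSI(choice) = 100 * count(choice) / sum(counts over the group's choices)

All PSIs of a group are missing (NaN) in a sample whose group total is below
``min_coverage`` (default 10 reads).  Replicates are pooled by summing
counts before taking the ratio, so pooled PSI is the count-weighted mean of
replicate PSIs and the coverage filter applies to the pooled total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .junctions import Junction, format_junction_id

__all__ = [
    "AcceptorGroup",
    "DonorGroup",
    "build_groups",
    "compute_psi",
    "pool_replicates",
    "psi_table",
    "write_psi_table",
    "read_psi_table",
    "read_external_psi_table",
]


@dataclass
class AcceptorGroup:
    """Junctions sharing (chrom, strand, donor): one 5'ss, >= 1 acceptor 3'ss."""

    chrom: str
    strand: str
    donor: int
    junctions: List[Junction] = field(default_factory=list)
    #: acceptor coordinate -> True if present in the annotation
    annotated: Dict[int, bool] = field(default_factory=dict)

    side = "acceptor"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.strand, self.donor)

    @property
    def choices(self) -> List[int]:
        """Acceptor coordinates, ascending genomic order."""
        return sorted(j.acceptor() for j in self.junctions)

    def junction_for(self, choice: int) -> Junction:
        for j in self.junctions:
            if j.acceptor() == choice:
                return j
        raise KeyError(choice)

    def counts(self, samples: Sequence[str]) -> pd.DataFrame:
        """Choice x sample count matrix."""
        data = {
            j.acceptor(): [j.counts.get(s, 0) for s in samples] for j in self.junctions
        }
        return pd.DataFrame(data, index=list(samples)).T.sort_index()


class DonorGroup(AcceptorGroup):
    """Junctions sharing (chrom, strand, acceptor): alternative 5'ss choices."""

    side = "donor"

    @property
    def choices(self) -> List[int]:
        return sorted(j.donor() for j in self.junctions)

    def junction_for(self, choice: int) -> Junction:
        for j in self.junctions:
            if j.donor() == choice:
                return j
        raise KeyError(choice)

    def counts(self, samples: Sequence[str]) -> pd.DataFrame:
        data = {j.donor(): [j.counts.get(s, 0) for s in samples] for j in self.junctions}
        return pd.DataFrame(data, index=list(samples)).T.sort_index()


def build_groups(
    junctions: Iterable[Junction],
    annotation: Optional[Iterable[tuple]] = None,
) -> Tuple[Dict[tuple, AcceptorGroup], Dict[tuple, DonorGroup], List[Junction]]:
    """Group junctions by shared donor (acceptor groups) and shared acceptor.

    ``annotation``, when given, is an iterable of annotated introns as
    ``(chrom, start, end, strand)`` 1-based inclusive tuples; acceptors seen
    there are marked annotated.  Unknown-strand junctions cannot be oriented
    and are quarantined into the returned side list, never silently dropped.

    Returns ``(acceptor_groups, donor_groups, quarantined)``.
    """
    annotated_acceptors = set()
    annotated_donors = set()
    if annotation is not None:
        for chrom, start, end, strand in annotation:
            if strand == "+":
                annotated_donors.add((chrom, strand, start))
                annotated_acceptors.add((chrom, strand, end))
            elif strand == "-":
                annotated_donors.add((chrom, strand, end))
                annotated_acceptors.add((chrom, strand, start))

    acceptor_groups: Dict[tuple, AcceptorGroup] = {}
    donor_groups: Dict[tuple, DonorGroup] = {}
    quarantined: List[Junction] = []
    for junc in junctions:
        if junc.strand not in ("+", "-"):
            quarantined.append(junc)
            continue
        akey = (junc.chrom, junc.strand, junc.donor())
        grp = acceptor_groups.get(akey)
        if grp is None:
            grp = AcceptorGroup(*akey)
            acceptor_groups[akey] = grp
        grp.junctions.append(junc)
        grp.annotated[junc.acceptor()] = (
            (junc.chrom, junc.strand, junc.acceptor()) in annotated_acceptors
        )
        dkey = (junc.chrom, junc.strand, junc.acceptor())
        dgrp = donor_groups.get(dkey)
        if dgrp is None:
            dgrp = DonorGroup(junc.chrom, junc.strand, junc.acceptor())
            donor_groups[dkey] = dgrp
        dgrp.junctions.append(junc)
        dgrp.annotated[junc.donor()] = (
            (junc.chrom, junc.strand, junc.donor()) in annotated_donors
        )
    return acceptor_groups, donor_groups, quarantined


def compute_psi(
    group: AcceptorGroup, sample: str, min_coverage: int = 10
) -> Dict[int, float]:
    """Per-choice PSI (0-100) for one sample; all NaN below ``min_coverage``."""
    counts = {}
    for choice in group.choices:
        n = group.junction_for(choice).counts.get(sample, 0)
        if n < 0:
            raise ValueError(f"negative count for choice {choice} in sample {sample!r}")
        counts[choice] = n
    total = sum(counts.values())
    if total < min_coverage:
        return {choice: math.nan for choice in counts}
    return {choice: 100.0 * n / total for choice, n in counts.items()}


def pool_replicates(
    group: AcceptorGroup, sample_ids: Sequence[str], min_coverage: int = 10
) -> Dict[int, float]:
    """Pooled PSI over replicates: counts are summed before the ratio.

    The coverage filter applies to the pooled total, so replicates that fail
    the per-sample filter still contribute their reads.
    """
    if not sample_ids:
        raise ValueError("pool_replicates requires at least one sample id")
    counts = {
        choice: sum(group.junction_for(choice).counts.get(s, 0) for s in sample_ids)
        for choice in group.choices
    }
    total = sum(counts.values())
    if total < min_coverage:
        return {choice: math.nan for choice in counts}
    return {choice: 100.0 * n / total for choice, n in counts.items()}


def psi_table(
    groups: Mapping[tuple, AcceptorGroup],
    samples: Sequence[str],
    min_coverage: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """PSI and group-coverage matrices over all choices of all groups.

    Rows are junction IDs of the choice junctions, columns samples.  The
    coverage matrix holds the group total (same value for all choices of a
    group) so the PSI filter is reproducible from the output.
    """
    psi_rows, cov_rows, index = [], [], []
    for key in sorted(groups):
        group = groups[key]
        counts = group.counts(samples)  # choice x sample
        totals = counts.sum(axis=0)
        psi = 100.0 * counts / totals.replace(0, np.nan)
        psi.loc[:, (totals < min_coverage).values] = np.nan
        for choice in counts.index:
            index.append(format_junction_id(group.junction_for(choice)))
            psi_rows.append(psi.loc[choice])
            cov_rows.append(totals)
    psi_df = pd.DataFrame(psi_rows, index=index)
    cov_df = pd.DataFrame(cov_rows, index=index)
    psi_df.index.name = cov_df.index.name = "junction_id"
    return psi_df, cov_df


def write_psi_table(psi: pd.DataFrame, coverage: pd.DataFrame, path: str) -> None:
    """Serialize PSI + coverage to one TSV (coverage columns suffixed)."""
    merged = psi.join(coverage.add_suffix(".cov"))
    merged.to_csv(path, sep="\t", na_rep="NA")


def read_psi_table(path: str) -> Tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA", comment="#")
    cov_cols = [c for c in df.columns if c.endswith(".cov")]
    cov = df[cov_cols].rename(columns=lambda c: c[: -len(".cov")])
    return df.drop(columns=cov_cols), cov


def read_external_psi_table(path: str, id_column: str = "event_id") -> pd.DataFrame:
    """Read an event-level PSI table (event-id + one PSI column per sample).

    Accepts externally quantified events (e.g. intron retention or exon
    skipping PSI tables) so downstream differential and control-set logic can
    consume them alongside junction-derived PSIs.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing id column {id_column!r}")
    return df.set_index(id_column)
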