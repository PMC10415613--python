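"""Classification of alternative 3' splice-site choices.

Within an acceptor group (one donor, several AG acceptors) the *canonical*
acceptor is the most used 3'ss in the reference (e.g. wild-type) samples.
Every other acceptor gets a signed distance ``d`` measured in transcript
orientation — ``d < 0`` means the non-canonical acceptor lies upstream
(5'-ward on the mRNA) of the canonical one — and a distance category:

========  ==========================================
NAGNAG    tandem acceptor, ``|d| <= nagnag_max`` (3)
UpN/DoN   near, ``|d| <= 50``
UpF/DoF   far, ``|d| > 50``
========  ==========================================

Status calls follow effect-size thresholds: an acceptor whose usage changes
by ``|dPSI| >= 15`` between conditions is *cryptic* when its reference-group
PSI is ``<= 5`` (essentially unused without the mutation) and *alternative*
otherwise; below the dPSI threshold it is *unchanged*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .junctions import format_junction_id
from .psi import AcceptorGroup, pool_replicates

__all__ = [
    "Alt3Call",
    "Alt3Event",
    "designate_canonical",
    "signed_distance",
    "distance_category",
    "classify_status",
    "count_choices",
    "classify_groups",
    "find_surrogate_markers",
    "choice_count_histogram",
]


@dataclass
class Alt3Call:
    """One non-canonical acceptor's classification within its group."""

    junction_id: str
    acceptor: int
    distance: int
    category: str
    status: str
    ref_psi: float
    contrast_psi: float
    dpsi: float
    reason: Optional[str] = None


@dataclass
class Alt3Event:
    """A donor-anchored acceptor group with canonical designation and calls."""

    chrom: str
    strand: str
    donor: int
    canonical: int
    canonical_id: str
    calls: List[Alt3Call] = field(default_factory=list)

    @property
    def n_choices(self) -> int:
        """Number of non-canonical acceptors (1 = a single pair of 3'ss)."""
        return len(self.calls)


def designate_canonical(
    group: AcceptorGroup,
    reference_samples: Sequence[str],
    min_coverage: int = 10,
) -> Optional[int]:
    """The most used acceptor in the pooled reference samples.

    Ties break deterministically: annotated over de-novo, then smaller
    genomic coordinate.  Returns None when the reference group has no
    coverage for the group (group skipped upstream with a reason).
    """
    psi = pool_replicates(group, list(reference_samples), min_coverage=min_coverage)
    if all(math.isnan(v) for v in psi.values()):
        return None
    best = max(
        psi,
        key=lambda choice: (
            psi[choice],
            group.annotated.get(choice, False),
            -choice,
        ),
    )
    return best


def signed_distance(canonical: int, alternative: int, strand: str) -> int:
    """Transcript-orientation offset of ``alternative`` from ``canonical``.

    Negative = upstream (5'-ward on the mRNA); on the minus strand the
    genomic difference is negated.
    """
    d = alternative - canonical
    if strand == "-":
        d = -d
    if d == 0:
        raise ValueError("duplicate acceptor: signed distance is zero")
    return d


def distance_category(d: int, nagnag_max: int = 3, near_max: int = 50) -> str:
    """Distance category of a non-canonical acceptor at signed offset ``d``."""
    if d == 0:
        raise ValueError("distance category undefined for d = 0")
    if abs(d) <= nagnag_max:
        return "NAGNAG-up" if d < 0 else "NAGNAG-down"
    if abs(d) <= near_max:
        return "UpN" if d < 0 else "DoN"
    return "UpF" if d < 0 else "DoF"


def classify_status(
    ref_psi: float,
    dpsi: float,
    min_dpsi: float = 15.0,
    max_ref_psi: float = 5.0,
) -> str:
    """cryptic / alternative / unchanged for one non-canonical acceptor."""
    if math.isnan(ref_psi) or math.isnan(dpsi):
        return "missing"
    if abs(dpsi) < min_dpsi:
        return "unchanged"
    return "cryptic" if ref_psi <= max_ref_psi else "alternative"


def count_choices(group: AcceptorGroup) -> int:
    """Number of non-canonical acceptors in the group (>= 1 choice pair)."""
    return max(len(group.choices) - 1, 0)


def choice_count_histogram(groups: Mapping[tuple, AcceptorGroup]) -> Dict[int, int]:
    """Histogram of non-canonical acceptor counts over multi-acceptor groups."""
    hist: Dict[int, int] = {}
    for group in groups.values():
        n = count_choices(group)
        if n >= 1:
            hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))


def classify_groups(
    groups: Mapping[tuple, AcceptorGroup],
    reference_samples: Sequence[str],
    contrast_samples: Sequence[str],
    min_coverage: int = 10,
    min_dpsi: float = 15.0,
    max_ref_psi: float = 5.0,
    nagnag_max: int = 3,
    near_max: int = 50,
) -> List[Alt3Event]:
    """Classify every multi-acceptor group against reference/contrast pools.

    dPSI is contrast minus reference.  Groups without reference coverage or
    with a single acceptor are skipped.  Classification is invariant to the
    input order of acceptors (choices are iterated in genomic order and the
    canonical is designated deterministically).
    """
    events: List[Alt3Event] = []
    for key in sorted(groups):
        group = groups[key]
        if len(group.choices) < 2:
            continue
        canonical = designate_canonical(group, reference_samples, min_coverage)
        if canonical is None:
            continue
        ref = pool_replicates(group, list(reference_samples), min_coverage)
        con = pool_replicates(group, list(contrast_samples), min_coverage)
        event = Alt3Event(
            chrom=group.chrom,
            strand=group.strand,
            donor=group.donor,
            canonical=canonical,
            canonical_id=format_junction_id(group.junction_for(canonical)),
        )
        for choice in group.choices:
            if choice == canonical:
                continue
            d = signed_distance(canonical, choice, group.strand)
            ref_psi, con_psi = ref[choice], con[choice]
            dpsi = con_psi - ref_psi
            status = classify_status(ref_psi, dpsi, min_dpsi, max_ref_psi)
            event.calls.append(
                Alt3Call(
                    junction_id=format_junction_id(group.junction_for(choice)),
                    acceptor=choice,
                    distance=d,
                    category=distance_category(d, nagnag_max, near_max),
                    status=status,
                    ref_psi=ref_psi,
                    contrast_psi=con_psi,
                    dpsi=dpsi,
                    reason="no-psi" if status == "missing" else None,
                )
            )
        events.append(event)
    return events


def events_to_frame(events: Sequence[Alt3Event]) -> pd.DataFrame:
    """Flatten classified events to one row per non-canonical acceptor."""
    rows = []
    for ev in events:
        for call in ev.calls:
            rows.append(
                {
                    "junction_id": call.junction_id,
                    "canonical_id": ev.canonical_id,
                    "chrom": ev.chrom,
                    "strand": ev.strand,
                    "donor": ev.donor,
                    "distance": call.distance,
                    "category": call.category,
                    "status": call.status,
                    "ref_psi": call.ref_psi,
                    "contrast_psi": call.contrast_psi,
                    "dpsi": call.dpsi,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id", "canonical_id", "chrom", "strand", "donor",
            "distance", "category", "status", "ref_psi", "contrast_psi", "dpsi",
        ],
    )


def find_surrogate_markers(
    events: pd.DataFrame,
    min_dpsi: float = 50.0,
) -> pd.DataFrame:
    """Screen for surrogate-marker candidates: large dPSI, lowest reference use.

    Keeps events with ``dPSI >= min_dpsi`` (gain of usage in the contrast
    group) and ranks them by ascending reference-group PSI, so the top
    candidate is the site most specifically activated by the mutation.
    ``events`` is the frame from :func:`events_to_frame` (or any frame with
    ``junction_id``, ``dpsi`` and ``ref_psi`` columns).
    """
    if events.empty:
        return events
    cand = events[events["dpsi"] >= min_dpsi].copy()
    cand = cand.sort_values(["ref_psi", "junction_id"], kind="mergesort")
    return cand.reset_index(drop=True)
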