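"""Canonical designation, distances, categories, status and surrogate screening."""

import math

import pandas as pd
import pytest

from juncscope.classify import (
    classify_groups,
    classify_status,
    count_choices,
    designate_canonical,
    distance_category,
    events_to_frame,
    find_surrogate_markers,
    signed_distance,
)
from juncscope.junctions import Junction
from juncscope.psi import AcceptorGroup, build_groups

from test_psi import make_group


def oracle_category(d, nagnag=3, near=50):
    """Independent piecewise reimplementation of the distance taxonomy."""
    assert d != 0
    if d < 0:
        if -d <= nagnag:
            return "NAGNAG-up"
        return "UpN" if -d <= near else "UpF"
    if d <= nagnag:
        return "NAGNAG-down"
    return "DoN" if d <= near else "DoF"


def test_distance_category_matches_exhaustive_oracle():
    for d in range(-200, 201):
        if d == 0:
            continue
        assert distance_category(d) == oracle_category(d), d


@pytest.mark.parametrize(
    "d,expected",
    [
        (13, "DoN"),  # ZNF561-like: 13 nt downstream of the canonical site
        (-20, "UpN"),  # MAP3K7-like: 20 nt upstream
        (-3, "NAGNAG-up"),  # TARBP1-like tandem acceptor (184 vs 187 nt products)
        (3, "NAGNAG-down"),
        (-50, "UpN"),
        (-51, "UpF"),
        (50, "DoN"),
        (51, "DoF"),
    ],
)
def test_distance_category_worked_examples(d, expected):
    assert distance_category(d) == expected


def test_distance_category_rejects_zero():
    with pytest.raises(ValueError):
        distance_category(0)


def test_signed_distance_orientation():
    assert signed_distance(100, 113, "+") == 13
    assert signed_distance(100, 80, "+") == -20
    # minus strand: genomic difference negated
    assert signed_distance(100, 130, "-") == -30
    with pytest.raises(ValueError):
        signed_distance(100, 100, "+")


def test_minus_strand_distance_against_transcript_walk(truth):
    """Brute-force: walk the reverse-complemented transcript and count bases
    between the two acceptor exon boundaries; must equal |signed distance|."""
    for g in truth.genes:
        if g.strand != "-":
            continue
        d = signed_distance(g.canonical_acceptor, g.cryptic_acceptor, "-")
        assert d == g.distance
        # on the minus strand an upstream (negative) shift has the cryptic
        # acceptor at a genomically larger coordinate
        assert (g.cryptic_acceptor > g.canonical_acceptor) == (d < 0)
        assert abs(g.cryptic_acceptor - g.canonical_acceptor) == abs(d)


def test_designate_canonical_argmax_and_tiebreaks():
    group = make_group({250: {"w": 90}, 263: {"w": 8}, 270: {"w": 2}})
    assert designate_canonical(group, ["w"]) == 250
    # tie: annotated acceptor wins
    tie = make_group({250: {"w": 50}, 263: {"w": 50}})
    tie.annotated = {250: False, 263: True}
    assert designate_canonical(tie, ["w"]) == 263
    # tie with equal annotation: smaller coordinate, deterministically
    tie2 = make_group({250: {"w": 50}, 263: {"w": 50}})
    assert designate_canonical(tie2, ["w"]) == 250
    # no coverage: skipped
    empty = make_group({250: {"w": 1}, 263: {"w": 2}})
    assert designate_canonical(empty, ["w"]) is None


@pytest.mark.parametrize(
    "ref_psi,dpsi,expected",
    [
        (2.87, 50.93, "cryptic"),  # ZDHHC16-like surrogate event
        (20.0, 20.0, "alternative"),
        (4.0, 10.0, "unchanged"),
        (5.0, 15.0, "cryptic"),  # boundaries: ref <= 5 and |dpsi| >= 15
        (5.01, 15.0, "alternative"),
        (0.0, -14.99, "unchanged"),
    ],
)
def test_classify_status(ref_psi, dpsi, expected):
    assert classify_status(ref_psi, dpsi) == expected


def test_classify_status_missing_psi():
    assert classify_status(math.nan, 20.0) == "missing"


def test_count_choices():
    assert count_choices(make_group({250: {}, 263: {}})) == 1
    assert count_choices(make_group({250: {}, 263: {}, 270: {}, 280: {}})) == 3


def test_classification_invariant_to_input_order(truth, counts):
    from juncscope.junctions import merge_junctions

    merged = merge_junctions(counts)
    samples = sorted(truth.samples)
    ref = [s for s in samples if truth.samples[s] == "WT"]
    mut = [s for s in samples if truth.samples[s] == "MUT"]
    fwd = list(merged.values())
    groups_a, _, _ = build_groups(fwd)
    groups_b, _, _ = build_groups(fwd[::-1])
    fa = events_to_frame(classify_groups(groups_a, ref, mut))
    fb = events_to_frame(classify_groups(groups_b, ref, mut))
    pd.testing.assert_frame_equal(
        fa.sort_values("junction_id").reset_index(drop=True),
        fb.sort_values("junction_id").reset_index(drop=True),
    )


def test_planted_cryptic_sites_recovered_with_upstream_near_distances(truth, counts):
    """Simulated cohorts plant cryptic acceptors 10-30 nt upstream; the
    classifier must recover them as cryptic with the distance density
    peaking in [-30, -10]."""
    from juncscope.junctions import merge_junctions

    merged = merge_junctions(counts)
    groups, _, _ = build_groups(merged.values(), annotation=truth.annotated_introns())
    samples = sorted(truth.samples)
    ref = [s for s in samples if truth.samples[s] == "WT"]
    mut = [s for s in samples if truth.samples[s] == "MUT"]
    frame = events_to_frame(classify_groups(groups, ref, mut))
    cryptic = frame[frame["status"] == "cryptic"]
    planted = {
        f"{g.chrom}:{g.cryptic_junction[0]}-{g.cryptic_junction[1]}({g.strand})": g
        for g in truth.genes
    }
    assert set(cryptic["junction_id"]) == set(planted)
    for _, row in cryptic.iterrows():
        assert row["distance"] == planted[row["junction_id"]].distance
    assert cryptic["distance"].between(-30, -10).mean() > 0.5


def test_surrogate_screening_ranks_lowest_reference_psi_first():
    frame = pd.DataFrame(
        {
            "junction_id": ["a", "b", "c", "d"],
            "dpsi": [50.93, 62.0, 49.0, 55.0],
            "ref_psi": [2.87, 8.0, 0.1, 4.0],
        }
    )
    ranked = find_surrogate_markers(frame, min_dpsi=50)
    assert list(ranked["junction_id"]) == ["a", "d", "b"]  # c fails the threshold
    assert ranked.iloc[0]["ref_psi"] == 2.87
    none = find_surrogate_markers(frame[frame["dpsi"] < 50], min_dpsi=50)
    assert len(none) == 0
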