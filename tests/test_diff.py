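"""Sample selection, group comparison, control sets, and summary statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from juncscope.diff import (
    build_control_sets,
    compare_groups,
    correlate_dpsi,
    event_type_enrichment,
    select_samples,
)

GROUPS = {"w1": "WT", "w2": "WT", "w3": "WT", "m1": "MUT", "m2": "MUT", "m3": "MUT"}


def psi_frame(rows):
    return pd.DataFrame(rows, columns=list(GROUPS)).rename_axis("event_id")


def test_select_samples_ccf_and_blacklist_rules():
    meta = pd.DataFrame(
        {
            "group": ["MUT", "MUT", "MUT", "MUT", "WT"],
            "ccf": [60.0, 30.0, math.nan, 80.0, math.nan],
            "excluded_gene": [False, False, False, True, False],
        },
        index=["hi", "lo", "na", "bl", "wt"],
    )
    included, excluded = select_samples(meta, mutated_groups=["MUT"], min_ccf=50)
    assert included == ["hi", "wt"]
    assert excluded == {
        "lo": "ccf-below-50",
        "na": "ccf-missing",
        "bl": "blacklisted-gene-mutation",
    }


def test_compare_groups_worked_example():
    """Replicates {8,10,12} vs {28,30,31}: dPSI 19.67, gap 16, reported."""
    psi = psi_frame([[8, 10, 12, 28, 30, 31]])
    (ev,) = compare_groups(psi, GROUPS, "WT", "MUT")
    assert ev.dpsi == pytest.approx((28 + 30 + 31) / 3 - 10.0)
    assert ev.gap == pytest.approx(28 - 12)
    assert ev.spread_ref == 4 and ev.spread_contrast == 3
    assert ev.passed


def test_compare_groups_below_dpsi_threshold_not_reported():
    psi = psi_frame([[40, 40, 40, 52, 52, 52]])
    (ev,) = compare_groups(psi, GROUPS, "WT", "MUT")
    assert ev.dpsi == pytest.approx(12.0) and not ev.passed
    assert "dpsi-below-threshold" in ev.reasons


def test_compare_groups_antisymmetry():
    rng = np.random.default_rng(0)
    psi = psi_frame(rng.uniform(0, 100, size=(20, 6)))
    fwd = compare_groups(psi, GROUPS, "WT", "MUT")
    rev = compare_groups(psi, GROUPS, "MUT", "WT")
    for a, b in zip(fwd, rev):
        assert a.dpsi == pytest.approx(-b.dpsi)
        assert a.passed == b.passed


def test_compare_groups_cohort_coverage_rule():
    """At least 10 reads in 5 mutated and 20 reference samples required."""
    groups = {f"m{i}": "MUT" for i in range(6)} | {f"w{i}": "WT" for i in range(25)}
    cols = list(groups)
    psi = pd.DataFrame([[50.0] * len(cols)], columns=cols, index=["e1"])
    cov = pd.DataFrame([[100.0] * len(cols)], columns=cols, index=["e1"])
    # only 4 mutated samples reach 10 reads
    cov.loc["e1", ["m0", "m1"]] = 5.0
    events = compare_groups(
        psi, groups, "WT", "MUT", coverage=cov, cohort_rule=(5, 20)
    )
    assert not events[0].passed
    assert any(r.startswith("cohort-coverage-contrast") for r in events[0].reasons)
    cov.loc["e1", ["m0", "m1"]] = 10.0
    events = compare_groups(psi, groups, "WT", "MUT", coverage=cov, cohort_rule=(5, 20))
    assert not any(r.startswith("cohort-coverage") for r in events[0].reasons)


def test_compare_groups_requires_both_groups():
    psi = psi_frame([[1, 2, 3, 4, 5, 6]])
    with pytest.raises(ValueError, match="zero eligible"):
        compare_groups(psi, GROUPS, "WT", "TREATED")


def test_pooled_psi_uses_count_weighting():
    psi = psi_frame([[0, 100, math.nan, 50, 50, 50]])
    cov = psi_frame([[30, 10, 0, 10, 10, 10]])
    (ev,) = compare_groups(psi, GROUPS, "WT", "MUT", coverage=cov)
    assert ev.ref_psi == pytest.approx(100 * 10 / 40)


def test_control_set_predicates():
    psi = psi_frame(
        [
            [97, 98, 97, 98, 97, 98],  # constitutive: PSI > 95 both groups
            [3, 4, 3, 4, 3, 4],  # cryptic exon: PSI < 5 both groups
            [50, 51, 50, 50.4, 50.6, 50.5],  # non-changing: -1 < dPSI < 1, 5 < PSI < 95
            [40, 41, 42, 60, 61, 62],  # retained: dPSI >= 15, spread < 5
            [60, 61, 62, 40, 41, 42],  # more-spliced: dPSI <= -15, spread < 5
            [30, 31, 30, 33, 32, 33],  # alternative non-changing: |dPSI| <= 5
        ],
    )
    psi.index = ["const", "cryp", "nc", "ret", "spl", "altnc"]
    sets = build_control_sets(psi, GROUPS, "WT", "MUT")
    assert sets.constitutive == ["const"]
    assert sets.cryptic_exon == ["cryp"]
    assert sets.nonchanging_intron == ["nc"]
    assert sets.retained == ["ret"]
    assert sets.more_spliced == ["spl"]
    assert "altnc" in sets.alternative_nonchanging
    # disjoint within each sense
    assert not set(sets.constitutive) & set(sets.cryptic_exon)
    assert not set(sets.retained) & set(sets.nonchanging_intron)


def brute_force_chi2(table):
    """Text-book continuity-corrected chi-square on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            exp = row[i] * col[j] / n
            stat += max(abs(table[i, j] - exp) - 0.5, 0.0) ** 2 / exp
    return stat, stats.chi2.sf(stat, 1)


def test_event_type_enrichment_matches_2x2_oracle():
    res = event_type_enrichment({"Alt3": 50, "IR": 50}, {"Alt3": 10, "IR": 90})
    row = res[res["event_type"] == "Alt3"].iloc[0]
    stat, p = brute_force_chi2([[50, 50], [10, 90]])
    assert row["chi2"] == pytest.approx(stat, abs=1e-6)
    assert row["p_value"] == pytest.approx(p, abs=1e-6)
    assert row["direction"] == "enriched"


def test_event_type_enrichment_identical_proportions_and_degenerate():
    res = event_type_enrichment({"Alt3": 10, "IR": 10}, {"Alt3": 100, "IR": 100})
    assert (res["p_value"] > 0.9).all()
    # one differential event total: still defined (continuity corrected)
    res1 = event_type_enrichment({"Alt3": 1, "IR": 0}, {"Alt3": 50, "IR": 50})
    assert res1["p_value"].notna().all()
    # zero-background types are skipped
    res2 = event_type_enrichment({"Alt3": 1}, {"Alt3": 50, "ES": 0})
    assert list(res2["event_type"]) == ["Alt3"]


def test_correlate_dpsi_oracle_and_limits():
    a = pd.Series([20.0, 30.0, -40.0, 50.0], index=list("abcd"))
    assert correlate_dpsi(a, a).iloc[0]["pearson_r"] == pytest.approx(1.0)
    assert correlate_dpsi(a, -a).iloc[0]["pearson_r"] == pytest.approx(-1.0)
    x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    y = pd.Series([2.0, 4.0, 6.0, 9.0], index=list("abcd"))
    res = correlate_dpsi(x, y, min_abs_dpsi=0.0)
    xm, ym = x - x.mean(), y - y.mean()
    r_hand = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    assert res.iloc[0]["pearson_r"] == pytest.approx(r_hand, abs=1e-12)
    # events failing the |dPSI| >= 15 filter in both vectors are dropped
    res2 = correlate_dpsi(x, y)
    assert res2.iloc[0]["n"] == 0 and res2.iloc[0]["reason"] == "fewer-than-3-pairs"
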