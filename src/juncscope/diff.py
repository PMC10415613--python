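"""Between-group differential splicing under effect-size thresholds.

A comparison is reference vs contrast; dPSI = PSI(contrast) - PSI(reference)
(on pooled replicates).  An event is differential when ``|dPSI| >= min_dpsi``
and the active range criterion holds.  Two range semantics exist and both
are always computed and stored:

* ``gap``    — between-group gap: min PSI of the higher group's replicates
  minus max PSI of the lower group's replicates, required ``>= min_gap``.
  This gates differential calls by default.
* ``spread`` — within-group replicate spread (max - min inside each group),
  required ``< max_spread``.  This is the semantics used by the control-set
  definitions below.

Control sets (exon sense, intron sense) are computed with the exact
predicates used for feature comparisons: constitutive exons PSI > 95 in both
groups; alternative non-changing 10 < PSI < 90 in at least one group and
|dPSI| <= 5; cryptic exons PSI < 5 in both groups; retained introns
|dPSI| >= 15 with spread < 5; more-spliced introns dPSI <= -15 with
spread < 5; non-changing introns -1 < dPSI < 1 and 5 < PSI < 95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiffEvent",
    "ControlSets",
    "select_samples",
    "compare_groups",
    "build_control_sets",
    "event_type_enrichment",
    "correlate_dpsi",
    "benjamini_hochberg",
]

#: Default blacklist: splicing-factor / RNA-metabolism genes whose mutations
#: confound attribution of splicing changes to the mutation of interest.
DEFAULT_GENE_BLACKLIST = (
    "BUD13", "CARNS1", "CELF4", "DDX3X", "EIF4A3", "MAGOH", "MPHOSPH10",
    "NXF1", "RNF113A", "SKIVV2L2", "SF3B4", "SRSF2", "SRSF7", "XPO1", "U1",
    "U2AF2", "ZRSR2",
)


@dataclass
class DiffEvent:
    """One event's between-group comparison with full diagnostics."""

    event_id: str
    ref_psi: float
    contrast_psi: float
    dpsi: float
    gap: float
    spread_ref: float
    spread_contrast: float
    n_ref: int
    n_contrast: int
    passed: bool
    reasons: List[str] = field(default_factory=list)


@dataclass
class ControlSets:
    """Labelled event-id sets for feature-comparison backgrounds."""

    constitutive: List[str]
    alternative_nonchanging: List[str]
    cryptic_exon: List[str]
    retained: List[str]
    more_spliced: List[str]
    nonchanging_intron: List[str]

    def counts(self) -> Dict[str, int]:
        return {
            "constitutive": len(self.constitutive),
            "alternative_nonchanging": len(self.alternative_nonchanging),
            "cryptic_exon": len(self.cryptic_exon),
            "retained": len(self.retained),
            "more_spliced": len(self.more_spliced),
            "nonchanging_intron": len(self.nonchanging_intron),
        }


def select_samples(
    meta: pd.DataFrame,
    mutated_groups: Sequence[str],
    min_ccf: float = 50.0,
    blacklist_column: str = "excluded_gene",
) -> Tuple[List[str], Dict[str, str]]:
    """Apply the cohort inclusion rules to a sample metadata table.

    ``meta`` is indexed by sample id with columns ``group``, ``ccf`` (0-100,
    may be missing) and a boolean blacklist flag.  Samples in a mutated group
    are retained iff CCF >= ``min_ccf`` and the blacklist flag is unset;
    reference-group samples only need a clear blacklist flag.  Returns the
    included ids and a machine-readable exclusion reason per excluded id.
    """
    included: List[str] = []
    excluded: Dict[str, str] = {}
    for sample_id, row in meta.iterrows():
        if blacklist_column in meta.columns and bool(row.get(blacklist_column, False)):
            excluded[sample_id] = "blacklisted-gene-mutation"
            continue
        if row["group"] in mutated_groups:
            ccf = row.get("ccf")
            if ccf is None or (isinstance(ccf, float) and math.isnan(ccf)):
                excluded[sample_id] = "ccf-missing"
                continue
            if ccf < min_ccf:
                excluded[sample_id] = f"ccf-below-{min_ccf:g}"
                continue
        included.append(sample_id)
    return included, excluded


def _pooled_psi(psi: pd.Series, coverage: Optional[pd.Series]) -> float:
    """Coverage-weighted pooled PSI (count pooling); plain mean without coverage."""
    valid = psi.dropna()
    if valid.empty:
        return math.nan
    if coverage is None:
        return float(valid.mean())
    w = coverage.reindex(valid.index).fillna(0.0)
    if w.sum() <= 0:
        return float(valid.mean())
    return float(np.average(valid, weights=w))


def compare_groups(
    psi: pd.DataFrame,
    groups: Mapping[str, str],
    reference: str,
    contrast: str,
    coverage: Optional[pd.DataFrame] = None,
    min_dpsi: float = 15.0,
    min_gap: float = 5.0,
    max_spread: float = 5.0,
    range_semantics: str = "gap",
    min_coverage: float = 10.0,
    cohort_rule: Optional[Tuple[int, int]] = None,
) -> List[DiffEvent]:
    """Compare two groups event-by-event under the effect-size thresholds.

    ``psi`` is events x samples (0-100, NaN = insufficient coverage);
    ``groups`` maps sample id -> group label; ``coverage`` (same shape as
    ``psi``) enables count pooling across replicates and the optional cohort
    coverage rule ``(n_contrast, n_reference)`` requiring at least
    ``min_coverage`` reads in that many samples of each group.

    ``range_semantics``: ``"gap"`` gates on the between-group gap >= min_gap
    (differential-call semantics), ``"spread"`` gates on within-group spread
    < max_spread in both groups.  Swapping reference and contrast negates
    dPSI and preserves pass/fail.
    """
    if range_semantics not in ("gap", "spread"):
        raise ValueError(f"unknown range semantics {range_semantics!r}")
    ref_ids = [s for s in psi.columns if groups.get(s) == reference]
    con_ids = [s for s in psi.columns if groups.get(s) == contrast]
    if not ref_ids or not con_ids:
        raise ValueError(
            f"comparison aborted: zero eligible samples in "
            f"{'reference' if not ref_ids else 'contrast'} group"
        )
    events: List[DiffEvent] = []
    for event_id, row in psi.iterrows():
        cov_row = coverage.loc[event_id] if coverage is not None else None
        ref_vals = row[ref_ids]
        con_vals = row[con_ids]
        ref_cov = cov_row[ref_ids] if cov_row is not None else None
        con_cov = cov_row[con_ids] if cov_row is not None else None
        reasons: List[str] = []
        if cohort_rule is not None:
            if cov_row is None:
                raise ValueError("cohort coverage rule requires a coverage matrix")
            need_con, need_ref = cohort_rule
            if (con_cov >= min_coverage).sum() < need_con:
                reasons.append(f"cohort-coverage-contrast<{need_con}")
            if (ref_cov >= min_coverage).sum() < need_ref:
                reasons.append(f"cohort-coverage-reference<{need_ref}")
        ref_psi = _pooled_psi(ref_vals, ref_cov)
        con_psi = _pooled_psi(con_vals, con_cov)
        dpsi = con_psi - ref_psi
        if math.isnan(dpsi):
            reasons.append("no-psi")
            gap = spread_ref = spread_con = math.nan
        else:
            hi, lo = (con_vals, ref_vals) if con_psi >= ref_psi else (ref_vals, con_vals)
            gap = float(hi.min() - lo.max()) if hi.notna().any() and lo.notna().any() else math.nan
            spread_ref = float(ref_vals.max() - ref_vals.min()) if ref_vals.notna().any() else math.nan
            spread_con = float(con_vals.max() - con_vals.min()) if con_vals.notna().any() else math.nan
            if abs(dpsi) < min_dpsi:
                reasons.append("dpsi-below-threshold")
            if range_semantics == "gap":
                if not (gap >= min_gap):
                    reasons.append("gap-below-threshold")
            else:
                if not (spread_ref < max_spread and spread_con < max_spread):
                    reasons.append("spread-above-threshold")
        events.append(
            DiffEvent(
                event_id=str(event_id),
                ref_psi=ref_psi,
                contrast_psi=con_psi,
                dpsi=dpsi,
                gap=gap,
                spread_ref=spread_ref,
                spread_contrast=spread_con,
                n_ref=int(ref_vals.notna().sum()),
                n_contrast=int(con_vals.notna().sum()),
                passed=not reasons,
                reasons=reasons,
            )
        )
    return events


def diff_events_to_frame(events: Sequence[DiffEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "ref_psi": e.ref_psi,
                "contrast_psi": e.contrast_psi,
                "dpsi": e.dpsi,
                "gap": e.gap,
                "spread_ref": e.spread_ref,
                "spread_contrast": e.spread_contrast,
                "n_ref": e.n_ref,
                "n_contrast": e.n_contrast,
                "passed": e.passed,
                "reasons": ";".join(e.reasons),
            }
            for e in events
        ]
    )


def build_control_sets(
    psi: pd.DataFrame,
    groups: Mapping[str, str],
    reference: str,
    contrast: str,
) -> ControlSets:
    """Compute the exon- and intron-sense control sets from a PSI table.

    Group PSI is the plain replicate mean here (set definitions operate on
    the per-group summary PSI); spread is the within-group replicate range.
    """
    ref_ids = [s for s in psi.columns if groups.get(s) == reference]
    con_ids = [s for s in psi.columns if groups.get(s) == contrast]
    ref_psi = psi[ref_ids].mean(axis=1)
    con_psi = psi[con_ids].mean(axis=1)
    dpsi = con_psi - ref_psi
    spread = pd.concat(
        [
            psi[ref_ids].max(axis=1) - psi[ref_ids].min(axis=1),
            psi[con_ids].max(axis=1) - psi[con_ids].min(axis=1),
        ],
        axis=1,
    ).max(axis=1)

    defined = ref_psi.notna() & con_psi.notna()
    constitutive = (ref_psi > 95) & (con_psi > 95)
    alt_nc = (
        (((ref_psi > 10) & (ref_psi < 90)) | ((con_psi > 10) & (con_psi < 90)))
        & (dpsi.abs() <= 5)
    )
    cryptic = (ref_psi < 5) & (con_psi < 5)
    retained = (dpsi >= 15) & (spread < 5)
    more_spliced = (dpsi <= -15) & (spread < 5)
    nonchanging = (dpsi > -1) & (dpsi < 1) & (ref_psi > 5) & (ref_psi < 95)

    def ids(mask: pd.Series) -> List[str]:
        return list(psi.index[mask & defined])

    return ControlSets(
        constitutive=ids(constitutive),
        alternative_nonchanging=ids(alt_nc & ~constitutive & ~cryptic),
        cryptic_exon=ids(cryptic),
        retained=ids(retained),
        more_spliced=ids(more_spliced),
        nonchanging_intron=ids(nonchanging & ~retained & ~more_spliced),
    )


def event_type_enrichment(
    differential: Mapping[str, int],
    background: Mapping[str, int],
) -> pd.DataFrame:
    """Per-type two-proportion test: differential share vs background share.

    For each event type a continuity-corrected chi-square test on the 2x2
    table (type vs rest, differential vs background) is run.  Types with
    zero background count are skipped.  Raw and Benjamini-Hochberg adjusted
    p-values are both reported.
    """
    n_diff = sum(differential.values())
    n_bg = sum(background.values())
    if n_bg <= 0:
        raise ValueError("background totals must be positive")
    rows = []
    for etype in sorted(background):
        b = background[etype]
        if b == 0:
            continue
        d = differential.get(etype, 0)
        table = np.array([[d, n_diff - d], [b, n_bg - b]])
        if n_diff == 0:
            continue
        if (table.sum(axis=0) == 0).any():
            chi2, p = 0.0, 1.0  # a degenerate margin carries no signal
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        p_diff = d / n_diff
        p_bg = b / n_bg
        rows.append(
            {
                "event_type": etype,
                "n_differential": d,
                "n_background": b,
                "prop_differential": p_diff,
                "prop_background": p_bg,
                "direction": "enriched" if p_diff > p_bg else "depleted",
                "chi2": chi2,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df


def correlate_dpsi(
    dpsi_a: pd.Series,
    dpsi_b: pd.Series,
    event_types: Optional[pd.Series] = None,
    min_abs_dpsi: float = 15.0,
) -> pd.DataFrame:
    """Pearson R between two dPSI vectors, per event type.

    Events are paired on the shared index and kept when ``|dPSI| >=
    min_abs_dpsi`` in at least one of the two vectors.  Types with fewer
    than 3 pairs report R as NaN with a reason.
    """
    paired = pd.DataFrame({"a": dpsi_a, "b": dpsi_b}).dropna()
    keep = (paired["a"].abs() >= min_abs_dpsi) | (paired["b"].abs() >= min_abs_dpsi)
    paired = paired[keep]
    if paired.empty:
        return pd.DataFrame(
            [{"event_type": "all", "n": 0, "pearson_r": math.nan,
              "p_value": math.nan, "reason": "fewer-than-3-pairs"}]
        )
    if event_types is None:
        types = pd.Series("all", index=paired.index)
    else:
        types = event_types.reindex(paired.index)
    rows = []
    for etype, sub in paired.groupby(types):
        if len(sub) < 3:
            rows.append({"event_type": etype, "n": len(sub), "pearson_r": math.nan,
                         "p_value": math.nan, "reason": "fewer-than-3-pairs"})
            continue
        r, p = stats.pearsonr(sub["a"], sub["b"])
        rows.append({"event_type": etype, "n": len(sub), "pearson_r": float(r),
                     "p_value": float(p), "reason": ""})
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
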