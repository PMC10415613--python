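"""3' splice-site sequence features: site strength, branch points, polyY, GC.

The site-strength scorer is a trainable first-order (adjacent-position
dependence) log-odds model over a fixed k-mer frame — 23 nt for acceptors
(20 intronic positions ending in the AG, then 3 exonic positions) and 9 nt
for donors.  Scores are dimensionless log2-odds of the foreground (trained
splice sites) against a background (uniform, or trained from supplied
background sequences): 0 means indistinguishable from background, higher
means closer to the foreground consensus.  The model serializes to JSON and
reloads bit-exactly.  Exact parity with externally published score tables
is not a goal; externally computed tables can be plugged in through the
same JSON format.

Branch-point candidates are adenosines in a window upstream of the 3'ss
(default 18-44 nt) scored against a heptamer weight matrix built from the
yUnAy-type consensus (branch A at position 6 of 7); the polypyrimidine
strength is the weighted pyrimidine content between the best branch point
and the 3' AG (T weighted 1.0, C 0.75 — U-rich tracts bind U2AF more
tightly than C-rich ones).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diff import benjamini_hochberg

__all__ = [
    "SpliceSiteModel",
    "BranchPointCall",
    "GcProfile",
    "train_acceptor_model",
    "train_donor_model",
    "score_acceptor",
    "acceptor_context",
    "predict_branch_points",
    "gc_rna_map",
    "compare_features",
    "DEFAULT_BP_PWM",
]

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}

ACCEPTOR_LEN = 23  # 20 intronic (ending ...AG) + 3 exonic
DONOR_LEN = 9  # 3 exonic + 6 intronic (GT...)


@dataclass
class SpliceSiteModel:
    """First-order position-weight model with log-odds scoring contract."""

    length: int
    #: log2 P(x at position 0), shape (4,)
    start_fg: np.ndarray = field(repr=False, default=None)
    start_bg: np.ndarray = field(repr=False, default=None)
    #: log2 P(x_i | x_{i-1}) for i in 1..length-1, shape (length-1, 4, 4)
    trans_fg: np.ndarray = field(repr=False, default=None)
    trans_bg: np.ndarray = field(repr=False, default=None)
    n_training: int = 0
    pseudocount: float = 0.5

    def score(self, seq: str) -> float:
        """log2 odds of ``seq`` under foreground vs background."""
        seq = seq.upper()
        if len(seq) != self.length:
            raise ValueError(f"expected a {self.length}-mer, got length {len(seq)}")
        try:
            idx = [_IDX[b] for b in seq]
        except KeyError as exc:
            raise ValueError(f"non-ACGT character in sequence: {exc}") from exc
        s = self.start_fg[idx[0]] - self.start_bg[idx[0]]
        for i in range(1, self.length):
            s += self.trans_fg[i - 1, idx[i - 1], idx[i]]
            s -= self.trans_bg[i - 1, idx[i - 1], idx[i]]
        return float(s)

    def consensus(self) -> str:
        """Greedy chain maximizer of the foreground model."""
        out = [int(np.argmax(self.start_fg))]
        for i in range(1, self.length):
            out.append(int(np.argmax(self.trans_fg[i - 1, out[-1]])))
        return "".join(BASES[i] for i in out)

    def to_json(self, path: str) -> None:
        payload = {
            "format": "juncscope-splice-site-model/1",
            "length": self.length,
            "n_training": self.n_training,
            "pseudocount": self.pseudocount,
            "start_fg": self.start_fg.tolist(),
            "start_bg": self.start_bg.tolist(),
            "trans_fg": self.trans_fg.tolist(),
            "trans_bg": self.trans_bg.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SpliceSiteModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "juncscope-splice-site-model/1":
            raise ValueError(f"{path}: unrecognized model format")
        return cls(
            length=payload["length"],
            start_fg=np.array(payload["start_fg"]),
            start_bg=np.array(payload["start_bg"]),
            trans_fg=np.array(payload["trans_fg"]),
            trans_bg=np.array(payload["trans_bg"]),
            n_training=payload["n_training"],
            pseudocount=payload["pseudocount"],
        )


def _log_freqs(seqs: Sequence[str], length: int, pseudocount: float):
    start = np.full(4, pseudocount)
    trans = np.full((length - 1, 4, 4), pseudocount)
    for seq in seqs:
        idx = [_IDX[b] for b in seq]
        start[idx[0]] += 1
        for i in range(1, length):
            trans[i - 1, idx[i - 1], idx[i]] += 1
    start = np.log2(start / start.sum())
    trans = np.log2(trans / trans.sum(axis=2, keepdims=True))
    return start, trans


def _train(seqs: Sequence[str], length: int, background, pseudocount: float) -> SpliceSiteModel:
    seqs = [s.upper() for s in seqs]
    bad = [i for i, s in enumerate(seqs) if len(s) != length or any(b not in _IDX for b in s)]
    if bad:
        raise ValueError(
            f"training sequences must be ACGT {length}-mers; offenders at indices {bad[:10]}"
        )
    start_fg, trans_fg = _log_freqs(seqs, length, pseudocount)
    if background is None or background == "uniform":
        start_bg = np.full(4, math.log2(0.25))
        trans_bg = np.full((length - 1, 4, 4), math.log2(0.25))
    else:
        bg = [s.upper() for s in background]
        bad = [i for i, s in enumerate(bg) if len(s) != length or any(b not in _IDX for b in s)]
        if bad:
            raise ValueError(f"background sequences malformed at indices {bad[:10]}")
        start_bg, trans_bg = _log_freqs(bg, length, pseudocount)
    return SpliceSiteModel(
        length=length,
        start_fg=start_fg,
        start_bg=start_bg,
        trans_fg=trans_fg,
        trans_bg=trans_bg,
        n_training=len(seqs),
        pseudocount=pseudocount,
    )


def train_acceptor_model(
    sequences: Sequence[str], background="uniform", pseudocount: float = 0.5
) -> SpliceSiteModel:
    """Train the 23-mer acceptor model (20 intronic + 3 exonic positions)."""
    return _train(sequences, ACCEPTOR_LEN, background, pseudocount)


def train_donor_model(
    sequences: Sequence[str], background="uniform", pseudocount: float = 0.5
) -> SpliceSiteModel:
    """Train the 9-mer donor model (3 exonic + 6 intronic positions)."""
    return _train(sequences, DONOR_LEN, background, pseudocount)


def score_acceptor(model: SpliceSiteModel, seq: str) -> float:
    """Deterministic log-odds score of a 23-mer acceptor context."""
    return model.score(seq)


def acceptor_context(genome, chrom: str, acceptor: int, strand: str,
                     intronic: int = 20, exonic: int = 3) -> str:
    """Strand-aware 23-mer around an acceptor (1-based last intronic base).

    Returns intron[-intronic:] + exon[:exonic] in transcript orientation, so
    positions ``intronic-2``/``intronic-1`` hold the AG for a genuine site.
    """
    from Bio.Seq import Seq

    if strand == "-":
        raw = str(genome[chrom][acceptor - exonic - 1 : acceptor + intronic - 1])
        return str(Seq(raw).reverse_complement()).upper()
    return str(genome[chrom][acceptor - intronic : acceptor + exonic]).upper()


# Branch-point heptamer weight matrix: consensus nnyTrAy with the branch
# adenosine at position 6 of 7 (index 5).
DEFAULT_BP_PWM = np.array(
    [
        [0.25, 0.25, 0.25, 0.25],  # n
        [0.25, 0.25, 0.25, 0.25],  # n
        [0.15, 0.35, 0.15, 0.35],  # y
        [0.10, 0.15, 0.05, 0.70],  # T
        [0.40, 0.15, 0.30, 0.15],  # r
        [0.94, 0.02, 0.02, 0.02],  # branch A
        [0.15, 0.35, 0.15, 0.35],  # y
    ]
)
BP_BRANCH_INDEX = 5  # 0-based position of the branch A within the heptamer


@dataclass
class BranchPointCall:
    """Branch-point summary for one 3'ss."""

    candidates: List[Tuple[int, float]]  # (distance to 3'ss, score), all passing
    best_distance: Optional[int]
    best_score: Optional[float]
    n_candidates: int
    polyy_strength: Optional[float]

    @property
    def missing(self) -> bool:
        return self.best_distance is None


def _pwm_score(heptamer: str, pwm: np.ndarray) -> float:
    s = 0.0
    for i, b in enumerate(heptamer):
        s += math.log2(max(pwm[i, _IDX[b]], 1e-9) / 0.25)
    return s


def polyy_score(seq: str, t_weight: float = 1.0, c_weight: float = 0.75) -> float:
    """Weighted pyrimidine content of a tract (0 = purine-only, 1 = all T)."""
    if not seq:
        return 0.0
    w = {"T": t_weight, "C": c_weight}
    return sum(w.get(b, 0.0) for b in seq.upper()) / len(seq)


def predict_branch_points(
    intron_seq: str,
    window: Tuple[int, int] = (18, 44),
    min_score: float = 0.0,
    pwm: np.ndarray = DEFAULT_BP_PWM,
) -> BranchPointCall:
    """Score adenosines in a window upstream of the 3'ss as branch points.

    ``intron_seq`` is the intron in transcript orientation, ending with the
    acceptor AG.  A candidate's distance is counted from the branch A to the
    intron's 3' end (the last intronic base), so the window (18, 44) spans
    the classical 18-35 nt regime with margin.  The best branch point is the
    highest-scoring candidate (ties broken toward the 3'ss); polyY strength
    is computed on the tract between the best branch A and the acceptor AG.
    """
    seq = intron_seq.upper()
    lo, hi = window
    candidates: List[Tuple[int, float]] = []
    for i, base in enumerate(seq):
        dist = len(seq) - i
        if base != "A" or not lo <= dist <= hi:
            continue
        if i < BP_BRANCH_INDEX or i + (len(pwm) - BP_BRANCH_INDEX) > len(seq):
            continue
        heptamer = seq[i - BP_BRANCH_INDEX : i - BP_BRANCH_INDEX + len(pwm)]
        if any(b not in _IDX for b in heptamer):
            continue
        score = _pwm_score(heptamer, pwm)
        if score >= min_score:
            candidates.append((dist, score))
    if not candidates:
        return BranchPointCall([], None, None, 0, None)
    best_dist, best_score = max(candidates, key=lambda c: (c[1], -c[0]))
    branch_idx = len(seq) - best_dist
    tract = seq[branch_idx + 1 : len(seq) - 2]  # between branch A and the AG
    return BranchPointCall(
        candidates=sorted(candidates),
        best_distance=best_dist,
        best_score=best_score,
        n_candidates=len(candidates),
        polyy_strength=polyy_score(tract),
    )


@dataclass
class GcProfile:
    """Binned GC along a standardized exon|intron|exon model for one set."""

    label: str
    segments: Tuple[str, ...]
    bin_gc: np.ndarray  # (n_segments, bins) mean GC fraction
    coverage: np.ndarray  # (n_segments, bins) contributing region count
    mean_intron_gc: float
    gc_differential: float  # intron GC minus downstream-exon GC
    exon_flank: int
    intron_flank: int


def _gc(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else math.nan


def _bin_gc(seq: str, bins: int) -> np.ndarray:
    out = np.full(bins, np.nan)
    if not seq:
        return out
    edges = np.linspace(0, len(seq), bins + 1).astype(int)
    for i in range(bins):
        if edges[i + 1] > edges[i]:
            out[i] = _gc(seq[edges[i] : edges[i + 1]])
    return out


def gc_rna_map(
    region_sets: Mapping[str, Sequence[tuple]],
    genome,
    exon_flank: int = 50,
    intron_flank: int = 150,
    bins: int = 10,
) -> Dict[str, GcProfile]:
    """Mean GC per bin over a standardized exon/intron model, per region set.

    Each region is an intron ``(chrom, start, end, strand)`` (1-based
    inclusive).  Four segments are profiled in transcript orientation:
    upstream-exon tail, intron head, intron tail, downstream-exon head;
    intron flanks are clipped at half the intron length so head and tail
    never overlap.  Also reports each set's mean intron GC and the
    differential between intron GC and downstream-exon GC.
    """
    from Bio.Seq import Seq

    segments = ("exon_up", "intron_head", "intron_tail", "exon_down")
    profiles: Dict[str, GcProfile] = {}
    for label, regions in region_sets.items():
        gc_stack = []
        intron_gcs, diffs = [], []
        for chrom, start, end, strand in regions:
            intron = str(genome[chrom][start - 1 : end]).upper()
            left = str(genome[chrom][max(start - 1 - exon_flank, 0) : start - 1]).upper()
            right = str(genome[chrom][end : end + exon_flank]).upper()
            if strand == "-":
                intron = str(Seq(intron).reverse_complement())
                left, right = (
                    str(Seq(right).reverse_complement()),
                    str(Seq(left).reverse_complement()),
                )
            flank = min(intron_flank, len(intron) // 2)
            segs = (left, intron[:flank], intron[-flank:] if flank else "", right)
            gc_stack.append(np.stack([_bin_gc(s, bins) for s in segs]))
            intron_gcs.append(_gc(intron))
            diffs.append(_gc(intron) - _gc(right))
        if gc_stack:
            arr = np.stack(gc_stack)  # (n, 4, bins)
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(arr, axis=0)
            cov = np.sum(~np.isnan(arr), axis=0)
        else:
            mean = np.full((4, bins), np.nan)
            cov = np.zeros((4, bins), dtype=int)
        profiles[label] = GcProfile(
            label=label,
            segments=segments,
            bin_gc=mean,
            coverage=cov,
            mean_intron_gc=float(np.nanmean(intron_gcs)) if intron_gcs else math.nan,
            gc_differential=float(np.nanmean(diffs)) if diffs else math.nan,
            exon_flank=exon_flank,
            intron_flank=intron_flank,
        )
    return profiles


def compare_features(
    features: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
    feature_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney comparison of two row sets.

    ``features`` is indexed by site/event id.  For each numeric feature the
    medians, the normalized mean difference ((mean A - mean B) / pooled SD)
    and the exact-where-feasible Mann-Whitney p-value are reported, with
    Benjamini-Hochberg q-values across features.  Constant features in both
    sets report p = 1 with a tie warning.
    """
    a = features.loc[[i for i in set_a if i in features.index]]
    b = features.loc[[i for i in set_b if i in features.index]]
    cols = feature_columns or [c for c in features.columns if pd.api.types.is_numeric_dtype(features[c])]
    rows = []
    for col in cols:
        xa = a[col].dropna().to_numpy()
        xb = b[col].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            rows.append({"feature": col, "n_a": len(xa), "n_b": len(xb),
                         "median_a": np.nan, "median_b": np.nan,
                         "norm_mean_diff": np.nan, "u_statistic": np.nan,
                         "p_value": np.nan, "warning": "too-few-observations"})
            continue
        pooled_sd = math.sqrt((xa.var(ddof=1) + xb.var(ddof=1)) / 2)
        nmd = (xa.mean() - xb.mean()) / pooled_sd if pooled_sd > 0 else 0.0
        if np.ptp(np.concatenate([xa, xb])) == 0:
            u, p, warn = len(xa) * len(xb) / 2, 1.0, "all-tied"
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
            u, p, warn = float(res.statistic), float(res.pvalue), ""
        rows.append({"feature": col, "n_a": len(xa), "n_b": len(xb),
                     "median_a": float(np.median(xa)), "median_b": float(np.median(xb)),
                     "norm_mean_diff": nmd, "u_statistic": u, "p_value": p,
                     "warning": warn})
    df = pd.DataFrame(rows)
    ok = df["p_value"].notna()
    df["q_value"] = np.nan
    if ok.any():
        df.loc[ok, "q_value"] = benjamini_hochberg(df.loc[ok, "p_value"].to_numpy())
    return df


def acceptor_feature_table(
    sites: Iterable[tuple],
    genome,
    model: SpliceSiteModel,
    bp_window: Tuple[int, int] = (18, 44),
    bp_min_score: float = 0.0,
) -> pd.DataFrame:
    """The per-3'ss feature battery for a set of acceptor sites.

    ``sites`` yields ``(site_id, chrom, donor, acceptor, strand)`` with
    1-based intron-boundary coordinates.  Columns: 3'ss strength, BP
    strength, number of BP candidates, best-BP distance to the 3'ss, polyY
    strength, intron GC fraction.
    """
    from Bio.Seq import Seq

    rows = []
    for site_id, chrom, donor, acceptor, strand in sites:
        lo, hi = (donor, acceptor) if strand != "-" else (acceptor, donor)
        intron = str(genome[chrom][lo - 1 : hi]).upper()
        if strand == "-":
            intron = str(Seq(intron).reverse_complement())
        try:
            strength = model.score(acceptor_context(genome, chrom, acceptor, strand))
        except ValueError:
            strength = math.nan
        bp = predict_branch_points(intron, window=bp_window, min_score=bp_min_score)
        rows.append({
            "site_id": site_id,
            "acceptor_strength": strength,
            "bp_strength": bp.best_score if not bp.missing else math.nan,
            "n_bp": bp.n_candidates,
            "bp_distance": bp.best_distance if not bp.missing else math.nan,
            "polyy_strength": bp.polyy_strength if not bp.missing else math.nan,
            "intron_gc": _gc(intron),
        })
    return pd.DataFrame(rows).set_index("site_id")
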