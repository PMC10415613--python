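"""Splice-site scoring, branch points, polyY, GC maps and set comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from juncscope.features import (
    ACCEPTOR_LEN,
    SpliceSiteModel,
    acceptor_context,
    compare_features,
    gc_rna_map,
    polyy_score,
    predict_branch_points,
    score_acceptor,
    train_acceptor_model,
)


def random_kmers(rng, n, k=ACCEPTOR_LEN):
    return ["".join(rng.choice(list("ACGT"), size=k)) for _ in range(n)]


def test_training_on_background_gives_near_zero_scores():
    rng = np.random.default_rng(0)
    seqs = random_kmers(rng, 400)
    model = train_acceptor_model(seqs, background=seqs)
    for s in random_kmers(rng, 20):
        assert score_acceptor(model, s) == pytest.approx(0.0, abs=1e-9)


def test_consensus_scores_above_all_single_base_variants():
    rng = np.random.default_rng(1)
    consensus = "TTTTTTTTTTCTTTCTTTAGGCT"
    train = []
    for _ in range(300):
        chars = list(consensus)
        for j in rng.integers(0, ACCEPTOR_LEN, size=2):
            chars[j] = rng.choice(list("ACGT"))
        train.append("".join(chars))
    model = train_acceptor_model(train)
    model_consensus = model.consensus()
    best = model.score(model_consensus)
    for pos in range(ACCEPTOR_LEN):
        for base in "ACGT":
            if base == model_consensus[pos]:
                continue
            variant = model_consensus[:pos] + base + model_consensus[pos + 1 :]
            assert model.score(variant) <= best + 1e-9


def test_model_serialization_is_bit_exact(tmp_path):
    rng = np.random.default_rng(2)
    model = train_acceptor_model(random_kmers(rng, 100))
    path = tmp_path / "model.json"
    model.to_json(str(path))
    back = SpliceSiteModel.from_json(str(path))
    for s in random_kmers(rng, 100):
        assert back.score(s) == model.score(s)


def test_training_rejects_malformed_sequences():
    with pytest.raises(ValueError, match="offenders"):
        train_acceptor_model(["ACGT"])
    with pytest.raises(ValueError):
        score_acceptor(train_acceptor_model(["A" * 23]), "N" * 23)


def test_true_sites_outrank_shuffled_decoys(truth, genome):
    """Ranking AUC > 0.9 for planted canonical acceptors vs shuffled 23-mers."""
    contexts = []
    for chrom, s, e, strand in truth.annotated_introns():
        acc = e if strand == "+" else s
        contexts.append(acceptor_context(genome, chrom, acc, strand))
    model = train_acceptor_model(contexts)
    rng = np.random.default_rng(3)
    pos = [model.score(c) for c in contexts]
    neg = [model.score("".join(rng.permutation(list(c)))) for c in contexts]
    auc = np.mean([[p > n for n in neg] for p in pos])
    assert auc > 0.9


def test_acceptor_context_is_strand_aware(truth, genome):
    for g in truth.genes:
        ctx = acceptor_context(genome, g.chrom, g.canonical_acceptor, g.strand)
        assert len(ctx) == ACCEPTOR_LEN
        assert ctx[18:20] == "AG"  # planted acceptor dinucleotide, both strands


def test_branch_point_single_and_no_adenosine():
    seq = "C" * 270 + "CCCCCACCCC" + "CTTTTTTTTTTTTTTTTTAG"
    call = predict_branch_points(seq, min_score=-100)
    assert call.n_candidates == 1
    assert call.best_distance == 25
    none = predict_branch_points("C" * 100 + "TTTTTTTTTTTTTTTCTTAG", min_score=-100)
    assert none.n_candidates == 0 and none.missing


def test_planted_consensus_heptamer_is_best_branch_point():
    """A planted TACTAAC at distance 25 wins over random background >= 95%."""
    rng = np.random.default_rng(4)
    wins = 0
    n = 200
    for _ in range(n):
        bg = list(rng.choice(list("ACGT"), size=300, p=[0.2, 0.3, 0.3, 0.2]))
        i_a = 300 - 25
        bg[i_a - 5 : i_a + 2] = list("TACTAAC")
        bg[300 - 3 :] = list("CAG")
        call = predict_branch_points("".join(bg), min_score=0.0)
        if call.best_distance == 25:
            wins += 1
    assert wins / n >= 0.95


def test_polyy_strength_orders_tracts():
    assert polyy_score("TTTTTTTT") == 1.0
    assert polyy_score("GGGGAAAA") == 0.0
    assert polyy_score("TTTT") > polyy_score("CCCC") > polyy_score("CCAA")


def test_gc_map_degenerate_sequences():
    genome = {"c": "G" * 1000, "d": "AC" * 500}
    prof = gc_rna_map({"allg": [("c", 200, 500, "+")]}, genome, bins=5)["allg"]
    assert np.allclose(prof.bin_gc, 1.0)
    assert prof.mean_intron_gc == 1.0
    prof2 = gc_rna_map({"alt": [("d", 200, 500, "+")]}, genome, bins=5)["alt"]
    assert np.allclose(prof2.bin_gc, 0.5, atol=0.05)


def test_gc_map_strand_symmetry():
    rng = np.random.default_rng(5)
    fwd = "".join(rng.choice(list("ACGT"), size=1000))
    comp = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    g = {"f": fwd, "r": comp}
    L = len(fwd)
    pf = gc_rna_map({"x": [("f", 301, 700, "+")]}, g, bins=4)["x"]
    pr = gc_rna_map({"x": [("r", L - 700 + 1, L - 301 + 1, "-")]}, g, bins=4)["x"]
    assert np.allclose(pf.bin_gc, pr.bin_gc, equal_nan=True)
    assert pf.gc_differential == pytest.approx(pr.gc_differential)


def test_gc_separation_between_high_and_low_gc_introns():
    from juncscope.simulate import SimConfig, make_genome_annotation

    hi = make_genome_annotation(SimConfig(seed=9, n_genes=10, intron_gc=0.6))
    lo = make_genome_annotation(SimConfig(seed=10, n_genes=10, intron_gc=0.4))
    ph = gc_rna_map(
        {"hi": [(g.chrom, *g.canonical_junction, g.strand) for g in hi.genes]}, hi.genome
    )["hi"]
    pl = gc_rna_map(
        {"lo": [(g.chrom, *g.canonical_junction, g.strand) for g in lo.genes]}, lo.genome
    )["lo"]
    assert ph.bin_gc[1].mean() - pl.bin_gc[1].mean() >= 0.15  # intron-head bins


def exact_mannwhitney_p(x, y):
    """Exhaustive permutation distribution of the U statistic."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").statistic

    def u_stat(a, b):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in a for yi in b)

    u_x = u_stat(x, y)
    dev_obs = abs(u_x - n1 * len(y) / 2)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if abs(u_stat(a, b) - n1 * len(b) / 2) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


@pytest.mark.parametrize(
    "x,y",
    [
        ([1, 2, 3], [4, 5, 6]),
        ([1.5, 2.5, 9.0, 4.0], [3.0, 7.0, 8.0]),
        ([10, 20], [15, 25, 35]),
        ([1, 2, 3, 4], [5, 6, 7, 8]),
    ],
)
def test_mannwhitney_matches_exact_enumeration(x, y):
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert res.pvalue == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-12)
    # compare_features uses the same exact path for small tie-free sets
    df = pd.DataFrame({"v": x + y}, index=[f"i{k}" for k in range(len(x) + len(y))])
    out = compare_features(df, [f"i{k}" for k in range(len(x))],
                           [f"i{k}" for k in range(len(x), len(x) + len(y))])
    assert out.iloc[0]["p_value"] == pytest.approx(res.pvalue, abs=1e-12)


def test_compare_features_identical_and_constant_sets():
    df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], "w": [5.0] * 6},
                      index=list("abcdef"))
    out = compare_features(df, list("abc"), list("def"))
    assert (out["p_value"] == 1.0).all()
    assert out.set_index("feature").loc["w", "warning"] == "all-tied"


def test_weaker_cryptic_motifs_flagged_lower(truth, genome):
    """Cryptic 3'ss score lower than canonical on site strength, BP strength
    and polyY strength at q < 0.05 (the direction seen for branch-point-
    mutant-activated sites)."""
    from juncscope.features import acceptor_feature_table, train_acceptor_model

    contexts = []
    for chrom, s, e, strand in truth.annotated_introns():
        acc = e if strand == "+" else s
        contexts.append(acceptor_context(genome, chrom, acc, strand))
    model = train_acceptor_model(contexts)
    sites = []
    for g in truth.genes:
        donor = g.canonical_junction[0] if g.strand == "+" else g.canonical_junction[1]
        sites.append((g.gene_id + ".can", g.chrom, donor, g.canonical_acceptor, g.strand))
        sites.append((g.gene_id + ".cry", g.chrom, donor, g.cryptic_acceptor, g.strand))
    table = acceptor_feature_table(sites, genome, model)
    res = compare_features(
        table,
        [i for i in table.index if i.endswith(".cry")],
        [i for i in table.index if i.endswith(".can")],
    ).set_index("feature")
    for feat in ("acceptor_strength", "bp_strength", "polyy_strength"):
        assert res.loc[feat, "median_a"] < res.loc[feat, "median_b"]
        assert res.loc[feat, "q_value"] < 0.05
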